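"""Registration, resampling, tiling, augmentation and the two-color
rendering."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from ramanstain import preprocess
from ramanstain.phantom import BandImage, RGBImage, generate_sample
from ramanstain.preprocess import (
    AffineTransform,
    ControlPoints,
    PatchRecord,
    augment,
    draw_crop_offset,
    estimate_affine,
    tile,
    two_color,
    upsample2x,
    warp,
)


class TestUpsample2x:
    def test_constant_image_stays_constant(self):
        out = upsample2x(np.full((10, 12), 3.5))
        assert out.shape == (20, 24)
        assert np.all(out == 3.5)

    def test_linear_ramp_even_columns_equal_input(self):
        ramp = np.tile(np.arange(8.0), (4, 1))
        out = upsample2x(ramp)
        np.testing.assert_allclose(out[:, 0::2], np.repeat(ramp, 2, axis=0))
        # odd columns are midpoints (except the clamped last one)
        np.testing.assert_allclose(out[0, 1:-1:2], np.arange(7.0) + 0.5)

    def test_shape_doubles(self):
        assert upsample2x(np.zeros((100, 100))).shape == (200, 200)


class TestEstimateAffine:
    def test_identity_recovered(self):
        pts = ControlPoints([((x, y), (x, y)) for x, y in
                             [(0, 0), (10, 0), (0, 10), (7, 3)]])
        np.testing.assert_allclose(estimate_affine(pts).matrix,
                                   AffineTransform.identity().matrix, atol=1e-12)

    def test_known_affine_recovered_exactly(self):
        theta = math.radians(10.0)
        a = 1.1 * np.array([[math.cos(theta), -math.sin(theta)],
                            [math.sin(theta), math.cos(theta)]])
        t = np.array([5.0, -3.0])
        truth = AffineTransform(np.hstack([a, t[:, None]]))
        rng = np.random.default_rng(0)
        moving = rng.uniform(0, 100, (6, 2))
        fixed = truth.apply(moving)
        est = estimate_affine(ControlPoints(list(zip(map(tuple, moving),
                                                     map(tuple, fixed)))))
        np.testing.assert_allclose(est.matrix, truth.matrix, atol=1e-6)

    def test_collinear_points_rejected(self):
        pts = ControlPoints([((0, 0), (0, 0)), ((1, 1), (1, 1)), ((2, 2), (2, 2))])
        with pytest.raises(ValueError, match="collinear"):
            estimate_affine(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            estimate_affine(ControlPoints([((0, 0), (0, 0)), ((1, 0), (1, 0))]))


class TestWarp:
    def test_identity_transform_preserves_image(self):
        img = np.random.default_rng(0).random((16, 16))
        out = warp(img, AffineTransform.identity())
        np.testing.assert_allclose(out, img, atol=1e-12)

    def test_integer_translation_is_exact_shift(self):
        img = np.random.default_rng(1).random((16, 16))
        shift = AffineTransform(np.array([[1.0, 0.0, 3.0], [0.0, 1.0, 2.0]]))
        out = warp(img, shift)
        np.testing.assert_allclose(out[2:, 3:], img[:-2, :-3], atol=1e-12)

    def test_composition_matches_single_warp_on_smooth_image(self):
        ys, xs = np.mgrid[0:32, 0:32]
        img = np.sin(xs / 8.0) + np.cos(ys / 6.0)
        a = AffineTransform(np.array([[1.0, 0.0, 1.5], [0.0, 1.0, 0.5]]))
        b = AffineTransform(np.array([[0.98, 0.02, -1.0], [-0.02, 0.98, 2.0]]))
        two_step = warp(warp(img, a), b)
        one_step = warp(img, b.compose(a))
        interior = np.s_[6:-6, 6:-6]
        np.testing.assert_allclose(two_step[interior], one_step[interior], atol=0.02)


class TestTile:
    @staticmethod
    def _pair(h, w):
        rng = np.random.default_rng(0)
        srs = BandImage(rng.random((h, w, 2)).astype(np.float32), (2847.0, 2933.0))
        he = RGBImage(rng.random((h, w, 3)).astype(np.float32))
        return srs, he

    def test_exact_fit_single_patch(self):
        records = tile(*self._pair(500, 500))
        assert len(records) == 1 and records[0].origin == (0, 0)

    def test_1000px_image_gives_four_patches(self):
        records = tile(*self._pair(1000, 1000))
        assert len(records) == 4
        assert {r.origin for r in records} == {(0, 0), (0, 500), (500, 0), (500, 500)}

    def test_origins_always_in_bounds(self):
        records = tile(*self._pair(1234, 777), size=500, stride=300)
        for r in records:
            assert r.origin[0] + 500 <= 1234 and r.origin[1] + 500 <= 777

    def test_undersized_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="smaller"):
            assert tile(*self._pair(100, 100)) == []

    def test_tiles_reassemble_interior_exactly(self):
        srs, he = self._pair(1000, 1000)
        records = tile(srs, he)
        rebuilt = np.zeros_like(srs.values)
        for r in records:
            oy, ox = r.origin
            rebuilt[oy : oy + 500, ox : ox + 500] = r.srs_patch.values
        np.testing.assert_array_equal(rebuilt, srs.values)


class TestAugment:
    @staticmethod
    def _patch(h=500, w=500):
        rng = np.random.default_rng(0)
        return PatchRecord(
            BandImage(rng.random((h, w, 2)).astype(np.float32), (2847.0, 2933.0)),
            RGBImage(rng.random((h, w, 3)).astype(np.float32)),
            (0, 0),
        )

    def test_output_is_384_from_500(self):
        out = augment(self._patch(), crop=384, seed=0)
        assert out.srs_patch.shape[:2] == (384, 384)
        assert out.he_patch.shape[:2] == (384, 384)

    def test_same_seed_reproduces_both_members(self):
        a = augment(self._patch(), crop=384, seed=9)
        b = augment(self._patch(), crop=384, seed=9)
        np.testing.assert_array_equal(a.srs_patch.values, b.srs_patch.values)
        np.testing.assert_array_equal(a.he_patch.values, b.he_patch.values)
        assert a.origin == b.origin

    def test_crop_larger_than_patch_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            augment(self._patch(100, 100), crop=384, seed=0)

    def test_geometry_shared_between_members(self):
        # encode coordinates in both members: the same warp must act on both
        ys, xs = np.mgrid[0:500, 0:500].astype(float)
        coord = np.stack([ys / 500, xs / 500], axis=-1).astype(np.float32)
        patch = PatchRecord(
            BandImage(coord, (2847.0, 2933.0)),
            RGBImage(np.concatenate([coord, coord[..., :1]], axis=-1)),
            (0, 0),
        )
        out = augment(patch, crop=384, seed=3)
        np.testing.assert_allclose(out.srs_patch.values,
                                   out.he_patch.values[..., :2], atol=1e-6)

    def test_crop_offsets_uniform_chi_square(self):
        # offsets live on {0..116}^2; bin into 4x4 and test uniformity
        counts = np.zeros((4, 4))
        n = 4000
        for seed in range(n):
            rng = np.random.default_rng(seed)
            oy, ox = draw_crop_offset(rng, 117, 117)
            counts[min(oy * 4 // 117, 3), min(ox * 4 // 117, 3)] += 1
        # bins are near-uniform (117 = 4*29 + 1: the last bin holds 30/117)
        probs = np.array([29, 29, 29, 30]) / 117.0
        expected = np.outer(probs, probs).ravel() * n
        stat = ((counts.ravel() - expected) ** 2 / expected).sum()
        p = sps.chi2.sf(stat, counts.size - 1)
        assert p > 0.01

    def test_augment_uses_the_shared_offset_draw(self):
        patch = self._patch()
        for seed in (0, 5, 11):
            rng = np.random.default_rng(seed)
            expected = draw_crop_offset(rng, 117, 117)
            assert augment(patch, crop=384, seed=seed).origin == expected


class TestTwoColor:
    def test_equal_bands_zero_blue(self):
        vals = np.ones((8, 8, 2), dtype=np.float32)
        img = two_color(BandImage(vals, (2847.0, 2933.0)))
        assert np.all(img.values[:, :, 2] == 0.0)

    def test_red_channel_identically_zero(self, small_sample):
        img = two_color(small_sample.bands)
        assert np.all(img.values[:, :, 0] == 0.0)

    def test_lipid_pixels_green_dominant(self):
        sample = generate_sample(4, shape=(96, 96), grade_class="moderate",
                                 noise_sd=0.0)
        img = two_color(sample.bands)
        from ramanstain.phantom import CLASS_CODES

        ld = sample.mask.labels == CLASS_CODES["lipid_droplet"]
        assert ld.any()
        green = img.values[:, :, 1][ld]
        blue = img.values[:, :, 2][ld]
        assert np.all(green > blue)

    def test_missing_channels_rejected(self):
        bands = BandImage(np.ones((4, 4, 1), dtype=np.float32), (2879.0,))
        with pytest.raises(KeyError, match="2847"):
            two_color(bands)
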