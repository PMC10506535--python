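"""Phantom generator: spectral library, masks, forward model, H&E renders,
depth stacks, dataset determinism."""

import numpy as np
import pytest

from ramanstain import phantom
from ramanstain.phantom import (
    CLASS_CODES,
    DEFAULT_BANDS,
    ArtifactConfig,
    LabelMask,
    extended_library,
    generate_sample,
    generate_stack,
    generate_tissue_mask,
    make_axis,
    make_spectral_library,
    render_cube,
    render_he,
    sample_bands,
)


class TestAxis:
    def test_default_axis_covers_ch_window(self):
        axis = make_axis()
        assert axis.shifts[0] == 2800.0
        assert axis.shifts[-1] == 3104.0
        assert len(axis) == 77
        assert np.allclose(np.diff(axis.values), 4.0)

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError):
            phantom.WavenumberAxis((2800.0, 2800.0, 2808.0))

    def test_nearest_tie_goes_to_lower_shift(self):
        axis = make_axis()
        # 2846 is equidistant from 2844 and 2848 on the 4 cm^-1 grid
        assert axis.values[axis.nearest_index(2846.0)] == 2844.0
        assert axis.values[axis.nearest_index(2845.0)] == 2844.0
        assert axis.values[axis.nearest_index(2847.0)] == 2848.0


class TestSpectralLibrary:
    def test_classes_and_normalization(self, library):
        assert set(library.class_spectra) == {"stroma", "nuclei", "epithelium",
                                              "lipid_droplet"}
        for name in library.class_spectra:
            spec = library.spectrum(name)
            assert spec.max() == pytest.approx(1.0)
            assert np.all(spec >= 0)

    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_lipid_ch2_dominance_and_protein_ch3_dominance(self, seed):
        lib = make_spectral_library(seed)
        assert lib.ratio("lipid_droplet") > 1.0
        for name in ("stroma", "nuclei", "epithelium"):
            assert lib.ratio(name) < 1.0

    def test_threshold_separates_lipid_from_epithelium(self, library):
        thr = library.ld_ratio_threshold()
        assert library.ratio("epithelium") < thr < library.ratio("lipid_droplet")


class TestTissueMask:
    def test_partition_covers_image(self):
        mask = generate_tissue_mask(0, (96, 96), "moderate")
        assert sum(mask.class_counts().values()) == 96 * 96

    def test_no_glands_means_stroma_and_border_only(self):
        mask = generate_tissue_mask(0, (64, 64), "low", gland_count=0,
                                    ld_area_fraction=0.0)
        present = {k for k, v in mask.class_counts().items() if v > 0}
        assert present == {"stroma", "background"}

    def test_planted_fraction_within_tolerance(self):
        mask = generate_tissue_mask(11, (128, 128), "moderate",
                                    ld_area_fraction=0.05)
        ld = mask.area("lipid_droplet")
        epi_total = mask.area("epithelium") + ld
        assert 0.045 <= ld / epi_total <= 0.055

    def test_grade_controls_lumen_architecture(self):
        low = generate_tissue_mask(3, (128, 128), "low", ld_area_fraction=0.0)
        high = generate_tissue_mask(3, (128, 128), "high", ld_area_fraction=0.0)
        assert low.area("lumen") > 0
        assert high.area("lumen") == 0  # fused sheets

    def test_unattainable_fraction_reports_maximum(self):
        with pytest.raises(ValueError, match="unattainable"):
            generate_tissue_mask(0, (64, 64), "low", gland_count=0,
                                 ld_area_fraction=0.1)

    def test_seeded_determinism(self):
        a = generate_tissue_mask(5, (96, 96), "moderate")
        b = generate_tissue_mask(5, (96, 96), "moderate")
        np.testing.assert_array_equal(a.labels, b.labels)


class TestRenderCube:
    def test_noiseless_single_class_reproduces_spectrum(self, library):
        mask = LabelMask(np.full((64, 64), CLASS_CODES["stroma"], dtype=np.uint8))
        cube = render_cube(mask, library, noise_sd=0.0, blur_sigma=0.0,
                           brightness_amp=0.0)
        expected = np.broadcast_to(library.spectrum("stroma"), cube.shape)
        np.testing.assert_allclose(cube.values, expected, rtol=1e-6)

    def test_band_count_matches_axis(self, small_sample):
        assert small_sample.cube.shape[2] == 77

    def test_noise_sd_recovered_empirically(self, library):
        mask = LabelMask(np.full((64, 64), CLASS_CODES["stroma"], dtype=np.uint8))
        clean = render_cube(mask, library, brightness_amp=0.0)
        noisy = render_cube(mask, library, noise_sd=0.01, brightness_amp=0.0,
                            seed=3)
        resid_sd = np.std(noisy.values - clean.values)
        assert 0.008 <= resid_sd <= 0.012

    def test_missing_class_raises(self, library):
        mask = LabelMask(np.full((64, 64), CLASS_CODES["lumen"], dtype=np.uint8))
        with pytest.raises(KeyError, match="lumen"):
            render_cube(mask, library)


class TestSampleBands:
    def test_default_seven_channels(self, small_sample):
        assert small_sample.bands.shifts == tuple(float(f) for f in DEFAULT_BANDS)
        assert small_sample.bands.shape[2] == 7

    def test_exact_frequencies_are_bitwise_slices(self, library):
        mask = generate_tissue_mask(0, (64, 64), "low")
        cube = render_cube(mask, extended_library(library), noise_sd=0.01, seed=1)
        bands = sample_bands(cube, (2800.0, 2900.0, 3104.0))
        for k, f in enumerate((2800.0, 2900.0, 3104.0)):
            idx = cube.axis.nearest_index(f)
            np.testing.assert_array_equal(bands.values[:, :, k],
                                          cube.values[:, :, idx])

    def test_out_of_range_frequency_rejected(self, small_sample):
        with pytest.raises(ValueError, match="outside axis range"):
            sample_bands(small_sample.cube, (2700.0,))


class TestRenderHE:
    def test_ffpe_has_higher_contrast_every_seed(self):
        for seed in range(5):
            mask = generate_tissue_mask(seed, (96, 96), "low")
            ff = render_he(mask, "FF_HE", seed=seed)
            ffpe = render_he(mask, "FFPE_HE", seed=seed)
            for c in range(3):
                assert ffpe.values[:, :, c].std() > ff.values[:, :, c].std()

    def test_artifacts_rejected_on_ffpe(self):
        mask = generate_tissue_mask(0, (64, 64), "low")
        cfg = ArtifactConfig(kinds=frozenset({"freezing"}))
        with pytest.raises(ValueError, match="artifact-free"):
            render_he(mask, "FFPE_HE", artifacts=cfg)

    def test_all_four_artifact_kinds_selectable(self):
        mask = generate_tissue_mask(0, (96, 96), "low")
        cfg = ArtifactConfig(
            kinds=frozenset({"staining", "freezing", "knife_cut", "blurring"}),
            seed=1,
        )
        img = render_he(mask, "FF_HE", artifacts=cfg, seed=0)
        clean = render_he(mask, "FF_HE", seed=0)
        assert np.abs(img.values - clean.values).max() > 0.05

    def test_unknown_artifact_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown artifact"):
            ArtifactConfig(kinds=frozenset({"smudge"}))

    def test_knife_cut_is_one_straight_streak_of_configured_contrast(self):
        mask = generate_tissue_mask(2, (128, 128), "low", ld_area_fraction=0.0)
        contrast = 0.15
        cfg = ArtifactConfig(kinds=frozenset({"knife_cut"}),
                             params={"knife_cut": {"width": 3.0,
                                                   "contrast": contrast}},
                             seed=4)
        with_cut = render_he(mask, "FF_HE", artifacts=cfg, seed=0)
        clean = render_he(mask, "FF_HE", seed=0)
        diff = (with_cut.values - clean.values).mean(axis=2)
        changed = np.abs(diff) > 1e-6
        assert changed.any()
        # changed pixels form a thin straight band: fit a line, check residuals
        ys, xs = np.nonzero(changed)
        pts = np.stack([xs, ys], axis=1).astype(float)
        pts -= pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts, full_matrices=False)
        perp = pts @ vt[1]
        assert np.abs(perp).max() <= 2.5  # within the configured width
        # streak raised by ~contrast wherever no clipping occurred
        raised = diff[changed]
        assert np.median(raised) == pytest.approx(contrast, rel=0.2)

    def test_no_artifact_renders_differ_only_by_style_transform(self):
        mask = generate_tissue_mask(1, (64, 64), "low")
        ff = render_he(mask, "FF_HE", seed=9).values
        ffpe = render_he(mask, "FFPE_HE", seed=9).values
        # invert both global stretches where unclipped; the underlying
        # textured base must agree
        base_ff = (ff - 0.5) / 0.85 + 0.5
        base_ffpe = (ffpe - 0.5) / 1.25 + 0.5
        unclipped = (ffpe > 1e-6) & (ffpe < 1 - 1e-6) & (ff > 1e-6) & (ff < 1 - 1e-6)
        np.testing.assert_allclose(base_ff[unclipped], base_ffpe[unclipped],
                                   atol=1e-5)


class TestStacks:
    def test_depth_tags_follow_request(self):
        stack = generate_stack(0, [20.0, 30.0], shape=(64, 64))
        assert [s.cube.depth_um for s in stack] == [20.0, 30.0]
        assert [s.meta["depth_um"] for s in stack] == [20.0, 30.0]

    def test_zero_decorrelation_freezes_morphology(self):
        stack = generate_stack(1, [0.0, 20.0, 40.0], decorrelation=0.0,
                               shape=(64, 64))
        np.testing.assert_array_equal(stack[0].mask.labels, stack[1].mask.labels)
        np.testing.assert_array_equal(stack[0].mask.labels, stack[2].mask.labels)

    def test_nonzero_decorrelation_keeps_planes_similar_not_identical(self):
        stack = generate_stack(1, [0.0, 20.0], decorrelation=0.1, shape=(96, 96))
        a, b = stack[0].mask.labels, stack[1].mask.labels
        assert not np.array_equal(a, b)
        assert (a == b).mean() > 0.7  # adjacent planes stay similar

    def test_tumor_appears_only_beyond_onset_depth(self):
        stack = generate_stack(2, [0.0, 20.0, 40.0], shape=(96, 96),
                               grade_class="low", tumor_onset_depth=20.0)
        assert stack[0].meta["n_tumor_glands"] == 0
        assert stack[1].meta["n_tumor_glands"] > 0
        assert stack[2].meta["n_tumor_glands"] > 0
        # fused tumor sheets add epithelium at depth
        assert stack[1].mask.area("epithelium") > stack[0].mask.area("epithelium")


class TestDatasetAndSpectralConsistency:
    def test_dataset_rerun_is_byte_identical(self, tmp_path):
        cfg = {"seed": 7, "shape": (64, 64), "noise_sd": 0.01}
        m1 = phantom.generate_dataset(2, cfg, tmp_path / "a")
        m2 = phantom.generate_dataset(2, cfg, tmp_path / "b")
        assert m1["class_counts"] == m2["class_counts"]
        for entry in m1["samples"]:
            for f in entry["files"].values():
                assert (tmp_path / "a" / f).read_bytes() == (
                    tmp_path / "b" / f
                ).read_bytes()

    def test_grade_mix_bookkeeping(self, tmp_path):
        cfg = {"seed": 0, "shape": (64, 64),
               "grade_mix": {"low": 2, "moderate": 1, "high": 1}}
        manifest = phantom.generate_dataset(4, cfg, tmp_path / "mix")
        assert manifest["class_counts"] == {"low": 2, "moderate": 1, "high": 1}

    def test_noise_free_sample_segments_at_planted_threshold(self):
        """Ratio thresholding at the library midpoint recovers ≥99% of
        planted droplet pixels on artifact-free, noise-free renders."""
        from ramanstain import ldquant

        lib = make_spectral_library(21)
        mask = generate_tissue_mask(21, (96, 96), "moderate", ld_area_fraction=0.05)
        cube = render_cube(mask, extended_library(lib), noise_sd=0.0,
                           blur_sigma=0.0, seed=21)
        bands = sample_bands(cube)
        ratio, valid = ldquant.ratio_map(bands)
        seg = ldquant.segment_ld(ratio, lib.ld_ratio_threshold(), valid=valid)
        truth = mask.labels == CLASS_CODES["lipid_droplet"]
        recall = (seg & truth).sum() / truth.sum()
        precision = (seg & truth).sum() / max(seg.sum(), 1)
        assert recall >= 0.99
        assert precision >= 0.99
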