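"""Lipid-droplet quantification: ratio segmentation, densities,
heterogeneity, and the group statistics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ramanstain import ldquant, phantom
from ramanstain.ldquant import (
    ROIAnnotation,
    anova_oneway,
    heterogeneity,
    ld_density,
    ld_report,
    pairwise_t,
    ratio_map,
    segment_ld,
)
from ramanstain.phantom import BandImage


def _bands(s2847, s2933):
    vals = np.stack([s2847, s2933], axis=-1).astype(np.float32)
    return BandImage(vals, (2847.0, 2933.0))


def permutation_p(a, b, n_perm=100_000, seed=0):
    """Monte-Carlo permutation null for the pooled-variance t statistic
    (vectorized): the two-sided tail probability of |t| under relabeling."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, na + nb)), axis=1)
    perms = pooled[order]
    ga, gb = perms[:, :na], perms[:, na:]
    va = ga.var(axis=1, ddof=1)
    vb = gb.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ga.mean(axis=1) - gb.mean(axis=1)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    t_obs = ldquant._t_two_sample(a, b)[0]
    return float(np.mean(np.abs(t) >= abs(t_obs) - 1e-12))


class TestRatioMap:
    def test_equal_bands_give_unit_ratio(self):
        b = _bands(np.full((8, 8), 0.5), np.full((8, 8), 0.5))
        ratio, valid = ratio_map(b)
        assert valid.all()
        np.testing.assert_allclose(ratio, 1.0, rtol=1e-4)

    def test_zero_denominator_flagged_invalid(self):
        s2933 = np.full((4, 4), 0.5)
        s2933[0, 0] = 0.0
        ratio, valid = ratio_map(_bands(np.ones((4, 4)), s2933))
        assert not valid[0, 0] and valid[1, 1]

    def test_phantom_lipid_above_one_stroma_below(self, library):
        sample = phantom.generate_sample(5, shape=(96, 96),
                                         grade_class="moderate", noise_sd=0.0)
        ratio, _ = ratio_map(sample.bands)
        ld = sample.mask.labels == phantom.CLASS_CODES["lipid_droplet"]
        stroma = sample.mask.labels == phantom.CLASS_CODES["stroma"]
        assert np.all(ratio[ld] > 1.0)
        assert np.all(ratio[stroma] < 1.0)

    def test_missing_channels_rejected(self):
        b = BandImage(np.ones((4, 4, 1), dtype=np.float32), (2879.0,))
        with pytest.raises(KeyError):
            ratio_map(b)


class TestSegmentLd:
    def test_threshold_above_max_gives_empty_mask(self):
        ratio = np.random.default_rng(0).random((8, 8))
        assert not segment_ld(ratio, threshold=2.0).any()

    def test_min_size_removes_single_pixel_components(self):
        ratio = np.zeros((10, 10))
        ratio[2, 2] = 2.0  # isolated pixel
        ratio[5:7, 5:7] = 2.0  # 4-pixel blob
        mask = segment_ld(ratio, 1.0, min_size=2)
        assert not mask[2, 2]
        assert mask[5:7, 5:7].all()

    def test_monotone_in_threshold(self):
        ratio = np.random.default_rng(1).random((32, 32)) * 2
        lo = segment_ld(ratio, 0.8)
        hi = segment_ld(ratio, 1.2)
        assert not (hi & ~lo).any()  # higher threshold is a subset


class TestLdDensity:
    def test_empty_and_full_masks(self):
        roi = ROIAnnotation(np.ones((8, 8), dtype=bool), "low")
        assert ld_density(np.zeros((8, 8), bool), roi).density == 0.0
        assert ld_density(np.ones((8, 8), bool), roi).density == 1.0

    def test_polygon_roi(self):
        mask = np.zeros((20, 20), bool)
        mask[5:10, 5:10] = True
        poly = np.array([[4.5, 4.5], [10.5, 4.5], [10.5, 10.5], [4.5, 10.5]])
        res = ld_density(mask, ROIAnnotation(poly, "high"))
        assert 0.5 < res.density <= 1.0

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            ROIAnnotation(np.zeros((4, 4), bool), "low").mask()

    def test_count_mode(self):
        mask = np.zeros((10, 10), bool)
        mask[1, 1] = mask[5:7, 5:7] = True  # 2 components
        roi = ROIAnnotation(np.ones((10, 10), bool), "low")
        assert ld_density(mask, roi, mode="count").density == pytest.approx(2 / 100)


class TestHeterogeneity:
    def test_constant_values_zero(self):
        assert heterogeneity([4.0, 4.0, 4.0]) == 0.0

    def test_hand_case_one_to_five(self):
        # quartiles 2 and 4 by linear interpolation; IQR 2 over mean 3
        assert heterogeneity([1, 2, 3, 4, 5]) == pytest.approx(2 / 3, abs=1e-12)

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, c):
        base = np.array([0.2, 1.0, 3.0, 7.5, 9.0])
        assert heterogeneity(base * c) == pytest.approx(heterogeneity(base),
                                                        rel=1e-9)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            heterogeneity([-1.0, 1.0])


class TestAnova:
    def test_hand_example_sums_of_squares(self):
        # groups {1,2} and {5,6}: SSB = 16, SSW = 1, F = 16/(1/2) = 32
        f, p = anova_oneway([[1, 2], [5, 6]])
        assert f == pytest.approx(32.0, abs=1e-12)
        assert 0 < p < 0.05

    def test_identical_groups_f_zero(self):
        f, p = anova_oneway([[1, 2, 3], [1, 2, 3]])
        assert f == 0.0
        assert p == pytest.approx(1.0)

    def test_two_group_f_equals_t_squared(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 1, 12)
        f, pf = anova_oneway([a, b])
        t, pt = ldquant._t_two_sample(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert pf == pytest.approx(pt, rel=1e-10)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(m, 1, 9) for m in (0.0, 0.3, 1.0)]
        f, p = anova_oneway(groups)
        ref = sps.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            anova_oneway([[1.0, 1.0], [1.0, 1.0]])


class TestPairwiseT:
    def test_identical_groups(self):
        out = pairwise_t({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert out[("a", "b")]["t"] == 0.0
        assert out[("a", "b")]["p"] == pytest.approx(1.0)

    def test_hand_computed_t(self):
        # pooled SD = 1, mean diff -3, t = -3*sqrt(3/2)
        out = pairwise_t({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert out[("a", "b")]["t"] == pytest.approx(-3 * np.sqrt(1.5), rel=1e-12)

    def test_matches_scipy_pooled(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(1, 2, 11)
        out = pairwise_t({"a": a, "b": b})
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert out[("a", "b")]["t"] == pytest.approx(ref.statistic, rel=1e-10)
        assert out[("a", "b")]["p"] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.0, 1.0, 12)
        b = rng.normal(0.8, 1.0, 12)
        _, p = ldquant._t_two_sample(a, b)
        assert p == pytest.approx(permutation_p(a, b), abs=0.01)

    def test_all_pairs_covered(self):
        groups = {c: [0.0, 1.0] for c in ("w", "x", "y")}
        assert set(pairwise_t(groups)) == {("w", "x"), ("w", "y"), ("x", "y")}


@pytest.fixture(scope="module")
def cohort_stats():
    lib = phantom.make_spectral_library(0)
    cohort = phantom.generate_ld_cohort(0, n_per_class=8, shape=(80, 80))
    samples = [(item["bands"], ROIAnnotation(item["roi"], item["class"]))
               for item in cohort]
    stats = ld_report(samples, threshold=lib.ld_ratio_threshold(), min_size=0)
    return cohort, stats


class TestLdReport:
    def test_classes_separate_and_ordered(self, cohort_stats):
        _, stats = cohort_stats
        means = {c: np.mean(v) for c, v in stats.densities.items()}
        assert stats.anova_p < 0.01
        assert means["moderate"] > means["high"] > means["low"] > means["stroma"]

    def test_bookkeeping_counts(self, cohort_stats):
        _, stats = cohort_stats
        assert stats.n_per_class == {c: 8 for c in ("stroma", "low", "moderate",
                                                    "high")}

    def test_densities_match_planted_fractions(self, cohort_stats):
        cohort, stats = cohort_stats
        by_class = {}
        for item in cohort:
            by_class.setdefault(item["class"], []).append(item["planted_fraction"])
        for cls in ("low", "moderate", "high"):
            measured = np.asarray(stats.densities[cls])
            planted = np.asarray(by_class[cls])
            np.testing.assert_allclose(measured, planted, rtol=0.10)

    def test_single_class_rejected(self):
        lib = phantom.make_spectral_library(0)
        cohort = phantom.generate_ld_cohort(1, n_per_class=2, shape=(80, 80))
        samples = [(item["bands"], ROIAnnotation(item["roi"], "low"))
                   for item in cohort[:2]]
        with pytest.raises(ValueError):
            ld_report(samples, threshold=lib.ld_ratio_threshold())

    def test_small_class_excluded_with_warning(self):
        lib = phantom.make_spectral_library(0)
        cohort = phantom.generate_ld_cohort(2, n_per_class=3, shape=(80, 80))
        samples = [(item["bands"], ROIAnnotation(item["roi"], item["class"]))
                   for item in cohort
                   if item["class"] in ("low", "moderate", "high")]
        # drop all but one 'low' ROI; moderate and high keep their 3 each
        lows = [s for s in samples if s[1].class_label == "low"]
        keep = [s for s in samples if s[1].class_label != "low"] + lows[:1]
        with pytest.warns(UserWarning, match="excluded"):
            stats = ld_report(keep, threshold=lib.ld_ratio_threshold())
        assert "low" not in stats.densities
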