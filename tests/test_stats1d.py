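"""SPM/SnPM on 1D curves: scalar-test oracles, permutation enumeration,
threshold behavior and cluster geometry."""

import itertools

import numpy as np
import pytest
from scipy import stats as ss

from dynifs.phantom import simulate_cohort_curves
from dynifs.stats1d import (
    CurveSample,
    clusters,
    compare_curves,
    estimate_fwhm,
    normality_gate,
    rft_threshold,
    snpm_threshold,
    t_curve_paired,
    t_curve_two_sample,
)


class TestTCurves:
    def test_identical_groups_zero(self, rng):
        a = rng.normal(size=(5, 20))
        t, df = t_curve_two_sample(CurveSample(a, a.copy()))
        np.testing.assert_allclose(t, 0.0)
        assert df == 8

    def test_matches_scipy_scalar_test_per_node(self, rng):
        a = rng.normal(size=(8, 15)) + 1.0
        b = rng.normal(size=(12, 15))
        t, df = t_curve_two_sample(CurveSample(a, b))
        for j in range(15):
            ref = ss.ttest_ind(a[:, j], b[:, j]).statistic
            assert t[j] == pytest.approx(ref, rel=1e-12)
        assert df == 18

    def test_location_invariance(self, rng):
        a = rng.normal(size=(6, 10))
        b = rng.normal(size=(7, 10))
        t1, _ = t_curve_two_sample(CurveSample(a, b))
        t2, _ = t_curve_two_sample(CurveSample(a + 100.0, b + 100.0))
        np.testing.assert_allclose(t1, t2, atol=1e-9)

    def test_paired_matches_scipy(self, rng):
        a = rng.normal(size=(9, 12)) + 0.5
        b = rng.normal(size=(9, 12))
        t, df = t_curve_paired(CurveSample(a, b, paired=True))
        for j in range(12):
            ref = ss.ttest_rel(a[:, j], b[:, j]).statistic
            assert t[j] == pytest.approx(ref, rel=1e-12)
        assert df == 8

    def test_paired_equals_one_sample_on_differences(self, rng):
        a = rng.normal(size=(6, 8))
        b = rng.normal(size=(6, 8))
        t, _ = t_curve_paired(CurveSample(a, b, paired=True))
        for j in range(8):
            ref = ss.ttest_1samp(a[:, j] - b[:, j], 0.0).statistic
            assert t[j] == pytest.approx(ref, rel=1e-12)

    def test_sign_flip_negates_paired_curve(self, rng):
        a = rng.normal(size=(6, 8))
        b = rng.normal(size=(6, 8))
        t1, _ = t_curve_paired(CurveSample(a, b, paired=True))
        t2, _ = t_curve_paired(CurveSample(b, a, paired=True))
        np.testing.assert_allclose(t1, -t2, atol=1e-12)

    def test_affine_rescaling_invariance(self, rng):
        a = rng.normal(size=(6, 10))
        b = rng.normal(size=(7, 10))
        t1, _ = t_curve_two_sample(CurveSample(a, b))
        t2, _ = t_curve_two_sample(CurveSample(3.0 * a - 7.0, 3.0 * b - 7.0))
        np.testing.assert_allclose(t1, t2, atol=1e-9)


class TestNormalityGate:
    def test_gaussian_selects_spm(self):
        hits = sum(
            normality_gate(CurveSample(
                *simulate_cohort_curves(n_a=10, n_b=10, seed=i))) == "SPM"
            for i in range(50)
        )
        assert hits >= 45

    def test_heavy_tailed_selects_snpm(self, rng):
        hits = 0
        for _ in range(50):
            a = 30 + rng.standard_t(2, size=(10, 101))
            b = 30 + rng.standard_t(2, size=(10, 101))
            hits += normality_gate(CurveSample(a, b)) == "SnPM"
        assert hits >= 45

    def test_tiny_sample_defaults_to_snpm(self, rng):
        a = rng.normal(size=(2, 10))
        b = rng.normal(size=(2, 10))
        with pytest.warns(UserWarning, match="too small"):
            assert normality_gate(CurveSample(a, b)) == "SnPM"


class TestRftThreshold:
    def test_smooth_limit_approaches_pointwise_quantile(self, rng):
        # nearly constant-in-node residuals -> huge FWHM
        base = rng.normal(size=(20, 1))
        res = np.repeat(base, 101, axis=1) + rng.normal(size=(20, 101)) * 1e-9
        t_star = rft_threshold(19, res, alpha=0.05)
        assert t_star == pytest.approx(ss.t.isf(0.025, 19), rel=0.02)

    def test_monotone_in_alpha_and_fwhm(self, rng):
        a, b = simulate_cohort_curves(n_a=12, n_b=12, seed=3)
        res = np.vstack([a - a.mean(0), b - b.mean(0)])
        t1 = rft_threshold(22, res, alpha=0.01)
        t2 = rft_threshold(22, res, alpha=0.05)
        t3 = rft_threshold(22, res, alpha=0.20)
        assert t1 > t2 > t3
        rough_a, rough_b = simulate_cohort_curves(n_a=12, n_b=12, fwhm_nodes=3, seed=3)
        rough = np.vstack([rough_a - rough_a.mean(0), rough_b - rough_b.mean(0)])
        assert rft_threshold(22, rough, alpha=0.05) > t2

    def test_fwhm_recovered_from_smooth_noise(self):
        a, b = simulate_cohort_curves(n_a=40, n_b=40, fwhm_nodes=15.0, seed=11)
        res = np.vstack([a - a.mean(0), b - b.mean(0)])
        assert estimate_fwhm(res) == pytest.approx(15.0, rel=0.15)

    def test_constant_residuals_rejected(self):
        with pytest.raises(ValueError):
            estimate_fwhm(np.zeros((5, 10)))


class TestSnpm:
    def test_paired_n5_exhaustive_matches_hand_enumeration(self, rng):
        """n = 5 pairs: all 2^5 = 32 sign flips, hand-coded oracle."""
        d = rng.normal(size=(5, 7)) + 0.8
        a = d + 30.0
        b = np.full((5, 7), 30.0)
        sample = CurveSample(a, b, paired=True)
        t_star, maxt = snpm_threshold(sample, alpha=0.05, n_perm=10_000, seed=0)
        assert maxt.shape[0] == 32

        hand = []
        diffs = a - b
        for signs in itertools.product((1.0, -1.0), repeat=5):
            sd = np.asarray(signs)[:, None] * diffs
            m = sd.sum(axis=0) / 5
            v = ((sd**2).sum(axis=0) - 5 * m**2) / 4
            t = m / np.sqrt(v / 5)
            hand.append(np.abs(t).max())
        hand = np.sort(hand)
        assert np.array_equal(np.sort(maxt), hand)  # bit-exact enumeration
        assert t_star == hand[::-1][int(np.floor(0.05 * 32))]

    def test_fixed_seed_determinism(self, rng):
        a = rng.normal(size=(12, 30))
        b = rng.normal(size=(14, 30))
        s = CurveSample(a, b)
        t1, m1 = snpm_threshold(s, n_perm=500, seed=42)
        t2, m2 = snpm_threshold(s, n_perm=500, seed=42)
        assert t1 == t2
        np.testing.assert_array_equal(m1, m2)

    def test_too_few_permutations_rejected(self, rng):
        a = rng.normal(size=(2, 10))
        b = rng.normal(size=(2, 10))
        with pytest.raises(ValueError, match="unreachable"):
            snpm_threshold(CurveSample(a, b, paired=True), alpha=0.05)

    def test_null_fwer_near_alpha(self):
        """Family-wise error of the max-statistic threshold under the null."""
        rej = 0
        n = 400
        for i in range(n):
            a, b = simulate_cohort_curves(n_a=12, n_b=18, effect_mm=0.0,
                                          seed=60_000 + i)
            r = compare_curves(CurveSample(a, b), n_perm=500, seed=i, method="SnPM")
            rej += r.significant
        assert 0.02 <= rej / n <= 0.08


class TestClusters:
    def test_below_threshold_empty(self):
        assert clusters(np.ones(101), 2.0, perm_maxt=np.ones(10)) == []

    def test_exact_node_crossings(self):
        t = np.zeros(101)
        t[40:61] = 3.0
        t[40] = 2.0
        t[60] = 2.0
        out = clusters(t, 2.0, perm_maxt=np.array([10.0]))
        assert len(out) == 1
        s, e, _ = out[0]
        assert 40.0 <= s <= 41.0 and 59.0 <= e <= 60.0

    def test_linear_interpolation_hand_value(self):
        """t = 1.9 at 40 %, 2.1 at 41 %, threshold 2.0 -> start 40.50 %."""
        t = np.zeros(101)
        t[40] = 1.9
        t[41:50] = 2.1
        t[50:] = 0.0
        out = clusters(t, 2.0, perm_maxt=np.array([10.0]))
        assert out[0][0] == pytest.approx(40.50, abs=1e-9)

    def test_mirror_symmetry(self, rng):
        t = np.abs(rng.normal(size=101)) * 2
        fwd = clusters(t, 1.5, perm_maxt=np.full(100, 3.0))
        rev = clusters(t[::-1], 1.5, perm_maxt=np.full(100, 3.0))
        mirrored = sorted((round(100 - e, 2), round(100 - s, 2), p) for s, e, p in rev)
        assert sorted(fwd) == mirrored

    def test_cluster_p_from_permutation_tail(self):
        t = np.zeros(101)
        t[50] = 5.0
        maxt = np.array([1.0, 2.0, 6.0, 7.0])
        out = clusters(t, 2.5, perm_maxt=maxt)
        assert out[0][2] == pytest.approx(0.5)


class TestCompareCurves:
    def test_identical_groups_no_clusters(self, rng):
        a = 30 + rng.normal(size=(10, 101))
        r = compare_curves(CurveSample(a, a.copy()), n_perm=200, seed=0,
                           method="SnPM")
        assert not r.significant

    def test_effect_detected_in_window(self):
        a, b = simulate_cohort_curves(n_a=18, n_b=12, effect_mm=6.0,
                                      noise_sd_mm=2.0, seed=5)
        r = compare_curves(CurveSample(a, b), n_perm=1000, seed=5)
        assert r.significant
        assert any(s < 80.0 and e > 40.0 for s, e, _ in r.clusters)

    def test_json_roundtrip(self):
        import json

        a, b = simulate_cohort_curves(n_a=12, n_b=12, effect_mm=6.0, seed=2)
        r = compare_curves(CurveSample(a, b), n_perm=200, seed=2)
        payload = json.loads(r.to_json())
        assert payload["alpha"] == 0.05
        assert len(payload["t_curve"]) == 101
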