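"""Group statistics: pseudo-t, max-statistics permutation, FDR, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from critmf.simulate import simulate_feature_cohort, synthetic_label_map
from critmf.stats import (bh_fdr, clinical_correlation, maxstat_permutation,
                          mediation_check, pseudo_t, roi_average)


class TestRoiAverage:
    def test_identity_partition(self, rng):
        X = rng.normal(size=(5, 12))
        labels = synthetic_label_map(12, 12)
        out = roi_average(X, labels)
        np.testing.assert_allclose(out.to_numpy(), X)

    def test_simple_mean(self):
        X = np.array([[0.4, 0.8]])
        labels = pd.DataFrame({"node_id": [0, 1], "roi_id": [0, 0],
                               "roi_name": ["a", "a"]})
        assert roi_average(X, labels).to_numpy()[0, 0] == pytest.approx(0.6)

    def test_atlas_scale_width(self, rng):
        X = rng.normal(size=(2, 8196))
        out = roi_average(X, synthetic_label_map(8196, 148))
        assert out.shape == (2, 148)

    def test_unmapped_node_raises(self, rng):
        labels = synthetic_label_map(4, 2)
        with pytest.raises(KeyError):
            roi_average(rng.normal(size=(2, 6)), labels)


class TestPseudoT:
    def test_identical_groups_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert pseudo_t(a, a.copy(), s0=0.1) == pytest.approx(0.0)

    def test_constant_groups(self):
        a, b = np.ones(4), np.zeros(4)
        with pytest.raises(ZeroDivisionError):
            pseudo_t(a, b, s0=0.0)
        assert pseudo_t(a, b, s0=0.5) == pytest.approx(2.0)  # 1 / s0

    def test_hand_computed_value(self):
        t = pseudo_t(np.array([1.0, 2, 3]), np.array([0.0, 1, 2]), s0=0.0)
        assert t == pytest.approx(1 / np.sqrt(2 / 3), abs=1e-12)

    @given(shift=st.floats(-5, 5), scale=st.floats(0.1, 10))
    def test_shift_invariance(self, shift, scale):
        """Adding a constant to every subject leaves t unchanged."""
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=6), rng.normal(size=5)
        t0 = pseudo_t(a, b, s0=0.1)
        t1 = pseudo_t(a + shift, b + shift, s0=0.1)
        assert t1 == pytest.approx(t0, rel=1e-9)


class TestMaxstat:
    def test_exhaustive_small_cohort_matches_oracle(self, maxstat_enum_oracle, rng):
        X = rng.normal(size=(8, 5))
        groups = np.array(["a"] * 4 + ["b"] * 4)
        res = maxstat_permutation(X, groups, n_perm=100, alpha=0.05, seed=0)
        assert res.exact and res.n_perm == 70
        p_oracle, thr_oracle, _ = maxstat_enum_oracle(
            X, 4, res.s0, res.t, 0.05)
        np.testing.assert_allclose(res.p_corrected, p_oracle, atol=1e-12)
        assert res.threshold == pytest.approx(thr_oracle)

    def test_injected_shift_reaches_min_p(self, rng):
        X, g = simulate_feature_cohort(10, 30, effect_nodes=[7],
                                       effect_size=0.45, noise_sd=0.1, seed=3)
        res = maxstat_permutation(X, g, n_perm=199, alpha=0.05, seed=1)
        assert not res.exact
        assert res.p_corrected[7] == pytest.approx(1 / 200)
        assert res.mask[7]

    def test_node_reordering_invariance(self, rng):
        X, g = simulate_feature_cohort(8, 12, seed=5)
        perm = rng.permutation(12)
        res1 = maxstat_permutation(X, g, n_perm=200, seed=9)
        res2 = maxstat_permutation(X[:, perm], g, n_perm=200, seed=9)
        np.testing.assert_allclose(res1.p_corrected[perm], res2.p_corrected)

    def test_constant_offset_invariance(self, rng):
        X, g = simulate_feature_cohort(8, 12, seed=6)
        res1 = maxstat_permutation(X, g, n_perm=200, seed=2)
        res2 = maxstat_permutation(X + 3.7, g, n_perm=200, seed=2)
        np.testing.assert_allclose(res1.p_corrected, res2.p_corrected, atol=1e-9)

    def test_p_bounds_and_mask_consistency(self, rng):
        X, g = simulate_feature_cohort(12, 20, seed=8)
        res = maxstat_permutation(X, g, n_perm=300, seed=4)
        assert np.all(res.p_corrected >= 1 / 301)
        assert np.all(res.p_corrected <= 1.0)
        np.testing.assert_array_equal(res.mask, res.p_corrected <= res.alpha)

    def test_n_perm_floor(self, rng):
        X, g = simulate_feature_cohort(10, 5, seed=0)
        with pytest.raises(ValueError):
            maxstat_permutation(X, g, n_perm=50)


class TestBhFdr:
    def test_all_ones_no_discoveries(self):
        q, mask = bh_fdr(np.ones(10), 0.05)
        assert not mask.any()

    def test_hand_stepup_case(self):
        q, mask = bh_fdr([0.01, 0.02, 0.03, 0.5], 0.05)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])
        np.testing.assert_array_equal(mask, [True, True, True, False])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12),
           st.sampled_from([0.01, 0.05, 0.1, 0.25]))
    def test_matches_stepup_oracle(self, bh_oracle, pvals, alpha):
        q, mask = bh_fdr(pvals, alpha)
        q_o, mask_o = bh_oracle(pvals, alpha)
        np.testing.assert_allclose(q, q_o, atol=1e-12)
        np.testing.assert_array_equal(mask, mask_o)

    def test_ties_handled(self, bh_oracle):
        p = [0.02, 0.02, 0.02, 0.9, 0.9]
        q, mask = bh_fdr(p, 0.05)
        q_o, mask_o = bh_oracle(p, 0.05)
        np.testing.assert_allclose(q, q_o)
        np.testing.assert_array_equal(mask, mask_o)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2], 0.05)

    def test_false_discovery_proportion_controlled(self):
        """Under the global null the FDP stays at or below alpha on average."""
        rng = np.random.default_rng(12)
        fdp = []
        for _ in range(300):
            p = rng.uniform(size=40)
            _, mask = bh_fdr(p, 0.05)
            fdp.append(mask.mean() if mask.any() else 0.0)
        assert np.mean(fdp) <= 0.05 + 0.01


class TestClinicalCorrelation:
    def test_perfect_coupling(self, rng):
        X = rng.normal(size=(20, 3))
        res = clinical_correlation(X, X[:, 1], method="pearson")
        assert res.r[1] == pytest.approx(1.0)
        assert res.p[1] < 1e-10

    def test_null_covariate_fdr_rarely_fires(self):
        empty = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(25, 100))
            cov = rng.normal(size=25)
            res = clinical_correlation(X, cov, method="pearson", alpha=0.05)
            raw_hits = (res.p < 0.05).sum()
            assert raw_hits <= 15  # E = 5, generous MC bound
            empty += not res.mask.any()
        assert empty >= 15

    def test_spearman_uncorrected_tag(self, rng):
        X = rng.normal(size=(15, 4))
        res = clinical_correlation(X, rng.normal(size=15), method="spearman")
        assert res.q is None and not res.corrected

    def test_missing_covariates_dropped(self, rng):
        X = rng.normal(size=(12, 3))
        cov = rng.normal(size=12)
        cov[:4] = np.nan
        res = clinical_correlation(X, cov)
        assert res.n_used == 8

    def test_pearson_affine_spearman_monotone_invariance(self, rng):
        X = rng.normal(size=(18, 2))
        cov = rng.normal(size=18)
        r0 = clinical_correlation(X, cov, "pearson").r
        r1 = clinical_correlation(X, 3.0 * cov + 2.0, "pearson").r
        np.testing.assert_allclose(r0, r1, atol=1e-12)
        s0 = clinical_correlation(X, cov, "spearman").r
        s1 = clinical_correlation(X, np.exp(cov), "spearman").r
        np.testing.assert_allclose(s0, s1, atol=1e-12)

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValueError):
            clinical_correlation(rng.normal(size=(10, 2)), np.ones(10))

    def test_too_few_subjects_rejected(self, rng):
        cov = np.full(10, np.nan)
        cov[:3] = 1.0
        with pytest.raises(ValueError):
            clinical_correlation(rng.normal(size=(10, 2)), cov)


class TestMediation:
    def test_independent_dose(self, rng):
        score = rng.normal(size=200)
        out = mediation_check(score, rng.normal(size=200))
        assert out["r2"] < 0.05

    def test_identical_dose(self, rng):
        score = rng.normal(size=30)
        out = mediation_check(score, score)
        assert out["r2"] == pytest.approx(1.0)

    def test_generator_rho_recovered(self):
        """cor(score, dose) = 0.55 in the generator gives R^2 near 0.30."""
        rho = 0.55
        r2 = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            score = rng.normal(size=25)
            dose = rho * score + np.sqrt(1 - rho**2) * rng.normal(size=25)
            r2.append(mediation_check(score, dose)["r2"])
        assert np.mean(r2) == pytest.approx(rho**2, abs=0.1)

    def test_constant_inputs_rejected(self):
        with pytest.raises(ValueError):
            mediation_check(np.ones(10), np.arange(10.0))
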