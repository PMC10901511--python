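import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import mprakit as mk
from mprakit.activity import allele_qc_matrix, fit_nb_da
from mprakit.exceptions import EstimationError, InputError


def nb_counts(rng, mean, dispersion, size):
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean), size=size)


@pytest.fixture(scope="module")
def null_activity():
    """2,500 targets, no treatment effect, both directions (5,000 tests)."""
    cfg = mk.SimConfig(n_targets=2500, mean_depth=300, da_frac=0.0,
                       nb_dispersion=0.05, frac_ase=0.0, frac_case=0.0,
                       frac_negative_control=0.0, seed=77)
    _, truth = mk.simulate_library(cfg)
    counts, samples = mk.simulate_activity_counts(truth, cfg)
    return mk.ActivityModel(counts, samples).fit()


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = pd.DataFrame({"s1": [10, 20, 5], "s2": [10, 20, 5]})
        np.testing.assert_allclose(mk.size_factors(m), [1.0, 1.0])

    def test_doubled_column_has_double_factor(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 100, size=5)
        m = pd.DataFrame({"s1": base, "s2": 2 * base, "s3": base})
        f = mk.size_factors(m)
        assert f["s2"] / f["s1"] == pytest.approx(2.0)
        # hand-computed median-of-ratios on the same toy
        logc = np.log(m.to_numpy(float))
        expect = np.exp(np.median(logc - logc.mean(1, keepdims=True), axis=0))
        expect /= np.exp(np.mean(np.log(expect)))
        np.testing.assert_allclose(f, expect)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.integers(1, 200, size=(20, 4)))
        f1 = mk.size_factors(m)
        f2 = mk.size_factors(m.sample(frac=1, random_state=2))
        np.testing.assert_allclose(f1, f2)


class TestNbFit:
    def _labels(self, n_rep):
        cond = np.array(["control"] * n_rep + ["caffeine"] * n_rep)
        return cond

    def test_noise_free_doubling_recovers_unit_lfc(self):
        # caffeine mean exactly twice control, both alleles, no noise
        n_rep = 6
        cond = np.tile(self._labels(n_rep), 2)
        allele = np.repeat(["ref", "alt"], 2 * n_rep)
        y = np.where(cond == "caffeine", 20000, 10000).astype(float)
        res = fit_nb_da(y, allele, cond, np.zeros_like(y), target_id="t")
        assert res.lfc_treatment == pytest.approx(1.0, abs=1e-3)

    def test_all_zero_condition_is_untested(self):
        n_rep = 3
        cond = np.tile(self._labels(n_rep), 2)
        allele = np.repeat(["ref", "alt"], 2 * n_rep)
        y = np.where(cond == "caffeine", 0, 100).astype(float)
        with pytest.raises(EstimationError, match="all-zero"):
            fit_nb_da(y, allele, cond, np.zeros_like(y))

    def test_wald_matches_poisson_lr_oracle_at_low_dispersion(self):
        """dispersion -> 0: Wald agrees with a Poisson LRT within 10%."""
        rng = np.random.default_rng(3)
        n_rep = 6
        cond = np.tile(self._labels(n_rep), 2)
        allele = np.repeat(["ref", "alt"], 2 * n_rep)
        X_full = np.column_stack([np.ones(4 * n_rep),
                                  (allele == "alt").astype(float),
                                  (cond == "caffeine").astype(float)])
        checked = 0
        for _ in range(50):
            lfc = rng.normal(0, 0.15)
            mean = 500 * 2.0 ** (lfc * (cond == "caffeine"))
            y = rng.poisson(mean).astype(float)
            # dispersion pinned at its floor: the Poisson limit of the NB GLM
            res = fit_nb_da(y, allele, cond, np.zeros_like(y), alpha=1e-8)
            full = sm.GLM(y, X_full, family=sm.families.Poisson()).fit()
            red = sm.GLM(y, X_full[:, :2],
                         family=sm.families.Poisson()).fit()
            lr = 2 * (full.llf - red.llf)
            oracle = np.sign(full.params[2]) * np.sqrt(max(lr, 0.0))
            if abs(oracle) > 1.0:
                checked += 1
                assert np.sign(res.wald) == np.sign(oracle)
                assert abs(res.wald) == pytest.approx(abs(oracle), rel=0.10)
        assert checked >= 20

    def test_count_doubling_absorbed_by_size_factors(self):
        rng = np.random.default_rng(4)
        cfg = mk.SimConfig(n_targets=20, da_frac=0.5, da_lfc_sd=1.0,
                           frac_negative_control=0.0, seed=8)
        _, truth = mk.simulate_library(cfg)
        counts, samples = mk.simulate_activity_counts(truth, cfg)
        r1 = mk.ActivityModel(counts, samples).fit()
        r2 = mk.ActivityModel(counts * 2, samples).fit()
        # lfc is invariant up to the dispersion refit on the rescaled counts
        np.testing.assert_allclose(r1.frame["lfc_treatment"],
                                   r2.frame["lfc_treatment"], atol=0.02)


class TestClassification:
    def _frame(self, q_fwd, q_rev, lfc_fwd=1.0, lfc_rev=-1.0):
        return pd.DataFrame({
            "target_id": ["t1", "t1"], "direction": ["fwd", "rev"],
            "lfc_treatment": [lfc_fwd, lfc_rev], "q": [q_fwd, q_rev]})

    def test_either_direction_rule(self):
        calls = mk.da_classify(self._frame(0.05, 0.5), fdr=0.10)
        assert calls.loc[0, "significant"]
        assert calls.loc[0, "direction_of_change"] == "up"

    def test_not_significant_when_both_fail(self):
        calls = mk.da_classify(self._frame(1.0, 1.0), fdr=0.10)
        assert not calls.loc[0, "significant"]

    def test_tie_broken_by_smaller_q(self):
        calls = mk.da_classify(self._frame(0.02, 0.01), fdr=0.10)
        assert calls.loc[0, "direction_of_change"] == "down"


class TestNullCalibration:
    def test_type_one_error_at_five_percent(self, null_activity):
        p = null_activity.frame["p"]
        assert len(p) >= 5000
        assert 0.04 <= (p < 0.05).mean() <= 0.06

    def test_null_pvalues_uniform(self, null_activity):
        ks = stats.kstest(null_activity.frame["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_lfc_estimates_center_on_zero(self, null_activity):
        assert abs(null_activity.frame["lfc_treatment"].mean()) < 0.02


class TestLfcRecovery:
    def test_regression_slope_near_unity(self):
        cfg = mk.SimConfig(n_targets=300, mean_depth=500, da_frac=0.5,
                           da_lfc_sd=1.0, nb_dispersion=0.05,
                           frac_negative_control=0.0, seed=15)
        _, truth = mk.simulate_library(cfg)
        counts, samples = mk.simulate_activity_counts(truth, cfg)
        res = mk.ActivityModel(counts, samples).fit()
        fwd = res.frame[res.frame["direction"] == "fwd"].set_index("target_id")
        true_lfc = truth.snps.set_index("snp_id")["true_da_lfc"].reindex(
            fwd.index)
        slope = np.polyfit(true_lfc, fwd["lfc_treatment"], 1)[0]
        assert 0.9 <= slope <= 1.1


class TestPcaQc:
    def test_duplicated_samples_share_scores(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.integers(1, 500, size=(50, 3)),
                         columns=["a", "b", "c"])
        m["d"] = m["c"]
        scores, _ = mk.pca_qc(m)
        np.testing.assert_allclose(scores.loc["c"], scores.loc["d"],
                                   atol=1e-8)

    def test_variance_fractions_sum_to_one(self, null_activity):
        _, var_frac = mk.pca_qc(null_activity.model.counts)
        assert var_frac.sum() == pytest.approx(1.0, abs=1e-10)

    def test_constant_matrix_flagged(self):
        m = pd.DataFrame(np.full((10, 4), 7.0))
        with pytest.raises(EstimationError, match="constant"):
            mk.pca_qc(m)

    def test_strong_allele_effect_separates_on_pc1(self):
        """Allele-split pseudo-samples separate by allele on PC1."""
        from sklearn.metrics import silhouette_score

        cfg = mk.SimConfig(n_targets=200, frac_ase=0.8, frac_case=0.0,
                           effect_sd=2.0, frac_negative_control=0.0,
                           nb_dispersion=0.02, seed=21)
        _, truth = mk.simulate_library(cfg)
        counts, samples = mk.simulate_activity_counts(truth, cfg)
        qc = allele_qc_matrix(counts)
        scores, _ = mk.pca_qc(qc)
        labels = [c.split("@")[1] for c in qc.columns]
        sil = silhouette_score(scores[["PC1"]].to_numpy(), labels)
        assert sil > 0


def test_model_requires_two_samples_per_condition():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(rng.integers(1, 100, size=(4, 2)),
                          index=["t|ref|fwd", "t|alt|fwd",
                                 "u|ref|fwd", "u|alt|fwd"],
                          columns=["control_1", "caffeine_1"])
    samples = pd.DataFrame({"condition": ["control", "caffeine"]},
                           index=["control_1", "caffeine_1"])
    with pytest.raises(InputError, match=">= 2 samples"):
        mk.ActivityModel(counts, samples)
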