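import numpy as np
import pandas as pd
import pytest
from scipy.special import betaln, expit, logit

import mprakit as mk
from mprakit.ase import AseReplicateFit
from mprakit.exceptions import EstimationError, InputError

from conftest import simulate_pairs


# --- independent beta-binomial oracle (betaln form, plain grid search) -----

def oracle_loglik(x, k, n, rho):
    mu = expit(x)
    if rho < 1e-9:
        return k * np.log(mu) + (n - k) * np.log1p(-mu)
    t = (1 - rho) / rho
    return betaln(k + mu * t, n - k + (1 - mu) * t) - betaln(mu * t,
                                                            (1 - mu) * t)


def oracle_fit(ref, alt, rho, pseudocount=0.5):
    k, n = ref + pseudocount, ref + alt + 2 * pseudocount
    grid = np.arange(-10.0, 10.0 + 1e-9, 1e-3)
    best = grid[np.argmax(oracle_loglik(grid, k, n, rho))]
    fine = best + np.arange(-1e-3, 1e-3 + 1e-9, 1e-5)
    beta = fine[np.argmax(oracle_loglik(fine, k, n, rho))]
    h = 1e-4
    curv = (oracle_loglik(beta + h, k, n, rho)
            - 2 * oracle_loglik(beta, k, n, rho)
            + oracle_loglik(beta - h, k, n, rho)) / h ** 2
    return beta, 1.0 / np.sqrt(-curv)


class TestDnaProportion:
    @pytest.mark.parametrize("ref, alt, expected", [
        (10, 10, 0.5), (0, 0, 0.5), (99, 0, 0.995)])
    def test_closed_form(self, ref, alt, expected):
        assert mk.estimate_dna_proportion(ref, alt) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            mk.estimate_dna_proportion(-1, 5)


class TestReplicateFit:
    def test_symmetric_counts_give_zero_beta(self):
        fit = mk.fit_replicate(5, 5, rho=1e-12)
        assert fit.beta == pytest.approx(0.0, abs=1e-6)

    def test_binomial_limit_matches_closed_form(self):
        fit = mk.fit_replicate(8, 2, rho=0.0)
        assert fit.beta == pytest.approx(float(logit(8.5 / 11)), abs=1e-4)

    def test_zero_total_reads_rejected(self):
        with pytest.raises(InputError, match="zero total"):
            mk.fit_replicate(0, 0, rho=0.05)

    def test_matches_grid_search_oracle_on_random_counts(self):
        """200 random count pairs across dispersions, |dbeta| < 1e-3."""
        rng = np.random.default_rng(123)
        n = rng.integers(1, 2000, size=200)
        k = rng.binomial(n, rng.uniform(0.02, 0.98, size=200))
        rhos = rng.choice([0.0, 0.01, 0.05, 0.1, 0.3], size=200)
        for ref, alt, rho in zip(k, n - k, rhos):
            beta, se = mk.fit_betabinom_mle(np.array([ref]), np.array([alt]),
                                            float(rho))
            ob, ose = oracle_fit(float(ref), float(alt), float(rho))
            assert beta[0] == pytest.approx(ob, abs=1e-3)
            assert se[0] == pytest.approx(ose, abs=1e-3)

    def test_allele_swap_negates_beta_exactly(self):
        rng = np.random.default_rng(7)
        n = rng.integers(1, 500, size=50)
        k = rng.binomial(n, 0.4)
        for rho in (0.0, 0.08):
            b1, s1 = mk.fit_betabinom_mle(k, n - k, rho)
            b2, s2 = mk.fit_betabinom_mle(n - k, k, rho)
            np.testing.assert_allclose(b1, -b2, atol=1e-9)
            np.testing.assert_allclose(s1, s2, atol=1e-9)


class TestDispersionEstimate:
    def test_recovers_truth_on_simulated_pairs(self):
        table = simulate_pairs(1500, depth=200, beta=0.0, rho=0.05, seed=4)
        rho = mk.estimate_dispersion(table, "control")
        assert rho == pytest.approx(0.05, abs=0.01)

    def test_binomial_data_estimates_at_lower_bound(self):
        table = simulate_pairs(400, depth=300, beta=0.0, rho=0.0, seed=5)
        assert mk.estimate_dispersion(table, "control") <= 1e-3

    def test_invariant_to_allele_swap(self, null_sim):
        _, _, table = null_sim
        sub = table[table["snp_id"] < "snp000300"]
        swapped = sub.copy()
        swapped["allele"] = swapped["allele"].map({"ref": "alt",
                                                   "alt": "ref"})
        r1 = mk.estimate_dispersion(sub, "control")
        r2 = mk.estimate_dispersion(swapped, "control")
        assert r1 == pytest.approx(r2, abs=1e-6)

    def test_insufficient_pairs_raise(self, toy_table):
        with pytest.raises(EstimationError, match="fixed rho"):
            mk.estimate_dispersion(toy_table, "control")


def _fit(beta, se, rep=1):
    return AseReplicateFit("rs1", "fwd", "control", rep, beta, se, 100)


class TestMetaAnalysis:
    def test_single_fit_identity(self):
        res = mk.meta_analyze([_fit(1.5, 0.3)], p0=0.5, min_replicates=1)
        assert res.beta_meta == pytest.approx(1.5)
        assert res.se_meta == pytest.approx(0.3)
        assert res.z == pytest.approx(5.0)

    def test_two_equal_weight_fits(self):
        res = mk.meta_analyze([_fit(0.0, 1.0), _fit(2.0, 1.0, 2)], p0=0.5,
                              min_replicates=2)
        assert res.beta_meta == pytest.approx(1.0)
        assert res.se_meta == pytest.approx(2 ** -0.5)
        assert res.z == pytest.approx(2 ** 0.5)

    def test_below_replicate_filter_is_untested(self):
        fits = [_fit(1.0, 0.5, r) for r in range(1, 4)]
        res = mk.meta_analyze(fits, p0=0.5, min_replicates=4)
        assert res.p is None and res.z is None
        assert res.n_replicates_used == 3

    def test_empty_fit_list_rejected(self):
        with pytest.raises(InputError):
            mk.meta_analyze([], p0=0.5)


class TestBhAdjust:
    def test_step_up_with_monotonicity(self):
        q = mk.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_inputs(self):
        np.testing.assert_allclose(mk.bh_adjust([1.0, 1.0]), [1.0, 1.0])
        np.testing.assert_allclose(mk.bh_adjust([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            mk.bh_adjust([0.5, 1.5])


class TestCallAse:
    def test_all_null_q_flags_nothing(self):
        frame = pd.DataFrame({"snp_id": ["a", "b"], "q": [1.0, 1.0],
                              "p": [1.0, 1.0]})
        flags, summary = mk.call_ase(frame)
        assert not flags.any()
        assert summary["n_significant_pairs"] == 0

    def test_pair_and_snp_counting(self):
        # one SNP significant in both directions: 2 pairs, 1 SNP
        frame = pd.DataFrame({
            "snp_id": ["a", "a", "b"], "direction": ["fwd", "rev", "fwd"],
            "p": [1e-5, 1e-4, 0.9], "q": [0.01, 0.02, 0.9]})
        _, summary = mk.call_ase(frame, fdr=0.10)
        assert summary["n_significant_pairs"] == 2
        assert summary["n_significant_snps"] == 1


class TestModelPipeline:
    def test_allele_swap_antisymmetry(self, null_sim):
        """Swapping ref/alt labels everywhere negates beta_meta and z."""
        _, _, table = null_sim
        sub = table[table["snp_id"] < "snp000200"]
        swapped = sub.copy()
        swapped["allele"] = swapped["allele"].map({"ref": "alt",
                                                   "alt": "ref"})
        f1 = mk.AseModel(sub, "control", rho=0.05).fit().frame
        f2 = mk.AseModel(swapped, "control", rho=0.05).fit().frame
        # agreement is limited only by the optimizer's final grid resolution
        np.testing.assert_allclose(f1["beta_meta"], -f2["beta_meta"],
                                   atol=1e-5)
        np.testing.assert_allclose(f1["z"], -f2["z"], atol=1e-4)
        np.testing.assert_allclose(f1["p"], f2["p"], atol=1e-5)

    def test_null_z_is_standard_normal(self, null_ase_fits):
        control, _ = null_ase_fits
        z = control.frame["z"].dropna()
        assert abs(z.mean()) < 0.05
        assert abs(z.std() - 1.0) < 0.05

    def test_replicate_filter_marks_pairs_untested(self, null_sim):
        _, _, table = null_sim
        sub = table[table["snp_id"] < "snp000100"].copy()
        # knock three control replicates of one SNP down to zero depth
        hit = (sub["snp_id"] == "snp000050") & (sub["condition"] == "control") \
            & (sub["replicate"] <= 3)
        sub.loc[hit, "count"] = 0
        frame = mk.AseModel(sub, "control", rho=0.05).fit().frame
        row = frame[frame["snp_id"] == "snp000050"]
        assert (row["n_replicates_used"] == 3).all()
        assert row["p"].isna().all()

    def test_power_monotone_in_effect_and_depth(self):
        """Detection rate grows with |beta| and with depth (3x3 grid)."""
        power = {}
        for bi, beta in enumerate((0.0, 0.5, 1.0)):
            for di, depth in enumerate((100, 300, 900)):
                table = simulate_pairs(250, depth=depth, beta=beta, rho=0.05,
                                       seed=100 + 10 * bi + di)
                frame = mk.AseModel(table, "control", rho=0.05,
                                    calibrate=False).fit().frame
                power[beta, depth] = (frame["p"] < 0.05).mean()
        tol = 0.05
        for depth in (100, 300, 900):
            assert power[0.5, depth] >= power[0.0, depth] - tol
            assert power[1.0, depth] >= power[0.5, depth] - tol
        for beta in (0.5, 1.0):
            assert power[beta, 300] >= power[beta, 100] - tol
            assert power[beta, 900] >= power[beta, 300] - tol
        assert power[1.0, 900] > 0.9


def test_fraction_percent_reporting():
    assert mk.fraction_percent(665, 30680) == 2.2
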