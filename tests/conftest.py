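import numpy as np
import pandas as pd
import pytest

import mprakit as mk


def make_count_table(rows):
    """Build a long-form allele count table from (snp, dir, allele, sample,
    condition, replicate, count) tuples."""
    return pd.DataFrame(rows, columns=["snp_id", "direction", "allele",
                                       "sample_id", "condition", "replicate",
                                       "count"])


@pytest.fixture
def toy_table():
    """One SNP/direction with DNA rows and two RNA replicates."""
    rows = []
    for allele, dna, r1, r2 in (("ref", 50, 30, 28), ("alt", 50, 10, 12)):
        rows.append(("rs1", "fwd", allele, "dna_1", "dna", 1, dna))
        rows.append(("rs1", "fwd", allele, "control_1", "control", 1, r1))
        rows.append(("rs1", "fwd", allele, "control_2", "control", 2, r2))
    return make_count_table(rows)


@pytest.fixture(scope="session")
def null_sim():
    """Medium null simulation shared by calibration tests.

    4,000 SNP/direction pairs, no true effects, study-default depth and
    overdispersion.
    """
    cfg = mk.SimConfig(n_targets=2000, frac_ase=0.0, frac_case=0.0,
                       frac_negative_control=0.0, seed=20)
    sequences, truth = mk.simulate_library(cfg)
    table = mk.simulate_allele_counts(truth, cfg)
    return cfg, truth, table


@pytest.fixture(scope="session")
def null_ase_fits(null_sim):
    cfg, truth, table = null_sim
    control = mk.AseModel(table, "control").fit()
    caffeine = mk.AseModel(table, "caffeine").fit()
    return control, caffeine


def simulate_pairs(n_pairs, depth, beta, rho, p0=0.5, n_replicates=6,
                   seed=0):
    """Hand-rolled count table: fixed effect size and depth for power grids."""
    rng = np.random.default_rng(seed)
    mu = 1.0 / (1.0 + np.exp(-(np.log(p0 / (1 - p0)) + beta)))
    rows = []
    for i in range(n_pairs):
        snp = f"s{i:05d}"
        dna_n = 4000
        dna_ref = rng.binomial(dna_n, p0)
        rows.append((snp, "fwd", "ref", "dna_1", "dna", 1, dna_ref))
        rows.append((snp, "fwd", "alt", "dna_1", "dna", 1, dna_n - dna_ref))
        for rep in range(1, n_replicates + 1):
            n = depth
            if rho > 0:
                t = (1 - rho) / rho
                p = rng.beta(mu * t, (1 - mu) * t)
            else:
                p = mu
            ref = rng.binomial(n, p)
            rows.append((snp, "fwd", "ref", f"control_{rep}", "control",
                         rep, ref))
            rows.append((snp, "fwd", "alt", f"control_{rep}", "control",
                         rep, n - ref))
    return make_count_table(rows)
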