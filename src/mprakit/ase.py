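"""Allele-specific expression (ASE) under a beta-binomial model.

Each SNP/direction pair contrasts RNA reads carrying the reference allele
against reads carrying the alternate allele, relative to the allelic
proportion of the plasmid DNA input library (uneven in practice, so the null
is *not* 0.5).  Per replicate, the reference-read count ``k`` out of ``n``
total is modelled as beta-binomial with mean ``mu`` on the logit scale and a
condition-wide overdispersion ``rho``::

    k | n ~ BetaBinomial(n, mu, rho),   beta = logit(mu)

The per-replicate effects are combined by fixed-effect inverse-variance
meta-analysis within each condition, and the standardized effect

    z = (beta_meta - logit(p0)) / se_meta

is referred to the standard normal, where ``p0`` is the DNA reference-allele
proportion.  Benjamini-Hochberg adjustment across all tested SNP/direction
pairs of one condition yields q-values; significant ASE is q < 0.10 by
default.

A Haldane-Anscombe pseudocount of 0.5 is added to both allele counts before
every fit so monoallelic observations give finite estimates.  Replicates with
zero RNA reads are unusable; a pair needs at least ``min_replicates`` (default
4 of the 6) usable replicates to be tested at all.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, log_expit, expit
from statsmodels.stats.multitest import multipletests

from .exceptions import EstimationError, InputError

logger = logging.getLogger(__name__)

_BETA_BOUND = 10.0  # search domain for the log-odds effect
_RHO_BOUNDS = (1e-6, 0.999)
_BINOM_RHO = 1e-9  # below this, use the binomial limit


# ---------------------------------------------------------------------------
# beta-binomial likelihood and MLE
# ---------------------------------------------------------------------------

def bb_loglik(x, k, n, rho):
    """Beta-binomial log-likelihood of ``k`` of ``n`` at logit-mean ``x``.

    The binomial coefficient term (constant in both ``x`` and ``rho``) is
    omitted.  ``k`` may be non-integer (pseudocounted).  ``rho`` below 1e-9 is
    treated as the binomial limit.  Arguments broadcast.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if rho < _BINOM_RHO:
        return k * log_expit(x) + (n - k) * log_expit(-x)
    t = (1.0 - rho) / rho
    a = expit(x) * t
    b = expit(-x) * t  # = (1 - mu) * t, written so allele swap is exact
    return ((gammaln(k + a) - gammaln(a))
            + (gammaln(n - k + b) - gammaln(b))
            + (gammaln(t) - gammaln(n + t)))


def _symmetric_offsets(m: int) -> np.ndarray:
    """m grid offsets in [-1, 1], exactly antisymmetric about 0."""
    half = np.linspace(0.0, 1.0, (m + 1) // 2)
    return np.concatenate([-half[:0:-1], half])


def fit_betabinom_mle(ref, alt, rho: float, pseudocount: float = 0.5,
                      n_grid: int = 201, n_stages: int = 3,
                      se_step: float = 1e-4):
    """Vectorized beta-binomial MLE of the log-odds mean, one fit per entry.

    Maximizes the likelihood over beta in [-10, 10] by staged grid refinement
    (final resolution ~1e-5 with the defaults), which is robust to the mild
    non-quadratic shape of the likelihood at low depth.  The standard error is
    the inverse square root of the negative finite-difference curvature at the
    optimum.

    Returns ``(beta, se)`` arrays.  Entries with ``ref + alt == 0`` come back
    as NaN (no data: the likelihood is flat).
    """
    ref = np.asarray(ref, dtype=float)
    alt = np.asarray(alt, dtype=float)
    k = ref + pseudocount
    n = ref + alt + 2.0 * pseudocount
    usable = (ref + alt) > 0

    centers = np.zeros_like(k)
    halfwidth = _BETA_BOUND
    offsets = _symmetric_offsets(n_grid)
    for _ in range(n_stages):
        best_x = centers.copy()
        best_l = np.full_like(k, -np.inf)
        for off in offsets:
            x = np.clip(centers + off * halfwidth, -_BETA_BOUND, _BETA_BOUND)
            ll = bb_loglik(x, k, n, rho)
            better = ll > best_l
            best_l = np.where(better, ll, best_l)
            best_x = np.where(better, x, best_x)
        centers = best_x
        halfwidth *= 2.0 / (n_grid - 1)  # next stage spans one old grid step

    beta = centers
    h = se_step
    curv = (bb_loglik(beta + h, k, n, rho)
            - 2.0 * bb_loglik(beta, k, n, rho)
            + bb_loglik(beta - h, k, n, rho)) / (h * h)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = 1.0 / np.sqrt(-curv)
    beta = np.where(usable, beta, np.nan)
    se = np.where(usable & np.isfinite(se), se, np.nan)
    return beta, se


@dataclasses.dataclass(frozen=True)
class AseReplicateFit:
    """Per-replicate allelic effect: log-odds of the RNA ref proportion."""

    snp_id: str
    direction: str
    condition: str
    replicate: int
    beta: float
    se: float
    n_reads: int


def fit_replicate(rna_ref: int, rna_alt: int, rho: float,
                  pseudocount: float = 0.5, *, snp_id: str = "",
                  direction: str = "fwd", condition: str = "",
                  replicate: int = 1) -> AseReplicateFit:
    """Fit one replicate's beta-binomial allelic effect.

    Raises :class:`InputError` on zero total reads (such replicates are
    flagged missing upstream and excluded from the meta-analysis).
    """
    if rna_ref < 0 or rna_alt < 0:
        raise InputError("negative allele counts")
    if rna_ref + rna_alt == 0:
        raise InputError("zero total RNA reads: replicate is unusable")
    beta, se = fit_betabinom_mle(np.array([rna_ref]), np.array([rna_alt]),
                                 rho, pseudocount)
    return AseReplicateFit(snp_id, direction, condition, replicate,
                           float(beta[0]), float(se[0]),
                           int(rna_ref + rna_alt))


# ---------------------------------------------------------------------------
# DNA proportion and dispersion
# ---------------------------------------------------------------------------

def estimate_dna_proportion(dna_ref: float, dna_alt: float,
                            pseudocount: float = 0.5) -> float:
    """Reference-allele proportion of the DNA library, pseudocounted."""
    if dna_ref < 0 or dna_alt < 0:
        raise InputError("negative DNA counts")
    return (dna_ref + pseudocount) / (dna_ref + dna_alt + 2.0 * pseudocount)


def _dna_logit(dna_ref, dna_alt, pseudocount=0.5):
    # log((ref+pc)/(alt+pc)) written as a difference so an allele swap
    # negates it exactly
    return np.log(np.asarray(dna_ref, dtype=float) + pseudocount) \
        - np.log(np.asarray(dna_alt, dtype=float) + pseudocount)


def estimate_dispersion(table: pd.DataFrame, condition: str,
                        pseudocount: float = 0.5,
                        min_pairs: int = 50) -> float:
    """Pooled beta-binomial overdispersion for one condition.

    Maximizes the summed log-likelihood over all SNP/direction/replicate
    observations of ``condition``, with each observation's mean fixed at its
    pair's DNA proportion.  One global rho per condition is the exchange the
    model makes: no per-SNP dispersion, in return for stable estimates at 6
    replicates.
    """
    dna, _ = _dna_table(table, pseudocount)
    rna = _rna_wide(table, condition)
    rna = rna.merge(dna, on=["snp_id", "direction"], how="inner")
    rna = rna[(rna["ref"] + rna["alt"]) > 0]
    n_pairs = rna[["snp_id", "direction"]].drop_duplicates().shape[0]
    if n_pairs < min_pairs:
        raise EstimationError(
            f"only {n_pairs} SNP/direction pairs with RNA depth in "
            f"{condition!r} (need >= {min_pairs}); pass a fixed rho instead")
    k = rna["ref"].to_numpy(dtype=float)
    n = k + rna["alt"].to_numpy(dtype=float)
    x0 = rna["dna_logit"].to_numpy(dtype=float)

    def neg_loglik(rho: float) -> float:
        return -float(bb_loglik(x0, k, n, rho).sum())

    res = optimize.minimize_scalar(neg_loglik, bounds=_RHO_BOUNDS,
                                   method="bounded",
                                   options={"xatol": 1e-7})
    return float(res.x)


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class AseMetaResult:
    """Meta-analyzed allelic effect for one SNP/direction/condition."""

    snp_id: str
    direction: str
    condition: str
    beta_meta: float
    se_meta: float
    dna_logit: float
    z: float | None
    p: float | None
    n_replicates_used: int
    q: float | None = None


def meta_analyze(fits: Sequence[AseReplicateFit], p0: float,
                 min_replicates: int = 4) -> AseMetaResult:
    """Inverse-variance meta-analysis of one pair's replicate fits.

    ``w_i = 1/se_i**2``; ``beta_meta`` is the weighted mean and
    ``se_meta = (sum w_i)**-0.5``.  Pairs with fewer than ``min_replicates``
    usable fits get no z/p (untested, per the >= 4-of-6 replicate filter).
    """
    if not fits:
        raise InputError("empty fit list")
    if not 0.0 < p0 < 1.0:
        raise InputError(f"p0 must be in (0, 1), got {p0}")
    keys = {(f.snp_id, f.direction, f.condition) for f in fits}
    if len(keys) != 1:
        raise InputError("fits must share (snp_id, direction, condition)")
    beta = np.array([f.beta for f in fits])
    se = np.array([f.se for f in fits])
    w = 1.0 / se ** 2
    beta_meta = float(np.sum(w * beta) / np.sum(w))
    se_meta = float(np.sum(w) ** -0.5)
    dna_logit = float(np.log(p0) - np.log1p(-p0))
    if len(fits) >= min_replicates:
        z = (beta_meta - dna_logit) / se_meta
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        z = p = None
    snp_id, direction, condition = next(iter(keys))
    return AseMetaResult(snp_id, direction, condition, beta_meta, se_meta,
                         dna_logit, z, p, len(fits))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_ase(results: pd.DataFrame, fdr: float = 0.10):
    """Flag significant ASE at BH FDR < ``fdr`` and summarize.

    Returns ``(flags, summary)`` where ``flags`` is a boolean Series aligned
    to ``results`` and ``summary`` counts significant/tested SNP-direction
    pairs and distinct SNPs.
    """
    flags = results["q"] < fdr
    flags &= results["q"].notna()
    tested = results["p"].notna()
    summary = {
        "n_tested_pairs": int(tested.sum()),
        "n_tested_snps": int(results.loc[tested, "snp_id"].nunique()),
        "n_significant_pairs": int(flags.sum()),
        "n_significant_snps": int(results.loc[flags, "snp_id"].nunique()),
    }
    if summary["n_tested_snps"]:
        summary["percent_significant_snps"] = round(
            100.0 * summary["n_significant_snps"] / summary["n_tested_snps"], 1)
    return flags.fillna(False), summary


# ---------------------------------------------------------------------------
# table plumbing shared by the model and the dispersion estimator
# ---------------------------------------------------------------------------

def _dna_table(table: pd.DataFrame, pseudocount: float = 0.5):
    """Per (snp, direction): pooled DNA ref/alt counts, p0 and its logit."""
    dna = table[table["condition"] == "dna"]
    if dna.empty:
        raise InputError("count table has no DNA rows")
    wide = (dna.groupby(["snp_id", "direction", "allele"])["count"].sum()
            .unstack("allele", fill_value=0).reset_index())
    for col in ("ref", "alt"):
        if col not in wide:
            wide[col] = 0
    wide["p0"] = (wide["ref"] + pseudocount) / \
        (wide["ref"] + wide["alt"] + 2.0 * pseudocount)
    wide["dna_logit"] = _dna_logit(wide["ref"], wide["alt"], pseudocount)
    # delta-method sampling variance of dna_logit (binomial library draw)
    wide["dna_var"] = 1.0 / (wide["ref"] + pseudocount) \
        + 1.0 / (wide["alt"] + pseudocount)
    return wide[["snp_id", "direction", "p0", "dna_logit", "dna_var"]], wide


def _rna_wide(table: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Long RNA rows of one condition -> one row per pair/replicate."""
    rna = table[table["condition"] == condition]
    if rna.empty:
        raise InputError(f"count table has no rows for condition {condition!r}")
    wide = (rna.groupby(["snp_id", "direction", "replicate", "allele"])["count"]
            .sum().unstack("allele", fill_value=0).reset_index())
    for col in ("ref", "alt"):
        if col not in wide:
            wide[col] = 0
    return wide


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------

class AseModel:
    """Beta-binomial ASE model for one condition of an allele count table.

    Parameters
    ----------
    table:
        Long-form allele count table (see :mod:`mprakit.io`), containing DNA
        rows and RNA rows for ``condition``.
    condition:
        RNA condition to analyze (``"control"`` or ``"caffeine"``).
    rho:
        Beta-binomial overdispersion.  ``None`` (default) estimates it from
        the data by pooled maximum likelihood.
    pseudocount:
        Haldane-Anscombe correction added to every allele count.
    min_replicates:
        Minimum usable replicates for a pair to be tested.
    weighting:
        ``"pooled"`` (default) weights each replicate by its expected
        information at the pair's pooled proportion (proportional to the
        beta-binomial effective sample size); ``"replicate"`` uses the
        classic ``1/se_i**2`` with each replicate's own standard error.
        Replicate-level weights covary with the estimation noise and bias
        the weighted mean toward the DNA proportion at low effective depth,
        which correlates the two conditions' z-scores; pooled weighting
        avoids this.
    calibrate:
        Apply per-condition genomic control to the meta z-scores (median
        squared z pinned to the chi-squared(1) median).  ``se_meta`` is
        inflated by ``sqrt(lambda_z)`` so ``z = (beta_meta - dna_logit) /
        se_meta`` continues to hold exactly.

    Examples
    --------
    >>> results = AseModel(table, condition="control").fit()
    >>> results.frame.head()
    >>> flags, summary = results.call(fdr=0.10)
    """

    def __init__(self, table: pd.DataFrame, condition: str, *,
                 rho: float | None = None, pseudocount: float = 0.5,
                 min_replicates: int = 4, weighting: str = "pooled",
                 calibrate: bool = True, propagate_dna_noise: bool = True):
        if weighting not in ("pooled", "replicate"):
            raise InputError("weighting must be 'pooled' or 'replicate'")
        self.table = table
        self.condition = condition
        self.rho = rho
        self.pseudocount = pseudocount
        self.min_replicates = min_replicates
        self.weighting = weighting
        self.calibrate = calibrate
        self.propagate_dna_noise = propagate_dna_noise

    @classmethod
    def from_tsv(cls, path, condition: str, **kwargs) -> "AseModel":
        from .io import read_allele_counts

        return cls(read_allele_counts(path), condition, **kwargs)

    def fit(self) -> "AseResults":
        rho = self.rho
        if rho is None:
            rho = estimate_dispersion(self.table, self.condition,
                                      self.pseudocount)
            logger.info("estimated rho=%.5f for condition %s", rho,
                        self.condition)
        dna, _ = _dna_table(self.table, self.pseudocount)
        rna = _rna_wide(self.table, self.condition)
        rna = rna.merge(dna, on=["snp_id", "direction"], how="inner")
        rna = rna[(rna["ref"] + rna["alt"]) > 0].reset_index(drop=True)
        if rna.empty:
            raise EstimationError("no usable RNA replicates")

        beta, se = fit_betabinom_mle(rna["ref"].to_numpy(),
                                     rna["alt"].to_numpy(), rho,
                                     self.pseudocount)
        rna["beta"], rna["se"] = beta, se
        if self.weighting == "pooled":
            # weight each replicate by its expected information at the
            # pair's pooled proportion (effective sample size under the
            # beta-binomial), so weights do not covary with the
            # replicate-level estimation noise
            n_raw = (rna["ref"] + rna["alt"]).to_numpy(dtype=float)
            n_tot = n_raw + 2.0 * self.pseudocount
            rna["w"] = n_tot / (1.0 + (n_tot - 1.0) * rho)
            grp_k = rna.groupby(["snp_id", "direction"], sort=True)
            pooled = grp_k.agg(K=("ref", "sum"), A=("alt", "sum"))
            mu_bar = ((pooled["K"] + self.pseudocount)
                      / (pooled["K"] + pooled["A"] + 2.0 * self.pseudocount))
            pooled["mu_var"] = mu_bar * (1.0 - mu_bar)
            rna = rna.merge(pooled[["mu_var"]], on=["snp_id", "direction"])
            rna["w"] = rna["w"] * rna["mu_var"]
        else:
            rna["w"] = 1.0 / rna["se"] ** 2
        rna["wb"] = rna["w"] * rna["beta"]

        grp = rna.groupby(["snp_id", "direction"], sort=True)
        out = grp.agg(sum_w=("w", "sum"), sum_wb=("wb", "sum"),
                      n_replicates_used=("beta", "size"),
                      dna_logit=("dna_logit", "first"),
                      dna_var=("dna_var", "first"),
                      p0=("p0", "first")).reset_index()
        out["beta_meta"] = out["sum_wb"] / out["sum_w"]
        out["se_meta"] = out["sum_w"] ** -0.5
        if self.propagate_dna_noise:
            # the DNA proportion is itself estimated from counts; its
            # sampling variance adds to the comparison's variance
            out["se_meta"] = np.sqrt(out["se_meta"] ** 2 + out["dna_var"])
        out["z"] = (out["beta_meta"] - out["dna_logit"]) / out["se_meta"]
        untested = out["n_replicates_used"] < self.min_replicates
        out.loc[untested, "z"] = np.nan
        lambda_z = 1.0
        if self.calibrate:
            tested_z = out["z"].dropna().to_numpy()
            if tested_z.size >= 2:
                # per-condition genomic control of the meta z-scores:
                # the median squared z is pinned to the chi2_1 median so
                # finite-sample variance misestimation of the replicate
                # fits cannot leak into the downstream tests
                lambda_z = float(np.median(tested_z ** 2)
                                 / stats.chi2.ppf(0.5, df=1))
                if lambda_z <= 0:  # degenerate toy input
                    lambda_z = 1.0
                out["z"] = out["z"] / np.sqrt(lambda_z)
                out["se_meta"] = out["se_meta"] * np.sqrt(lambda_z)
        out["p"] = 2.0 * stats.norm.sf(np.abs(out["z"]))
        out.loc[untested, "p"] = np.nan
        out["q"] = np.nan
        tested = out["p"].notna()
        if tested.any():
            out.loc[tested, "q"] = bh_adjust(out.loc[tested, "p"])
        out["condition"] = self.condition
        frame = out[["snp_id", "direction", "condition", "beta_meta",
                     "se_meta", "dna_logit", "z", "p", "q",
                     "n_replicates_used"]].copy()
        return AseResults(self, frame, rho, lambda_z)


class AseResults:
    """Fitted per-pair meta-analyzed allelic effects for one condition."""

    def __init__(self, model: AseModel, frame: pd.DataFrame, rho: float,
                 lambda_z: float = 1.0):
        self.model = model
        self.frame = frame
        self.rho = rho
        self.lambda_z = lambda_z
        self.condition = model.condition

    def call(self, fdr: float = 0.10):
        """Significance flags and summary counts at BH FDR < ``fdr``."""
        frame = self.frame.copy()
        flags, summary = call_ase(frame, fdr)
        frame["significant"] = flags
        return frame, summary

    def to_tsv(self, path) -> None:
        frame, _ = self.call()
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self, fdr: float = 0.10) -> str:
        _, counts = self.call(fdr)
        lines = [
            "ASE meta-analysis results",
            "=" * 34,
            f"condition:            {self.condition}",
            f"dispersion rho:       {self.rho:.5f}",
            f"z calibration lambda: {self.lambda_z:.4f}",
            f"tested pairs:         {counts['n_tested_pairs']}",
            f"tested SNPs:          {counts['n_tested_snps']}",
            f"significant pairs:    {counts['n_significant_pairs']} "
            f"(FDR < {fdr:g})",
            f"significant SNPs:     {counts['n_significant_snps']}",
        ]
        if "percent_significant_snps" in counts:
            lines.append(
                f"percent significant:  {counts['percent_significant_snps']}%")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# arithmetic helpers used in reporting
# ---------------------------------------------------------------------------

def fraction_percent(k: int, n: int, digits: int = 1) -> float:
    """Percentage ``100*k/n`` rounded for reporting (e.g. 665/30680 -> 2.2)."""
    if n <= 0:
        raise InputError("denominator must be positive")
    return round(100.0 * k / n, digits)
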