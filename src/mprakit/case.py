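"""Conditional allele-specific effects (cASE): the molecular signature of GxE.

A SNP whose allelic effect differs between treatment and control conditions is
a genotype-environment interaction at the reporter level.  Given the
per-condition meta-analyzed z-scores Z_T (treatment) and Z_C (control), the
test statistic is

    (dZ)^2 = (Z_T - Z_C)^2 / 2

which is chi-squared with 1 df when the two conditions share the same true
effect (the factor 2 is Var(Z_T - Z_C) under independence).  The statistic
ensemble is calibrated by genomic control — dividing by

    lambda_GC = median((dZ)^2) / median(chi2_1)

— before upper-tail chi-squared p-values are taken, so residual
miscalibration of the per-condition z-scores cannot masquerade as widespread
GxE.  lambda is deliberately not floored at 1: deflation is allowed and is
logged.  BH adjustment across all eligible pairs gives q-values; calls are
made at FDR < 5%, with a wider nominal p < 0.0215 follow-up set.

Only SNP/direction pairs tested in *both* conditions are eligible.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .ase import AseResults, bh_adjust
from .exceptions import InputError

logger = logging.getLogger(__name__)

DEFAULT_NOMINAL_P = 0.0215


def delta_z_squared(z_t: float, z_c: float):
    """The cASE statistic ``(z_t - z_c)**2 / 2``; symmetric in its arguments."""
    z_t = np.asarray(z_t, dtype=float)
    z_c = np.asarray(z_c, dtype=float)
    if not (np.all(np.isfinite(z_t)) and np.all(np.isfinite(z_c))):
        raise InputError("z-scores must be finite")
    return (z_t - z_c) ** 2 / 2.0


def chi2_1_median() -> float:
    """Median of chi-squared(1), ~0.4549364 (computed, not hard-coded)."""
    return float(stats.chi2.ppf(0.5, df=1))


def genomic_control_lambda(statistics) -> float:
    """Median-ratio genomic-control inflation factor for chi2_1 statistics."""
    s = np.asarray(statistics, dtype=float)
    if s.size == 0:
        raise InputError("empty statistic list")
    if np.any(~np.isfinite(s)) or np.any(s < 0):
        raise InputError("statistics must be finite and non-negative")
    return float(np.median(s) / chi2_1_median())


def case_pvalues(statistics, lambda_gc: float) -> np.ndarray:
    """Upper-tail chi2_1 p-values of the lambda-rescaled statistics."""
    if not np.isfinite(lambda_gc) or lambda_gc <= 0:
        raise InputError(f"lambda_gc must be positive, got {lambda_gc}")
    s = np.asarray(statistics, dtype=float)
    return stats.chi2.sf(s / lambda_gc, df=1)


def call_case(results: pd.DataFrame, fdr: float = 0.05,
              nominal_p: float = DEFAULT_NOMINAL_P):
    """FDR and nominal follow-up flags plus summary counts."""
    sig = (results["q"] < fdr) & results["q"].notna()
    nominal = (results["p"] < nominal_p) & results["p"].notna()
    summary = {
        "n_tested_pairs": int(results["p"].notna().sum()),
        "n_tested_snps": int(results.loc[results["p"].notna(),
                                         "snp_id"].nunique()),
        "n_significant_pairs": int(sig.sum()),
        "n_significant_snps": int(results.loc[sig, "snp_id"].nunique()),
        "n_nominal_pairs": int(nominal.sum()),
        "n_nominal_snps": int(results.loc[nominal, "snp_id"].nunique()),
    }
    return sig.fillna(False), nominal.fillna(False), summary


class CaseModel:
    """GxE model contrasting two fitted :class:`~mprakit.ase.AseResults`.

    Parameters
    ----------
    control, treatment:
        ASE results (or their exported frames) for the two conditions.
        Pairs lacking a valid z in either condition are excluded (with the
        count logged).

    Examples
    --------
    >>> ctl = AseModel(table, condition="control").fit()
    >>> caf = AseModel(table, condition="caffeine").fit()
    >>> gxe = CaseModel(ctl, caf).fit()
    >>> gxe.lambda_gc, gxe.frame.head()
    """

    def __init__(self, control, treatment):
        self.control = self._frame(control)
        self.treatment = self._frame(treatment)

    @staticmethod
    def _frame(obj) -> pd.DataFrame:
        if isinstance(obj, AseResults):
            return obj.frame
        return obj

    def fit(self, fdr: float = 0.05,
            nominal_p: float = DEFAULT_NOMINAL_P) -> "CaseResults":
        key = ["snp_id", "direction"]
        ctl = self.control.loc[self.control["z"].notna(), key + ["z"]]
        trt = self.treatment.loc[self.treatment["z"].notna(), key + ["z"]]
        n_ctl_only = len(set(map(tuple, ctl[key].to_numpy()))
                         - set(map(tuple, trt[key].to_numpy())))
        n_trt_only = len(set(map(tuple, trt[key].to_numpy()))
                         - set(map(tuple, ctl[key].to_numpy())))
        if n_ctl_only or n_trt_only:
            logger.info(
                "excluded from cASE: %d pairs tested in control only, "
                "%d in treatment only", n_ctl_only, n_trt_only)
        merged = ctl.merge(trt, on=key, suffixes=("_control", "_treatment"))
        if merged.empty:
            raise InputError("no SNP/direction pair tested in both conditions")
        merged["delta_z_sq"] = delta_z_squared(
            merged["z_treatment"].to_numpy(), merged["z_control"].to_numpy())
        lam = genomic_control_lambda(merged["delta_z_sq"].to_numpy())
        if lam < 1.0:
            logger.warning("genomic-control lambda %.3f < 1: statistics are "
                           "deflated; no flooring is applied", lam)
        merged["lambda_gc"] = lam
        merged["p"] = case_pvalues(merged["delta_z_sq"].to_numpy(), lam)
        merged["q"] = bh_adjust(merged["p"].to_numpy())
        sig, nominal, _ = call_case(merged, fdr, nominal_p)
        merged["significant_fdr05"] = sig
        merged["nominal_followup"] = nominal
        frame = merged[key + ["z_control", "z_treatment", "delta_z_sq",
                              "lambda_gc", "p", "q", "significant_fdr05",
                              "nominal_followup"]].copy()
        return CaseResults(self, frame, lam, fdr, nominal_p)


class CaseResults:
    """Calibrated (dZ)^2 tests for every pair tested in both conditions."""

    def __init__(self, model: CaseModel, frame: pd.DataFrame,
                 lambda_gc: float, fdr: float, nominal_p: float):
        self.model = model
        self.frame = frame
        self.lambda_gc = lambda_gc
        self.fdr = fdr
        self.nominal_p = nominal_p

    def call(self):
        return call_case(self.frame, self.fdr, self.nominal_p)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self) -> str:
        _, _, counts = self.call()
        return "\n".join([
            "cASE (GxE) results",
            "=" * 34,
            f"lambda_GC:            {self.lambda_gc:.4f}",
            f"tested pairs:         {counts['n_tested_pairs']}",
            f"tested SNPs:          {counts['n_tested_snps']}",
            f"significant pairs:    {counts['n_significant_pairs']} "
            f"(FDR < {self.fdr:g})",
            f"significant SNPs:     {counts['n_significant_snps']}",
            f"nominal pairs:        {counts['n_nominal_pairs']} "
            f"(p < {self.nominal_p:g})",
        ])
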