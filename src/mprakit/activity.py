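"""Differential activity of reporter targets under treatment.

Each target contributes two constructs (ref/alt allele) per orientation; the
question is whether treatment changes the target's overall transcriptional
output.  Per target and direction, construct-level RNA counts are modelled
with a negative-binomial log-linear GLM

    log E[y] = log(size_factor) + b0 + b_allele * I[alt] + b_trt * I[treatment]

i.e. a treatment effect correcting for allele, because the allelic effect is
the dominant within-target source of variation (visible as PC1 in the QC
PCA).  The per-target NB dispersion is profiled out by alternating coefficient
fits (IRLS via statsmodels) with 1-D dispersion MLE, floored at 1e-8.  The
reported test is a Wald z on the treatment coefficient (a likelihood-ratio
variant is available for cross-checks).  Directions are separate BH families;
a target is called differentially active when q < 0.10 in either direction.

There is no dispersion shrinkage across targets, no independent filtering and
no fold-change shrinkage — this is a deliberately plain, fully specified NB
GLM, not a DESeq2 re-implementation.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import gammaln

from .ase import bh_adjust
from .exceptions import EstimationError, InputError

logger = logging.getLogger(__name__)

_LN2 = float(np.log(2.0))
_ALPHA_FLOOR = 1e-8
_ALPHA_CEIL = 100.0


# ---------------------------------------------------------------------------
# normalization and QC
# ---------------------------------------------------------------------------

def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    For each row with all-positive counts, the ratio of each sample's count
    to the row's geometric mean is taken; a sample's factor is the median of
    its ratios, rescaled so the factors have geometric mean 1.  Falls back to
    column-total ratios (with a warning) when no all-positive row exists.
    """
    counts = matrix.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if positive.any():
        logc = np.log(counts[positive])
        log_ratios = logc - logc.mean(axis=1, keepdims=True)
        log_factors = np.median(log_ratios, axis=0)
    else:
        logger.warning("size_factors: no row with all-positive counts; "
                       "falling back to column totals")
        totals = counts.sum(axis=0)
        if (totals <= 0).any():
            raise EstimationError("sample with zero total counts")
        log_factors = np.log(totals)
    log_factors = log_factors - log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=matrix.columns,
                     name="size_factor")


def pca_qc(matrix: pd.DataFrame, factors: pd.Series | None = None):
    """Sample-level PCA of row-centered log2 normalized counts.

    Returns ``(scores, variance_fraction)``: per-sample component scores and
    the fraction of variance per component (summing to 1).  The expected QC
    signature is allele separating on PC1.  A constant matrix has no variance
    and raises :class:`EstimationError`.
    """
    if matrix.shape[1] < 3:
        raise InputError("PCA QC needs at least 3 samples")
    if factors is None:
        factors = size_factors(matrix)
    logc = np.log2(matrix.to_numpy(dtype=float)
                   / factors.to_numpy(dtype=float)[None, :] + 1.0)
    centered = logc - logc.mean(axis=1, keepdims=True)
    if not np.any(centered):
        raise EstimationError("constant matrix: no variance to decompose")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    var_frac = s ** 2 / np.sum(s ** 2)
    scores = pd.DataFrame(
        (vt * s[:, None]).T, index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(len(s))])
    return scores, var_frac


def allele_qc_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Reshape construct-by-sample counts to target-by-(sample, allele).

    Each column of the result is one RNA sample restricted to one allele's
    constructs, labelled ``sample@allele``.  Running :func:`pca_qc` on this
    matrix makes allelic imbalance visible as column separation by allele
    (the expected dominant component in an MPRA with true allelic effects).
    """
    rows = parse_construct_index(counts.index)
    frames = {}
    for allele in ("ref", "alt"):
        sub = counts[rows["allele"] == allele].copy()
        sub.index = [f"{t}|{d}" for t, d in zip(
            rows.loc[rows["allele"] == allele, "target_id"],
            rows.loc[rows["allele"] == allele, "direction"])]
        for col in counts.columns:
            frames[f"{col}@{allele}"] = sub[col]
    return pd.DataFrame(frames)


# ---------------------------------------------------------------------------
# per-target NB fit
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    if alpha < _ALPHA_FLOOR:
        alpha = _ALPHA_FLOOR
    r = 1.0 / alpha
    return float(np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
                        + y * np.log(mu / (mu + r))
                        + r * np.log(r / (mu + r))))


def _profile_alpha(y: np.ndarray, mu: np.ndarray,
                   X: np.ndarray | None = None) -> float:
    """Dispersion by (Cox-Reid adjusted) profile maximum likelihood.

    The adjustment term ``-0.5 log det(X' W X)`` accounts for the degrees of
    freedom absorbed by the fitted coefficients; without it the dispersion is
    biased low at a handful of samples and the Wald test is anti-conservative.
    """

    def neg_apl(la: float) -> float:
        alpha = 10.0 ** la
        ll = _nb_loglik(y, mu, alpha)
        if X is not None:
            w = mu / (1.0 + alpha * mu)  # NB2 log-link working weights
            xtwx = X.T @ (X * w[:, None])
            sign, logdet = np.linalg.slogdet(xtwx)
            ll -= 0.5 * logdet if sign > 0 else 0.0
        return -ll

    res = optimize.minimize_scalar(
        neg_apl, bounds=(np.log10(_ALPHA_FLOOR), np.log10(_ALPHA_CEIL)),
        method="bounded", options={"xatol": 1e-4})
    return float(10.0 ** res.x)


@dataclasses.dataclass
class DaResult:
    """Treatment effect on one target's activity in one direction."""

    target_id: str
    direction: str
    lfc_treatment: float  # log2 fold-change, treatment vs control
    se_lfc: float
    wald: float
    p: float
    alpha: float  # profiled NB dispersion
    lfc_allele: float
    q: float | None = None


def fit_nb_da(counts: np.ndarray, allele: np.ndarray, condition: np.ndarray,
              log_size_factors: np.ndarray, *, target_id: str = "",
              direction: str = "fwd", treatment: str = "caffeine",
              test: str = "wald", max_iter: int = 10,
              tol: float = 1e-3, alpha: float | None = None) -> DaResult:
    """NB GLM treatment test for one target (both alleles, all samples).

    ``counts`` is the flat vector of construct counts; ``allele`` and
    ``condition`` are parallel label arrays; ``log_size_factors`` enters as
    an offset.  ``test`` selects ``"wald"`` (default) or ``"lr"``.  Passing
    ``alpha`` fixes the NB dispersion instead of profiling it.
    """
    y = np.asarray(counts, dtype=float)
    is_alt = (np.asarray(allele) == "alt").astype(float)
    is_trt = (np.asarray(condition) == treatment).astype(float)
    if len({a for a in allele}) < 2:
        raise InputError(f"target {target_id}: both alleles required")
    for label, mask in (("treatment", is_trt == 1), ("control", is_trt == 0)):
        if y[mask].sum() == 0:
            raise EstimationError(
                f"target {target_id}: all-zero counts in {label} samples")
    X = np.column_stack([np.ones_like(y), is_alt, is_trt])
    offset = np.asarray(log_size_factors, dtype=float)

    fixed_alpha = alpha is not None
    alpha = max(alpha, _ALPHA_FLOOR) if fixed_alpha else 0.1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(0 if fixed_alpha else max_iter):
            model = sm.GLM(y, X, offset=offset,
                           family=sm.families.NegativeBinomial(alpha=alpha))
            fit = model.fit()
            new_alpha = _profile_alpha(y, fit.mu, X)
            if abs(np.log(new_alpha) - np.log(alpha)) < tol:
                alpha = new_alpha
                break
            alpha = new_alpha
        fit = sm.GLM(y, X, offset=offset,
                     family=sm.families.NegativeBinomial(alpha=alpha)).fit()
        b_trt, se = float(fit.params[2]), float(fit.bse[2])
        if test == "lr":
            reduced = sm.GLM(y, X[:, :2], offset=offset,
                             family=sm.families.NegativeBinomial(alpha=alpha)
                             ).fit()
            lr = 2.0 * (fit.llf - reduced.llf)
            p = float(stats.chi2.sf(max(lr, 0.0), df=1))
            wald = float(np.sign(b_trt) * np.sqrt(max(lr, 0.0)))
        elif test == "wald":
            wald = b_trt / se
            # Student-t reference on the residual df: the dispersion is
            # estimated from the same handful of samples, so a normal
            # reference is anti-conservative
            df = max(len(y) - X.shape[1], 1)
            p = 2.0 * float(stats.t.sf(abs(wald), df))
        else:
            raise InputError(f"unknown test {test!r}")
    return DaResult(target_id, direction, b_trt / _LN2, se / _LN2, wald, p,
                    alpha, float(fit.params[1]) / _LN2)


def da_classify(results: pd.DataFrame, fdr: float = 0.10) -> pd.DataFrame:
    """Combine per-direction tests into target-level calls.

    A target is significant when q < ``fdr`` in either direction; its
    direction of change follows the sign of the significant direction's
    log2 fold-change (the smaller-q direction when both qualify).
    """
    need = {"target_id", "direction", "lfc_treatment", "q"}
    if not need <= set(results.columns):
        raise InputError(f"results must have columns {sorted(need)}")
    rows = []
    for target, grp in results.groupby("target_id", sort=True):
        ok = grp[grp["q"].notna() & (grp["q"] < fdr)]
        if ok.empty:
            rows.append((target, False, None, np.nan, np.nan))
            continue
        best = ok.loc[ok["q"].idxmin()]
        change = "up" if best["lfc_treatment"] > 0 else "down"
        rows.append((target, True, change, float(best["lfc_treatment"]),
                     float(best["q"])))
    return pd.DataFrame(rows, columns=["target_id", "significant",
                                       "direction_of_change", "lfc", "q"])


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------

def parse_construct_index(index) -> pd.DataFrame:
    """Split ``target|allele|direction`` row labels into columns."""
    parts = [str(i).split("|") for i in index]
    bad = [i for i, p in zip(index, parts) if len(p) != 3]
    if bad:
        raise InputError(f"row label {bad[0]!r} is not target|allele|direction")
    return pd.DataFrame(parts, columns=["target_id", "allele", "direction"],
                        index=index)


class ActivityModel:
    """Per-direction NB treatment model over a construct-by-sample matrix.

    Parameters
    ----------
    counts:
        DataFrame of non-negative integer counts; rows labelled
        ``target|allele|direction``, columns are RNA sample ids.
    samples:
        DataFrame indexed by sample id with a ``condition`` column
        (``control``/``caffeine``).
    treatment:
        Condition label treated as the exposure.

    Examples
    --------
    >>> res = ActivityModel(counts, samples).fit()
    >>> res.frame.query("direction == 'fwd'").head()
    >>> res.classify(fdr=0.10)
    """

    def __init__(self, counts: pd.DataFrame, samples: pd.DataFrame, *,
                 treatment: str = "caffeine", test: str = "wald"):
        missing = [s for s in counts.columns if s not in samples.index]
        if missing:
            raise InputError(f"sample {missing[0]!r} missing from sample table")
        self.counts = counts
        self.samples = samples.loc[counts.columns]
        self.treatment = treatment
        self.test = test
        self.rows = parse_construct_index(counts.index)
        conds = self.samples["condition"]
        for label in ("control", treatment):
            if (conds == label).sum() < 2:
                raise InputError(f"need >= 2 samples in condition {label!r}")

    def fit(self) -> "ActivityResults":
        factors = size_factors(self.counts)
        log_sf = np.log(factors.to_numpy(dtype=float))
        condition = self.samples["condition"].to_numpy()
        results: list[DaResult] = []
        untested: list[tuple[str, str, str]] = []
        for direction in sorted(self.rows["direction"].unique()):
            dir_rows = self.rows[self.rows["direction"] == direction]
            for target, grp in dir_rows.groupby("target_id", sort=True):
                sub = self.counts.loc[grp.index].to_numpy(dtype=float)
                allele = np.repeat(grp["allele"].to_numpy(), sub.shape[1])
                cond = np.tile(condition, sub.shape[0])
                sf = np.tile(log_sf, sub.shape[0])
                try:
                    results.append(fit_nb_da(
                        sub.ravel(), allele, cond, sf, target_id=target,
                        direction=direction, treatment=self.treatment,
                        test=self.test))
                except (EstimationError, InputError) as exc:
                    untested.append((target, direction, str(exc)))
                    logger.debug("untested target: %s", exc)
        if not results:
            raise EstimationError("no target could be tested")
        frame = pd.DataFrame([dataclasses.asdict(r) for r in results])
        frame["q"] = np.nan
        for direction, grp in frame.groupby("direction"):
            frame.loc[grp.index, "q"] = bh_adjust(grp["p"].to_numpy())
        return ActivityResults(self, frame, factors, untested)


class ActivityResults:
    """Per-direction treatment effects with per-direction BH q-values."""

    def __init__(self, model: ActivityModel, frame: pd.DataFrame,
                 factors: pd.Series, untested: list):
        self.model = model
        self.frame = frame
        self.size_factors = factors
        self.untested = untested

    def classify(self, fdr: float = 0.10) -> pd.DataFrame:
        return da_classify(self.frame, fdr)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self, fdr: float = 0.10) -> str:
        calls = self.classify(fdr)
        sig = calls[calls["significant"]]
        return "\n".join([
            "Differential activity results",
            "=" * 34,
            f"targets tested:       {calls.shape[0]}",
            f"targets untested:     {len(self.untested)}",
            f"significant targets:  {sig.shape[0]} (FDR < {fdr:g}, either "
            "direction)",
            f"  upregulated:        {(sig['direction_of_change'] == 'up').sum()}",
            f"  downregulated:      {(sig['direction_of_change'] == 'down').sum()}",
        ])
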