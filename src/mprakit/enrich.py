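"""Enrichment tests: motif proportions, and annotation overlap by Fisher.

Two flavours of question are answered here.  First, are significant
targets/variants disproportionately found within the binding motif of a given
transcription factor?  That is a one-sample test of proportions per motif: the
observed proportion ``n_c/n_d`` (significant among targets containing *this*
motif) is tested against the null proportion ``n_a/n_b`` (significant among
targets containing *any* motif), with motifs seen in fewer than 100 targets
removed first.  Second, are significant variants enriched inside a genomic
annotation (open chromatin, eQTL membership)?  That is a 2x2 Fisher's exact
test on significance x annotation flags, reported with the conditional-MLE
odds ratio and the plain fold enrichment.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio
from intervaltree import IntervalTree

from .exceptions import InputError
from .io import GenomicInterval

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# test of proportions (R prop.test semantics)
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MotifEnrichmentResult:
    """Per-motif proportion test against the any-motif baseline."""

    motif_id: str
    n_a: int  # significant items within any motif
    n_b: int  # all items within any motif
    n_c: int  # significant items within this motif
    n_d: int  # all items within this motif
    null_prop: float
    obs_prop: float
    ci_low: float
    ci_high: float
    p: float


def _wilson_cc(x: int, n: int, conf: float = 0.95):
    """Wilson score interval with continuity correction (prop.test style)."""
    z = stats.norm.ppf(1.0 - (1.0 - conf) / 2.0)
    est = x / n
    z22n = z * z / (2.0 * n)
    p_c = est + 0.5 / n
    if p_c >= 1.0:
        upper = 1.0
    else:
        upper = (p_c + z22n + z * np.sqrt(p_c * (1 - p_c) / n
                                          + z22n / (2.0 * n))) \
            / (1.0 + 2.0 * z22n)
    p_c = est - 0.5 / n
    if p_c <= 0.0:
        lower = 0.0
    else:
        lower = (p_c + z22n - z * np.sqrt(p_c * (1 - p_c) / n
                                          + z22n / (2.0 * n))) \
            / (1.0 + 2.0 * z22n)
    return max(lower, 0.0), min(upper, 1.0)


def proportion_test(n_a: int, n_b: int, n_c: int, n_d: int,
                    motif_id: str = "", correct: bool = True
                    ) -> MotifEnrichmentResult:
    """One-sample chi-squared test of ``n_c/n_d`` against null ``n_a/n_b``.

    Yates continuity correction is applied by default; the 95% CI for the
    observed proportion is Wilson with continuity correction.  The two-sided
    p-value comes from the chi-squared distribution with 1 df.
    """
    if n_b <= 0 or n_d <= 0:
        raise InputError("n_b and n_d must be positive")
    if not (0 <= n_c <= n_d and 0 <= n_a <= n_b and n_c <= n_a and n_d <= n_b):
        raise InputError(
            f"inconsistent counts n_a={n_a}, n_b={n_b}, n_c={n_c}, n_d={n_d}")
    p0 = n_a / n_b
    obs = n_c / n_d
    if 0.0 < p0 < 1.0:
        expected = n_d * p0
        yates = min(0.5, abs(n_c - expected)) if correct else 0.0
        chi2 = (abs(n_c - expected) - yates) ** 2 / (n_d * p0 * (1.0 - p0))
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        p = 1.0 if obs == p0 else 0.0
    ci_low, ci_high = _wilson_cc(n_c, n_d)
    return MotifEnrichmentResult(motif_id, n_a, n_b, n_c, n_d, p0, obs,
                                 ci_low, ci_high, p)


def motif_enrichment(hits: pd.DataFrame, significant: Iterable[str],
                     target_of=None, min_occurrence: int = 100,
                     strict: bool = False, correct: bool = True,
                     bh: bool = False) -> pd.DataFrame:
    """Proportion tests for every motif passing the occurrence filter.

    ``hits`` is a scanner output frame; ``significant`` the set of target ids
    called significant by the upstream analysis.  Motifs present in fewer
    than ``min_occurrence`` targets are removed before testing.  ``bh=True``
    adds a BH-adjusted column (off by default; the conventional report is
    nominal p < 0.05).
    """
    from .motifs import filter_motifs_by_occurrence

    significant = set(significant)
    if hits.empty:
        return pd.DataFrame(columns=[f.name for f in dataclasses.fields(
            MotifEnrichmentResult)])
    targets = hits["sequence_id"]
    if target_of is not None:
        targets = targets.map(lambda s: target_of.get(s, s))
    pairs = pd.DataFrame({"motif_id": hits["motif_id"],
                          "target": targets}).drop_duplicates()
    any_motif = set(pairs["target"])
    n_b = len(any_motif)
    n_a = len(any_motif & significant)
    keep = set(filter_motifs_by_occurrence(hits, min_occurrence, strict,
                                           target_of))
    rows = []
    for motif_id, grp in pairs.groupby("motif_id", sort=True):
        if motif_id not in keep:
            continue
        in_motif = set(grp["target"])
        n_d = len(in_motif)
        if n_d == 0:  # unreachable in practice; kept for the contract
            logger.info("motif %s: no targets, skipped", motif_id)
            continue
        n_c = len(in_motif & significant)
        rows.append(proportion_test(n_a, n_b, n_c, n_d, motif_id=motif_id,
                                    correct=correct))
    frame = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    if bh and not frame.empty:
        from .ase import bh_adjust

        frame["q"] = bh_adjust(frame["p"].to_numpy())
    return frame


# ---------------------------------------------------------------------------
# interval membership and Fisher enrichment
# ---------------------------------------------------------------------------

def intersect_variants(variants: Sequence[tuple[str, int]],
                       intervals: Iterable[GenomicInterval]) -> np.ndarray:
    """Boolean flag per variant: inside some interval (half-open) or not.

    Chromosome names are matched literally (no ``chr`` aliasing); a warning
    is emitted when nothing overlaps, which usually signals a naming mismatch.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    flags = np.array([chrom in trees and bool(trees[chrom][pos])
                      for chrom, pos in variants], dtype=bool)
    if len(flags) and trees and not flags.any():
        logger.warning("no variant overlaps any interval; check chromosome "
                       "naming conventions")
    return flags


@dataclasses.dataclass(frozen=True)
class FisherResult:
    """2x2 enrichment of an annotation among significant items."""

    odds_ratio: float  # conditional MLE; NaN when a margin is zero
    fold_enrichment: float
    p: float
    table: tuple  # ((sig&ann, sig&!ann), (!sig&ann, !sig&!ann))


def fisher_enrichment(flag_significant: Sequence[bool],
                      flag_annotation: Sequence[bool]) -> FisherResult:
    """Two-sided Fisher's exact test of annotation x significance.

    ``fold_enrichment`` is the annotated proportion among significant items
    divided by the annotated proportion among non-significant items.
    """
    sig = np.asarray(flag_significant, dtype=bool)
    ann = np.asarray(flag_annotation, dtype=bool)
    if sig.shape != ann.shape:
        raise InputError("flag vectors must have equal length")
    a = int(np.sum(sig & ann))
    b = int(np.sum(sig & ~ann))
    c = int(np.sum(~sig & ann))
    d = int(np.sum(~sig & ~ann))
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("degenerate 2x2 table %s: p=1, odds ratio undefined",
                       table.tolist())
        return FisherResult(float("nan"), float("nan"), 1.0,
                            ((a, b), (c, d)))
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    or_cmle = float(_odds_ratio(table, kind="conditional").statistic)
    fold = (a / (a + b)) / (c / (c + d)) if (a + b) and (c + d) and c \
        else float("inf") if a else float("nan")
    return FisherResult(or_cmle, fold, p, ((a, b), (c, d)))
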