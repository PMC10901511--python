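"""PWM construction and motif scanning over designed target sequences.

A position frequency matrix is turned into a log-odds position weight matrix
in bits against a background base composition, and sequences are scanned with
an additive score; windows at or above a bit threshold (10 bits by default)
are reported as hits.  Both strands are scanned by default because the
designed library carries regulatory elements in both orientations.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import InputError
from .io import BASES, PositionFrequencyMatrix

DEFAULT_THRESHOLD_BITS = 10.0

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base -> row index; N and anything unknown -> 4 (scores -inf, killing the window)
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass(frozen=True)
class PwmModel:
    """Log-odds scoring matrix in bits (rows A, C, G, T)."""

    motif_id: str
    matrix: np.ndarray  # (4, L)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))


def pfm_to_pwm(pfm: PositionFrequencyMatrix, pseudocount: float = 0.25,
               background: np.ndarray | None = None) -> PwmModel:
    """Log2-odds PWM from a PFM with per-cell pseudocount and background.

    ``entry(b, j) = log2(((count(b,j)+pc) / (colsum_j+4*pc)) / background_b)``.
    """
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or (background <= 0).any() \
            or abs(background.sum() - 1.0) > 1e-8:
        raise InputError("background must be 4 positive values summing to 1")
    counts = pfm.counts
    colsum = counts.sum(axis=0, keepdims=True)
    if pseudocount <= 0 and (colsum == 0).any():
        raise InputError(
            f"motif {pfm.motif_id}: zero column sum with zero pseudocount")
    probs = (counts + pseudocount) / (colsum + 4.0 * pseudocount)
    matrix = np.log2(probs / background[:, None])
    pwm = PwmModel(pfm.motif_id, matrix)
    score_range = matrix.max(axis=0) - matrix.min(axis=0)
    if not (score_range > 0).any():
        # a perfectly uniform PFM scores 0 everywhere; legal but useless
        import logging

        logging.getLogger(__name__).warning(
            "motif %s: uninformative PWM (no column discriminates bases)",
            pfm.motif_id)
    return pwm


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Additive PWM score of every window; windows containing N are -inf."""
    L = matrix.shape[1]
    n_win = codes.size - L + 1
    if n_win <= 0:
        return np.empty(0)
    # 5th row = -inf sentinel for N / unknown bases
    lut = np.vstack([matrix, np.full((1, L), -np.inf)])
    scores = np.zeros(n_win)
    for j in range(L):
        scores += lut[codes[j:j + n_win], j]
    return scores


def scan_sequences(pwm: PwmModel, sequences: Mapping[str, str],
                   threshold_bits: float = DEFAULT_THRESHOLD_BITS,
                   both_strands: bool = True) -> pd.DataFrame:
    """Report every window scoring >= ``threshold_bits``.

    Offsets are 0-based on the given (forward) sequence for both strands; a
    ``-`` strand hit at offset ``o`` means the reverse complement of
    ``seq[o:o+L]`` matches.  Windows containing N are skipped.
    """
    records = []
    L = pwm.length
    rc_matrix = pwm.matrix[::-1, ::-1]  # score of revcomp window, fwd coords
    for seq_id, seq in sequences.items():
        codes = _encode(seq)
        for strand, matrix in (("+", pwm.matrix),) + (
                (("-", rc_matrix),) if both_strands else ()):
            scores = _window_scores(codes, matrix)
            for offset in np.flatnonzero(scores >= threshold_bits):
                records.append((seq_id, pwm.motif_id, int(offset), strand,
                                float(scores[offset])))
    return pd.DataFrame(records, columns=["sequence_id", "motif_id", "offset",
                                          "strand", "score_bits"])


def scan_motifs(pwms: Iterable[PwmModel], sequences: Mapping[str, str],
                threshold_bits: float = DEFAULT_THRESHOLD_BITS,
                both_strands: bool = True) -> pd.DataFrame:
    frames = [scan_sequences(p, sequences, threshold_bits, both_strands)
              for p in pwms]
    if not frames:
        return pd.DataFrame(columns=["sequence_id", "motif_id", "offset",
                                     "strand", "score_bits"])
    return pd.concat(frames, ignore_index=True)


def motif_target_counts(hits: pd.DataFrame,
                        target_of: Mapping[str, str] | None = None
                        ) -> pd.Series:
    """Number of distinct targets containing each motif (once per target).

    ``target_of`` optionally maps sequence ids to target ids (several
    construct sequences may derive from one designed target).
    """
    if hits.empty:
        return pd.Series(dtype=int, name="n_targets")
    targets = hits["sequence_id"]
    if target_of is not None:
        targets = targets.map(lambda s: target_of.get(s, s))
    frame = pd.DataFrame({"motif_id": hits["motif_id"], "target": targets})
    return (frame.drop_duplicates().groupby("motif_id")["target"].nunique()
            .rename("n_targets"))


def filter_motifs_by_occurrence(hits: pd.DataFrame, min_occurrence: int = 100,
                                strict: bool = False,
                                target_of: Mapping[str, str] | None = None
                                ) -> list[str]:
    """Motifs present in at least ``min_occurrence`` targets.

    ``strict=True`` switches the boundary to a strictly-greater-than rule
    (occurrence must exceed the cutoff).
    """
    counts = motif_target_counts(hits, target_of)
    keep = counts > min_occurrence if strict else counts >= min_occurrence
    return sorted(counts[keep].index)
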