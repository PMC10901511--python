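"""Readers, writers and validators for the formats the pipeline touches.

The pipeline's entry point is a long-form allele count table (TSV); upstream
read processing (demultiplexing, alignment, deduplication, pileup) is done by
external tools.  Only the UMI pattern rule is re-implemented here as a
stand-alone validator so count tables produced elsewhere can be sanity-checked.

Coordinates are 0-based half-open everywhere (BED convention); a variant
position is the single-base interval ``[pos, pos + 1)``.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FormatError

logger = logging.getLogger(__name__)

#: Columns of the long-form allele count table, in canonical order.
COUNT_COLUMNS = (
    "snp_id",
    "direction",
    "allele",
    "sample_id",
    "condition",
    "replicate",
    "count",
)

DIRECTIONS = ("fwd", "rev")
ALLELES = ("ref", "alt")
CONDITIONS = ("dna", "control", "caffeine")

#: IUPAC nucleotide codes and the bases each one matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


# ---------------------------------------------------------------------------
# allele count tables
# ---------------------------------------------------------------------------

def validate_allele_counts(table: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    """Validate a long-form allele count table.

    Checks column presence, categorical values, non-negative integer counts,
    key uniqueness, and that every SNP/direction seen in RNA also has DNA
    counts for both alleles (the DNA library is the null expectation for the
    RNA allelic ratio, so RNA rows without it are untestable).

    Raises :class:`FormatError` naming the offending row on the first
    violation; returns the table with canonical dtypes otherwise.
    """
    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{source}: missing column(s) {missing}")
    table = table.loc[:, list(COUNT_COLUMNS)].copy()

    for col, allowed in (("direction", DIRECTIONS), ("allele", ALLELES),
                         ("condition", CONDITIONS)):
        bad = ~table[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{source}: row {row}: invalid {col} "
                f"{table[col].iloc[row]!r} (allowed: {allowed})")

    counts = pd.to_numeric(table["count"], errors="coerce")
    bad = counts.isna() | (counts < 0) | (counts != counts.round())
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"{source}: row {row}: count {table['count'].iloc[row]!r} "
            "is not a non-negative integer")
    table["count"] = counts.astype(np.int64)
    table["replicate"] = pd.to_numeric(table["replicate"]).astype(np.int64)
    if (table["replicate"] < 1).any():
        row = int(np.flatnonzero((table["replicate"] < 1).to_numpy())[0])
        raise FormatError(f"{source}: row {row}: replicate must be >= 1")

    key = ["snp_id", "direction", "allele", "sample_id"]
    dup = table.duplicated(subset=key)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise FormatError(
            f"{source}: row {row}: duplicate key "
            f"{tuple(table.loc[table.index[row], key])}")

    # every RNA (snp, direction) needs DNA rows for both alleles
    is_dna = table["condition"] == "dna"
    rna_pairs = set(map(tuple, table.loc[~is_dna, ["snp_id", "direction"]]
                        .drop_duplicates().to_numpy()))
    dna = table.loc[is_dna, ["snp_id", "direction", "allele"]].drop_duplicates()
    dna_full = dna.groupby(["snp_id", "direction"])["allele"].nunique()
    covered = set(dna_full[dna_full == 2].index)
    orphans = rna_pairs - covered
    if orphans:
        snp, direction = sorted(orphans)[0]
        raise FormatError(
            f"{source}: RNA rows for ({snp}, {direction}) lack DNA rows for "
            "both alleles; every RNA SNP/direction requires a DNA baseline")
    return table


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-form allele count TSV."""
    try:
        table = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse TSV: {exc}") from exc
    return validate_allele_counts(table, source=str(path))


def write_allele_counts(table: pd.DataFrame, path: str | Path) -> None:
    table.loc[:, list(COUNT_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# UMI validation
# ---------------------------------------------------------------------------

def validate_umi(umi: str, pattern: str = "RDHBVDHBVD") -> bool:
    """True iff ``umi`` matches the IUPAC ``pattern`` position by position.

    Length must match exactly: short (or long) UMIs are rejected, mirroring
    the read-filtering rule applied upstream of the count tables.
    """
    for code in pattern:
        if code not in IUPAC:
            raise ConfigurationError(
                f"pattern contains non-IUPAC character {code!r}")
    if len(umi) != len(pattern):
        return False
    return all(base in IUPAC[code] for base, code in zip(umi, pattern))


# ---------------------------------------------------------------------------
# genomic intervals (BED)
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3+ column BED file into validated intervals.

    The fourth column, when present, is kept as the interval name; further
    columns are ignored.  Blank lines and ``track``/``browser``/``#`` lines
    are skipped.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}: line {lineno}: invalid interval "
                    f"{chrom}:{start}-{end} (need 0 <= start < end)")
            name = fields[3] if len(fields) > 3 else None
            intervals.append(GenomicInterval(chrom, start, end, name))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as handle:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None:
                fields.append(iv.name)
            handle.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# JASPAR position frequency matrices
# ---------------------------------------------------------------------------

BASES = "ACGT"


@dataclasses.dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Base counts per motif position; rows ordered A, C, G, T."""

    motif_id: str
    counts: np.ndarray  # shape (4, L), non-negative
    name: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise FormatError(
                f"motif {self.motif_id}: counts must be a 4 x L matrix")
        if (counts < 0).any():
            raise FormatError(f"motif {self.motif_id}: negative counts")
        if (counts.sum(axis=0) <= 0).any():
            raise FormatError(
                f"motif {self.motif_id}: column with no positive entry")
        object.__setattr__(self, "counts", counts)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        """Highest-count base at each position (ties broken A<C<G<T)."""
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


def read_jaspar_pfm(path: str | Path) -> list[PositionFrequencyMatrix]:
    """Read a JASPAR-format PFM text file.

    Expected layout per motif: a ``>ID NAME`` header followed by four rows
    ``A  [ 1 2 3 ]`` ... in A, C, G, T order (the bracket-delimited JASPAR
    2016+ flavour; bare number rows are accepted too).
    """
    motifs: list[PositionFrequencyMatrix] = []
    header: tuple[str, str, int] | None = None  # id, name, lineno
    rows: list[tuple[str, list[float], int]] = []

    def flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        motif_id, name, lineno = header
        if len(rows) != 4:
            raise FormatError(
                f"{path}: motif {motif_id} (line {lineno}): expected 4 base "
                f"rows, found {len(rows)}")
        lengths = {len(vals) for _, vals, _ in rows}
        if len(lengths) != 1:
            raise FormatError(
                f"{path}: motif {motif_id} (line {lineno}): rows of unequal length")
        letters = [letter for letter, _, _ in rows]
        if letters != list(BASES) and letters != ["", "", "", ""]:
            raise FormatError(
                f"{path}: motif {motif_id} (line {lineno}): base rows must be "
                f"ordered A,C,G,T (got {letters})")
        counts = np.array([vals for _, vals, _ in rows], dtype=float)
        if (counts < 0).any():
            bad = rows[int(np.argwhere(counts < 0)[0][0])]
            raise FormatError(
                f"{path}: line {bad[2]}: negative count in motif {motif_id}")
        motifs.append(PositionFrequencyMatrix(motif_id, counts, name=name))
        header, rows = None, []

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                if not parts:
                    raise FormatError(f"{path}: line {lineno}: empty header")
                header = (parts[0], parts[1] if len(parts) > 1 else "", lineno)
            else:
                if header is None:
                    raise FormatError(
                        f"{path}: line {lineno}: count row before any header")
                letter = ""
                body = line
                if body[0] in "ACGTacgt" and (len(body) == 1 or not body[1].isdigit()):
                    letter, body = body[0].upper(), body[1:]
                body = body.replace("[", " ").replace("]", " ")
                try:
                    vals = [float(v) for v in body.split()]
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: non-numeric count") from exc
                rows.append((letter, vals, lineno))
    flush()
    return motifs


def write_jaspar_pfm(motifs: Sequence[PositionFrequencyMatrix],
                     path: str | Path) -> None:
    with open(path, "w") as handle:
        for motif in motifs:
            name = f" {motif.name}" if motif.name else ""
            handle.write(f">{motif.motif_id}{name}\n")
            for base, row in zip(BASES, motif.counts):
                vals = " ".join(f"{v:g}" for v in row)
                handle.write(f"{base}  [ {vals} ]\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as handle:
        for rec_id, seq in records:
            handle.write(f">{rec_id}\n{seq}\n")


# ---------------------------------------------------------------------------
# flat key-value config files
# ---------------------------------------------------------------------------

def read_config_file(path: str | Path) -> dict[str, str]:
    """Read a flat ``key = value`` config file (``#`` comments allowed)."""
    out: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}: line {lineno}: expected key = value")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def write_config_file(values: dict, path: str | Path) -> None:
    with open(path, "w") as handle:
        for key, value in values.items():
            handle.write(f"{key} = {value}\n")
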