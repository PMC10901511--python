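"""Synthetic MPRA library and count generator with full ground truth.

Emulates the statistical structure the downstream tests assume, at arbitrary
scale: biallelic 200-nt targets with a centered SNP, forward/reverse
orientation copies, a DNA plasmid library with uneven allelic proportions,
six RNA replicates in each of two conditions (control, caffeine) with
beta-binomial overdispersed allele counts, a minority of true allelic effects
(shared or condition-specific), negative-control targets with exactly zero
effects, negative-binomial activity counts with a treatment fold-change, and
optionally planted motif occurrences biased toward effect-carrying targets.

Everything is driven by a single :class:`SimConfig`; identical configs
(including the seed) produce byte-identical outputs.  The truth channel
(:class:`SimTruth`) records every planted effect so recovery and calibration
can be measured exactly.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import ConfigurationError
from .io import (PositionFrequencyMatrix, write_config_file, write_fasta,
                 read_config_file)
from .motifs import reverse_complement

CONDITIONS = ("control", "caffeine")


@dataclasses.dataclass
class SimConfig:
    """Generator parameters; defaults are the study-scale conditions.

    ``frac_negative_control`` defaults to the designed library's share of
    negative-control sequences (1676 of 43,556).  ``mean_depth`` is the
    expected total RNA reads per SNP/direction per replicate; the DNA library
    is sequenced ``dna_depth_factor`` times deeper (one deep input pool
    against six RNA replicates) and with its own, near-binomial dispersion
    ``rho_dna``.
    """

    n_targets: int = 1000
    target_length: int = 200
    frac_negative_control: float = 1676 / 43556
    n_replicates: int = 6
    mean_depth: float = 300.0
    depth_dispersion: float = 0.3
    dna_proportion_concentration: float = 5.0
    rho: float = 0.05
    rho_dna: float = 0.0
    dna_depth_factor: float = 20.0
    dna_depth_dispersion: float = 0.05
    n_dna_replicates: int = 1
    frac_ase: float = 0.1
    frac_case: float = 0.05
    effect_sd: float = 1.0
    direction_specific_effects: bool = False
    da_frac: float = 0.1
    da_lfc_sd: float = 0.5
    nb_dispersion: float = 0.05
    size_factor_sd: float = 0.2
    motif_set: Sequence[PositionFrequencyMatrix] = ()
    motif_plant_base_rate: float = 0.15
    motif_ase_multiplier: float = 2.0
    seed: int = 0

    #: number of RNA conditions; the design is two-condition plus DNA
    n_conditions: int = dataclasses.field(default=2, init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_targets <= 0 or self.target_length <= 0 \
                or self.n_replicates <= 0 or self.n_dna_replicates <= 0:
            raise ConfigurationError("sizes must be positive")
        if self.target_length % 2 != 0:
            raise ConfigurationError("target_length must be even so the SNP "
                                     "sits at position target_length // 2")
        for name in ("frac_negative_control", "frac_ase", "frac_case",
                     "da_frac", "motif_plant_base_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.frac_ase + self.frac_case > 1.0:
            raise ConfigurationError("frac_ase + frac_case must be <= 1")
        for name in ("rho", "rho_dna"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1), got {v}")
        if self.mean_depth <= 0 or self.dna_depth_factor <= 0:
            raise ConfigurationError("depths must be positive")
        if self.effect_sd < 0 or self.da_lfc_sd < 0 or self.size_factor_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if self.depth_dispersion < 0 or self.nb_dispersion < 0:
            raise ConfigurationError("dispersions must be >= 0")

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        raw = read_config_file(path)
        kwargs: dict = {}
        for field in dataclasses.fields(cls):
            if not field.init or field.name not in raw:
                continue
            value = raw[field.name]
            if field.type in ("int", int):
                kwargs[field.name] = int(value)
            elif field.type in ("float", float):
                kwargs[field.name] = float(value)
            elif field.type in ("bool", bool):
                kwargs[field.name] = value.lower() in ("1", "true", "yes")
            else:
                raise ConfigurationError(
                    f"field {field.name} cannot be set from a config file")
        return cls(**kwargs)

    def to_file(self, path) -> None:
        values = {f.name: getattr(self, f.name)
                  for f in dataclasses.fields(self)
                  if f.init and f.name != "motif_set"}
        write_config_file(values, path)


@dataclasses.dataclass
class SimTruth:
    """Ground truth emitted alongside every simulated dataset.

    ``snps`` has one row per SNP: the true per-condition log-odds effects,
    effect-class flags, DNA reference proportion, activity fold-change and
    any planted motif.  Negative controls have all effects exactly zero.
    """

    snps: pd.DataFrame
    config: SimConfig

    def __post_init__(self) -> None:
        neg = self.snps["is_negative_control"]
        cols = ["true_beta_control", "true_beta_caffeine", "true_da_lfc"]
        if (self.snps.loc[neg, cols] != 0).any().any():
            raise ConfigurationError(
                "negative-control SNPs must have exactly zero effects")
        case = self.snps["is_case"]
        equal = (self.snps.loc[case, "true_beta_control"]
                 == self.snps.loc[case, "true_beta_caffeine"])
        if equal.any():
            raise ConfigurationError(
                "cASE SNPs must differ between conditions")

    def to_tsv(self, path) -> None:
        self.snps.to_csv(path, sep="\t", index=False, float_format="%.8g")


def library_combinatorics(n_targets: int) -> dict[str, int]:
    """Designed-library accounting: targets, allele constructs, orientations.

    Each target yields two single-allele constructs, each of which can
    integrate in either orientation.
    """
    if n_targets <= 0:
        raise ConfigurationError("n_targets must be positive")
    return {
        "targets": n_targets,
        "constructs": 2 * n_targets,
        "oriented_constructs": 4 * n_targets,
    }


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

def simulate_library(config: SimConfig):
    """Design a synthetic target library.

    Returns ``(sequences, truth)`` where ``sequences`` has one row per SNP
    with the full-length ref and alt sequences (differing only at the center
    position), and ``truth`` is the :class:`SimTruth` channel.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_targets
    L = config.target_length
    center = L // 2

    snp_ids = np.array([f"snp{i:06d}" for i in range(n)])
    n_neg = round(config.frac_negative_control * n)
    # effect carriers are drawn from the non-negative-control pool and
    # capped by its size (relevant only for degenerate configurations)
    n_ase = min(round(config.frac_ase * n), n - n_neg)
    n_case = min(round(config.frac_case * n), n - n_neg - n_ase)
    is_neg = np.zeros(n, dtype=bool)
    is_neg[:n_neg] = True
    effect_pool = rng.permutation(np.arange(n_neg, n))
    is_ase = np.zeros(n, dtype=bool)
    is_case = np.zeros(n, dtype=bool)
    is_ase[effect_pool[:n_ase]] = True
    is_case[effect_pool[n_ase:n_ase + n_case]] = True

    beta_ctl = np.zeros(n)
    beta_caf = np.zeros(n)
    shared = rng.normal(0.0, config.effect_sd, size=n_ase)
    beta_ctl[is_ase] = shared
    beta_caf[is_ase] = shared
    # condition-specific effects: independent draws per condition
    beta_ctl[is_case] = rng.normal(0.0, config.effect_sd, size=n_case)
    beta_caf[is_case] = rng.normal(0.0, config.effect_sd, size=n_case)

    c = config.dna_proportion_concentration
    p0 = rng.beta(c, c, size=n)

    da = np.zeros(n)
    n_da = round(config.da_frac * n)
    da_idx = rng.choice(np.arange(n_neg, n), size=min(n_da, n - n_neg),
                        replace=False)
    da[da_idx] = rng.normal(0.0, config.da_lfc_sd, size=len(da_idx))

    bases = np.array(list("ACGT"))
    seq_codes = rng.integers(0, 4, size=(n, L))
    ref_base = seq_codes[:, center]
    alt_base = (ref_base + rng.integers(1, 4, size=n)) % 4

    planted = np.array([""] * n, dtype=object)
    plant_offset = np.full(n, -1)
    if config.motif_set:
        rate = np.full(n, config.motif_plant_base_rate)
        rate[is_ase] = np.minimum(
            1.0, config.motif_plant_base_rate * config.motif_ase_multiplier)
        rate[is_neg] = config.motif_plant_base_rate
        for m_i, pfm in enumerate(config.motif_set):
            cons = pfm.consensus()
            cons_codes = np.array(["ACGT".index(b) for b in cons])
            # only the first motif is planted preferentially in ASE targets
            r = rate if m_i == 0 else np.full(n, config.motif_plant_base_rate)
            do_plant = rng.random(n) < r
            offsets = rng.integers(0, L - len(cons) + 1, size=n)
            for i in np.flatnonzero(do_plant):
                off = offsets[i]
                seq_codes[i, off:off + len(cons)] = cons_codes
                if off <= center < off + len(cons):
                    # keep the SNP biallelic: re-read ref, redraw alt
                    ref_base[i] = seq_codes[i, center]
                    alt_base[i] = (ref_base[i] + rng.integers(1, 4)) % 4
                planted[i] = (planted[i] + ";" + pfm.motif_id).lstrip(";")
                plant_offset[i] = off
    seq_codes[:, center] = ref_base

    ref_seqs = ["".join(row) for row in bases[seq_codes]]
    alt_seqs = [s[:center] + bases[a] + s[center + 1:]
                for s, a in zip(ref_seqs, alt_base)]
    sequences = pd.DataFrame({
        "snp_id": snp_ids,
        "ref_seq": ref_seqs,
        "alt_seq": alt_seqs,
    })
    snps = pd.DataFrame({
        "snp_id": snp_ids,
        "is_negative_control": is_neg,
        "is_ase": is_ase,
        "is_case": is_case,
        "true_beta_control": beta_ctl,
        "true_beta_caffeine": beta_caf,
        "dna_ref_proportion": p0,
        "true_da_lfc": da,
        "planted_motif_ids": planted,
        "planted_offset": plant_offset,
    })
    # degenerate draw guard: force strict inequality for cASE rows
    same = snps["is_case"] & (snps["true_beta_control"]
                              == snps["true_beta_caffeine"])
    if same.any():  # pragma: no cover - probability zero with float draws
        snps.loc[same, "true_beta_caffeine"] += 1e-9
    return sequences, SimTruth(snps, config)


def library_fasta_records(sequences: pd.DataFrame):
    """Yield ``(header, seq)`` for every allele x direction construct.

    Headers follow ``snpID|allele|direction``; the reverse direction is the
    reverse complement of the forward sequence.
    """
    for row in sequences.itertuples(index=False):
        for allele, seq in (("ref", row.ref_seq), ("alt", row.alt_seq)):
            yield f"{row.snp_id}|{allele}|fwd", seq
            yield f"{row.snp_id}|{allele}|rev", reverse_complement(seq)


def write_library_fasta(sequences: pd.DataFrame, path: str | Path) -> None:
    write_fasta(library_fasta_records(sequences), path)


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng, mean, dispersion, size):
    """NB draws with Var = mean + dispersion * mean^2 (Poisson at 0)."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _bb_draw(rng, n, mu, rho):
    """Beta-binomial draws of ref counts; rho=0 is plain binomial."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), n.shape)
    if rho <= 0:
        return rng.binomial(n, mu)
    t = (1.0 - rho) / rho
    p = rng.beta(np.maximum(mu * t, 1e-12), np.maximum((1.0 - mu) * t, 1e-12))
    return rng.binomial(n, p)


def simulate_allele_counts(truth: SimTruth, config: SimConfig | None = None
                           ) -> pd.DataFrame:
    """Long-form allele count table for DNA and both RNA conditions.

    Per SNP/direction/replicate the total depth is negative-binomial around
    ``mean_depth``; the reference-allele count is beta-binomial with mean
    ``logit^-1(logit(p0) + true_beta_condition)`` and overdispersion ``rho``.
    DNA depths use ``mean_depth * dna_depth_factor`` and dispersion
    ``rho_dna``.  Both directions share the same true effects unless
    ``direction_specific_effects`` is set, in which case the reverse
    direction's effects are independently redrawn.
    """
    config = config or truth.config
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1]))
    snps = truth.snps
    n = len(snps)
    p0 = snps["dna_ref_proportion"].to_numpy()
    x0 = np.log(p0) - np.log1p(-p0)

    betas = {"control": snps["true_beta_control"].to_numpy(),
             "caffeine": snps["true_beta_caffeine"].to_numpy()}
    dir_betas = {"fwd": betas}
    if config.direction_specific_effects:
        rev = {}
        for cond in CONDITIONS:
            redraw = rng.normal(0.0, config.effect_sd, size=n)
            rev[cond] = np.where(betas[cond] != 0.0, redraw, 0.0)
        dir_betas["rev"] = rev
    else:
        dir_betas["rev"] = betas

    frames = []
    snp_ids = snps["snp_id"].to_numpy()
    for direction in ("fwd", "rev"):
        # DNA library rows
        for rep in range(1, config.n_dna_replicates + 1):
            depth = _nb_draw(rng, config.mean_depth * config.dna_depth_factor,
                             config.dna_depth_dispersion, (n,))
            ref = _bb_draw(rng, depth, p0, config.rho_dna)
            frames.append(pd.DataFrame({
                "snp_id": snp_ids, "direction": direction,
                "allele": "ref", "sample_id": f"dna_{rep}",
                "condition": "dna", "replicate": rep, "count": ref}))
            frames.append(pd.DataFrame({
                "snp_id": snp_ids, "direction": direction,
                "allele": "alt", "sample_id": f"dna_{rep}",
                "condition": "dna", "replicate": rep, "count": depth - ref}))
        # RNA rows
        for cond in CONDITIONS:
            mu = expit(x0 + dir_betas[direction][cond])
            for rep in range(1, config.n_replicates + 1):
                depth = _nb_draw(rng, config.mean_depth,
                                 config.depth_dispersion, (n,))
                ref = _bb_draw(rng, depth, mu, config.rho)
                sample = f"{cond}_{rep}"
                frames.append(pd.DataFrame({
                    "snp_id": snp_ids, "direction": direction,
                    "allele": "ref", "sample_id": sample,
                    "condition": cond, "replicate": rep, "count": ref}))
                frames.append(pd.DataFrame({
                    "snp_id": snp_ids, "direction": direction,
                    "allele": "alt", "sample_id": sample,
                    "condition": cond, "replicate": rep,
                    "count": depth - ref}))
    table = pd.concat(frames, ignore_index=True)
    table["count"] = table["count"].astype(np.int64)
    return table


def simulate_activity_counts(truth: SimTruth, config: SimConfig | None = None):
    """Construct-by-sample NB activity counts plus the sample sheet.

    ``count ~ NB(mean = baseline * size_factor * 2**(lfc_allele * I[alt]
    + true_da_lfc * I[caffeine]), dispersion = nb_dispersion)``.  Per-sample
    size factors are log-normal; per-target baselines are log-normal around
    ``mean_depth``.  The allele activity effect is tied to the allelic
    expression truth (``lfc_allele = -mean(true betas)/ln 2``) so negative
    controls stay flat and the PCA QC signature is reproduced.

    Returns ``(counts, samples)``: counts indexed ``target|allele|direction``
    with one column per RNA sample, and the matching sample sheet.
    """
    config = config or truth.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    snps = truth.snps
    n = len(snps)
    n_rep = config.n_replicates
    sample_ids = [f"{cond}_{rep}" for cond in CONDITIONS
                  for rep in range(1, n_rep + 1)]
    is_caf = np.array([s.startswith("caffeine") for s in sample_ids])
    size_f = np.exp(rng.normal(0.0, config.size_factor_sd,
                               size=len(sample_ids)))
    baseline = np.exp(rng.normal(np.log(config.mean_depth), 0.5, size=n))
    lfc_allele = -(snps["true_beta_control"].to_numpy()
                   + snps["true_beta_caffeine"].to_numpy()) / (2.0 * math.log(2.0))
    da = snps["true_da_lfc"].to_numpy()

    rows = []
    index = []
    for direction in ("fwd", "rev"):
        for allele, a_ind in (("ref", 0.0), ("alt", 1.0)):
            log2_mean = (np.log2(baseline)[:, None]
                         + lfc_allele[:, None] * a_ind
                         + da[:, None] * is_caf[None, :])
            mean = (2.0 ** log2_mean) * size_f[None, :]
            counts = _nb_draw(rng, mean, config.nb_dispersion, mean.shape)
            rows.append(counts)
            index.extend(f"{s}|{allele}|{direction}"
                         for s in snps["snp_id"])
    counts = pd.DataFrame(np.vstack(rows), columns=sample_ids, index=index)
    # interleave so both alleles of a target sit together, sorted by label
    counts = counts.sort_index()
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "condition": ["caffeine" if c else "control" for c in is_caf],
        "replicate": [int(s.split("_")[1]) for s in sample_ids],
    }).set_index("sample_id")
    return counts, samples


def random_pfm(rng_or_seed, length: int = 10, sharpness: float = 85.0,
               motif_id: str = "SYN0001", total: int = 100
               ) -> PositionFrequencyMatrix:
    """A synthetic, sharply informative PFM (for planting and tests)."""
    rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
           else np.random.default_rng(rng_or_seed))
    best = rng.integers(0, 4, size=length)
    counts = np.full((4, length), (total - sharpness) / 3.0)
    counts[best, np.arange(length)] = sharpness
    if sharpness < total / 4.0:
        raise ConfigurationError("sharpness too low for an informative PFM")
    return PositionFrequencyMatrix(motif_id, counts)
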