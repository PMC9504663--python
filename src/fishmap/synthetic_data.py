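"""Seeded generators for toy genomes, genetic maps and signal measurements.

These generators make the whole pipeline testable without downloads. They
emulate the features of a real probe-design target that the method actually
exercises: a gene-bearing genome with soft-masked repeat families (tandem and
dispersed) and diverged paralogs; a genetic map whose cM coordinates come from
integrating a recombination-rate profile with suppressed zones (so marker
order scrambles exactly where recombination is suppressed); and noisy
per-metaphase RPHC measurements with a detection probability per homolog.

Every generator is deterministic for a fixed seed and emits truth tables
sufficient to score the downstream modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .sequence_io import SequenceRecord

__all__ = [
    "RepeatFamily",
    "GenomeSpec",
    "MapSpec",
    "SyntheticGenome",
    "generate_genome",
    "generate_genetic_map",
    "simulate_signals",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class RepeatFamily:
    """A repeat family to plant: unit length, copy number, tandem or dispersed."""

    name: str
    unit_length: int = 300
    copies: int = 10
    tandem: bool = False


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of a synthetic gene-bearing genome."""

    n_chromosomes: int = 2
    chromosome_length: int = 200_000
    gene_count: int = 20
    gene_length: int = 3000
    intron_count: int = 1
    intron_length: tuple[int, int] = (200, 800)
    repeat_families: tuple[RepeatFamily, ...] = (
        RepeatFamily("satellite", unit_length=300, copies=20, tandem=True),
        RepeatFamily("retro", unit_length=500, copies=15, tandem=False),
    )
    paralog_rate: float = 0.0
    paralog_divergence: float = 0.05
    seed: int = 0


@dataclass(frozen=True)
class MapSpec:
    """Parameters of a synthetic genetic map along an FL axis [0, 100]."""

    suppressed_zones: tuple[tuple[float, float, float], ...] = ()
    base_rate: float = 1.0  # cM per FL unit outside suppressed zones
    noise_sd_cM: float = 0.0
    flipped: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi, factor in self.suppressed_zones:
            if not (0 <= lo < hi <= 100):
                raise ValueError(f"zone [{lo}, {hi}] outside [0, 100]")
            if not (0 <= factor <= 1):
                raise ValueError("recombination factor must be in [0, 1]")


@dataclass
class SyntheticGenome:
    """A generated genome plus the truth tables describing planted features."""

    chromosomes: list[SequenceRecord]
    transcripts: list[SequenceRecord]
    genes: pd.DataFrame        # gene_id, seq_id, start, end, strand
    repeats: pd.DataFrame      # family, seq_id, start, end
    paralogs: pd.DataFrame     # gene_id, paralog_of, seq_id, start, end
    seed: int = 0


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base with probability ``rate`` (no indels)."""
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < rate
    if hit.any():
        subs = _BASES[rng.integers(0, 4, size=int(hit.sum()))]
        # force a real substitution where the draw equals the original
        same = subs == chars[hit]
        while same.any():
            subs[same] = _BASES[rng.integers(0, 4, size=int(same.sum()))]
            same = subs == chars[hit]
        chars[hit] = subs
    return "".join(chars)


def generate_genome(spec: GenomeSpec) -> SyntheticGenome:
    """Generate a genome with planted genes, repeats and paralogs.

    Features are planted at non-overlapping loci on a random background.
    Repeats are written soft-masked (lowercase) so the masking filters are
    exercised; genes stay uppercase. Each gene's transcript is the
    concatenation of its exons (introns spliced out). Raises when the
    requested features cannot be packed into the chromosomes.
    """
    rng = np.random.default_rng(spec.seed)
    total_feature = (
        spec.gene_count * (spec.gene_length + spec.intron_count
                           * spec.intron_length[1])
        + sum(f.unit_length * f.copies for f in spec.repeat_families)
    )
    if total_feature > 0.6 * spec.n_chromosomes * spec.chromosome_length:
        raise ValueError(
            "infeasible packing: planted features exceed 60% of genome"
        )

    chrom_seqs = {
        f"chr{i + 1}": list(_random_seq(rng, spec.chromosome_length))
        for i in range(spec.n_chromosomes)
    }
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_seqs}

    def place(length: int) -> tuple[str, int]:
        for _ in range(2000):
            chrom = f"chr{rng.integers(1, spec.n_chromosomes + 1)}"
            start = int(rng.integers(0, spec.chromosome_length - length))
            if all(
                start + length <= s or start >= e
                for s, e in occupied[chrom]
            ):
                occupied[chrom].append((start, start + length))
                return chrom, start
        raise ValueError("infeasible packing: could not place feature")

    genes, repeats, paralogs, transcripts = [], [], [], []

    for g in range(spec.gene_count):
        gene_id = f"gene{g + 1}"
        exon_len = spec.gene_length
        introns = [
            int(rng.integers(*spec.intron_length))
            for _ in range(spec.intron_count)
        ]
        total = exon_len + sum(introns)
        chrom, start = place(total)
        exon_seq = _random_seq(rng, exon_len)
        # split exon sequence evenly around the introns
        n_parts = spec.intron_count + 1
        bounds = [i * exon_len // n_parts for i in range(n_parts + 1)]
        genomic = []
        for i in range(n_parts):
            genomic.append(exon_seq[bounds[i] : bounds[i + 1]])
            if i < spec.intron_count:
                genomic.append(_random_seq(rng, introns[i]))
        gene_genomic = "".join(genomic)
        seq = chrom_seqs[chrom]
        seq[start : start + total] = list(gene_genomic)
        genes.append(
            dict(gene_id=gene_id, seq_id=chrom, start=start,
                 end=start + total, strand="+")
        )
        transcripts.append(SequenceRecord(id=gene_id, residues=exon_seq))

        if rng.random() < spec.paralog_rate:
            dup = _mutate(rng, gene_genomic, spec.paralog_divergence)
            pchrom, pstart = place(len(dup))
            chrom_seqs[pchrom][pstart : pstart + len(dup)] = list(dup)
            paralogs.append(
                dict(gene_id=f"{gene_id}_paralog", paralog_of=gene_id,
                     seq_id=pchrom, start=pstart, end=pstart + len(dup))
            )

    for fam in spec.repeat_families:
        unit = _random_seq(rng, fam.unit_length)
        if fam.tandem:
            block = (unit * fam.copies).lower()
            chrom, start = place(len(block))
            chrom_seqs[chrom][start : start + len(block)] = list(block)
            repeats.append(
                dict(family=fam.name, seq_id=chrom, start=start,
                     end=start + len(block))
            )
        else:
            for _ in range(fam.copies):
                copy = _mutate(rng, unit, 0.02).lower()
                chrom, start = place(len(copy))
                chrom_seqs[chrom][start : start + len(copy)] = list(copy)
                repeats.append(
                    dict(family=fam.name, seq_id=chrom, start=start,
                         end=start + len(copy))
                )

    chromosomes = [
        SequenceRecord(id=c, residues="".join(s)) for c, s in chrom_seqs.items()
    ]
    return SyntheticGenome(
        chromosomes=chromosomes,
        transcripts=transcripts,
        genes=pd.DataFrame(genes),
        repeats=pd.DataFrame(
            repeats, columns=["family", "seq_id", "start", "end"]
        ),
        paralogs=pd.DataFrame(
            paralogs, columns=["gene_id", "paralog_of", "seq_id", "start", "end"]
        ),
        seed=spec.seed,
    )


def _cm_profile(fl: np.ndarray, spec: MapSpec) -> np.ndarray:
    """Cumulative cM at each FL position: integral of rate x zone factor."""
    grid = np.linspace(0.0, 100.0, 2001)
    rate = np.full_like(grid, spec.base_rate)
    for lo, hi, factor in spec.suppressed_zones:
        rate[(grid >= lo) & (grid < hi)] *= factor
    cum = np.concatenate([[0.0], np.cumsum((rate[:-1] + rate[1:]) / 2
                                           * np.diff(grid))])
    return np.interp(fl, grid, cum)


def generate_genetic_map(
    true_fl_positions: Sequence[tuple[str, float]], spec: MapSpec
) -> pd.DataFrame:
    """Map true FL positions to noisy cM coordinates.

    cM is the cumulative integral of a recombination-rate profile (base rate
    scaled by each suppressed zone's factor) evaluated at the marker's FL,
    plus Gaussian noise. With ``flipped`` the map is emitted upended (long arm
    at top): cM is measured from the opposite end. Markers inside a fully
    suppressed zone collapse to equal cM (up to noise) and are flagged as tied.
    """
    rng = np.random.default_rng(spec.seed)
    ids = [m for m, _ in true_fl_positions]
    fl = np.array([p for _, p in true_fl_positions], dtype=float)
    if ((fl < 0) | (fl > 100)).any():
        raise ValueError("FL positions must lie in [0, 100]")
    cm = _cm_profile(fl, spec)
    if spec.flipped:
        cm = cm.max() - cm
    if spec.noise_sd_cM > 0:
        cm = cm + rng.normal(0.0, spec.noise_sd_cM, size=len(cm))
    cm = np.clip(cm, 0.0, None)
    df = pd.DataFrame({"marker_id": ids, "true_fl": fl, "cM": cm})
    df["tied"] = df.duplicated("cM", keep=False)
    return df


def simulate_signals(
    true_positions: Sequence[tuple[str, str, float]],
    *,
    rphc_noise_sd: float = 2.5,
    detection_p: float = 0.5,
    n_metaphases: int = 25,
    arm_length: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-metaphase signal measurements for (probe, arm, RPHC) truths.

    Per metaphase and homolog the signal is present with probability
    ``detection_p``; a present signal's measured RPHC is the truth plus
    Gaussian noise, clipped to [0, 100] (clip events are counted in the truth
    table). A metaphase counts as detected when at least one homolog shows a
    signal. Returns (signals table, per-probe truth/detection table).
    """
    if not (0 < detection_p <= 1):
        raise ValueError("detection_p must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for probe_id, arm, rphc in true_positions:
        if not (0 <= rphc <= 100):
            raise ValueError(f"true RPHC {rphc} outside [0, 100]")
        detected_cells = 0
        clipped = 0
        for cell in range(n_metaphases):
            any_signal = False
            for copy in ("a", "b"):
                if rng.random() >= detection_p:
                    continue
                any_signal = True
                measured = rphc + rng.normal(0.0, rphc_noise_sd)
                if measured < 0 or measured > 100:
                    clipped += 1
                    measured = min(max(measured, 0.0), 100.0)
                rows.append(
                    dict(
                        probe_id=probe_id,
                        metaphase_id=f"m{cell + 1}",
                        chromosome_copy=copy,
                        arm=arm,
                        d_centromere=measured / 100.0 * arm_length,
                        arm_length=arm_length,
                    )
                )
            if any_signal:
                detected_cells += 1
        truth.append(
            dict(
                probe_id=probe_id,
                arm=arm,
                true_rphc=rphc,
                n_metaphases=n_metaphases,
                n_detected=detected_cells,
                n_clipped=clipped,
            )
        )
    return pd.DataFrame(rows), pd.DataFrame(truth)
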