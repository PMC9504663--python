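"""Probe-candidate design: transcript placement, marker filtering, masking
filters and primer-delimited product proposal.

The pipeline this module implements designs FISH probes for transcript-based
genetic-map markers. A marker's transcript is placed on the genome by chaining
exact k-mer seeds (tolerating introns between seeds), the gene sequence at the
best placement is extracted, genes hit by hard-masking (runs of N) are
discarded, primer pairs delimiting 1-4 kb products are proposed, and products
containing any masked base are discarded so repeats cannot enter a probe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from ._seeds import SeedRun, cluster_runs, find_seed_runs
from .sequence_io import (
    GenomicInterval,
    MarkerInput,
    SequenceRecord,
    reverse_complement,
)

__all__ = [
    "PlacementParams",
    "PrimerParams",
    "TranscriptPlacement",
    "PrimerPair",
    "ProbeCandidate",
    "place_transcript",
    "filter_markers",
    "discard_hard_masked",
    "propose_primer_pairs",
    "extract_candidates",
    "primer_tm",
]


@dataclass(frozen=True)
class PlacementParams:
    """Seed-chaining parameters for transcript-to-genome placement."""

    k: int = 13
    max_intron: int = 5000
    ambiguity_ratio: float = 0.95


@dataclass(frozen=True)
class TranscriptPlacement:
    """Best genomic locus of a transcript, with ambiguity bookkeeping.

    ``ambiguous`` is set when the second-best chain (at a different locus)
    scores at least ``ambiguity_ratio`` of the best chain — the situation where
    a transcript cannot be assigned to a single genomic copy.
    """

    transcript_id: str
    locus: GenomicInterval | None
    chain_score: float = 0.0
    second_best_score: float = 0.0
    ambiguous: bool = False
    on_expected_chromosome: bool = False

    @property
    def placed(self) -> bool:
        return self.locus is not None


@dataclass(frozen=True)
class PrimerParams:
    """Primer and product constraints with penalty weights.

    The primer model is deliberately transparent: Wallace-style melting
    temperature Tm = 64.9 + 41 x (GC_count - 16.4) / length, GC bounds, and a
    penalty summing weighted absolute deviations from the optima (length 20,
    GC 50 %, Tm 60 C) plus the product-length deviation from the 2.5 kb
    midpoint. An external primer-design backend can be plugged in behind the
    same contract.
    """

    min_product: int = 1000
    max_product: int = 4000
    n_pairs: int = 5
    min_len: int = 18
    max_len: int = 27
    opt_len: int = 20
    min_gc: float = 40.0
    max_gc: float = 60.0
    opt_gc: float = 50.0
    opt_tm: float = 60.0
    opt_product: int = 2500
    w_len: float = 1.0
    w_gc: float = 0.2
    w_tm: float = 1.0
    w_product: float = 1.0 / 500.0


@dataclass(frozen=True)
class PrimerPair:
    """A primer pair delimiting one PCR product on the gene sequence.

    ``left_start``/``right_end`` are 0-based half-open product bounds on the
    gene sequence; the right primer is the reverse complement of the genomic
    window ending at ``right_end``.
    """

    left_seq: str
    right_seq: str
    left_start: int
    right_end: int
    tm_left: float
    tm_right: float
    gc_left: float
    gc_right: float
    penalty: float

    @property
    def product_length(self) -> int:
        return self.right_end - self.left_start


@dataclass(frozen=True)
class ProbeCandidate:
    """A primer-delimited probe candidate with masking and specificity state."""

    gene_id: str
    primer_pair: PrimerPair
    product_interval: GenomicInterval
    sequence: SequenceRecord
    masked_bases: int
    dangerous_hits: int = 0
    status: str = "candidate"  # candidate|discarded_masked|discarded_ambiguous|selected

    @property
    def probe_id(self) -> str:
        return f"{self.gene_id}|{self.primer_pair.left_start}-{self.primer_pair.right_end}"


def _chain_score(chain: Sequence[SeedRun]) -> int:
    """Query bases covered by a chain, overlaps between runs counted once."""
    covered = 0
    prev_end = -1
    for r in sorted(chain, key=lambda r: r.q_start):
        covered += max(0, r.q_end - max(prev_end, r.q_start))
        prev_end = max(prev_end, r.q_end)
    return covered


_CHAIN_OVERLAP_TOL = 20  # maximal exact runs can overlap a little at junctions


def _best_chain(runs: list[SeedRun], max_intron: int) -> tuple[int, list[SeedRun]]:
    """Highest-coverage colinear chain of seed runs (O(n^2) DP).

    Runs chain when both query and subject positions advance and the genomic
    gap between consecutive runs is at most ``max_intron`` (intron tolerance).
    Small overlaps between runs are allowed — maximal exact matches flanking
    an intron routinely share a few bases at the junction — and overlapped
    query bases are counted once in the chain score.
    """
    if not runs:
        return 0, []
    runs = sorted(runs, key=lambda r: (r.s_start, r.q_start))
    n = len(runs)
    score = [r.length for r in runs]
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            rj, ri = runs[j], runs[i]
            if (
                ri.s_end > rj.s_end
                and ri.q_end > rj.q_end
                and ri.s_start >= rj.s_end - _CHAIN_OVERLAP_TOL
                and ri.q_start >= rj.q_end - _CHAIN_OVERLAP_TOL
                and ri.s_start - rj.s_end <= max_intron
            ):
                gain = ri.length - max(0, rj.q_end - ri.q_start)
                cand = score[j] + gain
                if cand > score[i]:
                    score[i] = cand
                    prev[i] = j
    best = max(range(n), key=lambda i: score[i])
    chain = []
    i = best
    while i != -1:
        chain.append(runs[i])
        i = prev[i]
    chain.reverse()
    return _chain_score(chain), chain


def place_transcript(
    transcript: SequenceRecord,
    genome: Sequence[SequenceRecord],
    params: PlacementParams = PlacementParams(),
) -> TranscriptPlacement:
    """Place a transcript at its best genomic locus by chained exact seeds.

    Both strands of every genome sequence are searched; candidate loci are
    clusters of seed runs separated by more than ``max_intron``, each scored
    by the transcript coverage of its best colinear chain. The result is
    deterministic; a transcript with no seed hit anywhere returns an unplaced
    (not an error) result.
    """
    if len(transcript) < params.k:
        raise ValueError(
            f"transcript {transcript.id} shorter than seed size {params.k}"
        )
    scored: list[tuple[int, GenomicInterval]] = []
    for chrom in genome:
        for strand in "+-":
            subject = (
                chrom.residues
                if strand == "+"
                else reverse_complement(chrom.residues)
            )
            runs = find_seed_runs(transcript.residues, subject, params.k)
            for cluster in cluster_runs(runs, params.max_intron):
                score, chain = _best_chain(cluster, params.max_intron)
                if not chain:
                    continue
                s_lo = min(r.s_start for r in chain)
                s_hi = max(r.s_end for r in chain)
                if strand == "-":
                    s_lo, s_hi = len(chrom) - s_hi, len(chrom) - s_lo
                scored.append(
                    (score, GenomicInterval(chrom.id, s_lo, s_hi, strand))
                )
    if not scored:
        return TranscriptPlacement(transcript_id=transcript.id, locus=None)
    scored.sort(key=lambda t: (-t[0], t[1].seq_id, t[1].start, t[1].strand))
    best_score, best_locus = scored[0]
    second = 0
    for score, locus in scored[1:]:
        if not locus.overlaps(best_locus):
            second = score
            break
    return TranscriptPlacement(
        transcript_id=transcript.id,
        locus=best_locus,
        chain_score=float(best_score),
        second_best_score=float(second),
        ambiguous=second >= params.ambiguity_ratio * best_score,
    )


def filter_markers(
    markers: Sequence[MarkerInput],
    placements: dict[str, TranscriptPlacement],
    expected_chromosomes: set[str] | Sequence[str],
) -> dict[str, list[MarkerInput]]:
    """Partition markers by the design exclusion rules.

    A marker is retained when its transcript has a protein annotation, places
    unambiguously, and lands on one of the expected chromosome sequences.
    Every marker falls in exactly one partition: ``retained``,
    ``no_protein_annotation``, ``unplaced``, ``ambiguous`` or
    ``wrong_chromosome``.
    """
    expected = set(expected_chromosomes)
    parts: dict[str, list[MarkerInput]] = {
        "retained": [],
        "no_protein_annotation": [],
        "unplaced": [],
        "ambiguous": [],
        "wrong_chromosome": [],
    }
    for m in markers:
        if m.transcript_id not in placements:
            raise ValueError(
                f"marker {m.marker_id}: no placement for transcript "
                f"{m.transcript_id!r}"
            )
        p = placements[m.transcript_id]
        if not m.has_protein_annotation:
            parts["no_protein_annotation"].append(m)
        elif not p.placed:
            parts["unplaced"].append(m)
        elif p.ambiguous:
            parts["ambiguous"].append(m)
        elif p.locus.seq_id not in expected:
            parts["wrong_chromosome"].append(m)
        else:
            parts["retained"].append(m)
    return parts


def discard_hard_masked(gene_seq: SequenceRecord, max_N_run: int = 10) -> bool:
    """Keep a gene sequence only when it has no run of >= ``max_N_run`` Ns."""
    run = 0
    for c in gene_seq.residues:
        if c in "Nn":
            run += 1
            if run >= max_N_run:
                return False
        else:
            run = 0
    return True


def primer_tm(primer: str) -> float:
    """Wallace-style melting temperature: 64.9 + 41 x (GC - 16.4) / length."""
    gc = sum(1 for c in primer.upper() if c in "GC")
    return 64.9 + 41.0 * (gc - 16.4) / len(primer)


def _gc_pct(primer: str) -> float:
    return 100.0 * sum(1 for c in primer.upper() if c in "GC") / len(primer)


def _primer_penalty(primer: str, params: PrimerParams) -> float:
    return (
        params.w_len * abs(len(primer) - params.opt_len)
        + params.w_gc * abs(_gc_pct(primer) - params.opt_gc)
        + params.w_tm * abs(primer_tm(primer) - params.opt_tm)
    )


def _candidate_primers(
    gene: str, params: PrimerParams, *, bucket: int = 20
) -> list[tuple[int, int, float]]:
    """Viable (start, length, penalty) primer windows on the plus strand.

    A window is viable when wholly unmasked (uppercase A/C/G/T) and within GC
    bounds. The best window per ``bucket``-bp start bin is kept, so candidate
    primers stay spread along the gene and long products remain reachable.
    """
    best_per_bin: dict[int, tuple[int, int, float]] = {}
    n = len(gene)
    for start in range(n - params.min_len + 1):
        for length in range(params.min_len, params.max_len + 1):
            end = start + length
            if end > n:
                break
            window = gene[start:end]
            if any(c not in "ACGT" for c in window):
                continue
            gc = _gc_pct(window)
            if not (params.min_gc <= gc <= params.max_gc):
                continue
            cand = (start, length, _primer_penalty(window, params))
            key = start // bucket
            cur = best_per_bin.get(key)
            if cur is None or (cand[2], cand[0], cand[1]) < (cur[2], cur[0], cur[1]):
                best_per_bin[key] = cand
    return sorted(best_per_bin.values(), key=lambda t: (t[2], t[0], t[1]))


def propose_primer_pairs(
    gene_seq: SequenceRecord, params: PrimerParams = PrimerParams()
) -> list[PrimerPair]:
    """Propose up to ``n_pairs`` primer pairs with products in the design window.

    Returns pairs sorted ascending by penalty (primer deviations plus product
    length deviation from the midpoint). Primers never contain a masked base.
    An empty list is returned when the gene is shorter than ``min_product``.
    """
    gene = gene_seq.residues
    if len(gene) < params.min_product:
        return []
    singles = _candidate_primers(gene, params)
    pairs: list[PrimerPair] = []
    for ls, llen, lpen in singles:
        for rs, rlen, rpen in singles:
            right_end = rs + rlen
            product = right_end - ls
            if not (params.min_product <= product <= params.max_product):
                continue
            left = gene[ls : ls + llen]
            right = reverse_complement(gene[rs:right_end])
            penalty = (
                lpen + rpen + params.w_product * abs(product - params.opt_product)
            )
            pairs.append(
                PrimerPair(
                    left_seq=left,
                    right_seq=right,
                    left_start=ls,
                    right_end=right_end,
                    tm_left=primer_tm(left),
                    tm_right=primer_tm(right),
                    gc_left=_gc_pct(left),
                    gc_right=_gc_pct(right),
                    penalty=penalty,
                )
            )
    pairs.sort(key=lambda p: (p.penalty, p.left_start, p.right_end))
    # avoid returning n_pairs near-duplicates of one window: keep pairs whose
    # product midpoints differ by at least 50 bp
    chosen: list[PrimerPair] = []
    for p in pairs:
        mid = (p.left_start + p.right_end) / 2
        if all(abs(mid - (c.left_start + c.right_end) / 2) >= 50 for c in chosen):
            chosen.append(p)
        if len(chosen) == params.n_pairs:
            break
    return chosen


def extract_candidates(
    gene_seq: SequenceRecord,
    pairs: Sequence[PrimerPair],
    placement: TranscriptPlacement,
) -> list[ProbeCandidate]:
    """Cut primer-delimited products out of the gene and lift them to genome
    coordinates through the placement.

    A product containing any masked base (soft-masked lowercase or hard-masked
    N) is kept in the output with status ``discarded_masked`` so the report can
    account for it; clean products get status ``candidate``.
    """
    if placement.locus is None:
        raise ValueError("cannot extract candidates from an unplaced gene")
    locus = placement.locus
    out = []
    for pair in pairs:
        sub = gene_seq.residues[pair.left_start : pair.right_end]
        masked = sum(1 for c in sub if c in "acgtNn")
        if locus.strand == "+":
            g_start = locus.start + pair.left_start
            g_end = locus.start + pair.right_end
        else:
            g_start = locus.end - pair.right_end
            g_end = locus.end - pair.left_start
        out.append(
            ProbeCandidate(
                gene_id=gene_seq.id,
                primer_pair=pair,
                product_interval=GenomicInterval(
                    locus.seq_id, g_start, g_end, locus.strand
                ),
                sequence=SequenceRecord(
                    id=f"{gene_seq.id}|{pair.left_start}-{pair.right_end}",
                    residues=sub,
                ),
                masked_bases=masked,
                status="discarded_masked" if masked else "candidate",
            )
        )
    return out
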