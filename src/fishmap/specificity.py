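"""Genome-wide off-target screening of probe candidates.

A candidate probe is aligned against the whole assembly by seed-and-extend:
exact k-mer seed runs delimit candidate windows and each window is resolved by
an optimal local (Smith-Waterman) alignment. Hits outside the probe's own
product locus with identity > 80 % and aligned length > 100 bp are classified
as "dangerous" — long and similar enough to hybridize under the 80-82 %
washing stringency used for single-copy FISH — and per gene the probe with
none or the fewest dangerous hits is selected.

The screen is an internal aligner rather than a wrapper over an external
search tool; externally produced tabular hits can be injected through
:class:`AlignmentHit` for users who prefer a standard search engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio.Align import PairwiseAligner

from ._seeds import cluster_runs, find_seed_runs
from .probe_design import ProbeCandidate
from .sequence_io import GenomicInterval, SequenceRecord, reverse_complement

__all__ = [
    "ScanParams",
    "DangerThresholds",
    "AlignmentHit",
    "SpecificityVerdict",
    "scan_genome",
    "classify_dangerous",
    "count_dangerous",
    "rank_candidates",
    "screen_candidates",
    "stringency_identity_threshold",
]


@dataclass(frozen=True)
class ScanParams:
    """Seed-and-extend parameters: seed size, local-alignment scores and the
    reporting floors (minimum aligned columns and minimum alignment score)
    below which a local alignment is noise, not a hit."""

    k: int = 13
    match: int = 1
    mismatch: int = -1
    gap: int = -2
    min_report_len: int = 50
    min_report_score: int = 25
    window_pad: int = 50


@dataclass(frozen=True)
class DangerThresholds:
    """Strict thresholds of the dangerous-hit rule (identity >, length >)."""

    identity_gt: float = 80.0
    length_gt: int = 100


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment of a probe against the assembly."""

    query_id: str
    subject: GenomicInterval
    identity: float
    aln_length: int
    score: float
    is_target_locus: bool = False


@dataclass
class SpecificityVerdict:
    """Screen outcome for one probe candidate."""

    probe_id: str
    gene_id: str
    dangerous_count: int
    hits: list[AlignmentHit] = field(default_factory=list)
    offtarget_aligned_bases: int = 0
    primer_penalty: float = 0.0
    rank: int = 0
    selected: bool = False
    warning: str = ""


def _local_aligner(params: ScanParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap
    aligner.extend_gap_score = params.gap
    return aligner


def stringency_identity_threshold(stringency_pct: float) -> float:
    """Dangerous-hit identity threshold implied by hybridization stringency.

    The washing stringency sets the fraction of paired nucleotides needed to
    keep a probe-target duplex stable, so the identity threshold equals the
    stringency percentage (a documented pass-through).
    """
    if not (0 < stringency_pct <= 100):
        raise ValueError(
            f"stringency must be in (0, 100], got {stringency_pct}"
        )
    return float(stringency_pct)


def scan_genome(
    probe: SequenceRecord,
    genome: Sequence[SequenceRecord],
    params: ScanParams = ScanParams(),
    target: GenomicInterval | None = None,
) -> list[AlignmentHit]:
    """Find all local alignments of a probe against the assembly.

    Both strands are searched. Each seed cluster is resolved by an optimal
    local alignment of the probe against the cluster's genomic window;
    identity is 100 x matches / aligned columns (gap columns included) and
    ``aln_length`` the number of aligned columns. Hits shorter than
    ``min_report_len`` are dropped unless they overlap the target locus, which
    is always reported and flagged.
    """
    if len(probe) < params.k:
        raise ValueError(f"probe {probe.id} shorter than seed size {params.k}")
    aligner = _local_aligner(params)
    query = probe.residues.upper()
    hits: list[AlignmentHit] = []
    for chrom in genome:
        for strand in "+-":
            subject_full = (
                chrom.residues.upper()
                if strand == "+"
                else reverse_complement(chrom.residues).upper()
            )
            runs = find_seed_runs(query, subject_full, params.k)
            for cluster in cluster_runs(runs, max_gap=len(query)):
                w_lo = max(0, min(r.s_start for r in cluster) - len(query)
                           - params.window_pad)
                w_hi = min(len(subject_full),
                           max(r.s_end for r in cluster) + len(query)
                           + params.window_pad)
                # one seed cluster can hold several distinct loci (e.g. two
                # nearby paralog copies): enumerate suboptimal alignments by
                # masking each reported span and re-aligning
                window = list(subject_full[w_lo:w_hi])
                for _ in range(10):
                    alignments = aligner.align("".join(window), query)
                    if not alignments:
                        break
                    aln = alignments[0]
                    counts = aln.counts()
                    columns = counts.gaps + counts.identities + counts.mismatches
                    if columns == 0 or aln.score < params.min_report_score:
                        break
                    t_lo = int(aln.coordinates[0][0])
                    t_hi = int(aln.coordinates[0][-1])
                    if strand == "+":
                        s_lo, s_hi = w_lo + t_lo, w_lo + t_hi
                    else:
                        s_lo = len(chrom) - (w_lo + t_hi)
                        s_hi = len(chrom) - (w_lo + t_lo)
                    if s_hi <= s_lo:
                        break
                    subject_iv = GenomicInterval(chrom.id, s_lo, s_hi, strand)
                    is_target = target is not None and subject_iv.overlaps(target)
                    if columns >= params.min_report_len or is_target:
                        hits.append(
                            AlignmentHit(
                                query_id=probe.id,
                                subject=subject_iv,
                                identity=100.0 * counts.identities / columns,
                                aln_length=columns,
                                score=float(aln.score),
                                is_target_locus=is_target,
                            )
                        )
                    if columns < params.min_report_len:
                        break
                    for j in range(t_lo, t_hi):
                        window[j] = "#"
    return _dedupe_hits(hits)


def _dedupe_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Keep the best-scoring hit among hits covering the same genomic span.

    Adjacent seed clusters (and the two strands of a palindromic region) can
    yield overlapping alignments of the same locus.
    """
    hits = sorted(
        hits, key=lambda h: (-h.score, h.subject.seq_id, h.subject.start)
    )
    kept: list[AlignmentHit] = []
    for h in hits:
        redundant = False
        for k in kept:
            if h.subject.seq_id == k.subject.seq_id:
                lo = max(h.subject.start, k.subject.start)
                hi = min(h.subject.end, k.subject.end)
                if hi - lo > 0.5 * len(h.subject):
                    redundant = True
                    break
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (h.subject.seq_id, h.subject.start))
    return kept


def classify_dangerous(
    hit: AlignmentHit, thresholds: DangerThresholds = DangerThresholds()
) -> bool:
    """Dangerous iff off-target with identity and length strictly above the
    thresholds (identity exactly at the threshold is not dangerous)."""
    return (
        not hit.is_target_locus
        and hit.identity > thresholds.identity_gt
        and hit.aln_length > thresholds.length_gt
    )


def count_dangerous(
    hits: Sequence[AlignmentHit],
    thresholds: DangerThresholds = DangerThresholds(),
) -> int:
    return sum(1 for h in hits if classify_dangerous(h, thresholds))


def rank_candidates(
    verdicts: Sequence[SpecificityVerdict],
) -> list[SpecificityVerdict]:
    """Rank one gene's candidates: fewest dangerous hits first.

    Ties break by total off-target aligned bases, then primer penalty. Rank 1
    is selected; a lone candidate with dangerous hits is selected with a
    warning.
    """
    if not verdicts:
        raise ValueError("no verdicts to rank")
    genes = {v.gene_id for v in verdicts}
    if len(genes) > 1:
        raise ValueError(f"verdicts from multiple genes: {sorted(genes)}")
    ordered = sorted(
        verdicts,
        key=lambda v: (
            v.dangerous_count,
            v.offtarget_aligned_bases,
            v.primer_penalty,
            v.probe_id,
        ),
    )
    out = []
    for i, v in enumerate(ordered, start=1):
        selected = i == 1
        warning = v.warning
        if selected and v.dangerous_count > 0:
            warning = (
                f"selected probe has {v.dangerous_count} dangerous hit(s); "
                "no cleaner candidate available"
            )
        out.append(replace_fields(v, rank=i, selected=selected, warning=warning))
    return out


def replace_fields(v: SpecificityVerdict, **kw) -> SpecificityVerdict:
    d = {**v.__dict__, **kw}
    return SpecificityVerdict(**d)


def screen_candidates(
    candidates: Sequence[ProbeCandidate],
    genome: Sequence[SequenceRecord],
    params: ScanParams = ScanParams(),
    thresholds: DangerThresholds = DangerThresholds(),
) -> list[SpecificityVerdict]:
    """Screen and rank all (non-discarded) candidates of one gene."""
    verdicts = []
    for cand in candidates:
        if cand.status == "discarded_masked":
            continue
        hits = scan_genome(
            cand.sequence, genome, params, target=cand.product_interval
        )
        verdicts.append(
            SpecificityVerdict(
                probe_id=cand.probe_id,
                gene_id=cand.gene_id,
                dangerous_count=count_dangerous(hits, thresholds),
                hits=hits,
                offtarget_aligned_bases=sum(
                    h.aln_length for h in hits if not h.is_target_locus
                ),
                primer_penalty=cand.primer_pair.penalty,
            )
        )
    if not verdicts:
        return []
    return rank_candidates(verdicts)
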