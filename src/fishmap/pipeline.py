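"""End-to-end composition: probe design per gene and the packaged-study
map-integration analysis."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import map_integration as mi
from .cytogenetics import KaryotypeArm, ProbePosition
from .probe_design import (
    PlacementParams,
    PrimerParams,
    ProbeCandidate,
    discard_hard_masked,
    extract_candidates,
    filter_markers,
    place_transcript,
    propose_primer_pairs,
)
from .sequence_io import (
    MarkerInput,
    SequenceRecord,
    extract_interval,
    load_reference_table,
)
from .specificity import (
    DangerThresholds,
    ScanParams,
    SpecificityVerdict,
    screen_candidates,
)

__all__ = ["DesignResult", "design_probes", "reference_positions",
           "reference_report"]


@dataclass
class DesignResult:
    """Everything the design pipeline produced for one marker set."""

    partitions: dict[str, list[MarkerInput]]
    candidates: dict[str, list[ProbeCandidate]]
    verdicts: dict[str, list[SpecificityVerdict]]
    skipped_hard_masked: list[str] = field(default_factory=list)

    @property
    def selected(self) -> dict[str, SpecificityVerdict]:
        return {
            gene: next(v for v in vs if v.selected)
            for gene, vs in self.verdicts.items()
            if vs
        }


def design_probes(
    genome: Sequence[SequenceRecord],
    transcripts: Sequence[SequenceRecord],
    markers: Sequence[MarkerInput],
    expected_chromosomes: set[str] | Sequence[str],
    *,
    placement_params: PlacementParams = PlacementParams(),
    primer_params: PrimerParams = PrimerParams(),
    scan_params: ScanParams = ScanParams(),
    thresholds: DangerThresholds = DangerThresholds(),
    max_N_run: int = 10,
) -> DesignResult:
    """Run the full probe-design pipeline for a marker set.

    Steps: place each marker's transcript, apply the exclusion filters,
    extract the gene sequence at the placement, discard hard-masked genes,
    propose primer pairs, cut candidates, screen them genome-wide and rank by
    dangerous hits.
    """
    tx_by_id = {t.id: t for t in transcripts}
    missing = [m.marker_id for m in markers if m.transcript_id not in tx_by_id]
    if missing:
        raise ValueError(f"markers reference unknown transcripts: {missing}")

    placements = {
        tid: place_transcript(tx_by_id[tid], genome, placement_params)
        for tid in {m.transcript_id for m in markers}
    }
    partitions = filter_markers(markers, placements, expected_chromosomes)

    candidates: dict[str, list[ProbeCandidate]] = {}
    verdicts: dict[str, list[SpecificityVerdict]] = {}
    skipped: list[str] = []
    for m in partitions["retained"]:
        placement = placements[m.transcript_id]
        gene_seq = extract_interval(list(genome), placement.locus)
        gene_seq = SequenceRecord(id=m.marker_id, residues=gene_seq.residues)
        if not discard_hard_masked(gene_seq, max_N_run):
            skipped.append(m.marker_id)
            continue
        pairs = propose_primer_pairs(gene_seq, primer_params)
        cands = extract_candidates(gene_seq, pairs, placement)
        candidates[m.marker_id] = cands
        verdicts[m.marker_id] = screen_candidates(
            cands, genome, scan_params, thresholds
        )
    return DesignResult(
        partitions=partitions,
        candidates=candidates,
        verdicts=verdicts,
        skipped_hard_masked=skipped,
    )


def reference_positions(chromosome: str) -> list[ProbePosition]:
    """Aggregated probe positions of the packaged study for one chromosome."""
    if chromosome not in ("2", "6"):
        raise ValueError("packaged positions exist for chromosomes '2' and '6'")
    df = load_reference_table(f"positions_chr{chromosome}")
    return [
        ProbePosition(
            probe_id=str(r.probe_id),
            rphc_mean=float(r.rphc_mean),
            rphc_sd=float(r.rphc_sd),
            arm=str(r.arm),
            n_chromosomes=int(r.n_chromosomes),
            detection_frequency=float(r.detection_frequency),
            n_metaphases=int(r.n_metaphases),
        )
        for r in df.itertuples()
    ]


def reference_karyotype(chromosome: str) -> KaryotypeArm:
    df = load_reference_table("karyotype")
    row = df[df["chromosome_id"].astype(str) == chromosome]
    if row.empty:
        raise ValueError(f"no karyotype entry for chromosome {chromosome!r}")
    return KaryotypeArm(
        chromosome_id=chromosome,
        short_arm_fraction=float(row["short_arm_fraction"].iloc[0]),
        total_length=float(row["total_length"].iloc[0]),
    )


def reference_report(
    chromosome: str,
) -> tuple[dict[str, mi.ConcordanceReport], pd.DataFrame]:
    """Integrated map comparison for one chromosome of the packaged study."""
    positions = reference_positions(chromosome)
    karyotype = reference_karyotype(chromosome)
    genetic = load_reference_table(f"genetic_map_chr{chromosome}")
    pseudo = load_reference_table(f"pseudo_map_chr{chromosome}")
    entries = mi.entries_from_tables(positions, genetic, pseudo, karyotype)
    return mi.build_report(entries, positions, karyotype)
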