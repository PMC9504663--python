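"""Sequence and table I/O plus coordinate algebra.

All coordinates are 0-based half-open internally; 1-based fully-closed numbers
appear only in human-readable report output. Masking conventions follow the
usual FASTA usage: lowercase residues are soft-masked (repeat-derived),
``N``/``n`` are hard-masked (assembly gaps or discarded sequence).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "GenomicInterval",
    "SequenceRecord",
    "MarkerInput",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "extract_interval",
    "percent_identity",
    "reverse_complement",
    "load_reference_table",
    "write_bed6",
    "read_marker_table",
]

_VALID_RESIDUES = frozenset("ACGTNacgtn")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FastaFormatError(ValueError):
    """Raised on malformed FASTA input (empty file, duplicate ids, bad residues)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A located span on a named sequence; the coordinate currency of the pipeline.

    ``start`` is 0-based inclusive, ``end`` exclusive.
    """

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two spans share >= 1 bp on the same sequence (any strand)."""
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class SequenceRecord:
    """A named sequence over {A,C,G,T,N} with case carrying the masking state."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise FastaFormatError(f"record {self.id!r} is empty")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise FastaFormatError(
                f"record {self.id!r} contains illegal residue(s) {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_soft_masked(self) -> int:
        return sum(1 for c in self.residues if c in "acgt")

    @property
    def n_hard_masked(self) -> int:
        return sum(1 for c in self.residues if c in "Nn")

    @property
    def n_masked(self) -> int:
        """Masked bases of either kind (soft or hard)."""
        return sum(1 for c in self.residues if c in "acgtNn")


@dataclass(frozen=True)
class MarkerInput:
    """One transcript-based marker from a genetic-map table."""

    marker_id: str
    transcript_id: str
    linkage_group: str
    cM: float
    has_protein_annotation: bool = True

    def __post_init__(self) -> None:
        if not (self.cM >= 0 and self.cM == self.cM):  # finite, non-negative
            raise ValueError(f"marker {self.marker_id}: cM must be finite and >= 0")


def reverse_complement(residues: str) -> str:
    """Reverse complement preserving masking case (``a`` -> ``t``)."""
    return residues.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path | io.TextIOBase) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file, preserving residue case byte-for-byte.

    Raises :class:`FastaFormatError` on an empty file, duplicate record ids or
    residues outside {A,C,G,T,N} (either case).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq)))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path | io.TextIOBase, width: int = 70
) -> None:
    """Write records in input order, wrapped at ``width`` columns."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    handle = open(path, "w") if isinstance(path, (str, Path)) else path
    try:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)
    finally:
        if isinstance(path, (str, Path)):
            handle.close()


def extract_interval(
    assembly: list[SequenceRecord] | dict[str, SequenceRecord],
    interval: GenomicInterval,
) -> SequenceRecord:
    """Extract the residues of ``interval`` from an assembly.

    Minus-strand intervals return the reverse complement. The returned record
    id encodes the source coordinates (``seqid:start-end(strand)``).
    """
    if not isinstance(assembly, dict):
        assembly = {r.id: r for r in assembly}
    try:
        src = assembly[interval.seq_id]
    except KeyError:
        raise KeyError(f"unknown sequence id {interval.seq_id!r}") from None
    if interval.end > len(src):
        raise ValueError(
            f"interval [{interval.start}, {interval.end}) exceeds length "
            f"{len(src)} of {interval.seq_id!r}"
        )
    sub = src.residues[interval.start : interval.end]
    if interval.strand == "-":
        sub = reverse_complement(sub)
    return SequenceRecord(
        id=f"{interval.seq_id}:{interval.start}-{interval.end}({interval.strand})",
        residues=sub,
    )


def _global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def percent_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Percent identity of the optimal global alignment of ``a`` and ``b``.

    Scoring is match +1, mismatch -1, linear gap -2; identity is
    100 x matches / aligned columns, counting gap columns in the denominator.
    Case (masking) is ignored for alignment purposes.
    """
    if not a.residues or not b.residues:
        raise ValueError("percent_identity requires non-empty sequences")
    aln = _global_aligner().align(a.residues.upper(), b.residues.upper())[0]
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    return 100.0 * counts.identities / columns


def write_bed6(intervals: Iterable[tuple[GenomicInterval, str, float]],
               path: str | Path) -> None:
    """Write (interval, name, score) triples as BED6."""
    with open(path, "w") as fh:
        for iv, name, score in intervals:
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


def read_marker_table(path: str | Path) -> list[MarkerInput]:
    """Read a marker table TSV (marker_id, transcript_id, linkage_group, cM,
    has_protein_annotation)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"marker_id", "transcript_id", "linkage_group", "cM",
                "has_protein_annotation"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"marker table missing column(s): {sorted(missing)}")
    if df["marker_id"].duplicated().any():
        dups = df.loc[df["marker_id"].duplicated(), "marker_id"].tolist()
        raise ValueError(f"duplicate marker id(s): {dups}")
    return [
        MarkerInput(
            marker_id=str(r.marker_id),
            transcript_id=str(r.transcript_id),
            linkage_group=str(r.linkage_group),
            cM=float(r.cM),
            has_protein_annotation=bool(r.has_protein_annotation),
        )
        for r in df.itertuples()
    ]


_FIXTURE_FILES = {
    "probe_table": ["probe_table.tsv"],
    "positions_chr2": ["positions_chr2.tsv"],
    "positions_chr6": ["positions_chr6.tsv"],
    "genetic_map_chr2": ["genetic_map_chr2.tsv"],
    "genetic_map_chr6": ["genetic_map_chr6.tsv"],
    "pseudo_map_chr2": ["pseudo_map_chr2.tsv"],
    "pseudo_map_chr6": ["pseudo_map_chr6.tsv"],
    "karyotype": ["karyotype.tsv"],
}


def load_reference_table(name: str) -> pd.DataFrame:
    """Load one of the packaged reference tables from the onion Tyr-FISH study.

    Available names: ``probe_table``, ``positions_chr2``, ``positions_chr6``,
    ``genetic_map_chr2``, ``genetic_map_chr6``, ``pseudo_map_chr2``,
    ``pseudo_map_chr6``, ``karyotype``, and the combined ``marker_orders``
    (long-format genetic + pseudochromosome orders for both chromosomes).
    """
    if name == "marker_orders":
        frames = []
        for chrom in ("2", "6"):
            g = load_reference_table(f"genetic_map_chr{chrom}")
            g = g.rename(columns={"cM": "coordinate"})
            g["map"] = "genetic"
            g["chromosome"] = chrom
            p = load_reference_table(f"pseudo_map_chr{chrom}")
            p = p.rename(columns={"mbp_bin": "coordinate"})
            p["map"] = "pseudo"
            p["chromosome"] = chrom
            cols = ["chromosome", "map", "marker_id", "coordinate", "printed"]
            frames += [g[cols], p[cols]]
        return pd.concat(frames, ignore_index=True)
    if name not in _FIXTURE_FILES:
        raise KeyError(
            f"unknown reference table {name!r}; available: "
            f"{sorted(_FIXTURE_FILES) + ['marker_orders']}"
        )
    (fname,) = _FIXTURE_FILES[name]
    with resources.files("fishmap.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")
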