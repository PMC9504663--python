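import itertools

import numpy as np
import pytest

from fishmap.probe_design import (
    PlacementParams,
    PrimerParams,
    discard_hard_masked,
    extract_candidates,
    filter_markers,
    place_transcript,
    primer_tm,
    propose_primer_pairs,
)
from fishmap._seeds import find_seed_runs
from fishmap.sequence_io import MarkerInput, SequenceRecord

from .conftest import mutate, random_seq


def make_genome_with_gene(rng, gene, n_flank=2000, n_chroms=2):
    """Embed `gene` at a known locus on chr1 of a random background."""
    chroms = []
    left = random_seq(rng, n_flank)
    right = random_seq(rng, n_flank)
    chroms.append(SequenceRecord("chr1", left + gene + right))
    for i in range(1, n_chroms):
        chroms.append(SequenceRecord(f"chr{i + 1}", random_seq(rng, n_flank)))
    return chroms, n_flank, n_flank + len(gene)


class TestPlaceTranscript:
    def test_unique_exact_match(self, rng):
        gene = random_seq(rng, 600)
        genome, start, end = make_genome_with_gene(rng, gene)
        p = place_transcript(SequenceRecord("t", gene), genome)
        assert p.placed and not p.ambiguous
        assert p.locus.seq_id == "chr1"
        assert (p.locus.start, p.locus.end) == (start, end)

    def test_identical_paralog_is_ambiguous(self, rng):
        gene = random_seq(rng, 400)
        flank = random_seq(rng, 500)
        genome = [
            SequenceRecord("chr1", flank + gene + flank),
            SequenceRecord("chr2", random_seq(rng, 300) + gene),
        ]
        p = place_transcript(SequenceRecord("t", gene), genome)
        assert p.ambiguous
        assert p.second_best_score == p.chain_score

    def test_no_seed_hits_returns_unplaced(self, rng):
        genome = [SequenceRecord("chr1", "AT" * 500)]
        p = place_transcript(SequenceRecord("t", "GC" * 50), genome)
        assert not p.placed and p.locus is None

    def test_intron_spanning_chain(self, rng):
        """Two exons split by a 500-bp intron chain into one locus whose score
        matches exhaustive chaining over all seed-run subsets."""
        exon1, exon2 = random_seq(rng, 300), random_seq(rng, 300)
        intron = random_seq(rng, 500)
        genome = [
            SequenceRecord(
                "chr1",
                random_seq(rng, 200) + exon1 + intron + exon2 + random_seq(rng, 200),
            )
        ]
        transcript = SequenceRecord("t", exon1 + exon2)
        p = place_transcript(
            transcript, genome, PlacementParams(max_intron=600)
        )
        assert p.placed
        assert p.locus.start == 200
        assert p.locus.end == 200 + 300 + 500 + 300

        # exhaustive chaining oracle: best colinear subset of seed runs under
        # the chaining contract (small junction overlaps allowed, overlapped
        # query bases counted once)
        runs = find_seed_runs(transcript.residues, genome[0].residues, 13)
        best = 0
        for size in range(1, min(len(runs), 6) + 1):
            for subset in itertools.combinations(runs, size):
                chain = sorted(subset, key=lambda r: r.s_start)
                ok = all(
                    b.s_end > a.s_end
                    and b.q_end > a.q_end
                    and b.s_start >= a.s_end - 20
                    and b.q_start >= a.q_end - 20
                    and b.s_start - a.s_end <= 600
                    for a, b in zip(chain, chain[1:])
                )
                if ok:
                    covered = set()
                    for r in chain:
                        covered.update(range(r.q_start, r.q_end))
                    best = max(best, len(covered))
        assert p.chain_score == best

    def test_short_transcript_rejected(self):
        with pytest.raises(ValueError):
            place_transcript(
                SequenceRecord("t", "ACGTACGT"), [SequenceRecord("c", "ACGT" * 100)]
            )


class TestFilterMarkers:
    def _setup(self, rng):
        genes = {f"t{i}": random_seq(rng, 400) for i in range(10)}
        chrom = "".join(genes[f"t{i}"] + random_seq(rng, 100) for i in range(8))
        off = genes["t8"] + random_seq(rng, 100)
        genome = [
            SequenceRecord("chr1", chrom),
            SequenceRecord("scaffold_x", off + genes["t9"]),
            # t9 also sits on chr1-equivalent copy to make it ambiguous
            SequenceRecord("scaffold_y", genes["t9"]),
        ]
        placements = {
            tid: place_transcript(SequenceRecord(tid, seq), genome)
            for tid, seq in genes.items()
        }
        return genome, placements

    def test_partition_rules_and_conservation(self, rng):
        genome, placements = self._setup(rng)
        markers = [
            MarkerInput(f"m{i}", f"t{i}", "2", float(i),
                        has_protein_annotation=(i != 0))
            for i in range(10)
        ]
        parts = filter_markers(markers, placements, {"chr1"})
        assert [m.marker_id for m in parts["no_protein_annotation"]] == ["m0"]
        assert "m8" in [m.marker_id for m in parts["wrong_chromosome"]]
        assert "m9" in [m.marker_id for m in parts["ambiguous"]]
        assert sum(len(v) for v in parts.values()) == len(markers)
        assert len(parts["retained"]) == 7

    def test_unknown_transcript_raises(self, rng):
        genome, placements = self._setup(rng)
        with pytest.raises(ValueError, match="no placement"):
            filter_markers(
                [MarkerInput("m", "missing", "2", 0.0)], placements, {"chr1"}
            )


class TestHardMaskFilter:
    @pytest.mark.parametrize(
        "seq,keep",
        [
            ("ACGT" * 500 + "N" * 50 + "ACGT" * 10, False),
            ("ACGT" * 20 + "N" + "ACGT" * 20, True),
            ("ACGT" * 40, True),
        ],
    )
    def test_n_run_rule(self, seq, keep):
        assert discard_hard_masked(SequenceRecord("g", seq), max_N_run=10) is keep


class TestPrimers:
    def test_wallace_tm_hand_value(self):
        # 20-mer with 10 G/C: 64.9 + 41*(10-16.4)/20 = 51.78
        primer = "G" * 5 + "C" * 5 + "A" * 5 + "T" * 5
        assert primer_tm(primer) == pytest.approx(51.78)

    def test_products_within_window(self, rng):
        gene = SequenceRecord("g", random_seq(rng, 5000))
        pairs = propose_primer_pairs(gene)
        assert pairs, "expected at least one pair on a 5-kb gene"
        assert len(pairs) <= 5
        for p in pairs:
            assert 1000 <= p.product_length <= 4000
            assert p.left_seq.isupper() and "N" not in p.left_seq
        penalties = [p.penalty for p in pairs]
        assert penalties == sorted(penalties)

    def test_short_gene_yields_empty(self, rng):
        gene = SequenceRecord("g", random_seq(rng, 800))
        assert propose_primer_pairs(gene) == []

    def test_primers_avoid_masked_bases(self, rng):
        core = random_seq(rng, 1500)
        gene = SequenceRecord("g", core[:700] + core[700:800].lower() + core[800:])
        for p in propose_primer_pairs(gene):
            assert p.left_seq.isupper()
            assert p.right_seq.isupper()


class TestExtractCandidates:
    def test_masked_island_discards_product(self, rng):
        seq = random_seq(rng, 3000)
        # soft-masked island in the middle of every viable product window
        gene = SequenceRecord("g", seq[:1400] + seq[1400:1500].lower() + seq[1500:])
        genome, start, end = make_genome_with_gene(rng, gene.residues.upper())
        placement = place_transcript(
            SequenceRecord("g", gene.residues.upper()), genome
        )
        pairs = propose_primer_pairs(gene)
        cands = extract_candidates(gene, pairs, placement)
        for c in cands:
            assert len(c.sequence) == c.primer_pair.product_length
            assert len(c.product_interval) == c.primer_pair.product_length
            spans_island = (
                c.primer_pair.left_start < 1500 and c.primer_pair.right_end > 1400
            )
            if spans_island:
                assert c.status == "discarded_masked" and c.masked_bases > 0
            else:
                assert c.status == "candidate" and c.masked_bases == 0

    def test_genome_coordinates_lifted(self, rng):
        gene_seq = random_seq(rng, 2000)
        genome, start, end = make_genome_with_gene(rng, gene_seq)
        gene = SequenceRecord("g", gene_seq)
        placement = place_transcript(gene, genome)
        cands = extract_candidates(gene, propose_primer_pairs(gene), placement)
        for c in cands:
            g = genome[0].residues[c.product_interval.start : c.product_interval.end]
            assert g == c.sequence.residues
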