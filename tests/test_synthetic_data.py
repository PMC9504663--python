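import numpy as np
import pytest
from scipy import stats

from fishmap.cytogenetics import aggregate_position
from fishmap.pipeline import design_probes
from fishmap.sequence_io import MarkerInput, SequenceRecord
from fishmap.synthetic_data import (
    GenomeSpec,
    MapSpec,
    RepeatFamily,
    generate_genetic_map,
    generate_genome,
    simulate_signals,
)

SMALL = GenomeSpec(
    n_chromosomes=2,
    chromosome_length=30_000,
    gene_count=4,
    gene_length=2000,
    repeat_families=(
        RepeatFamily("sat", unit_length=200, copies=10, tandem=True),
        RepeatFamily("disp", unit_length=300, copies=5, tandem=False),
    ),
    seed=11,
)


class TestGenerateGenome:
    def test_deterministic_per_seed(self):
        g1, g2 = generate_genome(SMALL), generate_genome(SMALL)
        assert [c.residues for c in g1.chromosomes] == [
            c.residues for c in g2.chromosomes
        ]
        assert g1.genes.equals(g2.genes)

    def test_truth_tables_describe_planted_features(self):
        g = generate_genome(SMALL)
        chroms = {c.id: c for c in g.chromosomes}
        for row in g.genes.itertuples():
            span = chroms[row.seq_id].residues[row.start : row.end]
            assert span.isupper()
        for row in g.repeats.itertuples():
            span = chroms[row.seq_id].residues[row.start : row.end]
            assert span.islower(), "repeats must be written soft-masked"

    def test_transcript_is_spliced_gene(self):
        g = generate_genome(SMALL)
        chroms = {c.id: c for c in g.chromosomes}
        t = g.transcripts[0]
        row = g.genes.iloc[0]
        genomic = chroms[row.seq_id].residues[row.start : row.end]
        # exons of the transcript appear in order within the genomic span
        pos = genomic.find(t.residues[:200])
        assert pos == 0
        assert genomic.find(t.residues[-200:]) > 0

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="packing"):
            generate_genome(
                GenomeSpec(n_chromosomes=1, chromosome_length=5000, gene_count=10)
            )

    def test_paralog_free_genome_yields_clean_probes(self):
        g = generate_genome(SMALL)
        markers = [
            MarkerInput(t.id, t.id, "1", float(i))
            for i, t in enumerate(g.transcripts[:2])
        ]
        res = design_probes(
            g.chromosomes, g.transcripts[:2], markers,
            {c.id for c in g.chromosomes},
        )
        for verdict in res.selected.values():
            assert verdict.dangerous_count == 0

    def test_duplicated_gene_probes_gain_dangerous_hits(self):
        """Even the least-hit probe of a duplicated gene carries dangerous
        off-target hits when screened from its true locus."""
        from fishmap.probe_design import (
            TranscriptPlacement,
            extract_candidates,
            propose_primer_pairs,
        )
        from fishmap.sequence_io import GenomicInterval, extract_interval
        from fishmap.specificity import screen_candidates

        spec = GenomeSpec(
            n_chromosomes=2, chromosome_length=30_000, gene_count=3,
            gene_length=2000, repeat_families=(), paralog_rate=1.0,
            paralog_divergence=0.02, seed=5,
        )
        g = generate_genome(spec)
        assert len(g.paralogs) == 3
        row = g.genes.iloc[0]
        locus = GenomicInterval(row.seq_id, int(row.start), int(row.end))
        gene_seq = SequenceRecord(
            str(row.gene_id), extract_interval(g.chromosomes, locus).residues
        )
        placement = TranscriptPlacement(
            str(row.gene_id), locus, chain_score=float(len(gene_seq))
        )
        cands = extract_candidates(
            gene_seq, propose_primer_pairs(gene_seq), placement
        )
        verdicts = screen_candidates(cands, g.chromosomes)
        selected = next(v for v in verdicts if v.selected)
        assert selected.dangerous_count >= 1

    def test_near_identical_paralog_makes_placement_ambiguous(self):
        """A transcript whose gene has a near-identical copy elsewhere cannot
        be assigned to one locus and is excluded as ambiguous."""
        spec = GenomeSpec(
            n_chromosomes=2, chromosome_length=30_000, gene_count=3,
            gene_length=2000, repeat_families=(), paralog_rate=1.0,
            paralog_divergence=0.02, seed=5,
        )
        g = generate_genome(spec)
        markers = [MarkerInput(g.transcripts[0].id, g.transcripts[0].id, "1", 0.0)]
        res = design_probes(
            g.chromosomes, [g.transcripts[0]], markers,
            {c.id for c in g.chromosomes},
        )
        assert [m.marker_id for m in res.partitions["ambiguous"]] == [
            g.transcripts[0].id
        ]


class TestGeneticMap:
    FL = [(f"m{i}", float(fl)) for i, fl in enumerate(range(5, 100, 10))]

    def test_monotone_without_suppression_or_noise(self):
        df = generate_genetic_map(self.FL, MapSpec())
        assert df.cM.is_monotonic_increasing
        assert (df.cM.diff().dropna() > 0).all()

    def test_full_suppression_collapses_zone_to_ties(self):
        spec = MapSpec(suppressed_zones=((30.0, 70.0, 0.0),))
        df = generate_genetic_map(self.FL, spec)
        inside = df[(df.true_fl > 30) & (df.true_fl <= 70)]
        assert inside.cM.nunique() == 1
        assert inside.tied.all()

    def test_flip_flag_detected(self):
        from fishmap.map_integration import detect_orientation

        df = generate_genetic_map(self.FL, MapSpec(flipped=True))
        verdict = detect_orientation(
            list(zip(df.marker_id, df.cM)), self.FL
        )
        assert verdict == "flipped"


class TestSimulateSignals:
    TRUTH = [("p1", "short", 60.0), ("p2", "long", 25.0)]

    def test_noiseless_limit_recovers_truth_exactly(self):
        signals, truth = simulate_signals(
            self.TRUTH, rphc_noise_sd=0.0, detection_p=1.0, n_metaphases=10,
            seed=1,
        )
        for probe, arm, rphc in self.TRUTH:
            sub = signals[signals.probe_id == probe]
            recs = [
                _record(r) for r in sub.itertuples()
            ]
            t = truth[truth.probe_id == probe].iloc[0]
            pos = aggregate_position(recs, t.n_metaphases, t.n_detected)
            assert pos.rphc_mean == pytest.approx(rphc)
            assert pos.rphc_sd == pytest.approx(0.0)
            assert pos.detection_frequency == 100.0

    def test_mean_recovery_within_standard_error(self):
        """The recovered mean stays within 2 standard errors of truth at the
        nominal ~95% coverage rate across seeded replicates.

        Coverage of a 2-SE interval is 95.45% in expectation; over 100
        replicates the observed count fluctuates binomially (SD ~2), so the
        assertion uses the 99.9% lower binomial bound (90) rather than the
        nominal 95 to keep the check sound."""
        sd, n = 2.5, 50
        ok = 0
        reps = 100
        for seed in range(reps):
            signals, truth = simulate_signals(
                [("p", "short", 40.0)], rphc_noise_sd=sd, detection_p=1.0,
                n_metaphases=n // 2, seed=seed,
            )
            measured = signals.d_centromere / signals.arm_length * 100.0
            if abs(measured.mean() - 40.0) <= 2 * sd / np.sqrt(len(measured)):
                ok += 1
        assert ok >= 90

    def test_detection_frequency_within_binomial_interval(self):
        p, n = 0.5, 40
        signals, truth = simulate_signals(
            [("p", "short", 50.0)], rphc_noise_sd=1.0, detection_p=p,
            n_metaphases=n, seed=4,
        )
        t = truth.iloc[0]
        # a cell is detected when either homolog shows a signal
        p_cell = 1 - (1 - p) ** 2
        lo, hi = stats.binom.interval(0.95, n, p_cell)
        assert lo <= t.n_detected <= hi

    def test_deterministic_per_seed(self):
        s1, _ = simulate_signals(self.TRUTH, seed=9)
        s2, _ = simulate_signals(self.TRUTH, seed=9)
        assert s1.equals(s2)


def _record(row):
    from fishmap.cytogenetics import SignalRecord

    return SignalRecord(
        probe_id=row.probe_id,
        metaphase_id=row.metaphase_id,
        chromosome_copy=row.chromosome_copy,
        arm=row.arm,
        d_centromere=row.d_centromere,
        arm_length=row.arm_length,
    )
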