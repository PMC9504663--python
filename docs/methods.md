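# Methods

This note documents the models, parameters and numerical choices behind
fishmap, and what the synthetic tests do and do not demonstrate.

## Transcript placement

A transcript is placed on the assembly by exact k-mer seeding (default
k = 13) followed by colinear chaining. Maximal exact-match runs are found on
both strands of every sequence, clustered when separated by at most
`max_intron` (default 5 000 bp), and chained by an O(n²) dynamic program that
requires query and subject to advance and the genomic gap between runs to
stay within `max_intron`. Runs may overlap by up to 20 bp — maximal exact
matches flanking an intron routinely share a few junction bases — and
overlapped query bases count once in the chain score (transcript coverage).

A placement is *ambiguous* when the best chain at a second, non-overlapping
locus scores at least `ambiguity_ratio` (default 0.95) of the best chain.
This operationalizes "maps ambiguously": a transcript whose gene has a
near-identical copy cannot be assigned to one locus and its marker is
excluded, which is the correct conservative behavior for single-copy probe
design. The 0.95 default is a design choice (no published quantification
exists); it is exposed in the API and CLI.

This placement engine is scoped for the package's toy-genome scale. It does
not model splice-site consensus or score exon boundaries; for real
multi-gigabase assemblies a dedicated spliced aligner is the right tool, and
placements produced externally can be fed in through the same
`TranscriptPlacement` contract.

## Masking filters

Masking is carried in the sequence itself: lowercase = soft-masked repeat,
N = hard-masked. Gene sequences with a run of ≥ `max_N_run` (default 10)
consecutive Ns are discarded before primer design; the threshold separates
assembly gaps from isolated ambiguous bases, which are tolerated. Probe
products containing *any* masked base (soft or hard) are discarded — an
amplified FISH probe carrying even a short repeat fragment produces
genome-wide background.

## Primer model

The primer proposer is deliberately transparent rather than thermodynamic:
length 18–27 (optimum 20), GC 40–60 % (optimum 50 %), Wallace-style melting
temperature Tm = 64.9 + 41·(GC_count − 16.4)/length with optimum 60 °C, and
product length 1 000–4 000 bp. Pair penalty is the sum of weighted absolute
deviations from the optima plus the product-length deviation from the
2 500 bp midpoint (1 penalty unit per 500 bp). Candidate primers are
pre-selected as the best window per 20-bp start bucket, which keeps
candidates spread along the gene so long products stay reachable. No duplex,
hairpin or dimer screening is done; an external primer-design backend can be
substituted behind the same `PrimerPair` contract.

## Off-target screen and the dangerous-hit rule

Each candidate probe is aligned genome-wide by seed-and-extend: exact 13-mer
seed runs delimit candidate windows, and each window is resolved by optimal
local alignment (match +1, mismatch −1, linear gap −2). Because one window
can hold several distinct loci, suboptimal alignments are enumerated
Waterman–Eggert style: align, report, mask the aligned span, re-align, until
the alignment drops below the reporting floors (50 aligned columns, score
25). Identity is 100·matches/aligned columns with gap columns in the
denominator. On toy instances this screen is verified equal, above the
dangerous thresholds, to an exhaustive full-DP local-alignment oracle.

A hit is **dangerous** when it lies outside the probe's own product locus
(< 1 bp overlap) and has identity > 80 % *and* aligned length > 100 bp, both
strictly. The 80 % identity threshold equals the hybridization washing
stringency (80–82 %) under which a duplex with fewer paired bases is
unstable; the mapping from stringency to threshold is an asserted
pass-through, exposed as `stringency_identity_threshold`. Per gene,
candidates are ranked by (dangerous count, total off-target aligned bases,
primer penalty); the first two keys follow the selection rule, the third
tie-break is this package's choice.

E-values are not computed: the dangerous rule consumes only identity and
length, so explicit reporting floors replace a significance model.

## Cytogenetic statistics

RPHC = 100·(centromere-to-signal distance)/(arm length); aggregated per
probe as sample mean ± sample SD (n−1). A single measurement reports SD 0.0
with a warning rather than NaN, since position tables always print an SD.
Detection frequency = 100·detected/analyzed, rounded to one decimal. The
denominator is configurable (`metaphases`, default, or `chromosomes` =
2·metaphases) because published frequencies are not always expressible as
k/metaphases for integer k — the packaged chromosome-6 tables contain such
rows (e.g. 46.7 % at n = 19), so the true denominator in the source data is
ambiguous and the package does not guess.

FL conversion uses the short-arm fraction f_s: FL = f_s·(100 − RPHC) on the
short arm, 100·f_s + (1 − f_s)·RPHC on the long arm. The packaged arm
fractions (0.335 for chromosome 2, 0.40 for chromosome 6) are
reconstructions chosen to match the published FL figures (6.5/10.9/13.4 % on
chromosome 2), not measured values; they are inputs (karyotype TSV), not
constants. Report output rounds RPHC/FL to one decimal; full precision is
kept internally.

## Map integration

Physical order sorts by ascending FL (short arm descending RPHC, then long
arm ascending RPHC), per the cytogenetic convention of drawing the short arm
at the top. Ties break by marker id with a warning.

Orientation of a linkage group is detected by comparing Kendall rank
correlation of cM vs FL in both orientations over shared markers (≥ 3
required, else `undetermined`). Kendall's tau is robust at the ≤ 20-marker
scale these comparisons run at.

Two discordance metrics are first-class, because "markers in the wrong
position" has no unique counting rule and published counts mix two rules:

* **rank-mismatch** — markers whose ordinal rank differs between the orders;
  reproduces the chromosome-2 counts (3/12 and 3/13).
* **minimal-removal** — n − LIS, the fewest deletions after which the orders
  agree; reproduces the chromosome-6 counts (4/11 and 3/11). Verified
  against brute-force subset enumeration for all permutations of n ≤ 8 and
  200 random permutations of n ≤ 12.

Minimal-removal ≤ rank-mismatch always (deleting every rank-mismatched
marker reconciles the rest). The report prints both, labeled, for every map
pair, and never silently picks one.

Pseudochromosome coordinates are 1-Mbp bin numbers; markers sharing a bin
keep input order and are flagged. The genetic↔pseudo comparison reuses the
orientation decided against the physical chromosome.

## Packaged reference tables

The `data/` TSVs transcribe the probe, position and map tables of the onion
Tyr-FISH mapping study the package reproduces. Every numeric cell that the
study prints is verbatim; cells the study shows only graphically (most cM
values, most Mbp bins, the arm fractions) are reconstructions consistent
with the stated orders and are flagged `printed=0`. The mlh1 gene appears in
the position and pseudochromosome tables but not the genetic map (it was
never genetically mapped), which is why the genetic comparison covers 12
markers on chromosome 2 and the pseudochromosome comparison 13.

## Synthetic data

`generate_genome` plants non-overlapping genes (with introns), soft-masked
repeat families (tandem and dispersed) and substitution-diverged paralogs on
a uniform random background, emitting truth tables for every feature.
Defaults (2 × 200 kb chromosomes, 20 genes, 2 repeat families) exercise
seeding, masking and the off-target screen in seconds; tests use smaller
instances of the same generator. `generate_genetic_map` integrates a
recombination-rate profile whose rate is scaled inside suppressed zones, so
cM compresses and marker order becomes unrecoverable exactly where
suppression is total — the mechanism behind genetic/physical discordance.
`simulate_signals` draws per-metaphase, per-homolog detections
(Bernoulli p) and Gaussian RPHC noise, clipped to [0, 100] with clip events
counted. All generators are deterministic per seed.

What passing synthetic tests shows: the pipeline's filters, screen and order
metrics behave correctly under planted, known truth. What it does not show:
performance on real repeat landscapes (nested/truncated elements, satellite
higher-order structure), real intron/exon statistics, measurement error that
correlates with chromosome condensation, or assembly artifacts. The
generator's uniform background also makes seeding easier than in a real
16-Gb genome.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open everywhere internally; 1-based closed
  appears only in human-readable output.
* Percent identity (probe vs genomic sequence) uses global alignment with
  match +1, mismatch −1, linear gap −2, identity over all aligned columns
  including gaps; co-optimal alignments can differ by a fraction of a column.
* FL↔RPHC round-trips are exact to 1e−9; FL exactly at the centromere maps
  to ("centromere", 0) rather than picking an arm.
* `detect_orientation` with < 3 shared markers returns `undetermined`; map
  pairs sharing < 2 markers are reported `not comparable` rather than 0 %.
* Statistical tests on seeded replicates assert calibrated binomial bounds
  (e.g. ≥ 90/100 for a nominal 95.45 % 2-SE coverage), not nominal rates, so
  a correct generator does not fail by fluctuation.

## Problem sizes

Tests and the acceptance script run toy instances by design: genomes of
25–60 kb with 2–6 genes for pipeline runs, ≤ 1.5 kb windows for
alignment-oracle equivalence (50 seeded trials), all 46 233 permutations of
n ≤ 8 plus 200 random n ≤ 12 for the removal metric. These sizes fully
exercise every code path; the packaged-table analysis is exact and
deterministic at its natural size (11–13 markers per chromosome).
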