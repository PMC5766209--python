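# Methods

## The order statistic

The unit of measurement is the adjacent intron pair: two consecutive introns
of one transcript separated by a single internal exon. A paired-end read is
an *intermediate read* for a pair when one mate's alignment gap exactly
matches one intron of the pair (that intron has been removed) and the other
mate overlaps the neighboring intron by at least `min_overlap` nucleotides
(default 1 nt; that intron is still present). Junction matching is exact by
default (`junction_slop = 0`) because spliced aligners place gaps exactly at
annotated introns; both options are configurable. A read whose geometry
supports both directions simultaneously is contradictory and is discarded as
uninformative, as is a junction read whose mate touches only exonic
sequence. A read whose junction intron is shared by two adjacent pairs is
evaluated once per pair it can inform.

All fractions follow a single orientation convention —
`fraction_downstream_first` for the pair taken in transcription order — and
every downstream quantity (always-first calls, slowpoke logic) is derived
from it, so no sign conventions are ever mixed. Coordinates are BED-style
0-based half-open throughout; GTF input is converted on read. On the minus
strand, transcription order is descending genomic coordinate, and all
boundary matching (junction gaps, circle coordinates) is strand-aware.

Pairs with fewer than `min_reads = 10` intermediate reads are discarded; the
boundary is inclusive (10 is retained, 9 is not). Retained fractions are
binned into `n_bins = 20` equal-width bins over [0, 1], with the last bin
right-closed so a fraction of exactly 1 is counted. An intron is
*always-first* relative to its neighbor at threshold 0.95 (≥ 0.95 or ≤ 0.05);
at depth 10 this equals requiring a 19:1 margin. A *local slowpoke* is an
internal intron observed to splice after both its upstream neighbor
(fraction ≤ 0.05 in the pair where it is the downstream member) and its
downstream neighbor (fraction ≥ 0.95 in the pair where it is the upstream
member); terminal introns have one neighbor and are reported not-callable.

When several isoforms contribute an identical coordinate pair, the pair is
counted once and all contributing transcripts are recorded; its positional
(first/middle/last) label is taken from the deepest contributing isoform
(most introns, ties broken by transcript id) so the three labels stay
mutually exclusive per pair. Positional labels are only assigned in
transcripts with more than two introns.

## The kinetic null

The null model assumes memoryless first-order splicing: each intron's
waiting time is exponential with a rate drawn from
Normal(0.169 introns/min, 0.048), the in-vivo splicing-rate distribution;
non-positive draws are rejected and redrawn (a ~2×10⁻⁴ tail at the
defaults). If rejection would discard more than 40% of the distribution the
draw is refused with advice to use an explicit truncated law — for a
positive mean the non-positive tail can approach but never reach one half,
so the guard sits below that bound. The upstream intron's clock starts at
time zero (the pair exists once the upstream intron is transcribed); the
downstream clock starts after the polymerase, at 3.87 kb/min, has covered
the internal exon plus the downstream intron. Terminal-exon transcription is
irrelevant to the order statistic and is ignored. The closed form

    P(upstream first) = 1 − e^(−k_up·d) · k_down/(k_up + k_down)

is used everywhere for speed; a brute-force two-exponential Monte-Carlo
estimator is retained as an independent oracle and checked against the
closed form in the test suite. P is monotone in delay and in k_up, equals
k_up/(k_up+k_down) at zero delay, and tends to 1 as the delay grows.

For each observed pair (unique splice sites, depth-filtered), the null
simulator draws fresh rates, computes the order probability from the pair's
own internal-exon and downstream-intron lengths, and simulates the observed
number of reads as Bernoulli trials. Uniqueness is strict: all four splice
sites of the pair must occur exactly once among all annotated intron
instances, so an identical intron annotated in a second isoform makes the
pair non-unique; `scope="gene"` relaxes this to one count per gene.

The **excess test** is a Pearson chi-square of the observed histogram
against the simulated null scaled to the observed total, with bins pooled
left-to-right until every group's expected count reaches 5 and
df = (groups − 1); the observed-minus-expected count in the first and last
bin is reported alongside. The null histogram is the *average* of
`n_reps = 100` replicate simulations rather than a single realization:
the test treats the null as an expectation, and a single same-size
realization would contribute its own sampling variance and roughly double
the statistic. At 100 replicates the Monte-Carlo error of the expectation
is ~1% of the observed sampling error and the test is approximately
calibrated (slightly conservative, because per-pair bin memberships are
non-identical categoricals whose variance is below Poisson).

The steady-state square law covers the post-transcriptional limit: with a
two-intron precursor synthesized at constant rate and spliced independently
(P → I1 → M, P → I2 → M), the steady-state intermediate abundances obey
[I1]/[I2] = (k1/k2)². The implementation returns the closed form; the test
suite and acceptance script verify it against forward integration of the
ODE system.

`parameter_sweep` re-runs the null simulation and excess test over a grid of
(rate_mean, rate_sd, txn_rate), with per-grid-point seeds spawned
deterministically from one root seed so results are independent of
iteration order.

## Category analyses

*Skipping*: an annotated intron is a skipping intron when its 5′ and 3′
splice sites exactly match the 5′ss of one intron and the 3′ss of a later
consecutive intron of another (inclusion) isoform, spanning at most two
internal exons by default (configurable). Labels attach to the inclusion
isoform's pairs: for single-exon events the pair around the skipped exon is
`skip_internal` and its transcription-order neighbors `skip_before` /
`skip_after`; for two-exon events pairs wholly inside the shadowed intron
run are `multi_skip_middle` and pairs joining a run boundary to an outside
neighbor `multi_skip_flank`.

*Alternative splice sites*: introns sharing a 3′ss with ≥ 2 distinct 5′ss
form an alt-5′ group (symmetrically for alt-3′); the group representative is
the shortest intron, and pairs containing a representative are labeled
`alt5_flank` / `alt3_flank`.

*Circles*: a back-splice span matches a pair as "before" when its
transcription-first boundary coincides with the end of the pair's upstream
intron, and as "after" when its transcription-last boundary coincides with
the start of the pair's downstream intron; matching is exact coordinate
equality with an optional `slop`. Circle *candidates* are internal exons
whose two flanking introns are both ≥ 10 kb, optionally intersected with a
user-supplied exon whitelist that stands in for a conserved-start-site
criterion (a deliberate simplification: no conservation is computed).
The negative predicate (both flanking introns < 250 nt) is exposed
separately.

*Length*: per pair, upstream length minus downstream length (negative =
longer downstream intron), binned at 500 nt over ±10 kb with open outer
bins; per bin, the fraction of pairs whose downstream intron splices first
at least 95% of the time.

*Motifs*: density is exact string matching on the sense strand (U mapped to
T), non-overlapping by default, divided by intron length. Enrichment between
always-first and always-last introns uses a two-sided Mann-Whitney rank-sum
per motif with Benjamini–Hochberg correction across the panel; the matching
and testing rules are this package's choices, as is the 0.95-threshold group
definition. No PWM scanning or motif discovery is performed; any motif panel
file is accepted.

## Synthetic data generator

The molecule-level generator lays a gene out contiguously on a synthetic
chromosome ("synth1", plus strand) and simulates each molecule's splicing:
the polymerase advances at `txn_rate`; each intron becomes eligible when
fully transcribed *and* all its dependency parents (a user-specified acyclic
edge set, "j cannot splice until i is removed") are spliced, then completes
after an exponential waiting time with its own rate. Because eligibility is
a max over parent completion times and waiting times are memoryless,
completion times are computed exactly in topological order without event
queues.

Read emission is keyed on the per-molecule order event: a molecule that
removed one intron of a pair first passed through exactly one intermediate
state, and that state is emitted (with probability `capture_rate`) as a read
pair — a junction mate split exactly at the removed intron's boundaries plus
a mate placed uniformly inside the retained intron (truncated to the intron
when it is shorter than the 100 nt mate). This makes the read-level fraction
an unbiased estimate of the order probability and enables exact round-trip
tests. Sampling steady-state intermediate *abundance* instead would weight
each intermediate by its dwell time (the square-law effect) and estimate a
different quantity; molecule snapshots at harvest time remain available for
inspecting state occupancy, with steady-state harvest implemented as
continuous initiation over a window 10× the slowest expected completion.
Sequencing error, soft-clipping and sequence content are not modeled; reads
can also be written as plain-text SAM to exercise the alignment-reading
path.

The pair-level cohort generator produces genome-like cohorts directly from
the kinetic law for cohort-scale experiments: internal exon lengths
lognormal with median 140 nt (σ = 0.55), intron lengths lognormal with
median 1.5 kb (σ = 1.1) — both chosen once as hg19-like — and read depth
10 + Geometric(mean 15), emulating the depth-filtered ≥ 10-read population
with a heavy tail. A configurable fraction of pairs is dependency-forced
(order deterministic, direction 50/50), the synthetic analogue of introns
that require a neighboring splicing event.

What passing tests on these data do and do not show: the generator shares
the null model's kinetic core, so agreement demonstrates the correctness of
the classification, counting, filtering and testing machinery, and the
power/calibration of the excess test under the stated conditions — not the
biological fidelity of the kinetic model itself, nor robustness to
real-data artifacts (mixed cell types and nuclear fractions, alignment
error, recursive splicing, intron retention) which the generator does not
emulate.

## Problem sizes and numerical choices

The test suite and acceptance script run cohorts of 1,000 pairs (20
replicates for power, 200 for calibration), 200 free + 100 dependency-forced
molecule-level loci at depths 25–30, and 10⁵–10⁶-draw Monte-Carlo oracles —
sizes chosen so the full acceptance computation completes in well under a
minute while leaving Monte-Carlo error far below every asserted tolerance.
Genome-scale analyses (~10⁵ pairs from full ENCODE-like data) use the same
code paths; only the inputs grow.

Degenerate inputs are handled explicitly: single-exon transcripts yield no
introns; transcripts with overlapping exons are skipped with a warning;
zero-read pairs have undefined fractions and are excluded; histograms with
fewer than two effective bins after pooling refuse the chi-square rather
than fabricate a p-value; circles matching no boundary are counted and
dropped. All randomness flows from explicit seeds through numpy
`SeedSequence` spawning, so every result is reproducible and independent of
iteration order.

## Known limitations

- Uniqueness and category logic operate on the annotation as given; no
  de novo junction discovery is attempted.
- The kinetic null ignores rate–length coupling and recursive splicing, and
  models a homogeneous population.
- Library-selection metadata filtering (read length, polyA status, cellular
  fraction) is left to the user upstream of the tool.
- Conservation-based circle prediction is reduced to a length predicate plus
  a whitelist.
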