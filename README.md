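# spliceorder

Genome-wide order of intron removal from paired-end RNA-seq, with a
co-transcriptional kinetic null model.

## The problem

Human genes carry ~10 introns each, and the spliceosome does not remove them
in transcription order. Some introns cannot be spliced until a neighboring
intron has been removed — a dependency that can turn a single point mutation
into a multi-exon skipping disease allele. `spliceorder` measures splicing
order directly from total/nuclear RNA-seq: a *partially spliced intermediate*
is witnessed by a read pair in which one mate spans an exon–exon junction
(that intron is gone) while its mate lies inside the adjacent, still-retained
intron. For every **adjacent intron pair** (two consecutive introns around
one internal exon) the tool counts intermediates supporting
upstream-first vs downstream-first removal and reports

```
fraction_downstream_first = n_downstream_first / (n_upstream_first + n_downstream_first)
```

for pairs with ≥ 10 intermediate reads.

Order alone cannot distinguish dependency from fast-vs-slow kinetics, so the
observed distribution of per-pair fractions is compared with a **purely
kinetic null**: each intron splices independently with a first-order rate
drawn from the in-vivo rate distribution (normal, mean 0.169 introns/min,
sd 0.048), and the downstream intron only exists after the polymerase
(3.87 kb/min) has transcribed the internal exon and the downstream intron.
The upstream intron wins the race with probability

```
P(upstream first) = 1 − exp(−k_up · d) · k_down / (k_up + k_down),
d = (exon_len + downstream_intron_len) / txn_rate
```

A Pearson chi-square **excess test** asks whether the observed histogram has
more mass in the extreme ("always-first") bins than the simulated null. For
post-transcriptional splicing at steady state, the abundance ratio of the two
single-spliced intermediates follows the square law `(k1/k2)²`, also
implemented and verified against forward integration. Category analyses
relate order to exon skipping, alternative 5′/3′ splice sites, first/middle/
last position, circRNA-flanking introns, intron length differences, and RBP
motif density. A synthetic co-transcriptional splicing generator (with
configurable intron–intron dependency edges) makes the entire pipeline
testable without external data.

Audience: RNA processing labs analyzing total or nuclear RNA-seq who want
per-pair splicing-order estimates and a principled kinetic baseline.

## Worked example

Simulate a 3-intron gene whose middle intron is slow (rates 0.25, 0.08,
0.20 introns/min), emit 400 molecules' worth of intermediate reads, and run
the full pipeline:

```
$ cat locus.cfg
exon_lengths=150,150,150,150
intron_lengths=800,2500,600
rates=0.25,0.08,0.2
n_molecules=400
seed=11

$ spliceorder synth --spec locus.cfg --out-dir synth
800 read pairs written to synth

$ spliceorder run-all --annotation synth/model.bed12 --dialect bed12 \
      --reads synth/reads.tsv --out-dir run --seed 5
```

The generator's analytic truth (`synth/truth.tsv`):

```
pair_index  upstream_intron  downstream_intron  expected_fraction_downstream_first  dependent
1           1                2                  0.20428184402858107                 False
2           2                3                  0.7032969217174655                  False
```

and the pipeline's estimates recovered from the reads (`run/counts.tsv`):

```
pair_id                          n_upstream_first  n_downstream_first  fraction_downstream_first  passes_depth
synth1:150-950|1100-3600(+)      315               85                  0.2125                     True
synth1:1100-3600|3750-4350(+)    123               277                 0.6925                     True
```

The slow middle intron is removed after intron 1 in ~79% of molecules
(pair 1 fraction 0.21) and after intron 3 in ~69% (pair 2 fraction 0.69) —
both within binomial noise of the analytic expectation. `run/` also contains
the binned order histogram, the simulated kinetic null, always-first calls,
local-slowpoke calls (introns splicing after both neighbors), per-category
histograms and the length analysis, each TSV with a `#` provenance header.

The same stages are available piecewise (`extract-pairs`, `classify`,
`histogram`, `simulate-null`, `excess-test`, `categorize`,
`length-analysis`, `motif-analysis`) and as library functions.

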