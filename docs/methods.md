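# Methods

`mchtools` implements an integrative analysis of gene-body DNA methylation and
differential gene expression for a pair of conditional knockout models: one
lacking the methyltransferase that writes non-CpG methylation (mCH, cytosine
followed by A, C or T, enriched in postnatal neurons and preferentially found
at CAC), and one lacking the methyl-binding protein that reads it. This note
describes the models and procedures, the assumptions behind them, the choices
made where the design was genuinely open, and what the synthetic-data tests do
and do not establish about real data.

## Gene-body methylation levels

Per-cytosine calls arrive as allc-style tables (contig, 1-based position,
strand, trinucleotide context, methylated count, total count). Context classes
are read from the context string alone — CG iff the second base is G, CH
otherwise for a cytosine-first trinucleotide — so no reference genome is
needed.

The per-gene summary is the **weighted methylation level**
`level = Σ mc / Σ cov` over all sites of a class whose 0-based position falls
inside the gene body (annotations are BED-style 0-based half-open; allc
positions are 1-based; the conversion `pos − 1` is applied at the
intersection). The weighted level, rather than the mean of per-site fractions,
is the standard summary for sparse bisulfite-style data: it weights every read
equally and is robust to low-coverage sites. Both strands are pooled, and a
site inside two overlapping genes counts toward both, because per-gene levels
are marginal summaries, not a partition of the genome.

Genes with zero coverage in a class carry a NaN level (a flag, not an error)
and are dropped, with logged counts, wherever a defined level is required
downstream. The apparent methylation of an unmethylated spike-in contig
(lambda phage DNA added before bisulfite conversion) estimates the
non-conversion rate; it is reported only and never subtracted from levels.
Genomic summaries (global levels, per-gene levels) should exclude the spike
contig.

Knockout deltas are per-gene signed differences computed under an explicit
convention (`ko_minus_wt` or `wt_minus_ko`); switching the convention negates
both context deltas. The trend analysis below uses `ko_minus_wt` (a
methylation loss is a negative delta); difference summaries can be reported
under either convention.

## DEG classification and overlap

Differential-expression tables (gene, total count, log2 fold change, adjusted
p) are consumed, not fitted — negative-binomial DE modelling is out of scope.
Genes with total read counts below 10 are removed first. A gene is a DEG in a
model iff `padj < 0.01` strictly; non-DEG requires `padj > 0.01` strictly in
both models. Genes with missing padj in either model, or padj exactly at the
threshold, are excluded with logged counts: a missing adjusted p carries no
evidence either way, and the two strict inequalities leave no principled tie
rule. The four categories (common, A-only, B-only, non-DEG) are therefore
disjoint and exhaustive over evaluable genes.

Overlap statistics come from inclusion–exclusion
(`|A∩B| = |A| + |B| − |A∪B|`) and are reported as percentages of each model's
DEG set; the operation accepts either explicit gene sets or the three counts.
Category-level methylation distributions are compared with a two-sided
Mann–Whitney U test (the distributions are skewed and bounded, so a rank test
is the conservative default; the choice is configurable in principle but not
load-bearing). The long/short gene split uses the TSS-to-TES span with a
configurable threshold defaulting to 100 kb.

## The running-average trend statistic

For a chosen DEG set, genes are ordered by their methylation delta (ascending;
ties broken by gene id for determinism) and grouped into fixed-size
overlapping windows: window size B with 80% overlap, i.e. a step of
`B × (1 − 0.8)` genes, which must be integral. The defaults are B = 25, step 5
for single-model DEG sets and B = 10, step 2 for the smaller common and
reader-only sets. Windows that would run past the last gene are not formed, so
every bin holds exactly B genes and

    n_bins = floor((N − B) / step) + 1.

Each bin contributes one point: (mean delta, mean log2 fold change) — an
arithmetic running average, no medians. An ordinary least-squares line with
intercept is fit to the binned points; its R² (equivalently the squared
Pearson correlation of the points) is the trend statistic: the fraction of
variance in binned fold change explained by methylation change. Constant y
yields R² = 0 with zero slope; constant x leaves the line undefined and is an
error.

Because overlapping bins share members, the binned points are strongly
autocorrelated and the OLS R² has no usable parametric reference distribution.
Significance is therefore assessed by permutation: each of n repetitions
(default 1000) draws, without replacement, as many non-DEGs (padj > 0.01) as
there are DEGs, runs the identical sort/bin/fit procedure, and records its R².
With r the number of null repetitions whose R² strictly exceeds the observed
one, the p-value is the add-one estimate

    p = (r + 1) / (n + 1),

which is never zero and is exact for the permutation null. The draw sequence
is fully determined by a seed recorded in the output. Under a generator with
no methylation–expression coupling the p-values are uniform (checked by
Kolmogorov–Smirnov distance over 200 seeded datasets); under a planted linear
coupling (slope 5 log2 units per unit delta, noise SD 0.3, 200 DEGs against a
2000-gene pool) the test attains p ≤ 0.01 in ≥ 95% of seeds.

## Marker-based two-population deconvolution

Bulk RNA-seq of the modelled tissue mixes a dominant population (~95%) with a
minor one (~5%). Each sample's abundance of a population is proxied by a
**reference signal**: the mean normalized expression of that population's
marker genes in the sample. Counts are normalized by scaling each sample to a
fixed total (CPM by default). No log transform is applied before modelling:
the models below are linear in population contributions, and a log transform
breaks mixture additivity — in generator experiments it costs roughly thirty
points of recall on planted effects. A log option remains available for other
uses of the normalized matrix.

For each gene and each population a separate univariate model is fit across
samples:

    expression ~ intercept + signal_pop + signal_pop × group

with group = 1 for knockout samples. One model per population is a structural
necessity, not a stylistic choice: with two populations the fractions sum to
one, so the two reference signals plus a constant are exactly collinear and a
joint model cannot identify the intercept. In the per-population model the
intercept estimates the expression *not* attributable to the modelled
population, which is precisely the noise quantity the first filter screens.

Two filtering rounds select population-specific differential genes, all
inequalities strict:

- round 1 (model quality / noise): R² > 0.6, |intercept| / mean expression
  < 0.5, intercept p > 0.1;
- round 2 (significance): the population's interaction p < 0.05 (two-sided).

Round 2 implies round 1 by construction. Candidate population-specific DEGs
are the union of per-population round-2 pass lists. Consistency of a selected
set with an independent bulk DEG list is scored with a hypergeometric overlap
test using the **exclusive** upper tail, P(X > k) — the survival function at
the observed overlap k — so the maximal possible overlap scores exactly 0.

One calibration property deserves a note: the interaction p-values are
uniform under the null across all fitted genes, but *conditional on passing
round 1* the fraction below 0.05 exceeds 5%, because a gene can clear the R²
bar partly through variance absorbed by its interaction term. That selection
effect is intrinsic to the two-round procedure (it would affect any
implementation) and is documented in the test suite rather than "corrected".

## The synthetic-data generator

The generator reproduces the statistical structure the analysis assumes, so
the whole pipeline runs and is testable with no external data. Its defaults
describe the emulated study conditions; each is a single a-priori choice.

**Methylation.** Wild-type gene-body levels are Beta-distributed (bounded
support is why: mCH mean 0.04, concentration 30; mCG mean 0.75, concentration
20). The writer knockout scales mCH by per-gene loss fractions jittered around
90% (SD 10% relative, clipped to [0, 1]) and mCG likewise around 10%; the
reader knockout leaves methylation unchanged. The mCG delta is a linear blend
of the standardized mCH delta with independent noise, so the two deltas have
Pearson correlation 0.5 by construction (the clipping needed to keep levels in
[0, wild type] is rare and moves the realized correlation negligibly).
Because the loss jitter is clipped at a loss of 100%, the realized global mCH
loss is ~89%, not exactly 90. Optionally, levels are realized as per-site
binomial draws: ~30 CH and ~10 CG sites per gene, coverage 1 + Poisson(19),
plus a 2000-site spike contig at the 1% non-conversion rate. Site-level data
aggregated back through the level operations recover the planted gene levels
within binomial error.

**Expression.** Category counts are exact rounded fractions of the gene count
— defaults sized to 86 common, 636 writer-only and 127 reader-only DEGs per
5000 genes, mirroring the emulated overlap structure (213 and 722 DEGs with an
849-gene union). Affected genes receive log2fc = 5 × (mCH delta) + N(0, 0.3);
common genes receive the *same* draw in both models (equal dependence on
writer and reader). Adjusted p-values are generated on the correct side of the
0.01 threshold rather than computed — DE fitting is out of scope, and the
pipeline consumes exactly these columns. Low total counts (below the count
filter) are planted only on non-DEG genes so planted category counts survive
filtering and are exactly recoverable.

**Mixture.** Twelve samples (six control, six knockout) mix two populations at
95%/5% with per-sample Gaussian jitter (SD 3 percentage points — plausible
between-animal variability of sorted-tissue composition, and the leverage the
intercept filter needs). Ten marker genes per population are expressed
essentially only in their population; ten planted population-specific DEGs per
population change 2^1.5-fold (random sign) in the knockout group only, and are
strongly enriched in their own population (mean 300 vs 0.5 in the other), as
genuinely population-specific genes are. Counts are gamma-Poisson with
dispersion 0.001 around deep-library means (a 10× depth factor); with these
conditions the two-round filter recovers a majority of planted effects at
precision far above the 5% base rate.

**What the generator does not emulate:** genomic correlation structure
(domains, CpG islands), read-level sequences, mapping artifacts, library-size
imbalance, more than two populations, and real biological between-replicate
variance components. Passing tests therefore establish the correctness and
calibration of the *procedures*, not the reproduction of any real-data value:
the study's global methylation bar heights, its DEG lists, its observed trend
R² values and its 38 candidate minor-population genes all require the original
sequencing data and are deliberately not asserted anywhere.

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.default_rng` seeded explicitly;
  identical seeds give byte-identical emitted files and identical permutation
  null sequences.
- Sorting ties in the trend module break lexicographically by gene id.
- The permutation count r uses strict inequality (null R² > observed), and
  sampling is without replacement within a repetition, independent across
  repetitions.
- Degenerate inputs are defined, not guessed: zero-coverage levels are NaN
  flags; zero-variance correlation is NaN; constant-y trend fits give R² = 0;
  constant-x fits raise; a null draw with constant deltas contributes R² = 0.
- The command-line pipeline serializes its full configuration and a
  config hash into every run's manifest, and logs the gene count dropped at
  every filter step (count filter, missing padj, missing methylation), so the
  N entering each stage is always reconstructible.

## Known limitations

- The long-gene threshold (100 kb) is a configurable default; the analysis it
  mirrors cites an external standard whose exact value is not restated here.
- OLS p-values in the deconvolution module assume homoscedastic Gaussian
  residuals; count noise is mildly heteroscedastic, which is visible only as a
  slight thickening of the extreme tail of null interaction p-values.
- The permutation test's p granularity is 1/(n + 1); with the default 1000
  repetitions the smallest attainable p is ~0.001.
- The deconvolution filter's operating characteristics degrade quickly as
  composition variability shrinks or library noise grows; the intercept
  criteria are then the binding constraint, as they are in real data.
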