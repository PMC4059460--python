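# Methods

## Overview and assumptions

`derseg` detects differentially expressed regions (DERs) from per-base
RNA-seq coverage in three stages — per-base statistics, genome
segmentation, region-level significance — with annotation kept strictly
downstream. The method assumes:

- coverage has been computed upstream from aligned reads (junction reads
  treated like genomic reads); the package starts from bedGraph tracks;
- the log2-transformed coverage at each base is adequately described by a
  linear model, shared across bases, with group effects and optional
  confounders;
- differential expression is piecewise-constant along the genome: the
  per-base statistic track is a noisy step function, not a smooth curve,
  so segmentation (not smoothing) is the right aggregation;
- most of the genome is unexpressed, and expressed bases are mostly
  non-differential, so a three-state chain with high self-retention is an
  appropriate prior on the hidden structure.

## Per-base statistics

Each row of the base × sample coverage matrix is fitted by OLS under one
shared design `[1 | group | confounders | log2 library size]`. Because
the design is common to all bases, the genome-wide fit is two matrix
products with a single pseudo-inverse; residual degrees of freedom are
`d = n − rank(X)` everywhere.

Variance moderation follows the standard empirical-Bayes scheme for
small-sample expression data: sample variances are modelled as scaled
chi-squared draws around a scaled-inverse-chi-squared prior `(d0, s0²)`,
estimated by matching the mean and variance of `log s²` at expressed
bases (prior df by trigamma inversion, Newton iterations to 1e-10). When
the observed spread of log variances does not exceed chi-squared sampling
noise the prior df is infinite and the posterior variance is the pooled
mean variance. The moderated t is `β̂ / sqrt(s̃² v)` with
`s̃² = (d0 s0² + d s²)/(d0 + d)` and `v` the contrast entry of
`(X'X)⁻¹`. With more than two groups a moderated F on the group
coefficient block replaces the t; the documented and tested path is two
groups.

Bases whose across-sample average raw coverage falls below the expression
cutoff `c` are assigned statistic exactly 0 and flagged unexpressed. This
keeps the track contiguous and places those bases at the mode of the
no-expression state's emission.

### Library size

The recommended depth covariate is a robust per-sample coverage summary
("median" over all analyzed bases by default; "q75" uses the 75th
percentile with linear interpolation between order statistics — the
percentile convention is fixed because different conventions silently
change the covariate). On sparse spans (a short chromosome that is mostly
empty) these summaries degenerate to 0 for every sample; the model layer
then falls back to the median over covered bases, which stays positive
and — unlike a total-count summary — is robust to composition bias when a
minority of regions is strongly differential. A sample whose summary is
still 0 (an entirely empty column) receives the smallest positive summary
across samples, with a warning, so permutation re-runs never abort; a
constant depth column is dropped from the design as uninformative.

## Segmentation

Hidden states: 0 = unexpressed, 1 = expressed non-differential,
2 = differential. Emissions are normal; state 0 is `N(0, δ)` with δ a
tiny fixed variance. The prior `π0` is the fraction of bases below the
expression cutoff; the mixture weights fitted at expressed bases, scaled
by `1 − π0`, give the priors of states 1–2. The transition matrix is
fixed, not estimated.

### The two-groups mixture and its guardrails

States 1–2 emissions come from a two-component normal mixture fitted by
EM to the statistics at expressed bases. Three design choices matter, all
adopted after the naive fit demonstrably failed on legitimate inputs:

1. **The fit runs on the magnitude track `|t|`** (configurable,
   `segment_on="signed"` restores the raw track). Differential signal
   runs in both directions, and a single normal cannot represent two
   symmetric modes: on a signed track with clear up- and down-regulated
   regions, EM isolates one tail as its own component and lumps the other
   tail with the null, losing half the true regions. Folding collapses
   the two modes into one, giving the mixture a single, stable basin.
   The >2-group path runs on a non-negative F track for the same reason.
   Region direction is recovered afterwards from the signed statistics.

2. **Component labels are assigned by second moment about zero**: the
   null is the component with smaller `μ² + σ²`. Ordering by variance
   alone ("null = narrower") misassigns the labels whenever the
   differential blob is as tight as the null blob; concentration near
   zero is what actually characterises a null t-track. In ordinary
   regimes the two orderings agree.

3. **An empirical-null clamp**: the null component must satisfy
   `|μ1| ≤ 2` and `σ1² ≤ 9`. A moderated t under the null has mean 0 and
   variance near 1; the bounds are deliberately generous to allow
   correlation and overdispersion inflation. The clamp is inactive on
   ordinary tracks. It matters on a group-specific chromosome (the
   sex-chromosome contrast), where essentially *every* expressed base is
   differential: there is no null mass for EM to anchor to, and without
   the clamp both components drift onto the signal and nothing is called.

EM details: initialization at the median / 1.4826·MAD for the null and at
the mean of the 5% most extreme points (variance matched to their
spread, at least 4× the null) for the alternative; weights start at
0.95/0.05; component variances floored at 1e-8 and weights at 1e-4;
convergence when the log-likelihood changes by less than 1e-8 relative
(the tolerance is deliberately tight — a looser criterion stops while
component means are still drifting); maximum 500 iterations, with a
warning and `converged=False` beyond that.

### Decoding and regions

Decoding is the Viterbi path (joint MAP), matching the goal of a single
most likely segmentation; ties break toward the lower-numbered
(more conservative) state. The decoded path is collapsed into maximal
same-state runs, which partition the analyzed span; state-2 runs are the
candidate DERs.

The region score is the **sum** of base statistics over the run,
`s̄_r = Σ s(l)` (default; `stat_mode="mean"` available). The sum rewards
sustained signal: under the mean, a single-base noise spike with |t| ≈ 4
outranks most genuine null regions in the permutation pool and becomes a
false positive, while under the sum a spike scores ~4 against thousands
for a real region.

## Significance

Group labels are permuted uniformly with replacement `B` times; each
permutation re-runs the entire identification pass (model refit, variance
moderation, mixture re-estimation, decoding) so the observed and null
pipelines are exchangeable. `π0` is not recomputed — coverage is
invariant under label permutation. A permutation that happens to
reproduce the observed labeling is kept; excluding it would bias the
null. Null state-2 region scores are pooled across permutations.

The default p-value is two-sided with a pseudocount,
`p = (1 + #{|s̄⁰| ≥ |s̄_r|}) / (1 + pool size)`, which is strictly
positive and catches both directions; an "exact" mode (one-sided
strict inequality, no pseudocount) is provided for fidelity to the
classical formula. Multiple testing uses Benjamini–Hochberg
(statsmodels), reported as `q`.

With small samples the number of distinct labelings is limited (252 at
n = 5+5), so occasionally a permutation reproduces the true split and
contributes full-strength copies of the observed scores to the pool;
this inflates p-values by roughly `rank/B` and is an inherent property of
permutation inference at this sample size, mitigated by a large pool.

## Annotation

Regions are classified exonic (≥1 base of exon overlap), intronic (no
exon overlap but inside a gene span — the min-start/max-end hull of the
gene's exons), or intergenic. Strand is ignored for overlap (coverage is
unstranded) and carried for reporting. GTF input (1-based inclusive) is
converted to the package-wide 0-based half-open convention on read; BED
is native. An exon is called differentially expressed when a region with
`q < 0.05` covers at least 20% of it (both thresholds configurable —
there is no canonical criterion); genes are the distinct gene ids of
called exons.

## Default parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `offset` | 0.5 | pseudo-count before log2; keeps zeros finite |
| `cutoff_c` | 5 | average-coverage expression threshold (reads/base) |
| `delta` | 1e-4 | state-0 emission variance; pins unexpressed bases |
| `retain_prob` | 0.999 | transition self-retention; expected segments ~1 kb, gene-scale |
| `B` | 50 | label permutations for the null pool |
| `pvalue_mode` | pseudocount, two-sided | strictly positive p, both directions |
| `stat_mode` | sum | sustained-signal region score |
| `segment_on` | magnitude | fold the t-track for segmentation |
| `library_method` | median | per-sample depth summary |
| `q_threshold`, `exon_frac_threshold` | 0.05, 0.2 | annotation rollup |

## The simulator

The generator emulates the data the model assumes: a mostly-empty
chromosome carrying non-overlapping expressed regions; per-base counts
negative-binomial with mean `μ · factor_i · 2^(FC · group_i)` and
variance `μ + φμ²` (φ = 0 gives Poisson); log-normal per-sample depth
factors (sd 0.15 — realistic library-size variation); a fixed 20-base
linear ramp at region edges so boundaries blur the way read pileups do.
Infinite fold changes plant group-specific regions (zero mean in one
group). It writes standard bedGraph plus a sample sheet, so end-to-end
runs exercise file I/O.

It does **not** emulate read-level structure: junctions and splice
isoforms, mapability artifacts, GC-content or fragment-length biases, or
correlated noise along the genome (counts are independent across bases
given the mean). Passing tests therefore demonstrate correct behavior of
the statistical machinery under its own assumptions, not robustness to
alignment artifacts.

Study conditions used by the canned scenarios (and
`scripts/acceptance.py`): planted recovery — 100 kb genome, 30 expressed
500 bp regions at μ = 30, 10 of them DE at |log2FC| = 2 (5 up, 5 down),
φ = 0.1, n = 5+5, B = 50; null calibration — 20 kb genome with 8
expressed non-DE regions, 10 replicates, B = 20; group-specific — 50 kb
genome, 8 regions present only in one group, with a 3-vs-2 within-group
re-split as negative control. These sizes keep a full run under a minute
per scenario on one CPU while leaving hundreds of null regions in each
pool. All random streams derive from one master seed via
`numpy.random.SeedSequence.spawn`.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open everywhere internally; GTF is
  converted on read.
- Viterbi runs in log space; non-finite statistics raise with the
  offending position named.
- All-zero coverage (or fewer than 50 expressed-base statistics) yields
  one state-0 region and no candidates rather than an error, so
  degenerate permutation resamples cannot abort a run.
- An empty null pool in pseudocount mode returns p = 1 with a warning;
  exact mode raises.
- Statistic tracks round-trip bit-exactly through their TSV form
  (`%.17g` on write, `float_precision="round_trip"` on read).
- With fixed inputs and seed the whole pipeline is deterministic;
  re-running a saved configuration reproduces the output tables byte for
  byte.

## Known limitations

- Significance requires the simple two-group design; confounders are
  supported in the model fit, but the permutation scheme does not extend
  to them (a bootstrap would be needed).
- One normal for state 2 means adjacent up- and down-regulated regions
  separated by less than the transition penalty can merge into one
  "mixed" region.
- Permutation resolution is bounded by the number of distinct labelings;
  at n = 5+5 the smallest achievable single-test p is limited, and exact
  re-draws of the true split add conservative ties (see above).
- Regions are decoded per chromosome independently; there is no
  cross-chromosome pooling of the mixture or the variance prior.
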