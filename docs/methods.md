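# Methods

## Intron-ratio quantification

Each retained-intron event carries inclusion-supporting reads `I`,
skipping-junction reads `S`, and effective form lengths `LI >= LS >= 1`
(the number of alignable positions in the intron-retaining and spliced
forms; with bare count tables both default to 1 and psi reduces to
`I/(I+S)`, logged as a warning). The intron ratio is the length-adjusted
inclusion level `psi = (I/LI) / (I/LI + S/LS)`.

The coverage rule is applied **per cell** with a strict inequality: a
(event, sample) cell yields a psi estimate only when `I + S > coverage_min`
(default 10). Whether "coverage" should mean a per-sample minimum or a
cross-sample mean was an open choice; the per-cell rule is the stricter,
replicate-aware reading and is configurable. An event enters a two-group
comparison only when at least 2 samples per group pass — the minimum for
any replicate-aware test. Events missing everywhere are dropped.

Ordination (PCA via SVD of the column-centered matrix; classical MDS /
principal coordinates of Euclidean distances) drops events with any
missing psi rather than imputing: imputation would manufacture the very
between-group structure the plots are meant to reveal.

## Differential intron retention

Counts are modeled per sample as beta-binomial,
`I ~ BetaBin(n, theta, rho)` with `n = I + S`, where `theta` is the image
of psi under the length adjustment (`theta = psi LI / (psi LI + (1-psi) LS)`,
a monotone bijection, so maximizing over theta is maximizing over psi) and
`rho` is the intra-class correlation (`alpha = theta(1-rho)/rho`,
`beta = (1-theta)(1-rho)/rho`); `rho -> 0` recovers the binomial. The test
is a likelihood-ratio test of

- H0: one common theta, one common rho over both groups;
- H1: group-specific theta, shared rho;

with `2(l1 - l0)` referred to chi-square (1 df). `rho` is profiled out by
maximum likelihood in each hypothesis, floored at 1e-6 to avoid boundary
failures; the inner theta maximization uses three passes of 64-point grid
refinement (theta error ~2e-5, negligible against the chi-square scale),
the outer rho maximization bounded Brent on [1e-6, 0.95]. The statistic
agrees with brute-force grid maximization of the same likelihood (psi step
1e-4) to better than 1e-3.

This is a point-null test with a post-hoc effect filter, not an
interval-null ("|delta psi| > c") likelihood test: an event is called when
`(p < 0.05 or BH-FDR < 0.1)` **and** `|delta psi| > 0.05`, where delta psi
is the difference of group means of per-sample psi (second group minus
first; positive = IncIR). The FDR procedure is Benjamini–Hochberg. Output
rows are sorted by p with ties broken by |delta psi| descending then
event id, so results are deterministic.

Gene-level roll-up: a gene with only IncIR events is IncIR, only DecIR is
DecIR, both is Mixed; genes with no significant event are excluded. Both
event-level ("locus") and gene-level counts are exposed, since marker
counting can reasonably be done at either resolution.

## Differential expression

TMM normalization follows the canonical recipe: the reference sample is
the one whose 0.75-quantile of library-size-scaled counts is closest to
the mean of those quantiles; per sample, genes zero in either member of
the pair are removed, `M = log2` ratio and `A =` mean log2 abundance are
doubly trimmed (30% of M each tail, 5% of A each tail), and the
inverse-variance-weighted mean of the surviving M gives the log2 factor.
Factors are rescaled to geometric mean 1. Factors are computed **relative
to the stated library sizes**: with the default column-sum sizes a pure
depth change correctly yields a factor near 1 (the depth is already in the
library size), while against equal nominal sizes the factor absorbs the
scale itself. One test cross-checks the factors against an independent
reference implementation of the same estimator.

Expression testing is a per-gene negative-binomial likelihood-ratio test
of equal means with `log(library size x TMM factor)` offsets, fitted by
Fisher scoring. A single **common** dispersion is estimated across genes
by maximizing the Cox–Reid adjusted profile likelihood on a log-spaced
grid (25 points, 1e-4 to ~5) with parabolic refinement; common dispersion
is the minimal defensible model here and keeps the test desk-verifiable.
Genes need counts-per-million above 1 in at least min(group size) samples
to be tested. Calls require fold change strictly above 1.2
(`log2FC > log2 1.2 = 0.263`) and `(p < 0.05 or FDR < 0.1)`.

## Recovery classification

Recovery is defined at the locus level across three ordered groups
(control, pre-treatment, post-treatment): reverse-V = IncIR in
(control vs pre) and DecIR in (pre vs post); V = the converse. The
classification is the Venn intersection of two independent two-group runs
sharing the event universe. Note the patterns are invariant under
reversing the timeline (an up-then-down trajectory read backwards is still
up-then-down); what swaps reverse-V and V is flipping the case/control
direction of both legs. Each recovered trajectory is additionally tested
by one-way ANOVA on per-sample psi, with Tukey HSD pairwise comparisons
reported when the omnibus p < 0.05 (standard gatekeeping).

## Network link enrichment

The interactome is an undirected, score-filtered graph (confidence
`>= 0.7`, inclusive; STRING-dialect 0–1000 integer scores are auto-detected
and divided by 1000; self-loops dropped; duplicate pairs keep the highest
score). The observed statistic is the total number of distinct edges from
query genes to target-set genes (a query gene inside the target set does
not count itself). The null redraws the query as K uniform random sets of
equal size from the network nodes outside the target set, and
`p = (#{null >= observed} + 1) / (K + 1)` (default K = 999). A
normal-approximation z-test against the null mean/sd is available for
K >= 30. A five-set comparison cannot by counting produce p-values below
1/6, so the permutation test with large K is the primary statistic here; a
previously reported parametric-looking threshold from a 5-set design is
deliberately not reproduced.

## Overlap statistics

Fold enrichment of a two-set overlap is `k N / (n_a n_b)` over a stated
background universe of N genes — 4,546 by default for IR-gene comparisons
(the annotated-intron gene universe) and 22,000 for DEG comparisons, both
overrideable and mandatory at the CLI. Significance defaults to the
one-sided (enrichment) upper-tail hypergeometric `P(X >= k)`; a two-sided
Fisher option exists. Three-set comparisons report the 7 exclusive Venn
regions plus derived pairwise/triple overlaps and per-set shared-with-
others counts. Matching is by exact, case-sensitive gene symbol; alias
resolution is out of scope and a known caveat.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
the study's design shape (6 control, 8 case, optionally 8 post-treatment
paired with the cases):

- **IR counts**: junction depth `n ~ NB(mean 50, dispersion 0.3)` per cell;
  inclusion `I ~ BetaBin(n, theta, rho)` with default `rho = 0.01` (the
  within-group overdispersion of real replicates is not identifiable from
  published summaries; 0.01 is a mild, plausible level and is exposed in
  the scenario). Baseline psi is Beta(2, 6) (mostly low-retention introns,
  mean ~0.25). Planted effects add/subtract `delta_psi` in the second
  group, clamped to [0.01, 0.99]; any third group reverts to baseline, so
  planted increases trace reverse-V and decreases V trajectories. An
  optional logit-normal per-subject random effect (default sd 0) couples
  the paired second/third arms.
- **Expression**: gene base means lognormal (median 100, log-sd 1); counts
  NB with gene-shared dispersion and per-sample library-size multipliers;
  planted DE genes split evenly up/down at the stated log2FC.
- **Interactome**: Erdős–Rényi background plus independent excess
  query–target edges; scores uniform on [0.7, 1] so the default cutoff
  retains all.
- **Gene sets**: disjoint slices of a shuffled universe realize requested
  Venn region counts exactly.

Everything is driven by one `numpy` Generator per call: identical seeds
give bit-identical outputs.

What passing tests on these data do **not** show: real junction counts
have correlated events within genes, GC/length biases, mapping artifacts
and non-beta-binomial outliers; real interactomes are scale-free, not
Erdős–Rényi; and planted effects are homogeneous in size. The synthetic
results certify the statistics' calibration and power under their assumed
models, not robustness to those violations.

## Problem sizes and numerical choices

The calibration suite uses 2,000 events x 3 seeds for the null
false-positive rate of the IR test (expected p<0.05 rate close to nominal,
band [0.03, 0.07] — the chi-square reference is mildly anticonservative at
n = 16 with estimated rho, measured ~0.06), 400 events (200 planted) for
power and delta-psi bias, 300 events for recovery, 50 replicate graphs at
K = 199 for network calibration, and 2,000 genes for expression
calibration. These sizes put Monte-Carlo error comfortably inside the
asserted bands while keeping a full run in minutes on one CPU.

Degenerate inputs: zero-coverage cells are missing, not zero; events with
fewer than 2 passing samples per group are skipped with a logged reason;
all-zero genes and samples are rejected or excluded explicitly; empty
p-value lists adjust to empty; LRT statistics are clamped at 0 before the
chi-square tail. Ties are always broken deterministically (p, then
|effect|, then identifier; link counts by count then symbol).

## Known limitations

- The IR test assumes a shared overdispersion across groups and events are
  tested independently; no information sharing across events.
- Common (not tagwise/shrunken) NB dispersion; no covariates in either
  model.
- Only retained-intron events; no other splicing event classes.
- Gene-symbol matching for overlaps is exact; no alias resolution.
- No network visualization; outputs are tables for external viewers.
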