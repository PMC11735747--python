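# Methods

This note documents the modelling and numerical choices behind `neonet`,
in the order the pipeline runs.

## Cohort model and quality control

A cohort is a table of scan sessions with gestational age at birth (GA,
weeks), postmenstrual age at scan (PMA, weeks), sex, mean DVARS and a
radiology score (1–5).  Birth-age groups follow the WHO preterm and ACOG
at-term strata, realised as half-open intervals on continuous weeks so
the seven labels partition the entire range [20, 45]: [20, 28) extremely
preterm, [28, 32) very preterm, [32, 37) late preterm, [37, 39) early
term, [39, 41) full term, [41, 42) late term, [42, 45] postterm.
Half-open intervals make the assignment total and unambiguous for
fractional weeks; all group means of a typical cohort land in the right
stratum.

Quality control excludes scans with radiology score > 2 and scans whose
mean DVARS exceeds the cohort mean by more than two standard deviations.
The DVARS mean and SD are computed **once**, over all score-eligible
scans, not re-estimated iteratively: the rule is a single-pass outlier
screen, and a recursive version would keep trimming any smooth-tailed
motion distribution.  With zero DVARS spread the motion rule excludes
nothing.

The term-equivalent (cross-sectional) sample keeps scans with PMA in the
closed window [37, 44] weeks, one per subject; when a subject has several
in-window scans the latest is used (an `earliest` switch exists).
Longitudinal pairs take each subject's earliest scan before 37 weeks and
earliest scan inside the window; subjects lacking either are dropped.

## Connectome construction and thresholding

Connectivity is the Pearson correlation between region time series
(diagonal forced to zero; constant regions are an error naming the
region).  Proportional thresholding ranks the R(R−1)/2 upper-triangle
values by **signed** correlation, descending, and keeps the top
m(κ) = round-half-up(κ·R(R−1)/2); for R = 90 and κ = 0.30 that is 1202
edges.  Negative correlations are never retained, because the
weight-to-length map used downstream requires positive weights; if fewer
than m(κ) positive values exist only those are kept, with a warning.
Ranking by |r| is available behind `rank_by="absolute"`.  Ties at the
cutoff break by lexicographic (i, j) index so the output is a pure
function of the input.  Because all costs share one ranking, edge sets
are nested along the grid.

## Graph metrics

Strength is the row sum of weights.  Clustering defaults to the binary
triangle-density form computed on the thresholded adjacency — the
degree/triangle formula — with the Onnela geometric-mean weighted
variant behind `mode="weighted"`; both are validated against exhaustive
triple enumeration.  Shortest paths use Dijkstra on lengths
f(w) = 1/w (option: −ln w for weights in (0, 1]).  The characteristic
path length averages finite ordered pairs only, and the connected
fraction is reported alongside so sparse-cost disconnection is visible
rather than silently absorbed; a fully disconnected graph is an error.
Global efficiency averages 1/d over ordered pairs with unreachable pairs
contributing zero, which keeps it defined at every cost.  Local
efficiency applies global efficiency to each node's neighbour-induced
subgraph with weights preserved; nodes with fewer than two neighbours
score zero.

## Group inference

The group test is a one-way ANCOVA: an OLS model of the metric on group
dummies plus PMA at scan, sex (binary indicator) and mean DVARS, with
the group effect tested by Type-II F (full model vs the model with the
dummies dropped).  Type II is the conventional choice for a single
factor with covariates and is invariant to covariate order.  Groups with
a single scan are tolerated in the fit (their dummy absorbs the point)
but excluded from post hocs.  An exactly-fitted response (zero residual
variance up to floating-point noise) reports F = 0, p = 1 rather than a
0/0.

Post hocs are Tukey–Kramer on covariate-adjusted means: differences of
group coefficients with variances from the model covariance, referred to
the studentized-range distribution with k groups and the residual df.
With two groups this reduces exactly to the two-sided t test (q = t√2).

FDR control uses the Benjamini–Hochberg step-up.  The cost-wise grid
(10 costs × 4 metrics) is corrected as one family of 40 by default, with
a per-metric option, since the ambiguity between the two conventions is
real; nodal maps correct across the 90 regions per metric and report the
smallest rejected F — the "FDR line" a regional F-map plot would draw.
Whether the extreme groups (extremely preterm, postterm) enter the
cross-sectional ANCOVA is a config flag (`include_extreme_groups`,
default on): excluding tiny groups is defensible, but the default keeps
the test on all seven strata.

## Developmental trajectories

Three fixed-effect forms are fitted per metric: linear (1, age),
quadratic (1, age−ā, (age−ā)²; centring reduces collinearity, so the
age coefficients are on the centred scale) and logarithmic
(1, ln(age − 20)).  The logarithmic form is anchored 20 weeks
post-conception: over the 23–44-week scan window ln(age) itself is
almost perfectly linear (curvature ~1/age²), which would make the log
model statistically indistinguishable from the linear one; anchoring
restores the steep-early/flat-late shape that motivates a log model of
early brain maturation.  The linear and quadratic model spaces are
unchanged by any such shift.

All models carry a subject random intercept and (by default) a sex
indicator, and are estimated by full maximum likelihood — not REML —
because AIC comparisons across different fixed-effect structures are
only valid under ML.  AIC = 2k − 2·logLik with k = fixed coefficients +
2 variance parameters.  When no subject has a repeated scan the random
intercept is unidentifiable and the fit falls back to OLS with
k = fixed + 1, logged.  Exact fits (zero residual variance) are treated
as tied at the top, so selection falls through to the parameter-count
rule.  Selection is argmin AIC, ties to fewer parameters, then to the
linear form.  Age-term significance is a joint Wald F on the age
coefficients with residual-df denominator (an approximation in the
mixed case, noted in the output).  Regional trajectory maps fit all
three forms per region × metric, select by AIC, and BH-correct the
winning form's age p across regions within each metric.

## Longitudinal comparisons

Differences are second scan minus first.  Shapiro–Wilk on the
differences at α = 0.05 gates between the paired t test (effect size
Cohen's d = mean/SD of differences) and the Wilcoxon signed-rank test
(effect size r = |Z|/√n).  Zeros are dropped before ranking
(signed-rank convention) and n in the r denominator counts the pairs
that remain; the reported statistic is the positive-rank sum V, with p
from the normal approximation without continuity correction.  Fewer
than three pairs cannot be tested for normality and route to Wilcoxon;
constant nonzero differences with the t test give an infinite d, which
is reported as such rather than masked.

## The synthetic cohort generator

The generator emulates the *sufficient statistics* of a neonatal
rs-fMRI cohort, not images.  Birth ages come from truncated normals
matching the study cohort (preterm mean 31.96, SD 3.92, range [23, 37);
term mean 40.07, SD 1.40, range [37, 42.5]); term subjects are scanned
a gamma-distributed 1.5 weeks after birth, preterm subjects at
term-equivalent age, and the longitudinal subset additionally shortly
after birth.  Default cohort sizes (332 term, 115 preterm, 26
longitudinal) mirror that composition; tests use smaller cohorts.

Each scan receives one maturation scalar μ ∈ (0.01, 0.99) from a law in
PMA — logarithmic by default, μ = −0.10 + 0.22·ln(PMA − 20), minus a
prematurity deficit 0.006·max(0, 37 − GA) per week born before term,
plus 0.01 for male scans.  Ground-truth connectivity is the simplest
structure that makes all four metrics respond monotonically to μ: a
block-constant correlation matrix (6 modules of 15 regions) with
within-module correlation μ and between-module correlation μ − 0.25
(floored at 0), ridge-blended to positive definiteness if needed.
Time series are multivariate-normal draws from that matrix plus white
noise (SD 0.3), which attenuates all correlations by a common factor
without reordering them.  DVARS is an independent log-normal; it is a
covariate, not a noise driver.  The defaults were chosen once so that a
balanced 30-per-group cohort at 300 timepoints reproduces the expected
qualitative pattern (strength, clustering, efficiency rising with
birth-age group; path length falling) with comfortable margins.

Trajectory-recovery experiments draw the response directly from a law
(plus subject intercept SD 0.03 and residual SD 0.02) instead of
round-tripping through time series: the extra layer only adds noise
without changing what is being tested.  Two deliberate design choices
here: birth ages are drawn uniformly over the preterm range, because
the three curve shapes only separate when early PMAs are actually
observed; and the generating laws for these experiments carry no
prematurity deficit, because a subject-level offset correlated with
scan age sits outside the random-intercept family the fitted models
assume and would masquerade as curvature.  The per-form default laws
(linear 0.25 + 0.018x; quadratic 0.15 + 0.042x − 0.0008x²;
logarithmic −0.10 + 0.22·ln x, with x = PMA − 20) stay inside (0.01,
0.99) over the design — clipping would distort the curve family — and
the quadratic's vertex lies beyond the oldest scan so every law is
increasing in age.

What the generator does **not** emulate: hemodynamics, autocorrelated
fMRI spectra, motion artifacts coupled to DVARS, spatially realistic
module structure, or negative correlations.  Passing tests therefore
demonstrate that the *statistics* behave correctly under the assumed
data-generating structure, not that the pipeline is robust to every
property of real fMRI.

## Problem sizes and determinism

The test suite and the acceptance script use scaled-down but fully
powered designs: 300-timepoint scans, 30 subjects per group for
cross-sectional checks, 15 per preterm group for longitudinal checks,
100 replicates for recovery/calibration experiments, and brute-force
oracles on graphs of at most 7 nodes (where exhaustive simple-path
enumeration is feasible).  All randomness flows from explicit integer
seeds through `numpy.random.SeedSequence` spawning; pipeline outputs are
written with a fixed float format, so a rerun with the same config and
seed is byte-identical.

## Known limitations

- The Wald F for age terms in mixed fits uses a residual-df
  denominator; with few subjects a Satterthwaite or Kenward–Roger
  correction would be more accurate.
- AIC-based form selection keeps an irreducible ≈ 16% chance of
  preferring the quadratic over a true linear law (the classic
  one-extra-parameter overfit rate); recovery rates above ~84% are not
  attainable for that direction by design.
- Local efficiency at dense costs is the runtime bottleneck
  (one Dijkstra per node per graph); nodal metrics are therefore
  computed at the headline cost only in the default pipeline.
- The quality filter is single-pass by design and is not exactly
  idempotent on smooth-tailed motion distributions (re-running after
  trimming shrinks the SD and can exclude borderline scans).
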