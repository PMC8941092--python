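# Methods

This note records the models and procedures implemented in `reburnscape`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Burn histories from severity rasters

Annual integer severity grids are reclassified to burned/unburned with a
threshold of 2: severities below 2 are unburned, all others burned, and
nodata is never a burn. This literal threshold rule is the default;
severity classes such as 5 (increased greenness) and 6 (non-mapping) in
MTBS-style products arguably should not count as burns, so
`classify_burned(..., unburned_classes=(5, 6))` exposes that choice without
changing the default. Reclassification is monotone in the threshold and
idempotent on its own output (property-tested).

Sample points sit at the centers of a square lattice anchored at the
extent's lower-left corner; only cells that fit entirely inside the
(closed) extent yield a point, so a 10 km × 10 km extent at 2 km spacing
gives exactly 25 points. Coordinates are planar map units throughout — a
projected CRS is assumed and no geodesic arithmetic is attempted. Points on
the far raster edge are assigned to the last cell (closed extent). Raster
round trips go through GeoTIFF ModelPixelScale/ModelTiepoint/GDAL-nodata
tags written and read with tifffile.

## Interval statistics

Intervals are defined between *successive* burns only: a three-burn point
contributes two intervals, not three pairwise combinations. The interval
ECDF is truncated at a configurable maximum (default 16 years) because a
finite record observes long intervals with shrinking probability; the
truncated count is carried in the result metadata and no formal censoring
correction is applied — the truncation is the honest statement of the
bias. Tail fractions (share of intervals ≥ 5, ≥ 10 years) are computed over
the untruncated interval set. Burn-count tables use burned points as the
denominator for the single/two/three-plus split, which therefore sums to
100%, and all points as the denominator for overall burned percentage.

## The randomized-placement null model

The self-regulation test conditions on each focal year's observed margins:
the number of points burned in the W-year lookback window (n1) and in the
focal year (n2). Under the null, both sets are placed uniformly at random
(without replacement) over the N lattice points, making the overlap count
exactly Hypergeometric(N, n1, n2); the default sampler draws the overlap
directly from that distribution (mathematically identical to the literal
two-subset draw, which is retained as `method="subsets"` and checked
against it distributionally). The expected null proportion is n1/N — used
as the analytic oracle in tests, never as the reported value, which always
comes from the Monte Carlo (default 10,000 replicates; quartiles by the
nearest-rank rule).

The reburn proportion's denominator is the focal-year burned count, which
makes observed and null directly comparable year by year; `union` and
`all_burned` denominators are available as configuration. Focal years whose
window would extend before the record start are excluded rather than
computed with a truncated window, since such years would be biased low by
unobservable earlier fires. An interval-band variant places the window
[focal − hi, focal − lo − 1] to isolate, e.g., only 10–20-year intervals;
with lo = 0 it reduces exactly to the plain window series.

A calibration subtlety governs when the point-level null is a fair
reference for the observed statistic: fires are spatially contiguous, so if
many lattice points fall inside one fire footprint, the observed overlap
has much higher variance than the hypergeometric null and the null band
under-covers even without any feedback. The lattice spacing should
therefore exceed the typical fire diameter — the same logic that puts a
2 km sampling lattice on 30 m severity rasters. The calibration tests use
16 fires per year of roughly 12 cells each with a 5-cell lattice pitch;
under no feedback (rho = 1) the observed proportion then falls inside the
null 5th–95th band in ~95% of seed-years.

## Trend estimation

Series are pre-checked for short-term autocorrelation with the Box–Pierce
portmanteau statistic Q = n Σ_{k≤h} r_k² referred to χ² with h degrees of
freedom, h defaulting to min(10, n/5). The check is advisory: a rejection
is logged and the trend still computed.

The Theil–Sen slope is the median of all pairwise slopes (tied x skipped),
the intercept the median of y − slope·x. Two uncertainty summaries are
reported because users want both: 5th/95th confidence bounds from the
classical rank-based procedure on the ordered pairwise slopes, and a
standard error from a 2,000-replicate seeded pair-resampling bootstrap
(resamples with all x equal are discarded). The slope path is delegated to
`scipy.stats.theilslopes` and verified exhaustively against a brute-force
all-pairs enumeration in the tests.

The cover-composition trend uses weighted least squares (statsmodels WLS)
of the conifer share of reburns on focal year, weighted by the number of
qualifying reburn events per year; weighted r², the slope F-test with
(1, n−2) degrees of freedom, and its p-value are reported. Years with zero
qualifying reburns keep their row (flagged NaN) and are excluded from the
fit. Cover is attributed from the beginning-of-record map with no
successional update between fires — after one fire, conifer regeneration is
assumed irrespective of severity — and a three-burn point contributes each
successive pair independently. The landcover collapse onto the five
analysis classes (coniferous, broadleaf, shrub/herbaceous, barren/sparse,
wetland incl. bogs and fens) ships as an editable two-column mapping.

## Conditional permutation importance

The predictability analysis fits scikit-learn random forests (default
1,000 trees; out-of-bag and held-out accuracy reported) on a
stratified-by-label 80/20 split, optionally downsampling the majority class
to parity in training (on by default, configurable off). Importance is the
permutation-based mean decrease in held-out accuracy, computed
conditionally: variable j is permuted only within strata formed by the
cross-classification of quantile bins (default 4 per variable, coarsened
until the median stratum holds ≥ 10 rows) of the variables whose linear
correlation with j is significant at alpha = 0.05. This preserves the joint
distribution of j with its correlated covariates while destroying its
residual association with the response — the defining contract of
conditional importance — without depending on any one forest
implementation's internal partitions. With an empty conditioning set (or
alpha = 0) the procedure reduces exactly to marginal permutation
importance, permutations included. Each variable is permuted 4 times per
forest and the accuracy drops averaged (a single permutation on a ~560-row
test set has granularity 1/560, too coarse near zero); all permuted
matrices are scored in one batched forest prediction. Stability is
reported across 20 independently seeded forests as medians and quartiles,
ordered by median, with ties keeping input order.

Aspect enters the feature matrix through the folded transform
(cos(45° − aspect) + 1)/2 ∈ [0, 1] (northeast = 1, southwest = 0); flat
cells, flagged NaN upstream, map to the neutral 0.5.

## Synthetic generator

The generator emulates the statistical structure the analyses assume, not
fire physics. Cover is a nearest-seed (Voronoi) mosaic of ~40 patches drawn
to target fractions with conifer dominant (45%); covariate fields are
standardized sums of six low-frequency random cosine surfaces — smooth and
seed-deterministic but not Gaussian-process exact; slope/aspect derive from
the synthetic elevation gradient. Fires grow by weighted cluster expansion:
ignite at a cell drawn with probability proportional to its selection
weight, then repeatedly annex a random 4-neighbour boundary cell with
probability proportional to its weight until the year's area target is met,
the target split evenly across the year's fires. The selection weight is
cover flammability times the refractory factor: cells burned within the
previous `tau` years carry multiplier `rho`, so `rho = 0` makes reburning
within `tau` years impossible (weight-zero cells can neither ignite nor be
annexed) and `rho = 1` removes the feedback entirely, interpolating
continuously in between. If every remaining cell has zero weight the year's
shortfall is logged rather than forced. Severity is written as class 3
(burned) / 1 (unburned) so the ≥ 2 reclassification threshold is actually
exercised on ingest.

Defaults mirror the study conditions the analyses target: a 33-year record
(1984–2016), burned fraction ramping 0.4% → 1.1% per year so roughly a
fifth of the landscape burns at least once (an intensifying fire regime),
16 fires per year, and a first-decade feedback tau = 10, rho = 0.1. Cover
weights may be per-year sequences, which is how a rising conifer
flammability scenario is expressed.

The trend-recovery experiment for the conifer share was designed by a power
argument: the binding noise is fire-level clustering (each focal year
contributes only as many independent reburn events as fires that land on
old footprints), so that check uses 32 smaller fires per year, the 10-year
window (23 focal years), a conifer weight ramp 0.1 → 2.0 crossing the
region where the conifer share responds most steeply, and a 1-cell lattice.
The resulting median share trend (~1.7%/yr) is deliberately weaker than
trends reported from real records, and is detected in every seed while the
constant-flammability control stays sign-balanced.

The tabular generator for the classification analysis plants signal only in
the four precipitation variables: reburn log-odds are beta·z with z the
standardized mean of the group's z-scores, and beta solved (by quadrature
and root-finding at run time) so the Bayes accuracy E[sigmoid(beta·|Z|)]
equals the requested value (default 0.8). Within-group equicorrelation is
0.2: large enough that the p < 0.05 screen reliably places group members in
each other's conditioning sets, small enough that each variable's
idiosyncratic component retains half the group signal — with higher
correlation the forest's greedy splits can lean on two of the four and
leave the others with genuinely near-zero conditional importance, which
would contradict the premise that every precipitation field carries signal.
Temperature variables are internally correlated but label-independent;
topography is independent noise; classes come out balanced by symmetry.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: fire weather and spread dynamics, fuel
succession between fires, spatially autocorrelated *nulls* (the null is
interaction-free by design), perimeter-mapping artifacts, survey gaps, or
the true covariance structure of bioclimatic fields. Results on real
rasters inherit none of the generator's guarantees.

## Numerical conventions and edge cases

- All randomness flows from explicit integer seeds through numpy
  Generators; the pipeline expands one master seed into named per-stage
  seeds (simulate, null_model, trends, rf) drawn in a fixed order, so
  stages can be re-run in isolation and full reruns are byte-identical.
- Null quantiles use the nearest-rank (inverted-CDF) convention; an
  undefined focal year (no focal burns) propagates as NaN with a flag, and
  defined-year filtering happens at the analysis layer.
- Theil–Sen pairs with tied x are skipped; bootstrap resamples with
  degenerate x are dropped from the SE.
- A stratum with fewer than two rows is left unpermuted; if every stratum
  is a singleton the variable falls back to marginal permutation with a
  warning.
- Points with incomplete covariates are dropped and counted; duplicate ids
  in a covariate table and empty joins are hard errors, as are unmapped
  landcover labels (named in the error).
- Problem sizes in the tests (100×100 grids, 33 years, 100 seeds for the
  calibration and recovery checks, 20 forests of 1,000 trees on 2,816
  points split 2,252/564) were chosen to make the statistical properties
  sharp at desk scale; the same code runs unchanged at larger sizes.
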