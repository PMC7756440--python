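# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `wiltscan`.

## The synthetic scene generator

The generator (`wiltscan.scene`) emulates the statistical structure of one
drought summer of 10 m optical observations over a forested landscape,
with full ground truth. It is first-class, tested code: every downstream
estimator is validated against quantities the generator knows exactly.

**Driver fields.** Fifteen named environmental drivers (vegetation height,
distance to forest edge, forest mixture, slope, north/south exposition,
rooting depth, hydraulic conductivity, August soil moisture and its
anomaly, August maximum temperature and its anomaly, prior-year
temperature anomaly, April–August precipitation, August and prior-year
precipitation anomalies) are spatially autocorrelated Gaussian random
fields: seeded white noise smoothed with a Gaussian kernel (correlation
length `smoothing_length`, default 5 pixels), rescaled to a stated
mean/sd and clipped to a physically plausible range. The variance
attenuation of the smoothing kernel is computed exactly from its impulse
response, so with `smoothing_length = 0` each field is white noise with
known moments — the basis of the generator's moment tests. A pure-noise
nuisance driver is always included as a negative control.

**Forest mask and artifacts.** The mapped forest mask covers exactly
`1 − artifact_fraction` of the scene (empirical-quantile threshold on a
smoothed field, so non-forest comes in patches); non-forest splits into
grassland and bare soil. In addition, `mask_leakage` (default 3%) of the
mapped-forest pixels are truly grassland — the commission error any
tree-cover product has at this resolution, and the reason grassland can
produce false positives in the wilting map. These leaked pixels carry the
grassland trajectory and are exactly what the "artifact" interpretation
polygons delineate.

**Wilting probability.** The per-pixel wilting probability follows a
logistic link on standardized drivers, p = expit(b₀ + Σ lin·z + quad·z²),
with vegetation height entering concavely (unimodal risk: mid-sized
canopies most susceptible). The intercept b₀ is calibrated by bisection so
the forest-mask mean of p equals `prevalence_target` within 10⁻³; the
default target of 0.108 makes the simulated landscape match a 10.8%
regional wilting prevalence. Labels are independent Bernoulli draws per
true-forest pixel; wilted pixels get an onset day uniform in
`wilt_onset_window` (default Aug 1–Sep 15).

**NDVI trajectories.** All pixels share one observation calendar
(Mar 1–Nov 30 of the drought year plus May 1–Jun 30 of the next spring;
integer gaps uniform on revisit ± 1 day, default mean 4 days), as for a
satellite tile. Non-wilted forest follows a double-logistic phenology
curve (winter 0.35, summer 0.85, green-up day 110, senescence day 295).
Wilted pixels drop by `wilt_drop` (default 0.3) along a linear onset ramp
of `wilt_ramp_days`, and show a `persistence_delta` (default 0.015) lower
NDVI the following spring. Grassland has a lower, later curve with a
mid-July senescence dip of similar magnitude to the wilting drop — the
designed false-positive source; bare soil is flat at 0.15. Observations
receive a per-pixel baseline offset N(0, `pixel_offset_sd`, default 0.05)
representing between-pixel phenology variability, plus i.i.d. observation
noise N(0, `noise_sd`, default 0.05), are clipped to [−1, 1], and are
dropped independently with `cloud_gap_prob` (default 0.3).

**Ramp length.** The onset ramp defaults to 3 days — no longer than the
minimum revisit gap — so that with noise off, one consecutive observation
pair always captures at least half of the drop. This makes the generator
self-certifying: thresholding the maximum consecutive NDVI drop at
`wilt_drop/2` reproduces the labels exactly, giving an oracle every
change-point test can lean on. A longer ramp (configurable) spreads the
drop across several revisits and weakens the observed change magnitude.

**Climate statistics.** Period statistics follow the usual conventions:
temperature anomalies are absolute (°C deviation of the period mean from
the climatological mean), precipitation anomalies are relative (period
sum as a percentage of the climatological period sum). The 15 canonical
single/consecutive-month periods April–August are provided.

**What the generator does not emulate.** Radiative-transfer or multi-band
realism, topographic illumination, geolocation error, spatially
correlated cloud fields, wilting-severity continua (every wilted pixel
drops by the same amount), species identity, and label noise in the
interpretation polygons (polygons trace truth exactly). Passing tests
therefore demonstrate that the estimators recover what they claim under
clean, well-specified conditions — not that the classifier would reach
the same skill on real imagery, where interpretation ambiguity,
mixed pixels and geolocation error dominate the error budget.

## Time-series statistics

Window statistics use valid observations in closed date windows; a window
with zero valid observations yields NaN-flagged statistics, which marks
the pixel incomplete (the snow-exclusion pathway: pixels without
March–April coverage are excluded from prediction and from all area
denominators).

The CAT analysis requires ≥ 4 valid summer observations. The change point
is defined on **consecutive valid observations** (not fitted segments):
the pair maximizing the absolute difference, ties broken earliest, the
signed difference reported as magnitude and the later date as timing (the
first date the change is visible). Trends are ordinary least squares of
NDVI on date for the full period and for the segments at ≤ t_k / ≥
t_{k+1}, each needing ≥ 3 points; the full-period slope gets a two-sided
t-test p-value (p = 1 for an exactly constant series, where the slope SE
is 0), and the "summer mean absolute error" is the mean |residual| around
the full-period line. All stack-level routines are vectorized with
forward-fill index tricks; equivalence with exhaustive search and
closed-form OLS is asserted to 10⁻¹⁰ on hundreds of random series.

Feature screening is a greedy pass in relevance order that drops any
candidate whose absolute Pearson correlation with an already-retained
feature exceeds 0.75; constant columns (undefined correlation) are
dropped with a warning.

## Classifier

`WiltingClassifier` is a scikit-learn-style estimator: an ensemble of
CART trees, each grown on a class-stratified bootstrap of up to 75 000
presence and 20 000 absence-or-artifact pixels (capped at the class size,
drawn with replacement), √p feature subsetting, majority-vote prediction
with a configurable threshold (default 0.5), optional out-of-bag scoring,
and full determinism given `random_state`. Artifact pixels are merged into
the negative class for fitting; their count is logged. Rasterization of
interpretation polygons uses pixel-center containment, with overlap
conflicts resolved presence > artifact > absence and counted.

Pixels that are non-forest or lack complete features are a third,
"not-predicted" state: mapped as absence for display but excluded from
stratum weights, area denominators and coarse-fraction denominators.

## Design-based validation

The post-stratified estimators are implemented for k classes with the
standard delta-method producer's-accuracy variance (mapped-proportion
form, in which the total map size cancels). Monte-Carlo tests draw
hundreds of stratified samples from a known confusion process and check
unbiasedness, SE calibration (reported SE within 20% of the empirical
sampling SD) and 93–97% coverage of the nominal 95% intervals.

## Driver analysis

Balanced samples equalize total presence and absence weight. At pixel
scale both classes get unit weights; at coarse-cell scale each sampled
cell contributes presence weight c·p_k and absence weight a_k with
c = Σa_k/Σp_k, and the response is a weighted binomial (presence fraction
with total weight as trials) — non-integer weights are kept as weights
rather than replicated rows, which would inflate the apparent sample
size.

Smooth terms are unpenalized B-spline regression bases fitted by IRLS:
cubic with basis dimension 6 by default, quadratic with basis dimension 3
for ordinal soil-class drivers (a cubic basis needs at least dimension
4). Fixed-dimension regression splines keep every fit at ~50 ms, which
the 100-refit response-curve ensembles and deviance rankings require;
the basis is generous enough for the monotone and unimodal shapes the
synthetic link contains, and the explained-deviance bookkeeping
(1 − D/D_null, with the null deviance from an intercept-only fit on
identical weights) is exact. One test cross-checks the explained deviance
against an R mgcv fit with the same fixed basis dimension.

Response-curve ensembles refit on freshly re-drawn samples (a new child
seed per refit from a master seed), evaluate on a fixed grid spanning the
1st–99th percentile of the driver, and report the pointwise median and
2.5%/97.5% quantiles across refits. Curve evaluation clips the grid to
the fitted data span (B-spline bases are undefined outside it).

## Persistence

Cell deltas require at least `min_pixels = 10` pixels per class per year
(no established threshold exists; the value is configurable and the
choice only discards cells where a median of fewer than 10 values would
be fragile). Per-pixel spring NDVI is the mean of valid May/June
observations. Cell-level CAT predictors are means over the wilted pixels
of the cell. Delta models use a Gaussian family; the balanced-binomial
machinery is reused unchanged for the smooth terms and deviance
accounting.

## Pipeline

Stages (simulate → features → train → predict → validate → drivers →
persistence) exchange file artifacts: single/multi-band float32 TIFF
rasters (nodata −9999) plus uint8 class rasters, GeoJSON label polygons,
CSV tables and a plain-text key-value scene config. Each stage writes a
manifest (stage, seed, config hash, package version, SHA-256 input
checksums); replaying a manifest's config reproduces its artifacts
byte-identically. Rasters carry no CRS metadata: the synthetic scene has
its own pixel coordinate frame (row-major, origin top-left, pixel area =
pixel_size²) and reprojection is out of scope. The forest-mask rule is
inclusive: tree cover ≥ 80% is forest, with fractional or percent scales
auto-detected.

## Problem sizes

The default evaluation experiments use a 200×200-pixel scene (4 km²) for
the end-to-end map-and-estimate replicates, a 250×250 scene for driver
ranking (so both balanced classes reach 5 000 pixels), 150×150 scenes
with 30-pixel cells for persistence recovery, and 4 900-cell constructed
tables for the persistence-predictor ranking. These sizes put every
Monte-Carlo standard error well below the effects being recovered while
keeping the full suite at around a minute of compute.

## Known limitations

- **Degenerate validation intervals on nearly perfect maps.** Under the
  default generator conditions the wilting signal is ~6 standard
  deviations of observation noise, and the trained map's error rate is a
  few 10⁻⁴. A stratified reference sample of 500 pixels per stratum then
  usually contains zero disagreements, the post-stratified standard
  errors collapse to zero, and the degenerate ±1.96·SE interval cannot
  cover the map's small residual bias. Normal-theory intervals are simply
  invalid in this regime; the estimator's coverage is correct (93–97%)
  whenever per-stratum error rates are resolvable at the sample size, as
  the Monte-Carlo tests show. With real imagery — interpretation
  ambiguity, geolocation error, mixed pixels — error rates are orders of
  magnitude higher and the issue does not arise.
- Explained deviance of unpenalized regression splines is slightly
  optimistic at small n (no smoothness penalty); rankings and the
  100-refit medians are unaffected.
- The CAT "mean absolute error" is defined around the full-period OLS
  line; other residual definitions (e.g. around segment fits) would give
  different absolute values.
- Coarse-cell driver values are plain block means; no area weighting of
  partial edge cells.
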