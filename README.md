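# wiltscan

Detection, mapping and attribution of drought-induced **early wilting** —
premature leaf discoloration and shedding of forest canopies before the
normal onset of autumn senescence — from dense NDVI time series, exercised
end-to-end on a fully known synthetic landscape.

The package is aimed at remote-sensing ecologists who want to test, teach
or extend the classic map-and-estimate workflow for drought damage
mapping: per-pixel NDVI summary statistics → supervised presence/absence
classification → design-based accuracy and area estimation → multi-scale
environmental-driver models → a following-spring greenness persistence
metric. Every stage runs against a synthetic scene generator whose truth
(labels, onset days, driver effects, effect sizes) is known exactly, so
each estimator can be validated against the quantity it claims to recover.

## The method

**Features.** Each pixel's dated NDVI series (observations every 3–5 days,
with cloud gaps) is reduced to ten statistics: spring (Mar 1–Apr 30) and
fall (Oct 1–Nov 30) minima and maxima, the summer (May 1–Sep 30) mean, and
a Change–Aftereffect–Trend (CAT) analysis of the summer series giving the
most pronounced change point — the consecutive valid-observation pair
(t_k, t_{k+1}) maximizing |v_{k+1} − v_k| — with its signed magnitude and
timing, the OLS summer trend, the trend's two-sided significance, and the
mean absolute residual around the trend line.

**Classification.** A random forest whose trees are grown on
class-stratified bootstraps (up to 75 000 presence and 20 000
absence-or-artifact pixels per tree, majority vote) maps early-wilting
presence wall-to-wall over the forest mask; predictions aggregate to
coarse-cell wilted fractions.

**Validation and area.** From a stratified random reference sample the
post-stratified ("good practices") estimators give overall accuracy,
user's/producer's accuracies and reference-class areas. With mapped-area
weights W_i, cell proportions p̂_ij = W_i n_ij / n_i·:

    OA = Σ_j p̂_jj                 SE(OA) = √(Σ_i W_i² UA_i(1−UA_i)/(n_i·−1))
    p̂_·j = Σ_i W_i n_ij/n_i·      Â_j = p̂_·j · A_total

**Drivers.** Class-balanced samples (equal total presence and absence
weight, at pixel scale and at coarse-cell scale with weighted binomial
responses) feed univariate and multivariate additive logistic models
(B-spline smooths, basis dimension 6; 3 for ordinal soil classes).
Calibration strength is the explained deviance (D_null − D)/D_null;
response curves are medians with 95% pointwise bands over 100 refits on
re-drawn samples.

**Persistence.** Within each coarse cell, delta =
(NDVI_g − NDVI_b)_year2 − (NDVI_g − NDVI_b)_year1, where NDVI_b/NDVI_g are
May/June median NDVI of wilted/non-wilted pixels — how much further the
wilted patches fell behind the following spring — related to drivers and
to CAT change magnitude/timing with Gaussian additive models.

## Worked example

```python
from wiltscan.evaluation import run_end_to_end

r = run_end_to_end(seed=42)   # default 200×200 scene, 10.8% prevalence
print(f"held-out accuracy      : {r.heldout_accuracy:.4f}")
print(f"PPV / NPV              : {r.ppv:.3f} / {r.npv:.3f}")
print(f"estimated wilted area  : {r.est_area_km2:.4f} ± {r.est_area_se_km2:.4f} km²")
print(f"true wilted area       : {r.true_area_km2:.4f} km²")
print(f"estimated prevalence   : {100*r.est_area_km2/r.total_area_km2:.2f} %")
```

prints

```
held-out accuracy      : 0.9995
PPV / NPV              : 1.000 / 1.000
estimated wilted area  : 0.3828 ± 0.0000 km²
true wilted area       : 0.3847 km²
estimated prevalence   : 10.63 %
```

One seeded run generates a 4 km² scene (40 000 pixels at 10 m) with 10.8%
simulated wilting prevalence, trains on 30 interpretation polygons,
predicts wall-to-wall, and validates with 500 reference pixels per
predicted stratum. The classifier recovers the wilting map almost
perfectly under the default signal-to-noise conditions (a 0.3 NDVI drop
against 0.05 observation noise), so the estimated area matches the truth
to within half a percent; note the degenerate ±0.0000 standard error — a
500-pixel sample that observes zero disagreements cannot resolve error
rates of a few 10⁻⁴ (see `docs/methods.md`, limitations).

The same pipeline is scriptable from the shell:

```sh
wiltscan all --out run/        # simulate → … → persistence, with manifests
wiltscan validate --out run/   # re-run a single stage
```

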