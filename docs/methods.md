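# Methods

## The model

For one crop, yield anomalies of all regions are pooled into a single
hierarchical model.  Writing `dY`, `dT`, `dS` for detrended log yield,
growing-season temperature and growing-season SPEI (standardized
precipitation–evapotranspiration index; negative = dry) of region *c* in
year *t*:

```
dY[c,t] = x[c,t]' (beta + b_c) + eps[c,t]

x = (1, dT, dT², dS, dS²,
     dT·dS, dT²·dS, dT·dS², dT²·dS²,        # temperature-drought interactions
     dT₋₁, dS₋₁, dT₋₁·dT, dS₋₁·dS)          # previous-year "intensification"

b_c ~ N(0, D),  D = diag(d₁ … d₁₃)          # region-specific sensitivities
eps[c,t] ~ N(0, sigma² · phi_c),  phi₁ = 1   # heteroscedastic by region
```

The quadratic terms allow an optimum; the interactions allow the
temperature response to differ between dry and wet years; the lag terms
capture carry-over from consecutive warm or dry years.  Random effects are
diagonal and share the active-term mask with the fixed effects: when a term
is eliminated, its global slope and its per-region deviations leave
together.  (Whether the source analysis removed the random part together
with the fixed part is not documented; joint removal is this package's
choice, because a random slope without a fixed counterpart changes the
meaning of "removing a variable".)

Estimation is maximum likelihood.  At fixed variance parameters, the fixed
effects have the closed-form GLS solution and the residual scale has a
closed-form profile, so the optimizer works only on `log(d_j / sigma²)` and
`log(phi_c)` (L-BFGS-B with an analytic gradient; the envelope theorem makes
the profile gradient equal to the partial derivative).  ML rather than REML
is the default so that likelihoods, BIC and the elimination path are
comparable across fixed-effect structures; REML is available
(`fit_mixed(..., reml=True)`, finite-difference gradient).

Inference is Wald with the normal reference: z = estimate / se, joint
groups via the chi-square quadratic form.  No small-sample df correction is
applied; with ~1 300 observations and 25 regions the normal approximation
is adequate, and the parameter-recovery check (below) confirms 95% CI
coverage between 91% and 97% in simulation.  Backward elimination removes
the least significant removable term with p > 0.05, where "removable"
respects marginality (a term stays while any retained higher-order term
contains it, judged on the exponent table of the 13 terms).

Single-region models use the same 13 columns by OLS with classical t-based
inference; term selection there drops the largest-p removable term while
BIC decreases, stopping at the first increase.  The interplay of
"non-significant excluded" and "minimum BIC" is ambiguous in prose;
p-ordered greedy is the default and a BIC-ordered variant sits behind
`order="bic"` (both select identically on pure-noise simulations, 76%
intercept-only over 200 seeds).

## Data preparation

**Yields.**  Yield = production / harvested area (t/ha).  Records with
non-positive area or yield are rejected and logged.  If a series reports
exactly identical production in consecutive years (a hallmark of
carried-forward reporting), only the years strictly before the first such
run or strictly after the last one are kept, whichever segment is longer
(ties to the more recent side); series falling below a configurable
minimum length (default 20 years) are dropped.  Individually implausible
observations can be removed via an explicit exclusion list; no automated
outlier rule beyond the stated ones is applied.

**Growing-season climate.**  Monthly gridded temperature and SPEI are
averaged over all months containing any day between planting and harvest
(whole months, no day-weighting: a March 2 planting brings in all of
March).  Cross-year seasons are attributed to the harvest year.  Wheat uses
exactly the four months ending at the harvest month — the crop is dormant
in winter and the winter/spring calendar split is unreliable.  Cell values
are aggregated to regions by crop-area weights, renormalized over
non-missing cells (a warning fires if more than 25% of the weight is
missing).  Rice may combine two weighted seasons; maize uses only the main
season.

**Detrending.**  The response is log yield (climate acts multiplicatively),
and the log is taken *before* detrending.  Trends are penalized cubic
regression splines of year with the exact curvature penalty ∫f″² (null
space: straight lines).  Basis dimension: `max(3, n_years // 10)` for
yields — doubled for series flagged as poorly fit via a config list (an
automatic warning fires at residual lag-1 autocorrelation above 0.5 but is
never auto-applied) — and 5 for climate.  Smoothing is selected by GCV with
a degrees-of-freedom inflation of gamma = 1.4, the standard guard against
GCV's tendency to undersmooth short series.  For climate series the fit
additionally chooses, again by GCV, between leaving the linear component
unpenalized and shrinking the whole trend to a constant ("penalize to zero
when there is no trend").  Making this a discrete choice rather than a
second continuous smoothing parameter keeps two exact invariances: adding a
linear ramp to a trend-bearing series leaves its anomalies unchanged
(< 1e-6 rms), and re-detrending an already-detrended series changes nothing
(< 1e-6 rms).  Anomalies are residuals from these fits; lagged anomalies
refer to calendar year t−1 and are missing (and the row excluded from
fitting, not zero-imputed) where that year is absent.

## Effects, validation, robustness

**Percent effects.**  A fitted model is summarized as
`100 · (exp(c'beta) − 1)` with `c` the design row at chosen anomaly values,
the intercept excluded (so the all-average point is exactly 0%), and
variables not involved in the displayed effect pinned at zero.  Interaction
structure is shown by sweeping one variable over its empirical 5th–95th
percentile range while the other sits at its 0.05 / 0.50 / 0.95 quantile
(dry / normal / wet, or cold / normal / hot).  Lag variables are pinned at
zero except in intensification curves, where the lag is the conditioning
variable.  Pointwise 95% bands use the delta method
(`exp(eta ± 1.96 se) − 1`); no simultaneous bands.  Global curves exclude
the BLUP contributions — they describe the pooled sensitivity, not any one
region — and use pooled quantiles; per-region curves use that region's own
fit and quantiles.

**LOOCV.**  Model structure is fixed before cross-validation; no
re-selection inside folds.  For the hierarchical model, variance parameters
stay frozen at their full-data ML values and each fold re-estimates the
GLS fixed effects and the held-out region's BLUP from the remaining data
(a full per-fold refit is available behind `refit_variance=True` at ~n
times the cost).  Errors are summarized as RMSE and median absolute error
on the log scale.  The nested comparison re-selects a no-interaction model
(NoInter) starting from the selected model minus interaction columns, and
fixes OnlyLin at the linear columns (1, 2, 4, 10, 11); variants whose
formula coincides with a richer one get empty cells.

**Noise injection.**  Measurement error in reported yields is emulated by
adding `N(0, (f · sd_series)²)` noise to each series' detrended log yields
— the same relative error everywhere — for f = 1%…50%, refitting the
*original* model (same mask, warm-started from the clean fit), and
recording the p-value of the highest-order retained term group (ranked
interaction > quadratic > linear on the exponent table; joint Wald for
multi-term groups).  Sub-seeds derive deterministically from the master
seed and the (fraction, replication) indices.  Noisy responses are *not*
re-detrended.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, with
known truth written beside the data under a `.truth` extension so recovery
tests cannot read it through the pipeline path.

* Temperature: cell climatology + seasonal sinusoid + linear warming trend
  (default 0.25 °C/decade) + a regional year anomaly (sd 0.5 °C) shared by a
  region's cells + cell-month noise (sd 1 °C).
* SPEI: exactly standard normal per (cell, month), split into a regional
  component (80% of variance — droughts are regional) and cell noise;
  optional AR(1) across years as a stress test (default off: the index is
  standardized per month/location, temporal persistence is not assumed).
* Log yield: base level + saturating ("green-revolution") trend of ~1 log
  unit over 1961–2014 + the 13-term expansion with global coefficients
  (defaults: intercept 0, dT −0.02, dT² −0.01, dS 0.03, dS² −0.005,
  dT·dS −0.015), per-region random slopes at 50% relative sd, residual sd
  0.08, variance ratios uniform in [0.5, 2].
* Region anomaly scales for the direct (no-grid) generator: temperature
  sd 0.6 °C, SPEI sd 1.0 — SPEI is a standardized index, and at unit scale
  the default coefficients produce percent effects of the magnitude seen in
  observational studies (a dry-year 5th percentile costs ~5% yield).

What the generator does **not** emulate: spatial autocorrelation structure
of real half-degree grids beyond the shared regional component, irrigation,
pests, management or socio-economic drivers, intra-seasonal extremes, and
reporting artifacts other than the two QC failure modes it can inject.
Passing recovery tests therefore demonstrates correctness of the estimator
under the model's own assumptions, not robustness to real-data violations
of them.

## Numerical choices

* Variance parameters are optimized on the log scale, clamped to
  exp(±30) relative scale with a boundary flag; convergence at L-BFGS-B
  ftol 1e-12 / gtol 1e-6, optional 3-point multi-start for flat likelihoods.
* With 13 random variances per ~54-observation region, D is weakly
  identified at full mask; the active mask keeps the random part in step
  with elimination, which is also what keeps BIC's parameter count honest.
* GCV grids: 36 log-spaced smoothing values (including 0), discrete
  {0, 1e12} null-space choice, ties resolved toward the smoother fit with
  an absolute floor so exactly-representable inputs (constants, lines)
  reproduce to machine precision.
* Quantiles use linear interpolation (NumPy default), recorded in the
  QuantileSet.
* Elimination ties break alphabetically on term name (mixed model) or by
  higher polynomial order then column index (single-region).

## Problem sizes

The analysis scripts run 12 regions × 4 cells × 54 years; the acceptance
script and the test suite use 100 replications for recovery/LOOCV/noise
studies and 200 for detrending rates.  These sizes give Monte-Carlo
standard errors comfortably below the asserted margins (e.g. recovery bias
MC se ≈ 3% of the smallest coefficient at 100 replications).

## Known limitations

* GCV shrinkage leaves a white-noise series at effective df ≤ 1.5 only
  ~76–82% of the time at n = 54, k = 5 (the same range as the canonical R
  implementation under its available selectors); occasional spurious
  wiggle in trendless climate series is absorbed downstream as extra
  anomaly noise.
* Wald/ML inference is mildly anticonservative; simulated CI coverage sits
  at 0.91–0.97 rather than exactly 0.95.
* LOOCV with frozen variance parameters slightly understates prediction
  error relative to a full refit.
* Single-region BIC selection on ~50 observations is noisy; the pooled
  hierarchical model is the primary instrument, which is the point of the
  random-effects specification.
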