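# Methods

This note documents the models, numerical choices, and design decisions in
`foodclim`, and what the simulation evidence does and does not establish.

## Climate indicators

**Annual temperature anomaly.** For each region, the anomaly in year *y* is
the mean of that year's 12 monthly temperatures minus the mean of all
monthly temperatures in the inclusive 1981–2010 baseline window.  Both
baseline endpoints are inclusive; incomplete baseline coverage is an error,
while an incomplete target year yields a flagged missing value.  Because
the baseline is computed from the series itself, adding a constant to the
*whole* series leaves every anomaly unchanged, and adding a constant to
post-baseline years only shifts those years' anomalies by exactly that
constant.  Both properties are tested.

**Monthly-anomaly bins.** Monthly anomalies are computed against
calendar-month-specific baseline means (a monthly climatology).  Without
this, the seasonal cycle would dominate the bins and the counts would be
uninformative; with it, the bins measure how unusual a month was for its
season.  Bin edges are half-open `[a, b)` — an anomaly of exactly 0.4 °C
falls in the 0.4–0.6 bin — and the five bins (<0.2, 0.2–0.4, 0.4–0.6,
0.6–0.8, ≥0.8 °C) partition each complete year's 12 months.  The 0.2–0.4
bin is the omitted reference in the binned regressions.

**SPI-6.** The six-month Standardized Precipitation Index accumulates
precipitation over the rolling window *ending* in the indexed month.  For
each region and calendar month, a gamma distribution is fitted by maximum
likelihood (zero location; method-of-moments fallback if ML fails) to the
positive accumulations in the calibration window (default 1981–2010,
aligned with the anomaly baseline), with an explicit point mass `q` for
zero accumulations.  SPI is the standard-normal quantile of
`H(x) = q + (1 - q) * GammaCDF(x)`, with `H` clipped to `[1e-6, 1 - 1e-6]`
before the quantile transform; months whose calibration accumulations are
all zero have undefined SPI and are flagged.  Accumulations outside the
calibration window are transformed with the frozen calibration parameters.
A drought month is one with SPI strictly below −1.5; the annual drought
covariate counts such months.

**Grid aggregation.** `grid_to_region` is a weight-normalised spatial mean
per region and time step; the weights are caller-supplied (area weights,
population weights, or binary masks), since nothing in the method fixes
that choice.

## Survey scoring

The eight FIES items are ordered by severity.  The default classification
is item-based: a respondent is moderately-to-severely food insecure if they
affirm any of items 4–8 (skipping meals, eating less, running out of food,
going hungry, or not eating for a day) and severely food insecure if they
affirm item 7 or 8.  A raw-score dialect (≥4 of 8 / ≥7 of 8 affirmations)
is available; the two coincide exactly on Guttman-structured responses,
which is tested.  This deterministic classification deliberately replaces
the Rasch-model scaling used operationally for the real survey: latent-trait
estimation is a different inferential machine, out of scope here, and the
two agree only approximately on real data — a stated limitation.

Prevalence is the survey-weighted share of flagged respondents, times 100;
`effective_n = (Σw)² / Σw²`.  A record missing any classification-relevant
item is dropped with a logged count (the simplest defensible policy;
imputation is out of scope).

## Regression

The headline specification regresses region-year prevalence (0–100) on the
annual anomaly with a separate slope per year, one SHDI slope, one drought
slope, region fixed effects, and year intercepts.  Year intercepts coexist
with year-varying anomaly slopes without collinearity as long as the
anomaly has cross-sectional variance within each year; a year without such
variance raises an explicit error.  Slopes for the controls can optionally
vary by year, and the time-varying path can be constrained equal, which
reproduces the constant-coefficient fit exactly.

Time variation is implemented as saturated year interactions — one free
coefficient per calendar year — rather than a kernel-smoothed path: with
six study years and one reported coefficient per year, smoothing would add
a bandwidth choice without adding information.

SHDI enters in units of 0.1, so a coefficient of −2.3 reads "2.3
percentage points lower prevalence per 0.1 of HDI".  Prevalences are
percentage points throughout; anomalies are °C.

**Estimation and inference.** Dummy-variable least squares via QR/lstsq,
with a pivoted-QR rank check that names the collinear columns on failure.
The default covariance is the cluster-robust sandwich by region with the
`G/(G-1) * (n-1)/(n-p)` small-sample factor and `t(G-1)` critical values
(the convention used by common econometrics software; the test suite
verifies exact agreement with statsmodels' cluster covariance on identical
designs).  Classical and HC1 covariances are available.  Clustering by
region is a choice: it allows arbitrary serial correlation within a region,
and under the generator's iid errors it agrees with the classical
covariance on average (tested).  Unbalanced panels are accepted; rows with
missing values are listwise-deleted with a logged count.

**Sequential Wald tests.** For consecutive years,
`z = (λ̂_t − λ̂_{t−1}) / se(difference)` using the joint covariance, with a
one-sided normal p-value against "this year's effect exceeds last year's".
The five tests are reported individually, without multiplicity correction,
matching how such paths are usually read; a Bonferroni adjustment is a
one-line wrapper if wanted.

**Outcome heterogeneity.** The two severity outcomes are stacked into one
two-equation regression (each with its own fixed effects, year intercepts,
anomaly path, and control slopes), clustered by region *across both
equations* so cross-equation error correlation is absorbed the way a
seemingly-unrelated-regression system would absorb it.  The Wald statistic
for equal anomaly paths uses a pseudo-inverse of the restricted covariance
(robust to the degenerate identical-outcome case) and is referred to
`F(T, G−1)`, which calibrates better than the raw chi-square at 83
clusters.

## Counterfactual attribution

The default counterfactual fits a per-region linear trend to 1981–2010
annual means and extrapolates it through the study years; the
counterfactual anomaly is the trend value minus the baseline mean.
Pre-aggregated counterfactual series from natural-forcing climate-model
runs can be supplied in the same scenario-table format instead — the
package never processes native climate-model archives.

Predictions are `α̂_i + τ̂_t + λ̂_t V + γ̂'X`.  Standalone predictions are
clipped to [0, 100] with a logged count, but attribution deliberately uses
unclipped predictions so the group difference is *exactly* linear in the
estimated slopes: group difference = weighted mean of `λ̂_t ΔV_it` over
member region-years.  That identity is asserted in tests, and it yields a
delta-method CI on the difference from the slope covariance.  Differences
are reported as factual minus counterfactual, so positive numbers mean
warming worsened food insecurity.  Group weights default to equal regions;
population weights are accepted.  Only coefficient uncertainty is
propagated — scenario (climate-model ensemble) spread is out of scope.

## Synthetic data generator

The generator defines the study conditions for every simulation result.

*Climate*: 83 regions, monthly series 1981–2019.  Temperature = region
mean (N(18, 6²) °C) + seasonal sinusoid (amplitude 8 °C) + per-region
linear trend + post-baseline acceleration + N(0, 0.5²) monthly noise.
Per-region trends are N(0.0112, 0.008²) °C/yr and the acceleration adds
0.05 °C/yr after 2010; the two are jointly calibrated so the expected
2014–2019 mean anomaly is 0.56 °C, the study-sample value.  The
acceleration term matters structurally: it is warming *in excess of* the
1981–2010 trend, hence exactly the factual-minus-counterfactual scenario
gap; without it the trend-based counterfactual would coincide with the
factual series and attribution would be degenerately zero.  Precipitation
is calendar-month Gamma(2, 40 mm) with a 5% point mass at zero, so the
SPI's zero-handling is genuinely exercised.

*Panel outcomes* follow the linear model above with the published per-year
coefficient paths as defaults (moderate-to-severe 1.58 → 2.14, severe
1.40 → 1.64 %/°C), SHDI slopes −2.7/−2.3 per 0.1, drought slopes
0.014/0.011 per event-month, region-effect sd 2.5, and outcome noise sd
0.15 — the noise level implied by the published coefficient standard
errors at 83 regions.  Intercepts are set so sample means sit near the
study levels (22.7% moderate-to-severe, 7.9% severe).  Outcomes are
clipped to [0, 100] and severe is constrained not to exceed
moderate-to-severe.  The region-effect spread is kept moderate so the
linear-probability outcomes stay interior (clipping censors the model the
regression assumes); fixed effects absorb level differences regardless.

*Survey microdata*: each respondent draws a latent severity from a
logistic distribution and affirms item *j* iff the latent exceeds
threshold *j* (thresholds −3…4), giving Guttman structure by construction.
The location *and* scale are solved in closed form so that the expected
shares above the item-4 and item-7 cutoffs equal the region-year's true
moderate-to-severe and severe prevalences — both prevalences are matched
exactly in expectation, not just ordered.  Survey weights are lognormal
with mean 1.  The default of 800 respondents per region-year matches the
real study's ≈826 (411,403 respondents over 498 country-years).

What the generator does *not* emulate: survey design effects
(strata/PSUs), item-response noise around the Guttman pattern,
spatially-correlated climate across regions, serially-correlated outcome
shocks, and outcome levels as dispersed as real cross-country data (which
a linear probability model could not host without heavy censoring).
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to those real-data complications.

## Simulation evidence and problem sizes

All simulation studies fix one covariate design (climate and SHDI drawn
once) and redraw region effects and outcome noise per replicate, which is
the standard fixed-design framing for unbiasedness and coverage.  Sizes
were chosen to keep the full suite within minutes on one CPU:

- Parameter recovery: 500 replicates at 83 regions × 6 years; per-year
  slope bias and pooled 95% CI coverage.
- Sequential Wald calibration: 400 null replicates (flat path at 1.5) and
  200 alternative replicates.  The alternative climbs 0.2 %/°C per year
  with outcome noise 0.08: with 83 regions and cross-sectional anomaly sd
  ≈ 0.21 °C, that noise level puts the designed per-comparison power near
  95%, i.e. a deliberately strong alternative for the >80% power check.
- Heterogeneity-test calibration: 400/200 replicates; null shares the
  severe path across outcomes, the alternative separates the paths by
  0.5 %/°C.
- SPI calibration: one region, 360-month window, series started a year
  early so all 360 calibration months have defined accumulations.

## Known limitations

- The item-based severity classification approximates, but is not, the
  operational Rasch-probability definition of the published prevalence
  indicators.
- The counterfactual trend is linear in time; curvature in 1981–2010
  warming would leak into the attributed difference.
- Attribution CIs condition on the fitted fixed effects and treat the
  scenario anomalies as known.
- The SPI gamma fit needs a recommended ≥20 years per calendar month;
  shorter calibrations degrade the normality of the index, and strongly
  zero-inflated climates leave a discrete jump at `q`.
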