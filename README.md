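# foodclim

Climate attribution of food-insecurity prevalence.

`foodclim` is a tested, reusable pipeline for the question: *how much of the
recent rise in food insecurity can be attributed to warming?*  It takes
region-level monthly climate series and individual responses to the 8-item
Food Insecurity Experience Scale (FIES) survey module, builds region-year
panels of survey-weighted prevalence and climate covariates, fits two-way
fixed-effects regressions in which the temperature-anomaly coefficient
varies by year, and compares predicted prevalence under observed warming
with a counterfactual in which each region's temperature merely follows its
1981–2010 historical trend.

It is written for quantitative epidemiologists and environmental economists
who want the full chain — indicator construction, survey scoring,
time-varying-coefficient estimation, and counterfactual attribution — as
composable, unit-tested functions rather than a one-off analysis script.
Because the original microdata (FAO FIES surveys, ERA5-Land reanalysis)
cannot be redistributed, the package ships a first-class synthetic-data
generator with known ground truth that emulates the study setting: 83
regions, six survey years (2014–2019), a warming trend calibrated to a
0.56 °C mean anomaly over the study window, and published per-year
coefficient paths as the true effect sizes.

## The model

For region *i* and year *t*, prevalence (0–100 scale) of either
moderate-to-severe or severe food insecurity is modelled as

```
y_it = alpha_i + tau_t + lambda_t * V_it + gamma' X_it + u_it
```

where `V_it` is the annual temperature anomaly in °C (annual mean minus the
region's 30-year 1981–2010 baseline mean), `X_it` contains sub-national HDI
(in units of 0.1) and the annual drought count (months with six-month SPI
below −1.5), `alpha_i` and `tau_t` are region and year fixed effects, and
the anomaly slope `lambda_t` is estimated separately for every study year.
Estimation is dummy-variable least squares with cluster-robust (by region)
covariance; a constant-slope variant and "binned" variants (month counts in
monthly-anomaly bins, 0.2–0.4 °C as the reference bin) are also provided,
along with sequential one-sided Wald tests of `lambda_t > lambda_{t-1}` and
a stacked-regression test of whether the anomaly effect differs between the
two severity outcomes.

The counterfactual module predicts `y_it` under the factual anomalies and
under trend-extrapolated (or externally supplied) counterfactual anomalies;
attribution tables report group-level prevalence under both scenarios and
their difference in percentage points, with delta-method confidence
intervals from the coefficient covariance.

## Worked example

```python
import pandas as pd
import foodclim as fc

clim = fc.simulate_climate(fc.ClimateGenParams(n_regions=20, seed=42))
regions = sorted(clim["region_id"].unique())
shdi = fc.simulate_shdi(regions, fc.STUDY_YEARS, seed=43)
panel = fc.simulate_panel(clim, fc.PanelGenParams(seed=44), shdi)

fit = fc.fit_tvc(panel, "sfi_true")          # severe food insecurity
print(fit.lambda_ci().round(3))

scen = fc.counterfactual_anomaly(clim)
groups = pd.DataFrame({"region_id": regions, "group": "All"})
print(fc.attribute({"sfi": fit}, panel, scen, groups).round(3))
```

which prints

```
      estimate  ci_low  ci_high
2014     1.790   1.239    2.341
2015     1.602   1.138    2.067
2016     1.357   0.890    1.825
2017     1.340   1.059    1.622
2018     1.787   1.381    2.192
2019     1.757   1.539    1.975

group  sfi_factual  sfi_counterfactual  sfi_difference  ...
  All        8.374               7.827           0.548
```

The first table is the estimated per-year anomaly coefficient path with 95%
cluster-robust confidence intervals: at this small 20-region scale the
generator's true severe path (1.40 → 1.64 percentage points of prevalence
per °C) is recovered within its intervals.  The attribution row says that
under observed warming, severe food insecurity averages 8.37% across these
regions versus 7.83% had temperature followed its historical trend — an
attributable difference of 0.55 percentage points.

A command-line interface mirrors the library
(`foodclim simulate | indicators | score | fit | attribute | report`); the
`report` subcommand chains the whole pipeline from a YAML configuration and
writes coefficient tables, the attribution table, and a manifest with
content hashes, byte-identical across reruns with the same seed.

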