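"""Synthetic climate, survey, and panel generators with known ground truth.

The generators emulate the study setting end to end: a panel of regions with
monthly climate over 1981–2019, individual 8-item food-insecurity survey
responses, and region-year prevalences produced by the linear
fixed-effects model with per-year anomaly coefficients that the regression
module estimates.  Every default is the study-scale condition: 83 regions,
six survey years 2014–2019, a warming trend calibrated so the 2014–2019
sample-mean anomaly is 0.56 °C against the 1981–2010 baseline, and the
published per-year coefficient paths as the true effect sizes.

All randomness flows through explicit integer seeds; no global state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import indicators as ind

log = logging.getLogger(__name__)

STUDY_YEARS = tuple(range(2014, 2020))

#: Published per-year anomaly coefficients (percentage points of prevalence
#: per °C), used as default ground truth for recovery experiments.
LAMBDA_MSFI = (1.58, 1.71, 1.83, 1.94, 1.95, 2.14)
LAMBDA_SFI = (1.40, 1.54, 1.60, 1.61, 1.62, 1.64)

#: Ascending latent-severity cutoffs for the eight survey items (Guttman
#: structure: affirming item j implies affirming every easier item).
DEFAULT_ITEM_THRESHOLDS = (-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0, 4.0)


def _as_monthly_vector(x, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (12,)).copy()
    if (arr <= 0).any():
        raise ValueError(f"{name} must be positive, got {x}")
    return arr


@dataclass(frozen=True)
class ClimateGenParams:
    """Parameters for the monthly climate generator.

    Temperature is a region mean plus a seasonal sinusoid, a linear warming
    trend centred on the baseline midpoint, a post-baseline acceleration,
    and Gaussian noise.  Precipitation is calendar-month gamma with an
    explicit point mass at zero.  ``warming_trend`` may be a scalar
    (per-region trends are then drawn around it with sd
    ``warming_trend_sd``) or a length-``n_regions`` vector of per-region
    trends in °C/year.

    ``accel_trend`` is extra warming per year applied only after the
    baseline window ends: it is the part of recent warming that a
    counterfactual extrapolating the 1981–2010 trend does not contain, so
    it is exactly the factual-minus-counterfactual scenario gap.  The
    defaults are calibrated so the expected 2014–2019 sample-mean anomaly
    is 0.56 °C: trend*(2016.5-1995.5) + accel*(2016.5-2010) = 0.56.
    """

    n_regions: int = 83
    start_year: int = 1981
    end_year: int = 2019
    baseline_start: int = 1981
    baseline_end: int = 2010
    warming_trend: float | Sequence[float] = (0.56 - 0.05 * 6.5) / 21.0
    warming_trend_sd: float = 0.008
    accel_trend: float = 0.05
    region_temp_mean: float = 18.0
    region_temp_sd: float = 6.0
    seasonal_amplitude: float = 8.0
    temp_noise_sd: float = 0.5
    precip_gamma_shape: float | Sequence[float] = 2.0
    precip_gamma_scale: float | Sequence[float] = 40.0
    zero_precip_prob: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.start_year > self.baseline_start:
            raise ValueError("climate must start no later than the baseline window")
        if self.end_year < self.baseline_end:
            raise ValueError("climate must cover the full baseline window")
        if self.temp_noise_sd < 0 or self.warming_trend_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.accel_trend < 0:
            raise ValueError("accel_trend must be >= 0")
        if not (0.0 <= self.zero_precip_prob < 1.0):
            raise ValueError("zero_precip_prob must be in [0, 1)")
        _as_monthly_vector(self.precip_gamma_shape, "precip_gamma_shape")
        _as_monthly_vector(self.precip_gamma_scale, "precip_gamma_scale")

    @property
    def baseline_mid(self) -> float:
        return 0.5 * (self.baseline_start + self.baseline_end)


def region_ids(n: int) -> list[str]:
    return [f"R{i:03d}" for i in range(1, n + 1)]


def simulate_climate(params: ClimateGenParams) -> pd.DataFrame:
    """Monthly temperature and precipitation per region.

    Returns a tidy frame ``region_id, year, month, tmean_c, precip_mm``
    spanning [start_year, end_year]; bit-reproducible given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_regions
    regions = region_ids(n)

    region_mean = rng.normal(params.region_temp_mean, params.region_temp_sd, n)
    trend = np.asarray(params.warming_trend, dtype=float)
    if trend.ndim == 0:
        trend = rng.normal(float(trend), params.warming_trend_sd, n)
    elif trend.shape != (n,):
        raise ValueError("warming_trend vector must have length n_regions")

    years = np.arange(params.start_year, params.end_year + 1)
    months = np.arange(1, 13)
    ny, nm = len(years), 12
    seasonal = params.seasonal_amplitude * np.sin(2 * np.pi * (months - 4) / 12.0)

    post_baseline = np.maximum(years - params.baseline_end, 0.0)
    # (region, year, month)
    tmean = (
        region_mean[:, None, None]
        + trend[:, None, None] * (years - params.baseline_mid)[None, :, None]
        + (params.accel_trend * post_baseline)[None, :, None]
        + seasonal[None, None, :]
        + rng.normal(0.0, params.temp_noise_sd, (n, ny, nm))
    )
    shape_m = _as_monthly_vector(params.precip_gamma_shape, "precip_gamma_shape")
    scale_m = _as_monthly_vector(params.precip_gamma_scale, "precip_gamma_scale")
    precip = rng.gamma(
        np.broadcast_to(shape_m, (n, ny, nm)), np.broadcast_to(scale_m, (n, ny, nm))
    )
    precip[rng.random((n, ny, nm)) < params.zero_precip_prob] = 0.0

    idx = pd.MultiIndex.from_product([regions, years, months], names=["region_id", "year", "month"])
    return pd.DataFrame(
        {"tmean_c": tmean.ravel(), "precip_mm": precip.ravel()}, index=idx
    ).reset_index()


def simulate_shdi(
    regions: Sequence[str],
    years: Sequence[int],
    seed: int = 0,
    base_mean: float = 0.65,
    base_sd: float = 0.06,
    annual_trend: float = 0.004,
    noise_sd: float = 0.004,
) -> pd.DataFrame:
    """Sub-national HDI per region-year: region level + slow upward drift."""
    rng = np.random.default_rng(seed)
    years = np.asarray(list(years))
    base = rng.normal(base_mean, base_sd, len(regions))
    rows = []
    for i, r in enumerate(regions):
        vals = base[i] + annual_trend * (years - years[0]) + rng.normal(0, noise_sd, len(years))
        rows.append(pd.DataFrame({"region_id": r, "year": years, "shdi": np.clip(vals, 0.2, 0.98)}))
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class PanelGenParams:
    """True parameters of the prevalence-generating model.

    Region-year prevalence (0–100 scale) is::

        y_it = base + alpha_i + lambda_t * anomaly_it
               + gamma_shdi * (SHDI_it / 0.1) + gamma_drought * drought_it
               + year_effect_t + noise

    clipped to [0, 100], with the severe outcome additionally constrained
    not to exceed the moderate-to-severe outcome.  Defaults put the sample
    means near the study levels (22.7% moderate-to-severe, 7.9% severe) and
    use the published per-year coefficient paths as truth.
    """

    lambda_path_msfi: tuple[float, ...] = LAMBDA_MSFI
    lambda_path_sfi: tuple[float, ...] = LAMBDA_SFI
    gamma_shdi_msfi: float = -2.7
    gamma_shdi_sfi: float = -2.3
    gamma_drought_msfi: float = 0.014
    gamma_drought_sfi: float = 0.011
    base_msfi: float = 39.2
    base_sfi: float = 22.0
    year_effects_msfi: tuple[float, ...] | None = None
    year_effects_sfi: tuple[float, ...] | None = None
    alpha_sd: float = 2.5
    noise_sd: float = 0.15
    study_start_year: int = 2014
    seed: int = 0

    def __post_init__(self):
        if len(self.lambda_path_msfi) != len(self.lambda_path_sfi):
            raise ValueError("the two lambda paths must have equal length")
        for ye in (self.year_effects_msfi, self.year_effects_sfi):
            if ye is not None and len(ye) != len(self.lambda_path_msfi):
                raise ValueError("year_effects must match the lambda path length")
        if self.alpha_sd < 0 or self.noise_sd < 0:
            raise ValueError("alpha_sd and noise_sd must be >= 0")

    @property
    def study_years(self) -> tuple[int, ...]:
        t = len(self.lambda_path_msfi)
        return tuple(range(self.study_start_year, self.study_start_year + t))


def build_covariates(
    climate: pd.DataFrame,
    study_years: Sequence[int] = STUDY_YEARS,
    baseline: Sequence[int] = ind.DEFAULT_BASELINE,
    spi_calibration_window: Sequence[int] | None = None,
    drought_threshold: float = ind.DROUGHT_THRESHOLD,
) -> pd.DataFrame:
    """Region-year climate covariates for the study window.

    Computes the annual anomaly, monthly-anomaly bin counts, and SPI-6
    drought counts through the indicator operations, merged on
    ``(region_id, year)``.
    """
    study_years = list(study_years)
    anom = ind.annual_temperature_anomaly(climate, baseline, years=study_years)
    if anom["anomaly_c"].isna().any():
        bad = anom.loc[anom["anomaly_c"].isna(), ["region_id", "year"]].iloc[0]
        raise ind.CoverageError(
            f"incomplete climate for region {bad['region_id']} year {bad['year']}"
        )
    missing = set(study_years) - set(anom["year"].unique())
    if missing:
        raise ind.CoverageError(f"climate does not cover study years {sorted(missing)}")
    bins = ind.monthly_anomaly_bins(climate, baseline, years=study_years)
    spi = ind.spi6(climate, spi_calibration_window or baseline)
    drought = ind.drought_count(spi, drought_threshold, years=study_years)
    out = (
        anom.drop(columns="n_months")
        .merge(bins, on=["region_id", "year"], validate="1:1")
        .merge(
            drought[["region_id", "year", "drought_months"]].rename(
                columns={"drought_months": "drought"}
            ),
            on=["region_id", "year"],
            validate="1:1",
        )
    )
    return out


def simulate_outcomes(
    covariates: pd.DataFrame, gen: PanelGenParams, seed: int | None = None
) -> pd.DataFrame:
    """Draw true prevalences for a fixed covariate design.

    ``covariates`` needs ``region_id, year, anomaly_c, shdi_scaled,
    drought``.  Separating the (expensive, deterministic-given-climate)
    covariates from the (cheap) outcome draw lets simulation studies redraw
    outcomes many times on one design.
    """
    rng = np.random.default_rng(gen.seed if seed is None else seed)
    df = covariates.copy()
    years = gen.study_years
    if set(df["year"].unique()) - set(years):
        raise ValueError("covariates contain years outside the study window")
    lam_m = dict(zip(years, gen.lambda_path_msfi))
    lam_s = dict(zip(years, gen.lambda_path_sfi))
    tau_m = dict(zip(years, gen.year_effects_msfi or [0.0] * len(years)))
    tau_s = dict(zip(years, gen.year_effects_sfi or [0.0] * len(years)))

    regions = sorted(df["region_id"].unique())
    alpha_m = dict(zip(regions, rng.normal(0.0, gen.alpha_sd, len(regions))))
    alpha_s = dict(zip(regions, rng.normal(0.0, gen.alpha_sd, len(regions))))

    yr = df["year"].to_numpy()
    anom = df["anomaly_c"].to_numpy(dtype=float)
    shdi_scaled = df["shdi_scaled"].to_numpy(dtype=float)
    drought = df["drought"].to_numpy(dtype=float)
    a_m = df["region_id"].map(alpha_m).to_numpy(dtype=float)
    a_s = df["region_id"].map(alpha_s).to_numpy(dtype=float)
    lam_mv = df["year"].map(lam_m).to_numpy(dtype=float)
    lam_sv = df["year"].map(lam_s).to_numpy(dtype=float)
    tau_mv = df["year"].map(tau_m).to_numpy(dtype=float)
    tau_sv = df["year"].map(tau_s).to_numpy(dtype=float)

    msfi = (
        gen.base_msfi + a_m + tau_mv + lam_mv * anom
        + gen.gamma_shdi_msfi * shdi_scaled + gen.gamma_drought_msfi * drought
        + rng.normal(0.0, gen.noise_sd, len(df))
    )
    sfi = (
        gen.base_sfi + a_s + tau_sv + lam_sv * anom
        + gen.gamma_shdi_sfi * shdi_scaled + gen.gamma_drought_sfi * drought
        + rng.normal(0.0, gen.noise_sd, len(df))
    )
    n_clip = int(((msfi < 0) | (msfi > 100) | (sfi < 0) | (sfi > 100)).sum())
    if n_clip:
        log.info("clipped %d generated prevalences to [0, 100]", n_clip)
    msfi = np.clip(msfi, 0.0, 100.0)
    sfi = np.minimum(np.clip(sfi, 0.0, 100.0), msfi)
    df["msfi_true"] = msfi
    df["sfi_true"] = sfi
    return df


def simulate_panel(
    climate: pd.DataFrame,
    gen: PanelGenParams,
    shdi: pd.DataFrame,
    baseline: Sequence[int] = ind.DEFAULT_BASELINE,
) -> pd.DataFrame:
    """Region-year panel with covariates and true prevalences.

    Covariates come from the indicator operations applied to ``climate``;
    outcomes follow the generating model in :class:`PanelGenParams`.
    """
    cov = build_covariates(climate, gen.study_years, baseline)
    cov = cov.merge(shdi, on=["region_id", "year"], how="left", validate="1:1")
    if cov["shdi"].isna().any():
        bad = cov.loc[cov["shdi"].isna(), ["region_id", "year"]].iloc[0]
        raise ValueError(f"missing SHDI for region {bad['region_id']} year {bad['year']}")
    cov["shdi_scaled"] = cov["shdi"] / 0.1
    return simulate_outcomes(cov, gen)


# ---------------------------------------------------------------------------
# Survey microdata
# ---------------------------------------------------------------------------

def _logistic_location_scale(
    p_m: np.ndarray, p_s: np.ndarray, t_mod: float, t_sev: float
) -> tuple[np.ndarray, np.ndarray]:
    """Solve for the latent logistic (loc, scale) hitting both prevalences.

    With items answered "yes" iff latent > threshold, the moderate-to-severe
    flag is latent > t_mod (item 4's cutoff) and the severe flag is
    latent > t_sev (item 7's cutoff); two logistic survival equations give
    location and scale in closed form.
    """
    eps = 1e-4
    p_m = np.clip(p_m, 2 * eps, 1 - eps)
    p_s = np.clip(p_s, eps, None)
    p_s = np.minimum(p_s, p_m - eps)
    l_m = np.log((1 - p_m) / p_m)
    l_s = np.log((1 - p_s) / p_s)
    scale = (t_sev - t_mod) / (l_s - l_m)
    loc = t_mod - scale * l_m
    return loc, scale


def simulate_fies_responses(
    panel: pd.DataFrame,
    item_thresholds: Sequence[float] = DEFAULT_ITEM_THRESHOLDS,
    respondents_per_region: int = 800,
    seed: int = 0,
    weight_sigma: float = 0.5,
) -> pd.DataFrame:
    """Individual 8-item responses consistent with the panel's prevalences.

    Each respondent draws a latent severity from a logistic distribution
    whose location/scale are solved so the expected share above the item-4
    (item-7) cutoff equals the region-year's true moderate-to-severe
    (severe) prevalence.  Item j is affirmed iff latent > threshold_j, so
    responses are Guttman-structured by construction.  Survey weights are
    positive lognormal draws with mean 1.
    """
    thr = np.asarray(item_thresholds, dtype=float)
    if thr.shape != (8,):
        raise ValueError("item_thresholds must have length 8")
    if not np.all(np.diff(thr) > 0):
        raise ValueError("item_thresholds must be strictly ascending")
    if respondents_per_region < 1:
        raise ValueError("respondents_per_region must be >= 1")
    rng = np.random.default_rng(seed)

    n_cells = len(panel)
    m = respondents_per_region
    loc, scale = _logistic_location_scale(
        panel["msfi_true"].to_numpy(dtype=float) / 100.0,
        panel["sfi_true"].to_numpy(dtype=float) / 100.0,
        t_mod=thr[3],
        t_sev=thr[6],
    )
    u = rng.random((n_cells, m))
    latent = loc[:, None] + scale[:, None] * np.log(u / (1.0 - u))
    answers = (latent[:, :, None] > thr[None, None, :]).astype(np.int8)
    weights = rng.lognormal(-0.5 * weight_sigma**2, weight_sigma, (n_cells, m))

    out = pd.DataFrame(
        {
            "region_id": np.repeat(panel["region_id"].to_numpy(), m),
            "year": np.repeat(panel["year"].to_numpy(), m),
            "weight": weights.ravel(),
        }
    )
    flat = answers.reshape(n_cells * m, 8)
    for j in range(8):
        out[f"q{j + 1}"] = flat[:, j]
    return out
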