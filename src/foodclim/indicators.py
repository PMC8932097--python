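"""Climate covariates from monthly region series.

Four indicators feed the food-insecurity regressions:

* annual temperature anomaly — annual mean temperature minus the region's
  30-year (1981–2010) baseline mean, in °C;
* monthly-anomaly bin counts — months per year whose anomaly (relative to
  the calendar-month baseline climatology) falls in <0.2, [0.2, 0.4),
  [0.4, 0.6), [0.6, 0.8), ≥0.8 °C;
* SPI-6 — six-month Standardized Precipitation Index via a calendar-month
  zero-inflated gamma calibration;
* drought count — months per year with SPI-6 strictly below −1.5.

All functions take tidy monthly climate tables with columns
``region_id, year, month, tmean_c, precip_mm``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

CLIMATE_COLUMNS = ["region_id", "year", "month", "tmean_c", "precip_mm"]

#: Monthly-anomaly bin edges in °C; bins are half-open [a, b).
BIN_EDGES = (0.2, 0.4, 0.6, 0.8)
BIN_LABELS = ("bin_lt02", "bin_02_04", "bin_04_06", "bin_06_08", "bin_ge08")
#: The 0.2–0.4 °C bin is the omitted reference category in binned regressions.
REFERENCE_BIN = "bin_02_04"
NONREF_BINS = tuple(b for b in BIN_LABELS if b != REFERENCE_BIN)

DEFAULT_BASELINE = (1981, 2010)
DROUGHT_THRESHOLD = -1.5
SPI_SCALE_MONTHS = 6


class CoverageError(ValueError):
    """A series does not span the window an operation requires."""


def _require_columns(df: pd.DataFrame, cols: Iterable[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"climate table is missing columns {missing}")


def _baseline_slice(df: pd.DataFrame, baseline: Sequence[int]) -> pd.DataFrame:
    b0, b1 = int(baseline[0]), int(baseline[1])
    if b1 < b0:
        raise ValueError(f"baseline window {baseline} is reversed")
    return df[(df["year"] >= b0) & (df["year"] <= b1)]


def _check_baseline_coverage(region: str, base: pd.DataFrame, baseline: Sequence[int]) -> None:
    b0, b1 = int(baseline[0]), int(baseline[1])
    expected = 12 * (b1 - b0 + 1)
    if len(base) != expected or base["tmean_c"].isna().any():
        raise CoverageError(
            f"region {region}: baseline {b0}-{b1} needs {expected} complete "
            f"months, found {len(base) - int(base['tmean_c'].isna().sum())}"
        )


def annual_temperature_anomaly(
    climate: pd.DataFrame,
    baseline: Sequence[int] = DEFAULT_BASELINE,
    years: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Annual mean temperature minus the full-baseline mean, per region-year.

    The baseline mean is the average of all monthly temperatures in the
    (inclusive) baseline window.  Years with fewer than 12 months get a NaN
    anomaly and are flagged via ``n_months``.

    Returns a frame with columns ``region_id, year, anomaly_c, n_months``.
    """
    _require_columns(climate, ["region_id", "year", "month", "tmean_c"])
    out = []
    for region, grp in climate.groupby("region_id", sort=True):
        base = _baseline_slice(grp, baseline)
        _check_baseline_coverage(region, base, baseline)
        base_mean = base["tmean_c"].mean()
        ann = grp.groupby("year")["tmean_c"].agg(["mean", "count"]).reset_index()
        ann["anomaly_c"] = ann["mean"] - base_mean
        ann.loc[ann["count"] < 12, "anomaly_c"] = np.nan
        ann["region_id"] = region
        out.append(ann.rename(columns={"count": "n_months"})[
            ["region_id", "year", "anomaly_c", "n_months"]])
    res = pd.concat(out, ignore_index=True)
    if years is not None:
        res = res[res["year"].isin(list(years))].reset_index(drop=True)
    return res


def monthly_anomaly_bins(
    climate: pd.DataFrame,
    baseline: Sequence[int] = DEFAULT_BASELINE,
    years: Sequence[int] | None = None,
    edges: Sequence[float] = BIN_EDGES,
) -> pd.DataFrame:
    """Count months per region-year in each monthly-anomaly bin.

    The monthly anomaly is the month's temperature minus that calendar
    month's baseline mean (a calendar-month climatology, so the seasonal
    cycle does not leak into the bins).  Bins are half-open ``[a, b)``:
    an anomaly of exactly 0.4 °C falls in the 0.4–0.6 bin.
    """
    _require_columns(climate, ["region_id", "year", "month", "tmean_c"])
    edges = np.asarray(edges, dtype=float)
    out = []
    for region, grp in climate.groupby("region_id", sort=True):
        base = _baseline_slice(grp, baseline)
        _check_baseline_coverage(region, base, baseline)
        climatology = base.groupby("month")["tmean_c"].mean()
        anom = grp["tmean_c"].to_numpy() - climatology.reindex(grp["month"]).to_numpy()
        idx = np.digitize(anom, edges, right=False)  # 0 => <0.2, 4 => >=0.8
        counts = (
            pd.DataFrame({"year": grp["year"].to_numpy(), "bin": idx})
            .pivot_table(index="year", columns="bin", aggfunc="size", fill_value=0)
            .reindex(columns=range(len(edges) + 1), fill_value=0)
        )
        counts.columns = list(BIN_LABELS)
        counts = counts.reset_index()
        counts["region_id"] = region
        out.append(counts[["region_id", "year", *BIN_LABELS]])
    res = pd.concat(out, ignore_index=True)
    if years is not None:
        res = res[res["year"].isin(list(years))].reset_index(drop=True)
    return res


# ---------------------------------------------------------------------------
# SPI-6
# ---------------------------------------------------------------------------

def accumulate_precip(climate: pd.DataFrame, scale_months: int = SPI_SCALE_MONTHS) -> pd.DataFrame:
    """Rolling ``scale_months``-month precipitation sum ending in each month.

    Requires contiguous monthly coverage per region; the first
    ``scale_months - 1`` months are NaN.
    """
    _require_columns(climate, ["region_id", "year", "month", "precip_mm"])
    if (climate["precip_mm"] < 0).any():
        bad = climate.index[climate["precip_mm"] < 0][0]
        raise ValueError(f"negative precipitation at row {bad}")
    out = []
    for region, grp in climate.groupby("region_id", sort=True):
        grp = grp.sort_values(["year", "month"])
        stamp = grp["year"].to_numpy() * 12 + grp["month"].to_numpy()
        if len(stamp) > 1 and not np.all(np.diff(stamp) == 1):
            raise CoverageError(f"region {region}: monthly series is not contiguous")
        acc = grp["precip_mm"].rolling(scale_months, min_periods=scale_months).sum()
        out.append(pd.DataFrame({
            "region_id": region,
            "year": grp["year"].to_numpy(),
            "month": grp["month"].to_numpy(),
            "accum_mm": acc.to_numpy(),
        }))
    return pd.concat(out, ignore_index=True)


def _fit_gamma_pos(x: np.ndarray) -> tuple[float, float]:
    """Gamma (shape, scale) for positive accumulations: ML with MoM fallback."""
    mean, var = float(np.mean(x)), float(np.var(x, ddof=1)) if len(x) > 1 else 0.0
    mom = (mean * mean / var, var / mean) if var > 0 else (np.nan, np.nan)
    try:
        shape, _, scale = stats.gamma.fit(x, floc=0)
    except Exception:  # pragma: no cover - scipy convergence failure
        return mom
    if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
        return mom
    return float(shape), float(scale)


@dataclass(frozen=True)
class SPICalibration:
    """Per-(region, calendar month) zero-inflated gamma SPI parameters.

    ``params`` has columns ``region_id, month, zero_prob, shape, scale,
    n_cal``; shape/scale are NaN where every calibration accumulation was
    zero (SPI undefined for such months).
    """

    window: tuple[int, int]
    scale_months: int
    params: pd.DataFrame

    def transform(self, accum: pd.DataFrame) -> pd.DataFrame:
        """Map 6-month accumulations to SPI using the calibration parameters.

        ``H(x) = q + (1 - q) * GammaCDF(x)`` with q the calibration share of
        zero accumulations; SPI is the standard-normal quantile of H, so it
        applies unchanged to months outside the calibration window.
        """
        df = accum.merge(self.params, on=["region_id", "month"], how="left", validate="m:1")
        x = df["accum_mm"].to_numpy(dtype=float)
        q = df["zero_prob"].to_numpy(dtype=float)
        shape = df["shape"].to_numpy(dtype=float)
        scale = df["scale"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            h = q + (1.0 - q) * stats.gamma.cdf(x, shape, scale=scale)
        h = np.where(x == 0, q, h)
        eps = 1e-6
        spi = stats.norm.ppf(np.clip(h, eps, 1.0 - eps))
        spi = np.where(np.isnan(x) | np.isnan(shape), np.nan, spi)
        out = accum.copy()
        out["spi6"] = spi
        return out


def fit_spi_calibration(
    climate: pd.DataFrame,
    window: Sequence[int] = DEFAULT_BASELINE,
    scale_months: int = SPI_SCALE_MONTHS,
) -> SPICalibration:
    """Fit the per-calendar-month zero-inflated gamma SPI calibration.

    For each region and calendar month, the positive 6-month accumulations in
    the calibration window are fitted by a gamma distribution (ML, zero
    location); the point mass at zero gets probability equal to the observed
    share of zero accumulations.  Months whose accumulations are all zero are
    flagged (NaN parameters) and yield NaN SPI downstream.
    """
    acc = accumulate_precip(climate, scale_months)
    w0, w1 = int(window[0]), int(window[1])
    cal = acc[(acc["year"] >= w0) & (acc["year"] <= w1) & acc["accum_mm"].notna()]
    if cal.empty:
        raise CoverageError(f"no accumulations inside calibration window {w0}-{w1}")
    rows = []
    for (region, month), grp in cal.groupby(["region_id", "month"], sort=True):
        vals = grp["accum_mm"].to_numpy(dtype=float)
        pos = vals[vals > 0]
        q = float(np.mean(vals == 0))
        if len(pos) == 0:
            log.warning("SPI undefined for region %s month %d: all-zero accumulations", region, month)
            shape, scale = np.nan, np.nan
        else:
            shape, scale = _fit_gamma_pos(pos)
        rows.append((region, int(month), q, shape, scale, len(vals)))
    params = pd.DataFrame(rows, columns=["region_id", "month", "zero_prob", "shape", "scale", "n_cal"])
    return SPICalibration(window=(w0, w1), scale_months=scale_months, params=params)


def spi6(
    climate: pd.DataFrame,
    calibration_window: Sequence[int] = DEFAULT_BASELINE,
    calibration: SPICalibration | None = None,
) -> pd.DataFrame:
    """Six-month SPI for every region-month in ``climate``.

    Returns ``region_id, year, month, accum_mm, spi6``; pass a prefitted
    ``calibration`` to transform new data with frozen parameters.
    """
    if calibration is None:
        calibration = fit_spi_calibration(climate, calibration_window)
    acc = accumulate_precip(climate, calibration.scale_months)
    return calibration.transform(acc)


def drought_count(
    spi: pd.DataFrame,
    threshold: float = DROUGHT_THRESHOLD,
    years: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Months per region-year with SPI strictly below ``threshold``.

    ``n_months`` counts months with a defined SPI; a year with fewer than 12
    is a partial count (flagged by that column, not an error).
    """
    _require_columns(spi, ["region_id", "year", "spi6"])
    ok = spi["spi6"].notna()
    df = spi.assign(_hit=(spi["spi6"] < threshold) & ok, _ok=ok)
    res = (
        df.groupby(["region_id", "year"], sort=True)[["_hit", "_ok"]]
        .sum()
        .reset_index()
        .rename(columns={"_hit": "drought_months", "_ok": "n_months"})
    )
    res["drought_months"] = res["drought_months"].astype(int)
    res["n_months"] = res["n_months"].astype(int)
    if years is not None:
        res = res[res["year"].isin(list(years))].reset_index(drop=True)
    return res


# ---------------------------------------------------------------------------
# Grid-to-region aggregation
# ---------------------------------------------------------------------------

def grid_to_region(field, masks: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Weight-normalised spatial mean of a gridded field per region.

    Parameters
    ----------
    field
        ``xarray.DataArray`` or ``xarray.Dataset`` with a leading ``time``
        dimension and one or more spatial dimensions.
    masks
        Mapping region_id -> non-negative weight array matching the spatial
        shape.  Weights need not be normalised; each region needs at least
        one positive cell.

    Returns a tidy frame with ``region_id, time`` plus one column per
    variable.  If the time coordinate is datetime-like, ``year`` and
    ``month`` columns are added.
    """
    import xarray as xr

    if isinstance(field, xr.DataArray):
        ds = field.to_dataset(name=field.name or "value")
    else:
        ds = field
    time = np.asarray(ds["time"].values)
    spatial_shape = tuple(ds.sizes[d] for d in ds[list(ds.data_vars)[0]].dims if d != "time")
    rows = {}
    for region, w in masks.items():
        w = np.asarray(w, dtype=float)
        if w.shape != spatial_shape:
            raise ValueError(f"mask for region {region} has shape {w.shape}, grid is {spatial_shape}")
        if (w < 0).any():
            raise ValueError(f"mask for region {region} has negative weights")
        total = w.sum()
        if total <= 0:
            raise CoverageError(f"mask for region {region} has no positive weight")
        wflat = (w / total).ravel()
        rec = {"region_id": region, "time": time}
        for var in ds.data_vars:
            arr = np.asarray(ds[var].values).reshape(len(time), -1)
            rec[var] = arr @ wflat
        rows[region] = pd.DataFrame(rec)
    out = pd.concat(rows.values(), ignore_index=True)
    if np.issubdtype(out["time"].dtype, np.datetime64):
        ts = pd.DatetimeIndex(out["time"])
        out["year"] = ts.year
        out["month"] = ts.month
    return out
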