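"""Counterfactual attribution of food insecurity to temperature anomalies.

The question: how much higher is predicted food-insecurity prevalence under
the observed (factual) warming than it would have been had each region's
temperature merely followed its 1981–2010 historical trend?  The default
counterfactual extrapolates a per-region linear trend fitted to baseline
annual means; externally supplied counterfactual anomaly series (e.g. from
natural-forcing climate-model runs aggregated to regions) can be passed in
the same scenario-table format instead.

Differences are reported as factual minus counterfactual, so a positive
number means climate change worsened food insecurity.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .indicators import CoverageError, DEFAULT_BASELINE, annual_temperature_anomaly
from .regression import PanelFit

log = logging.getLogger(__name__)

STUDY_YEARS = tuple(range(2014, 2020))


def counterfactual_anomaly(
    climate: pd.DataFrame,
    baseline: Sequence[int] = DEFAULT_BASELINE,
    study_years: Sequence[int] = STUDY_YEARS,
) -> pd.DataFrame:
    """Factual vs trend-extrapolated counterfactual anomalies per region-year.

    A linear trend is fitted by least squares to each region's baseline
    annual mean temperatures; the counterfactual anomaly in study year y is
    the trend-line value at y minus the baseline mean.  Returns
    ``region_id, year, anomaly_factual, anomaly_counterfactual``.
    """
    study_years = list(study_years)
    fact = annual_temperature_anomaly(climate, baseline, years=study_years)
    if fact["anomaly_c"].isna().any():
        bad = fact.loc[fact["anomaly_c"].isna()].iloc[0]
        raise CoverageError(
            f"incomplete factual year {bad['year']} for region {bad['region_id']}"
        )
    b0, b1 = int(baseline[0]), int(baseline[1])
    rows = []
    for region, grp in climate.groupby("region_id", sort=True):
        base = grp[(grp["year"] >= b0) & (grp["year"] <= b1)]
        ann = base.groupby("year")["tmean_c"].agg(["mean", "count"])
        if len(ann) != b1 - b0 + 1 or (ann["count"] != 12).any():
            raise CoverageError(f"region {region}: incomplete baseline {b0}-{b1}")
        slope, intercept = np.polyfit(ann.index.to_numpy(dtype=float), ann["mean"].to_numpy(), 1)
        base_mean = base["tmean_c"].mean()
        for y in study_years:
            rows.append((region, y, intercept + slope * y - base_mean))
    cf = pd.DataFrame(rows, columns=["region_id", "year", "anomaly_counterfactual"])
    out = fact.rename(columns={"anomaly_c": "anomaly_factual"}).drop(columns="n_months")
    return out.merge(cf, on=["region_id", "year"], validate="1:1")


def predict_prevalence(
    fit: PanelFit,
    panel: pd.DataFrame,
    anomalies: pd.Series | np.ndarray | None = None,
    clip: bool = True,
) -> pd.DataFrame:
    """Model-predicted prevalence per region-year under a scenario.

    ``anomalies`` replaces the panel's anomaly column (aligned row-wise);
    ``None`` uses the factual column, reproducing in-sample fitted values.
    Predictions are clipped to [0, 100] with a logged count unless
    ``clip=False``.
    """
    if fit.anomaly_col is None:
        raise ValueError("prediction requires an anomaly-based fit")
    unknown = sorted(set(panel["region_id"]) - set(fit.regions))
    if unknown:
        raise ValueError(f"regions {unknown} have no estimated fixed effect")
    unknown_years = sorted(set(panel["year"]) - set(fit.years))
    if unknown_years:
        raise ValueError(f"years {unknown_years} are outside the fitted window")
    v = (
        panel[fit.anomaly_col].to_numpy(dtype=float)
        if anomalies is None
        else np.asarray(anomalies, dtype=float)
    )
    if len(v) != len(panel):
        raise ValueError("scenario anomalies must align with the panel rows")
    pred = (
        panel["region_id"].map(fit.alpha_hat).to_numpy(dtype=float)
        + panel["year"].map(fit.year_effects).to_numpy(dtype=float)
        + panel["year"].map(fit.lambda_hat).to_numpy(dtype=float) * v
    )
    for name, g in fit.gamma_hat.items():
        pred = pred + g * panel[name].to_numpy(dtype=float)
    out = panel[["region_id", "year"]].copy()
    if clip:
        n_clip = int(((pred < 0) | (pred > 100)).sum())
        if n_clip:
            log.info("clipped %d predictions to [0, 100]", n_clip)
        pred = np.clip(pred, 0.0, 100.0)
    out["predicted"] = pred
    return out


def attribution_differences(table: pd.DataFrame) -> pd.DataFrame:
    """Add the percentage-point difference column, factual minus counterfactual.

    ``table`` needs ``prevalence_factual`` and ``prevalence_counterfactual``
    columns (percent); the returned copy gains ``difference`` computed
    exactly as their subtraction.
    """
    for c in ("prevalence_factual", "prevalence_counterfactual"):
        if c not in table.columns:
            raise ValueError(f"attribution table is missing column {c!r}")
    out = table.copy()
    out["difference"] = out["prevalence_factual"] - out["prevalence_counterfactual"]
    return out


def _group_weights(
    panel: pd.DataFrame, group_map: pd.DataFrame, weights: pd.DataFrame | None
) -> pd.DataFrame:
    if set(group_map.columns) < {"region_id", "group"}:
        raise ValueError("group map needs columns region_id, group")
    if group_map["region_id"].duplicated().any():
        dup = group_map.loc[group_map["region_id"].duplicated(), "region_id"].iloc[0]
        raise ValueError(f"region {dup} is mapped to more than one group")
    df = panel[["region_id", "year"]].merge(group_map, on="region_id", how="left", validate="m:1")
    if df["group"].isna().any():
        bad = df.loc[df["group"].isna(), "region_id"].iloc[0]
        raise ValueError(f"region {bad} is not mapped to a group")
    if weights is None:
        df["w"] = 1.0
    else:
        df = df.merge(weights.rename(columns={"weight": "w"}), on="region_id", how="left", validate="m:1")
        if df["w"].isna().any() or (df["w"] < 0).any():
            raise ValueError("every region needs a non-negative aggregation weight")
    empty = set(group_map["group"]) - set(df["group"])
    if empty:
        raise ValueError(f"empty group(s): {sorted(empty)}")
    return df


def attribute(
    fits: Mapping[str, PanelFit],
    panel: pd.DataFrame,
    scenarios: pd.DataFrame,
    group_map: pd.DataFrame,
    weights: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group-level factual vs counterfactual prevalence per outcome.

    For each fitted outcome, region-year prevalence is predicted under the
    factual and counterfactual anomaly scenarios and averaged (weighted by
    region weights, equal by default) over each group's region-years.
    Predictions are deliberately not clipped so the difference is exactly
    linear in the estimated anomaly coefficients, which also yields a
    delta-method CI on the difference from the coefficient covariance.

    Returns one row per group with, per outcome key ``k``: ``k_factual``,
    ``k_counterfactual``, ``k_difference``, ``k_diff_se``, ``k_diff_ci_low``,
    ``k_diff_ci_high``.
    """
    sc = panel[["region_id", "year"]].merge(
        scenarios, on=["region_id", "year"], how="left", validate="1:1"
    )
    for c in ("anomaly_factual", "anomaly_counterfactual"):
        if c not in sc.columns or sc[c].isna().any():
            raise ValueError(f"scenario table must supply {c!r} for every panel region-year")
    gw = _group_weights(panel, group_map, weights)
    groups = sorted(gw["group"].unique())
    out = pd.DataFrame({"group": groups}).set_index("group")
    dv = (sc["anomaly_factual"] - sc["anomaly_counterfactual"]).to_numpy()

    for key, fit in fits.items():
        pf = predict_prevalence(fit, panel, sc["anomaly_factual"], clip=False)["predicted"]
        pc = predict_prevalence(fit, panel, sc["anomaly_counterfactual"], clip=False)["predicted"]
        lam_names = [f"{fit.anomaly_col}:year[{y}]" for y in fit.lambda_hat.index]
        if lam_names[0] in fit.vcov.index:
            Vl = fit.vcov.loc[lam_names, lam_names].to_numpy()
        else:  # constant-slope fit: one-dimensional covariance
            Vl = np.full((len(lam_names), len(lam_names)), fit.vcov.loc[fit.anomaly_col, fit.anomaly_col])
        crit = stats.t.ppf(1 - alpha / 2, fit.df_inference) if fit.use_t else stats.norm.ppf(1 - alpha / 2)
        for g in groups:
            mask = (gw["group"] == g).to_numpy()
            w = gw.loc[mask, "w"].to_numpy()
            tot = w.sum()
            if tot <= 0:
                raise ValueError(f"group {g} has zero total weight")
            out.loc[g, f"{key}_factual"] = float((w * pf.to_numpy()[mask]).sum() / tot)
            out.loc[g, f"{key}_counterfactual"] = float((w * pc.to_numpy()[mask]).sum() / tot)
            # gradient of the group difference w.r.t. the per-year slopes
            a = np.array(
                [
                    (w * dv[mask] * (gw.loc[mask, "year"] == y).to_numpy()).sum() / tot
                    for y in fit.lambda_hat.index
                ]
            )
            out.loc[g, f"{key}_diff_se"] = float(np.sqrt(a @ Vl @ a))
        out[f"{key}_difference"] = out[f"{key}_factual"] - out[f"{key}_counterfactual"]
        out[f"{key}_diff_ci_low"] = out[f"{key}_difference"] - crit * out[f"{key}_diff_se"]
        out[f"{key}_diff_ci_high"] = out[f"{key}_difference"] + crit * out[f"{key}_diff_se"]
    return out.reset_index()


def attribution_long(result: pd.DataFrame) -> pd.DataFrame:
    """Tidy long view of :func:`attribute` output."""
    rows = []
    for _, row in result.iterrows():
        keys = sorted({c.rsplit("_", 1)[0] for c in result.columns if c.endswith("_factual")})
        for k in keys:
            rows.append(
                {
                    "group": row["group"],
                    "outcome": k,
                    "prevalence_factual": row[f"{k}_factual"],
                    "prevalence_counterfactual": row[f"{k}_counterfactual"],
                    "difference": row[f"{k}_difference"],
                    "diff_se": row[f"{k}_diff_se"],
                }
            )
    return pd.DataFrame(rows)
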