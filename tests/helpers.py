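"""Shared builders for hand-constructed test inputs."""

from __future__ import annotations

import numpy as np
import pandas as pd

from foodclim.regression import PanelFit


def month_frame(region, years, temp_fn, precip_fn=None):
    """Monthly climate frame from closed-form temperature/precip functions."""
    precip_fn = precip_fn or (lambda y, m: 50.0)
    rows = [
        (region, y, m, temp_fn(y, m), precip_fn(y, m))
        for y in years
        for m in range(1, 13)
    ]
    return pd.DataFrame(rows, columns=["region_id", "year", "month", "tmean_c", "precip_mm"])


def toy_panel(
    n_regions=5,
    years=range(2014, 2020),
    seed=0,
    beta_anomaly=2.0,
    gamma_shdi=-2.0,
    gamma_drought=0.01,
    noise_sd=0.0,
    lambda_path=None,
):
    """Region-year panel generated from known coefficients by hand.

    ``lambda_path`` (one slope per year) overrides the constant
    ``beta_anomaly``; region and year intercepts are random so fixed
    effects are genuinely needed.
    """
    rng = np.random.default_rng(seed)
    years = list(years)
    regions = [f"T{i:02d}" for i in range(n_regions)]
    alpha = dict(zip(regions, rng.normal(20.0, 5.0, n_regions)))
    tau = dict(zip(years, np.concatenate([[0.0], rng.normal(0.0, 1.0, len(years) - 1)])))
    lam = dict(zip(years, lambda_path)) if lambda_path is not None else {y: beta_anomaly for y in years}
    rows = []
    for r in regions:
        for y in years:
            v = rng.normal(0.5, 0.3)
            shdi = rng.normal(6.5, 0.5)
            dr = float(rng.poisson(1.0))
            out = (
                alpha[r] + tau[y] + lam[y] * v + gamma_shdi * shdi + gamma_drought * dr
                + rng.normal(0.0, noise_sd)
            )
            rows.append((r, y, v, shdi, dr, out))
    return pd.DataFrame(
        rows, columns=["region_id", "year", "anomaly_c", "shdi_scaled", "drought", "y"]
    )


def manual_fit(regions, years, lam, alpha=10.0, outcome="msfi", se_lambda=0.0):
    """PanelFit with hand-set coefficients (no controls, zero year effects)."""
    years = [int(y) for y in years]
    lam = {int(y): (lam[y] if isinstance(lam, dict) else lam) for y in years}
    names = [f"region[{r}]" for r in regions] + [f"anomaly_c:year[{y}]" for y in years]
    values = [alpha] * len(regions) + [lam[y] for y in years]
    params = pd.Series(values, index=names, dtype=float)
    vcov = pd.DataFrame(0.0, index=names, columns=names)
    for y in years:
        n = f"anomaly_c:year[{y}]"
        vcov.loc[n, n] = se_lambda**2
    return PanelFit(
        spec="tvc",
        outcome=outcome,
        params=params,
        vcov=vcov,
        n_obs=len(regions) * len(years),
        n_clusters=len(regions),
        df_inference=max(len(regions) - 1, 1),
        years=years,
        regions=list(regions),
        anomaly_col="anomaly_c",
    )
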