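"""Fixed-effects panel regressions with time-varying coefficients.

The central model regresses region-year food-insecurity prevalence (0–100
scale) on the annual temperature anomaly with a separate slope per study
year, controlling for sub-national HDI (in units of 0.1) and the annual
drought count, with region fixed effects and year intercepts::

    y_it = alpha_i + tau_t + lambda_t * V_it + gamma' X_it + u_it

Variants: a constant-coefficient specification (single slope per
covariate), and "binned" specifications in which the regressors are counts
of months per monthly-anomaly bin (the 0.2–0.4 °C bin omitted as
reference), with or without year-varying bin coefficients.

Estimation is dummy-variable least squares; inference defaults to a
cluster-robust (by region) sandwich covariance with the G/(G-1) x
(n-1)/(n-p) small-sample factor and t(G-1) critical values, with classical
and HC1 covariances available.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .indicators import NONREF_BINS

log = logging.getLogger(__name__)

DEFAULT_CONTROLS = ("shdi_scaled", "drought")


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; ``columns`` names the culprits."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")


@dataclass
class PanelFit:
    """A fitted panel regression.

    ``params``/``vcov`` hold every coefficient by name: ``region[R]`` for
    fixed effects, ``year[t]`` for year intercepts (first study year
    omitted), ``<var>:year[t]`` for year-varying slopes, and bare covariate
    names for constant slopes.
    """

    spec: str
    outcome: str
    params: pd.Series
    vcov: pd.DataFrame
    n_obs: int
    n_clusters: int | None
    df_inference: float
    years: list[int]
    regions: list[str]
    anomaly_col: str | None = None
    use_t: bool = True
    n_dropped: int = 0

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov.to_numpy())), index=self.params.index)

    def _crit(self, alpha: float = 0.05) -> float:
        if self.use_t:
            return float(stats.t.ppf(1 - alpha / 2, self.df_inference))
        return float(stats.norm.ppf(1 - alpha / 2))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        c = self._crit(alpha)
        se = self.se
        return pd.DataFrame(
            {"ci_low": self.params - c * se, "ci_high": self.params + c * se}
        )

    # -- named blocks -------------------------------------------------
    def _year_varying(self, var: str) -> pd.Series:
        prefix = f"{var}:year["
        sel = {int(k[len(prefix):-1]): v for k, v in self.params.items() if k.startswith(prefix)}
        return pd.Series(sel).sort_index()

    @property
    def lambda_hat(self) -> pd.Series:
        """Per-year anomaly slopes (empty for constant/binned specs)."""
        if self.anomaly_col is None:
            return pd.Series(dtype=float)
        tv = self._year_varying(self.anomaly_col)
        if tv.empty and self.anomaly_col in self.params.index:
            return pd.Series(
                {y: self.params[self.anomaly_col] for y in self.years}
            )
        return tv

    @property
    def lambda_se(self) -> pd.Series:
        names = [f"{self.anomaly_col}:year[{y}]" for y in self.lambda_hat.index]
        if names and names[0] not in self.params.index:
            names = [self.anomaly_col] * len(self.lambda_hat)
        return pd.Series(self.se[names].to_numpy(), index=self.lambda_hat.index)

    def lambda_ci(self, alpha: float = 0.05) -> pd.DataFrame:
        c = self._crit(alpha)
        lam, se = self.lambda_hat, self.lambda_se
        return pd.DataFrame({"estimate": lam, "ci_low": lam - c * se, "ci_high": lam + c * se})

    @property
    def alpha_hat(self) -> pd.Series:
        sel = {k[7:-1]: v for k, v in self.params.items() if k.startswith("region[")}
        return pd.Series(sel)

    @property
    def year_effects(self) -> pd.Series:
        sel = {int(k[5:-1]): v for k, v in self.params.items() if k.startswith("year[") }
        ser = pd.Series(sel, dtype=float)
        for y in self.years:
            if y not in ser.index:
                ser[y] = 0.0  # omitted reference year
        return ser.sort_index()

    @property
    def gamma_hat(self) -> pd.Series:
        keep = [
            k for k in self.params.index
            if not (k.startswith("region[") or k.startswith("year[") or ":year[" in k)
        ]
        if self.anomaly_col in keep:
            keep.remove(self.anomaly_col)
        return self.params[keep]

    def tidy(self) -> pd.DataFrame:
        """Long coefficient table: term, year, estimate, se, ci, p."""
        se = self.se
        ci = self.conf_int()
        rows = []
        for name in self.params.index:
            year = None
            term = name
            if ":year[" in name:
                term, y = name.split(":year[")
                year = int(y[:-1])
            elif name.startswith("year["):
                term, year = "year_intercept", int(name[5:-1])
            stat = self.params[name] / se[name] if se[name] > 0 else np.nan
            if self.use_t:
                p = 2 * stats.t.sf(abs(stat), self.df_inference)
            else:
                p = 2 * stats.norm.sf(abs(stat))
            rows.append(
                (term, year, self.params[name], se[name], ci.loc[name, "ci_low"],
                 ci.loc[name, "ci_high"], p)
            )
        return pd.DataFrame(
            rows, columns=["term", "year", "estimate", "se", "ci_low", "ci_high", "p"]
        )

    # -- persistence --------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "spec": self.spec,
            "outcome": self.outcome,
            "param_names": list(self.params.index),
            "params": self.params.to_numpy().tolist(),
            "vcov": self.vcov.to_numpy().tolist(),
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
            "df_inference": self.df_inference,
            "years": [int(y) for y in self.years],
            "regions": list(self.regions),
            "anomaly_col": self.anomaly_col,
            "use_t": self.use_t,
            "n_dropped": self.n_dropped,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PanelFit":
        with open(path) as fh:
            d = json.load(fh)
        names = d.pop("param_names")
        d["params"] = pd.Series(d["params"], index=names)
        d["vcov"] = pd.DataFrame(d["vcov"], index=names, columns=names)
        return cls(**d)


# ---------------------------------------------------------------------------
# Core least squares with sandwich covariances
# ---------------------------------------------------------------------------

def _ols(
    X: pd.DataFrame,
    y: np.ndarray,
    clusters: np.ndarray | None,
    cov: str = "cluster",
) -> tuple[pd.Series, pd.DataFrame, float, int | None]:
    """Least squares with classical / HC1 / cluster-robust covariance.

    Returns (params, vcov, df_inference, n_clusters).  Raises
    :class:`RankDeficientError` naming collinear columns.
    """
    names = list(X.columns)
    A = X.to_numpy(dtype=float)
    n, p = A.shape
    if n <= p:
        raise ValueError(f"{n} observations cannot identify {p} parameters")

    _, R, piv = linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(A.shape) * np.finfo(float).eps if diag[0] > 0 else 0.0
    rank = int(np.sum(diag > tol))
    if rank < p:
        raise RankDeficientError([names[j] for j in sorted(piv[rank:])])

    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    xtx_inv = np.linalg.inv(A.T @ A)

    if cov == "classical":
        sigma2 = float(resid @ resid) / (n - p)
        V = sigma2 * xtx_inv
        dfi, G = float(n - p), None
    elif cov == "hc1":
        scores = A * resid[:, None]
        meat = scores.T @ scores
        V = (n / (n - p)) * xtx_inv @ meat @ xtx_inv
        dfi, G = float(n - p), None
    elif cov == "cluster":
        if clusters is None:
            raise ValueError("cluster covariance requires cluster labels")
        scores = pd.DataFrame(A * resid[:, None]).groupby(clusters).sum().to_numpy()
        G = scores.shape[0]
        if G < 2:
            raise ValueError("cluster covariance requires at least 2 clusters")
        meat = scores.T @ scores
        c = (G / (G - 1)) * ((n - 1) / (n - p))
        V = c * xtx_inv @ meat @ xtx_inv
        dfi = float(G - 1)
    else:
        raise ValueError(f"unknown covariance {cov!r}")
    return (
        pd.Series(beta, index=names),
        pd.DataFrame(V, index=names, columns=names),
        dfi,
        G,
    )


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _check_panel(panel: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    for c in ("region_id", "year", *cols):
        if c not in panel.columns:
            raise ValueError(f"panel is missing column {c!r}")
    if panel.duplicated(["region_id", "year"]).any():
        dup = panel[panel.duplicated(["region_id", "year"])].iloc[0]
        raise ValueError(f"duplicated panel key ({dup['region_id']}, {dup['year']})")
    use = panel[["region_id", "year", *cols]]
    complete = use.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("listwise-deleted %d incomplete panel rows", n_dropped)
    out = use[complete].reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    return out


def _build_design(
    df: pd.DataFrame,
    covariates: Sequence[str],
    tv_covariates: Sequence[str],
    region_fe: bool,
    year_intercepts: bool,
    years: Sequence[int],
    regions: Sequence[str],
) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    if region_fe:
        for r in regions:
            cols[f"region[{r}]"] = (df["region_id"] == r).to_numpy(dtype=float)
    else:
        cols["const"] = np.ones(len(df))
    if year_intercepts:
        for y in years[1:]:
            cols[f"year[{y}]"] = (df["year"] == y).to_numpy(dtype=float)
    for v in covariates:
        x = df[v].to_numpy(dtype=float)
        if v in tv_covariates:
            for y in years:
                cols[f"{v}:year[{y}]"] = x * (df["year"] == y).to_numpy(dtype=float)
        else:
            cols[v] = x
    return pd.DataFrame(cols, index=df.index)


def _fit(
    panel: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    tv_covariates: Sequence[str],
    spec: str,
    anomaly_col: str | None,
    region_fe: bool = True,
    year_intercepts: bool = True,
    cov: str = "cluster",
) -> PanelFit:
    df = _check_panel(panel, [outcome, *covariates])
    years = sorted(df["year"].unique())
    regions = sorted(df["region_id"].unique())
    for v in tv_covariates:
        var_by_year = df.groupby("year")[v].std(ddof=0)
        degenerate = var_by_year[var_by_year == 0]
        if len(degenerate):
            raise ValueError(
                f"covariate {v!r} has zero cross-sectional variance in year(s) "
                f"{list(degenerate.index)}; its year-specific slope is not identified"
            )
    counts = df.groupby("region_id").size()
    if region_fe and (counts < 2).any() and len(years) > 1:
        log.warning("%d region(s) contribute a single observation", int((counts < 2).sum()))
    X = _build_design(df, covariates, tv_covariates, region_fe, year_intercepts, years, regions)
    y = df[outcome].to_numpy(dtype=float)
    clusters = df["region_id"].to_numpy() if cov == "cluster" else None
    params, vcov, dfi, G = _ols(X, y, clusters, cov)
    return PanelFit(
        spec=spec,
        outcome=outcome,
        params=params,
        vcov=vcov,
        n_obs=len(df),
        n_clusters=G,
        df_inference=dfi,
        years=[int(y_) for y_ in years],
        regions=regions,
        anomaly_col=anomaly_col,
        use_t=True,
        n_dropped=df.attrs["n_dropped"],
    )


def fit_fe_constant(
    panel: pd.DataFrame,
    outcome: str,
    anomaly_col: str = "anomaly_c",
    controls: Sequence[str] = DEFAULT_CONTROLS,
    cov: str = "cluster",
    year_intercepts: bool = True,
) -> PanelFit:
    """Two-way fixed-effects regression with one constant slope per covariate."""
    return _fit(
        panel, outcome, [anomaly_col, *controls], [], "constant", anomaly_col,
        year_intercepts=year_intercepts, cov=cov,
    )


def fit_tvc(
    panel: pd.DataFrame,
    outcome: str,
    anomaly_col: str = "anomaly_c",
    controls: Sequence[str] = DEFAULT_CONTROLS,
    tv_controls: bool = False,
    region_fe: bool = True,
    year_intercepts: bool = True,
    cov: str = "cluster",
    constrain_equal: bool = False,
) -> PanelFit:
    """Time-varying-coefficient fit: a separate anomaly slope per year.

    The default keeps year intercepts alongside anomaly-only time variation
    (one SHDI slope, one drought slope), mirroring the headline
    specification.  ``tv_controls=True`` lets the control slopes vary by
    year as well; ``constrain_equal=True`` collapses the anomaly path to a
    single slope, reproducing :func:`fit_fe_constant` exactly.
    """
    if constrain_equal:
        fit = fit_fe_constant(panel, outcome, anomaly_col, controls, cov, year_intercepts)
        fit.spec = "tvc-constrained"
        return fit
    tv = [anomaly_col] + (list(controls) if tv_controls else [])
    return _fit(
        panel, outcome, [anomaly_col, *controls], tv, "tvc", anomaly_col,
        region_fe=region_fe, year_intercepts=year_intercepts, cov=cov,
    )


def _check_bins(panel: pd.DataFrame, bins: Sequence[str]) -> None:
    present = [b for b in bins if b in panel.columns]
    if len(present) < len(bins):
        raise ValueError(f"panel is missing bin columns {sorted(set(bins) - set(present))}")
    if (panel[list(bins)].to_numpy() == 0).all():
        raise ValueError(
            "all months fall in the reference anomaly bin; bin coefficients are not identified"
        )


def fit_binned_tvc(
    panel: pd.DataFrame,
    outcome: str,
    bins: Sequence[str] = NONREF_BINS,
    controls: Sequence[str] = DEFAULT_CONTROLS,
    cov: str = "cluster",
    year_intercepts: bool = True,
    region_fe: bool = True,
) -> PanelFit:
    """Year-varying coefficients on monthly-anomaly bin month counts.

    The 0.2–0.4 °C bin is the omitted reference; SHDI and drought enter
    with constant coefficients.
    """
    _check_bins(panel, bins)
    return _fit(
        panel, outcome, [*bins, *controls], list(bins), "binned-tvc", None,
        year_intercepts=year_intercepts, cov=cov, region_fe=region_fe,
    )


def fit_binned_constant(
    panel: pd.DataFrame,
    outcome: str,
    bins: Sequence[str] = NONREF_BINS,
    controls: Sequence[str] = DEFAULT_CONTROLS,
    cov: str = "cluster",
    year_intercepts: bool = True,
    region_fe: bool = True,
) -> PanelFit:
    """Constant coefficients on bin month counts (two-way FE OLS)."""
    _check_bins(panel, bins)
    return _fit(
        panel, outcome, [*bins, *controls], [], "binned-constant", None,
        year_intercepts=year_intercepts, cov=cov, region_fe=region_fe,
    )


# ---------------------------------------------------------------------------
# Hypothesis tests
# ---------------------------------------------------------------------------

def wald_sequential_test(fit: PanelFit) -> pd.DataFrame:
    """One-sided Wald tests that each year's anomaly slope exceeds the last.

    For consecutive study years, statistic = (lambda_t - lambda_{t-1}) /
    se(difference) with the joint coefficient covariance; the p-value is
    one-sided normal against H1: lambda_t > lambda_{t-1}.
    """
    lam = fit.lambda_hat
    if len(lam) < 2:
        raise ValueError("sequential test needs at least two year-specific slopes")
    names = [f"{fit.anomaly_col}:year[{y}]" for y in lam.index]
    if names[0] not in fit.vcov.index:
        raise ValueError("fit does not carry year-specific anomaly coefficients")
    V = fit.vcov.loc[names, names].to_numpy()
    rows = []
    years = list(lam.index)
    for j in range(1, len(years)):
        d = lam.iloc[j] - lam.iloc[j - 1]
        var = V[j, j] + V[j - 1, j - 1] - 2 * V[j, j - 1]
        se = np.sqrt(max(var, 0.0))
        z = d / se if se > 0 else 0.0
        rows.append((years[j - 1], years[j], d, se, z, float(stats.norm.sf(z))))
    return pd.DataFrame(
        rows, columns=["year_from", "year_to", "difference", "se", "statistic", "p_one_sided"]
    )


@dataclass(frozen=True)
class HeterogeneityResult:
    """Wald test of equal anomaly-coefficient paths across two outcomes."""

    wald_stat: float
    f_stat: float
    df_num: int
    df_den: float
    p_value: float
    differences: pd.DataFrame


def heterogeneity_test(
    fit_a: PanelFit,
    fit_b: PanelFit,
    panel: pd.DataFrame,
    controls: Sequence[str] = DEFAULT_CONTROLS,
    cov: str = "cluster",
) -> HeterogeneityResult:
    """Test whether the anomaly effect differs between two outcomes.

    Stacks the two outcome equations (each with its own fixed effects, year
    intercepts, year-specific anomaly slopes and control slopes) into one
    regression, clusters by region across both equations — capturing
    cross-equation error correlation the way a seemingly-unrelated system
    would — and Wald-tests equality of the per-year anomaly slopes.  The
    statistic is referred to F(T, G-1).
    """
    out_a, out_b = fit_a.outcome, fit_b.outcome
    anomaly_col = fit_a.anomaly_col
    if anomaly_col != fit_b.anomaly_col:
        raise ValueError("fits use different anomaly columns")
    df = _check_panel(panel, [out_a, out_b, anomaly_col, *controls])
    years = sorted(df["year"].unique())
    regions = sorted(df["region_id"].unique())

    blocks, ys = [], []
    for tag, out_col in (("a", out_a), ("b", out_b)):
        X = _build_design(df, [anomaly_col, *controls], [anomaly_col], True, True, years, regions)
        X.columns = [f"{c}|{tag}" for c in X.columns]
        blocks.append(X)
        ys.append(df[out_col].to_numpy(dtype=float))
    Xa = pd.concat(
        [
            pd.concat([blocks[0], pd.DataFrame(0.0, index=blocks[0].index, columns=blocks[1].columns)], axis=1),
            pd.concat([pd.DataFrame(0.0, index=blocks[1].index, columns=blocks[0].columns), blocks[1]], axis=1),
        ],
        ignore_index=True,
    )
    y = np.concatenate(ys)
    clusters = np.concatenate([df["region_id"].to_numpy()] * 2)
    params, V, dfi, G = _ols(Xa, y, clusters if cov == "cluster" else None, cov)

    names_a = [f"{anomaly_col}:year[{y_}]|a" for y_ in years]
    names_b = [f"{anomaly_col}:year[{y_}]|b" for y_ in years]
    r = params[names_a].to_numpy() - params[names_b].to_numpy()
    R = np.zeros((len(years), len(params)))
    idx = {n: i for i, n in enumerate(params.index)}
    for k, (na, nb) in enumerate(zip(names_a, names_b)):
        R[k, idx[na]] = 1.0
        R[k, idx[nb]] = -1.0
    mid = R @ V.to_numpy() @ R.T
    wald = float(r @ linalg.pinvh(mid) @ r)
    q = len(years)
    f_stat = wald / q
    dfd = dfi if cov == "cluster" else float(len(y) - len(params))
    p = float(stats.f.sf(f_stat, q, dfd))
    diffs = pd.DataFrame({"year": years, "difference": r})
    return HeterogeneityResult(wald, f_stat, q, dfd, p, diffs)
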