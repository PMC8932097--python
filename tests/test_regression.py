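"""Fixed-effects estimators, time-varying slopes, and hypothesis tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import foodclim as fc
from foodclim.regression import RankDeficientError, _build_design
from helpers import manual_fit, toy_panel


# -- constant-coefficient FE ----------------------------------------------

def test_noiseless_constant_slope_identified_exactly():
    panel = toy_panel(seed=1, beta_anomaly=2.0, noise_sd=0.0)
    fit = fc.fit_fe_constant(panel, "y")
    assert fit.params["anomaly_c"] == pytest.approx(2.0, abs=1e-8)
    assert fit.params["shdi_scaled"] == pytest.approx(-2.0, abs=1e-8)


def test_within_transformation_equals_dummy_variable_ols():
    """Frisch–Waugh check: demeaning by region reproduces the dummy LS slopes."""
    panel = toy_panel(seed=2, noise_sd=1.0)
    fit = fc.fit_fe_constant(panel, "y")

    years = sorted(panel["year"].unique())
    cols = {"anomaly_c": panel["anomaly_c"], "shdi_scaled": panel["shdi_scaled"],
            "drought": panel["drought"]}
    for y in years[1:]:
        cols[f"year[{y}]"] = (panel["year"] == y).astype(float)
    X = pd.DataFrame(cols)
    # within transform: remove region means from outcome and every regressor
    Xw = X - X.groupby(panel["region_id"]).transform("mean")
    yw = panel["y"] - panel.groupby("region_id")["y"].transform("mean")
    beta_within, *_ = np.linalg.lstsq(Xw.to_numpy(), yw.to_numpy(), rcond=None)
    oracle = pd.Series(beta_within, index=X.columns)
    for name in ("anomaly_c", "shdi_scaled", "drought"):
        assert fit.params[name] == pytest.approx(oracle[name], abs=1e-9)


def test_constant_slope_unbiased_over_seeds():
    estimates = [
        fc.fit_fe_constant(toy_panel(n_regions=30, seed=s, noise_sd=1.0), "y").params["anomaly_c"]
        for s in range(60)
    ]
    se_mean = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
    assert abs(np.mean(estimates) - 2.0) < 4 * se_mean


# -- time-varying coefficients --------------------------------------------

def test_tvc_recovers_published_path_on_noiseless_panel(noiseless_panel12):
    fit = fc.fit_tvc(noiseless_panel12, "msfi_true")
    assert np.allclose(fit.lambda_hat.to_numpy(), fc.LAMBDA_MSFI, atol=1e-8)
    assert fit.gamma_hat["shdi_scaled"] == pytest.approx(-2.7, abs=1e-8)
    assert fit.gamma_hat["drought"] == pytest.approx(0.014, abs=1e-8)
    sfit = fc.fit_tvc(noiseless_panel12, "sfi_true")
    assert np.allclose(sfit.lambda_hat.to_numpy(), fc.LAMBDA_SFI, atol=1e-8)


def test_tvc_without_fe_equals_per_year_slopes():
    """Without region effects or shared controls the model separates by year,
    so each year's slope must equal the plain cross-sectional OLS slope."""
    panel = toy_panel(n_regions=40, seed=3, lambda_path=[1.0, 1.3, 1.1, 2.0, 1.7, 1.5],
                      noise_sd=1.0)
    fit = fc.fit_tvc(panel, "y", controls=(), region_fe=False)
    for y, lam in fit.lambda_hat.items():
        grp = panel[panel["year"] == y]
        v, out = grp["anomaly_c"].to_numpy(), grp["y"].to_numpy()
        slope = np.cov(v, out)[0, 1] / np.var(v, ddof=1)
        assert lam == pytest.approx(slope, abs=1e-9)


def test_tvc_with_fe_matches_conditional_per_year_slopes(panel12):
    """Given the estimated fixed effects and control slopes, the joint
    normal equations require each year's slope to equal the per-year OLS
    slope on the partial residual."""
    fit = fc.fit_tvc(panel12, "msfi_true")
    partial = (
        panel12["msfi_true"]
        - panel12["region_id"].map(fit.alpha_hat)
        - fit.gamma_hat["shdi_scaled"] * panel12["shdi_scaled"]
        - fit.gamma_hat["drought"] * panel12["drought"]
    )
    for y, lam in fit.lambda_hat.items():
        mask = panel12["year"] == y
        v, out = panel12.loc[mask, "anomaly_c"].to_numpy(), partial[mask].to_numpy()
        slope = np.cov(v, out)[0, 1] / np.var(v, ddof=1)
        assert lam == pytest.approx(slope, abs=1e-8)


def test_constrained_tvc_reproduces_constant_fit(panel12):
    a = fc.fit_tvc(panel12, "msfi_true", constrain_equal=True)
    b = fc.fit_fe_constant(panel12, "msfi_true")
    pd.testing.assert_series_equal(a.params, b.params)
    assert np.allclose(a.vcov.to_numpy(), b.vcov.to_numpy())


def test_rank_deficient_design_names_columns(panel12):
    panel = panel12.assign(shdi_dup=panel12["shdi_scaled"])
    with pytest.raises(RankDeficientError) as err:
        fc.fit_tvc(panel, "msfi_true", controls=("shdi_scaled", "shdi_dup"))
    assert any("shdi" in c for c in err.value.columns)


def test_zero_anomaly_variance_year_is_explicit_error(panel12):
    panel = panel12.copy()
    panel.loc[panel["year"] == 2016, "anomaly_c"] = 0.7
    with pytest.raises(ValueError, match="2016"):
        fc.fit_tvc(panel, "msfi_true")


def test_duplicate_panel_keys_rejected(panel12):
    dup = pd.concat([panel12, panel12.head(1)], ignore_index=True)
    with pytest.raises(ValueError, match="duplicated"):
        fc.fit_tvc(dup, "msfi_true")


def test_listwise_deletion_is_counted(panel12):
    panel = panel12.copy()
    panel.loc[panel.index[:3], "drought"] = np.nan
    fit = fc.fit_tvc(panel, "msfi_true")
    assert fit.n_dropped == 3
    assert fit.n_obs == len(panel) - 3


def test_cluster_covariance_matches_statsmodels(panel12):
    """Independent sandwich route: statsmodels OLS with cluster covariance on
    the identical design must agree with the in-house estimator."""
    fit = fc.fit_tvc(panel12, "msfi_true")
    years = sorted(panel12["year"].unique())
    regions = sorted(panel12["region_id"].unique())
    X = _build_design(panel12, ["anomaly_c", "shdi_scaled", "drought"], ["anomaly_c"],
                      True, True, years, regions)
    res = sm.OLS(panel12["msfi_true"].to_numpy(), X.to_numpy()).fit(
        cov_type="cluster", cov_kwds={"groups": panel12["region_id"].to_numpy()}
    )
    assert np.allclose(res.params, fit.params.to_numpy(), atol=1e-10)
    assert np.allclose(res.cov_params(), fit.vcov.to_numpy(), rtol=1e-8, atol=1e-12)


def test_classical_covariance_close_to_cluster_under_iid(climate12, shdi12):
    # errors are iid in the generator, so the two covariances agree on average
    gen = fc.PanelGenParams(seed=21)
    panel = fc.simulate_panel(climate12, gen, shdi12)
    cl = fc.fit_tvc(panel, "sfi_true", cov="cluster").lambda_se
    classical = fc.fit_tvc(panel, "sfi_true", cov="classical").lambda_se
    assert np.allclose(cl, classical, rtol=0.6)


# -- binned specifications -------------------------------------------------

def _binned_panel(covariates, seed=0, tv=False, noise=0.0):
    rng = np.random.default_rng(seed)
    df = covariates.copy()
    years = sorted(df["year"].unique())
    truth = {
        "bin_lt02": -0.009, "bin_04_06": 0.031, "bin_06_08": 0.041, "bin_ge08": 0.050,
    }
    regions = sorted(df["region_id"].unique())
    alpha = dict(zip(regions, rng.normal(20, 3, len(regions))))
    y = df["region_id"].map(alpha).to_numpy()
    for b, coef in truth.items():
        scale = (1 + 0.02 * (df["year"] - years[0])) if tv else 1.0
        y = y + coef * scale * df[b].to_numpy()
    y = y - 2.6 * df["shdi_scaled"].to_numpy() + 0.014 * df["drought"].to_numpy()
    df["y"] = y + rng.normal(0, noise, len(df))
    return df, truth


@pytest.fixture(scope="module")
def bin_covariates(climate12, shdi12):
    cov = fc.build_covariates(climate12)
    cov = cov.merge(shdi12, on=["region_id", "year"])
    cov["shdi_scaled"] = cov["shdi"] / 0.1
    return cov


def test_binned_tvc_noiseless_recovery(bin_covariates):
    panel, truth = _binned_panel(bin_covariates, seed=4, tv=True)
    fit = fc.fit_binned_tvc(panel, "y")
    years = sorted(panel["year"].unique())
    for b, coef in truth.items():
        path = fit._year_varying(b)
        expected = coef * (1 + 0.02 * (np.asarray(years) - years[0]))
        assert np.allclose(path.to_numpy(), expected, atol=1e-8)


def test_binned_constant_noiseless_recovery_and_ordering(bin_covariates):
    panel, truth = _binned_panel(bin_covariates, seed=5)
    fit = fc.fit_binned_constant(panel, "y")
    for b, coef in truth.items():
        assert fit.params[b] == pytest.approx(coef, abs=1e-8)
    # monotone truth across bins is recovered monotone
    est = [fit.params[b] for b in ("bin_lt02", "bin_04_06", "bin_06_08", "bin_ge08")]
    assert est == sorted(est)


def test_binned_tvc_degenerates_to_constant_with_one_year(bin_covariates):
    panel, _ = _binned_panel(bin_covariates, seed=6, noise=0.3)
    one = panel[panel["year"] == 2014]
    a = fc.fit_binned_tvc(one, "y", region_fe=False, cov="hc1")
    b = fc.fit_binned_constant(one, "y", region_fe=False, cov="hc1")
    for bin_col in ("bin_lt02", "bin_04_06", "bin_06_08", "bin_ge08"):
        assert a.params[f"{bin_col}:year[2014]"] == pytest.approx(b.params[bin_col], abs=1e-9)


def test_all_months_in_reference_bin_rejected(bin_covariates):
    panel, _ = _binned_panel(bin_covariates, seed=7)
    for b in fc.NONREF_BINS:
        panel[b] = 0
    with pytest.raises(ValueError, match="reference"):
        fc.fit_binned_tvc(panel, "y")


# -- sequential Wald test --------------------------------------------------

def test_wald_statistic_zero_for_equal_slopes():
    fit = manual_fit(["A", "B"], [2014, 2015, 2016], lam=1.5, se_lambda=0.1)
    res = fc.wald_sequential_test(fit)
    assert np.allclose(res["statistic"], 0.0)
    assert np.allclose(res["p_one_sided"], 0.5)


def test_wald_statistic_matches_hand_formula():
    fit = manual_fit(["A", "B"], [2014, 2015], lam={2014: 1.4, 2015: 1.64})
    fit.vcov.loc["anomaly_c:year[2014]", "anomaly_c:year[2014]"] = 0.05**2
    fit.vcov.loc["anomaly_c:year[2015]", "anomaly_c:year[2015]"] = 0.03**2
    res = fc.wald_sequential_test(fit)
    expected = (1.64 - 1.4) / np.sqrt(0.05**2 + 0.03**2)
    assert res["statistic"].iloc[0] == pytest.approx(expected, abs=1e-12)


def test_wald_covariance_term_enters_difference_se():
    fit = manual_fit(["A", "B"], [2014, 2015], lam={2014: 1.0, 2015: 1.2})
    for a, b, v in ((2014, 2014, 0.04), (2015, 2015, 0.04), (2014, 2015, 0.03)):
        fit.vcov.loc[f"anomaly_c:year[{a}]", f"anomaly_c:year[{b}]"] = v
        fit.vcov.loc[f"anomaly_c:year[{b}]", f"anomaly_c:year[{a}]"] = v
    res = fc.wald_sequential_test(fit)
    assert res["se"].iloc[0] == pytest.approx(np.sqrt(0.04 + 0.04 - 2 * 0.03), abs=1e-12)


def test_wald_detects_clearly_increasing_path(climate12, shdi12):
    gen = fc.PanelGenParams(seed=22, noise_sd=0.01)
    panel = fc.simulate_panel(climate12, gen, shdi12)
    fit = fc.fit_tvc(panel, "msfi_true")
    res = fc.wald_sequential_test(fit)
    assert res["p_one_sided"].iloc[0] < 0.01  # 2014 -> 2015 rises by 0.13


# -- heterogeneity test ----------------------------------------------------

def test_identical_outcomes_cannot_reject_equality(panel12):
    panel = panel12.assign(copy_true=panel12["msfi_true"])
    fit_a = fc.fit_tvc(panel, "msfi_true")
    fit_b = fc.fit_tvc(panel, "copy_true")
    res = fc.heterogeneity_test(fit_a, fit_b, panel)
    assert res.wald_stat == pytest.approx(0.0, abs=1e-6)
    assert res.p_value == pytest.approx(1.0)


def test_heterogeneity_statistic_matches_stacked_ols_oracle():
    """Brute-force oracle: build the stacked two-equation design from scratch
    with patsy-style dummies, estimate with statsmodels cluster OLS, and form
    the quadratic form for equal anomaly paths by hand."""
    panel = toy_panel(n_regions=6, seed=8, noise_sd=0.5)
    panel["y2"] = toy_panel(n_regions=6, seed=9, noise_sd=0.5, beta_anomaly=2.5)["y"]
    fit_a = fc.fit_tvc(panel, "y")
    fit_b = fc.fit_tvc(panel, "y2")
    res = fc.heterogeneity_test(fit_a, fit_b, panel)

    years = sorted(panel["year"].unique())
    frames = []
    for tag, out in (("a", "y"), ("b", "y2")):
        block = pd.get_dummies(panel["region_id"], prefix=f"r{tag}").astype(float)
        for y in years[1:]:
            block[f"t{tag}{y}"] = (panel["year"] == y).astype(float)
        for y in years:
            block[f"v{tag}{y}"] = panel["anomaly_c"] * (panel["year"] == y)
        block[f"s{tag}"] = panel["shdi_scaled"]
        block[f"d{tag}"] = panel["drought"]
        block["__y"] = panel[out]
        frames.append(block)
    stacked = pd.concat(frames, ignore_index=True).fillna(0.0)
    yv = stacked.pop("__y").to_numpy()
    groups = np.concatenate([panel["region_id"].to_numpy()] * 2)
    ols = sm.OLS(yv, stacked.to_numpy()).fit(cov_type="cluster", cov_kwds={"groups": groups})
    cols = list(stacked.columns)
    R = np.zeros((len(years), len(cols)))
    for k, y in enumerate(years):
        R[k, cols.index(f"va{y}")] = 1.0
        R[k, cols.index(f"vb{y}")] = -1.0
    r = R @ ols.params
    wald = float(r @ np.linalg.pinv(R @ ols.cov_params() @ R.T) @ r)
    assert res.wald_stat == pytest.approx(wald, rel=1e-6)


def test_heterogeneity_detects_separated_paths(climate12, shdi12):
    gen = fc.PanelGenParams(
        seed=23,
        lambda_path_msfi=tuple(v + 0.8 for v in fc.LAMBDA_SFI),
        lambda_path_sfi=fc.LAMBDA_SFI,
        noise_sd=0.1,
    )
    panel = fc.simulate_panel(climate12, gen, shdi12)
    fit_a = fc.fit_tvc(panel, "msfi_true")
    fit_b = fc.fit_tvc(panel, "sfi_true")
    assert fc.heterogeneity_test(fit_a, fit_b, panel).p_value < 0.01


# -- persistence -----------------------------------------------------------

def test_fit_round_trips_through_json(panel12, tmp_path):
    fit = fc.fit_tvc(panel12, "msfi_true")
    path = tmp_path / "fit.json"
    fit.to_json(path)
    back = fc.PanelFit.from_json(path)
    pd.testing.assert_series_equal(fit.params, back.params)
    pd.testing.assert_frame_equal(fit.vcov, back.vcov)
    assert back.years == fit.years and back.outcome == fit.outcome
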