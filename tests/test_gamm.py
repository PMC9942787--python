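"""Design construction, penalized IRLS, prediction, and the turning point."""

import numpy as np
import pandas as pd
import pytest

import scholarmigrate as sm
from scholarmigrate import gamm


def frame_for(n_countries=2, n_years=4, seed=0, rate=0.02):
    """Small model frame with constant true rate."""
    rng = np.random.default_rng(seed)
    codes = sm.synthesize.country_codes(n_countries)
    rows = []
    for c in codes:
        for y in range(2000, 2000 + n_years):
            e = int(rng.integers(500, 2000))
            rows.append((c, y, rng.poisson(e * rate), e, np.exp(rng.uniform(7, 11))))
    df = pd.DataFrame(rows, columns=["country", "year", "emigrants", "exposure", "gdp_ppp_2017"])
    df["log_gdp"] = np.log(df["gdp_ppp_2017"])
    return df


def zero_lambdas(design, value=0.0):
    return {t.name: value for t in design.terms}


# --- design ---------------------------------------------------------------


def test_design_column_counts():
    d = sm.build_design(frame_for(n_countries=2, n_years=4), k=4)
    # intercept + (k-1) per smooth + n_countries per random term
    assert d.p == 1 + 3 + 3 + 2 + 2
    assert [t.name for t in d.terms] == ["s(log_gdp)", "s(year)", "re_intercept", "re_slope"]


def test_doubling_exposure_shifts_offset_by_log2():
    f = frame_for()
    d1 = sm.build_design(f, k=4)
    d2 = sm.build_design(f.assign(exposure=2 * f["exposure"]), k=4)
    np.testing.assert_allclose(d2.offset - d1.offset, np.log(2.0), rtol=0, atol=1e-14)


def test_penalty_matches_independent_second_difference_construction():
    k = 7
    # oracle: build D~ row by row, S = D~' D~
    d2 = np.zeros((k - 2, k))
    for i in range(k - 2):
        d2[i, i], d2[i, i + 1], d2[i, i + 2] = 1.0, -2.0, 1.0
    np.testing.assert_allclose(gamm.second_difference_penalty(k), d2.T @ d2)
    # constrained penalties are PSD and carried into the design blocks
    d = sm.build_design(frame_for(n_countries=3, n_years=6), k=5)
    for t in d.terms:
        eigs = np.linalg.eigvalsh(t.penalty) if t.penalty.size else t.penalty_eigs
        assert eigs.min() > -1e-10


def test_smooth_columns_sum_to_zero():
    d = sm.build_design(frame_for(n_countries=4, n_years=6), k=6)
    for t in d.terms:
        if not t.is_random:
            np.testing.assert_allclose(
                d.X[:, t.start : t.stop].sum(axis=0), 0.0, atol=1e-9
            )


def test_design_errors():
    f = frame_for()
    with pytest.raises(ValueError, match="smaller k"):
        sm.build_design(f, k=40)
    with pytest.raises(ValueError, match="non-finite"):
        sm.build_design(f.assign(log_gdp=np.nan), k=4)
    with pytest.raises(ValueError, match="positive"):
        sm.build_design(f.assign(exposure=0), k=4)


# --- fitting --------------------------------------------------------------


def test_unpenalized_fit_matches_statsmodels_glm():
    import statsmodels.api as smapi

    f = frame_for(n_countries=3, n_years=8, seed=2)
    d = sm.build_design(f, k=4, random_effects=False)
    fit = sm.fit(d, lambdas=zero_lambdas(d))
    oracle = smapi.GLM(
        d.y, d.X, family=smapi.families.Poisson(), offset=d.offset
    ).fit()
    np.testing.assert_allclose(fit.beta, oracle.params, rtol=1e-6)
    assert fit.deviance == pytest.approx(oracle.deviance, rel=1e-6)


def test_null_model_limit_under_heavy_smoothing():
    rate = 0.03
    f = frame_for(n_countries=5, n_years=10, seed=3, rate=rate)
    d = sm.build_design(f, k=5)
    fit = sm.fit(d, lambdas={t.name: 1e9 for t in d.terms})
    # heavy smoothing shrinks each smooth to the penalty null space (a line),
    # whose fitted size is bounded by sampling noise around the constant rate
    contrib = d.X[:, 1:] @ fit.beta[1:]
    assert np.abs(contrib).max() < 0.1
    assert fit.intercept == pytest.approx(np.log(rate), abs=0.05)


def test_penalized_solution_matches_direct_normal_equations():
    f = frame_for(n_countries=6, n_years=10, seed=4)
    d = sm.build_design(f, k=6)
    lams = {t.name: 3.0 for t in d.terms}
    fit = sm.fit(d, lambdas=lams)
    # oracle: one penalized WLS solve at the converged IRLS weights
    mu = fit.fitted_mean()
    w = mu
    z = (fit.linear_predictor() - d.offset) + (d.y - mu) / mu
    a = d.X.T @ (d.X * w[:, None]) + d.penalty_total(lams)
    beta_direct = np.linalg.solve(a, d.X.T @ (w * z))
    np.testing.assert_allclose(fit.beta, beta_direct, rtol=1e-6, atol=1e-9)


def test_adding_random_terms_never_increases_deviance():
    f = sm.simulate_rate_panel(n_countries=30, n_years=8, seed=5)
    lams = {"s(log_gdp)": 10.0, "s(year)": 10.0}
    d0 = sm.build_design(f, k=6, random_effects=False)
    d1 = sm.build_design(f, k=6)
    fit0 = sm.fit(d0, lambdas=lams)
    fit1 = sm.fit(d1, lambdas=dict(lams, re_intercept=1.0, re_slope=1.0))
    assert fit1.deviance <= fit0.deviance + 1e-8


def test_shrinkage_limit_approaches_fixed_effects_model():
    f = sm.simulate_rate_panel(n_countries=25, n_years=8, seed=6)
    lams = {"s(log_gdp)": 10.0, "s(year)": 10.0}
    d0 = sm.build_design(f, k=6, random_effects=False)
    eta0 = sm.fit(d0, lambdas=lams).linear_predictor()
    d1 = sm.build_design(f, k=6)
    gaps = []
    for lam_re in (1e2, 1e4, 1e6, 1e8):
        fit = sm.fit(d1, lambdas=dict(lams, re_intercept=lam_re, re_slope=lam_re))
        gaps.append(np.abs(fit.linear_predictor() - eta0).max())
    assert all(a > b for a, b in zip(gaps, gaps[1:]))
    assert gaps[-1] < 1e-3


def test_exposure_scaling_shifts_intercept_and_preserves_fitted_rates():
    f = sm.simulate_rate_panel(n_countries=25, n_years=8, seed=8)
    lams = dict.fromkeys(
        ["s(log_gdp)", "s(year)", "re_intercept", "re_slope"], 10.0
    )
    fits = []
    for scale in (1.0, 5.0):
        d = sm.build_design(f.assign(exposure=f["exposure"] * scale), k=6)
        fits.append(sm.fit(d, lambdas=lams, tol=1e-14, maxiter=200))
    # the unpenalized intercept absorbs the whole ln c offset shift ...
    assert fits[1].intercept - fits[0].intercept == pytest.approx(-np.log(5.0), abs=1e-8)
    np.testing.assert_allclose(fits[0].beta[1:], fits[1].beta[1:], rtol=0, atol=1e-8)
    # ... so per-observation fitted rates are unchanged
    np.testing.assert_allclose(
        fits[0].fitted_mean(), fits[1].fitted_mean(), rtol=1e-10, atol=1e-10
    )


def test_function_recovery_improves_with_sample_size():
    true = sm.HazardSpec(h_max=1.0)
    rmses = []
    for nc, ny, seed in ((25, 10, 21), (100, 20, 22)):
        f = sm.simulate_rate_panel(n_countries=nc, n_years=ny, seed=seed)
        fit = sm.fit(sm.build_design(f, k=10), lambdas="auto")
        x = np.linspace(f["log_gdp"].min() + 0.2, f["log_gdp"].max() - 0.2, 100)
        fitted = fit.smooth_values("s(log_gdp)", x)
        target = true.gamma1 * x + true.gamma2 * x * x
        resid = (fitted - fitted.mean()) - (target - target.mean())
        rmses.append(np.sqrt(np.mean(resid**2)))
    assert rmses[1] < rmses[0]
    assert rmses[1] < 0.1


def test_invalid_family_and_missing_lambdas_rejected():
    d = sm.build_design(frame_for(), k=4)
    with pytest.raises(ValueError, match="family"):
        sm.fit(d, family="gaussian", lambdas=zero_lambdas(d, 1.0))
    with pytest.raises(ValueError, match="missing"):
        sm.fit(d, lambdas={"s(log_gdp)": 1.0})


def test_negative_binomial_theta_estimated_and_fit_converges():
    f = sm.simulate_rate_panel(n_countries=20, n_years=8, seed=9)
    d = sm.build_design(f, k=6)
    fit = sm.fit(d, family="negative_binomial", lambdas=zero_lambdas(d, 10.0))
    assert fit.converged and fit.theta is not None and fit.theta > 0


# --- prediction & turning point ------------------------------------------


def test_country_curve_equals_marginal_when_random_effects_vanish(rate_fit):
    # crank the ridge: random coefficients shrink to ~0
    f = sm.fit(rate_fit.design, lambdas=dict(rate_fit.lambdas, re_intercept=1e10, re_slope=1e10))
    grid = sm.default_gdp_grid(f)
    marginal = sm.predict_marginal(f, grid)["rate_per_1000"]
    country = sm.predict_country(f, f.design.levels[0], grid)["rate_per_1000"]
    np.testing.assert_allclose(marginal, country, rtol=1e-6)


def test_null_fit_gives_flat_curve_at_intercept_rate():
    import dataclasses

    f = frame_for(n_countries=5, n_years=10, seed=13)
    d = sm.build_design(f, k=5)
    fit = sm.fit(d, lambdas={t.name: 1e6 for t in d.terms})
    beta_null = np.zeros_like(fit.beta)
    beta_null[0] = fit.beta[0]
    null_fit = dataclasses.replace(fit, beta=beta_null)
    curve = sm.predict_marginal(null_fit, sm.default_gdp_grid(fit, 200))
    np.testing.assert_allclose(
        curve["rate_per_1000"], 1000.0 * np.exp(null_fit.intercept), rtol=1e-12
    )


def test_marginal_inside_envelope_of_country_curves(rate_fit):
    grid = sm.default_gdp_grid(rate_fit, 200)
    marginal = sm.predict_marginal(rate_fit, grid)["rate_per_1000"].to_numpy()
    per_country = np.array(
        [
            sm.predict_country(rate_fit, c, grid)["rate_per_1000"].to_numpy()
            for c in rate_fit.design.levels
        ]
    )
    eps = 1e-9
    assert (per_country.min(axis=0) <= marginal + eps).all()
    assert (per_country.max(axis=0) >= marginal - eps).all()


def test_prediction_outside_fitted_range_errors_unless_extrapolating(rate_fit):
    hi = rate_fit.design.gdp.max() * 10
    with pytest.raises(ValueError, match="outside fitted range"):
        sm.predict_marginal(rate_fit, np.linspace(1000, hi, 300))
    out = sm.predict_marginal(rate_fit, np.linspace(1000, hi, 300), extrapolate=True)
    assert np.isfinite(out["rate_per_1000"]).all()


def test_turning_point_of_analytic_quadratic_curve():
    g = np.exp(np.linspace(np.log(1000), np.log(120000), 400))
    curve = pd.DataFrame({"gdp": g, "rate_per_1000": (np.log(g) - 10.12663) ** 2})
    tp = sm.find_turning_point(curve)
    assert tp == pytest.approx(np.exp(10.12663), rel=1e-3)


def test_monotone_curve_has_no_turning_point():
    g = np.exp(np.linspace(np.log(1000), np.log(120000), 400))
    assert sm.find_turning_point(pd.DataFrame({"gdp": g, "rate_per_1000": np.log(g)})) is None


def test_turning_point_matches_dense_grid_argmin(rate_fit):
    coarse = sm.predict_marginal(rate_fit, sm.default_gdp_grid(rate_fit, 400))
    dense = sm.predict_marginal(rate_fit, sm.default_gdp_grid(rate_fit, 8000))
    tp = sm.find_turning_point(coarse)
    brute = dense["gdp"].iloc[int(np.argmin(dense["rate_per_1000"]))]
    assert tp == pytest.approx(brute, rel=0.01)


def test_turning_point_input_validation():
    g = np.exp(np.linspace(np.log(1000), np.log(120000), 400))
    with pytest.raises(ValueError, match="non-finite"):
        sm.find_turning_point(pd.DataFrame({"gdp": g, "rate_per_1000": np.full(400, np.nan)}))
    with pytest.raises(ValueError, match="grid points"):
        sm.find_turning_point(pd.DataFrame({"gdp": g[:50], "rate_per_1000": g[:50]}))


def test_fit_json_roundtrip_preserves_predictions(rate_fit):
    restored = gamm.fit_from_json(gamm.fit_to_json(rate_fit))
    grid = sm.default_gdp_grid(rate_fit, 200)
    np.testing.assert_allclose(
        sm.predict_marginal(rate_fit, grid)["rate_per_1000"],
        sm.predict_marginal(restored, grid)["rate_per_1000"],
    )
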