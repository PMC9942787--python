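"""Poisson generalized additive mixed model for emigration counts.

The model for the emigrant count Y of country c in year t with exposure E
(active scholars at risk) is

    log E(Y) = b0 + s(log GDP) + s(year) + a_c + b_c * (log GDP - mean) + log E

where s(.) are penalized cubic B-spline smooths (second-difference penalties,
sum-to-zero constrained against the intercept) and a_c, b_c are country
random intercepts and random slopes on centered log GDP, estimated as
ridge-penalized coefficients (the ridge weight is the reciprocal of the
variance component). Everything is fitted by penalized IRLS; smoothing
parameters are chosen by an outer coordinate search minimizing a
Laplace-approximate REML criterion evaluated at the working model, with a
fixed-lambda override always available.

Marginal predicted-rate curves set the random-effect columns to zero and
average predictions over the observed years; the turning point of the
development-emigration relationship is the grid-refined interior minimum of
that curve.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.interpolate import BSpline

__all__ = [
    "GammDesign",
    "GammFit",
    "build_design",
    "fit",
    "predict_marginal",
    "predict_country",
    "find_turning_point",
    "default_gdp_grid",
    "bspline_basis",
    "second_difference_penalty",
    "fit_to_json",
    "fit_from_json",
]

logger = logging.getLogger(__name__)

FAMILIES = ("poisson", "quasipoisson", "negative_binomial")

MAX_ETA = 30.0  # linear-predictor clamp guarding exp() during IRLS


# ---------------------------------------------------------------------------
# bases and penalties
# ---------------------------------------------------------------------------


def bspline_knots(xmin: float, xmax: float, k: int, degree: int = 3) -> np.ndarray:
    """Open knot vector giving k cubic B-spline basis functions on [xmin, xmax].

    Interior knots are evenly spaced; boundary knots have multiplicity
    degree + 1.
    """
    if k < degree + 1:
        raise ValueError(f"basis dimension k={k} must be >= {degree + 1}")
    inner = np.linspace(xmin, xmax, k - degree + 1)[1:-1]
    return np.concatenate([[xmin] * (degree + 1), inner, [xmax] * (degree + 1)])


def bspline_basis(
    x: np.ndarray, knots: np.ndarray, degree: int = 3, extrapolate: bool = False
) -> np.ndarray:
    """Evaluate the B-spline basis at x; (n, k) dense matrix."""
    x = np.asarray(x, dtype=float)
    lo, hi = knots[degree], knots[-degree - 1]
    if not extrapolate and (x.min() < lo or x.max() > hi):
        raise ValueError(
            f"values outside fitted range [{lo:.6g}, {hi:.6g}]; "
            "enable extrapolation explicitly to override"
        )
    if extrapolate:
        k = knots.size - degree - 1
        out = np.empty((x.size, k))
        for j in range(k):
            coef = np.zeros(k)
            coef[j] = 1.0
            out[:, j] = BSpline(knots, coef, degree, extrapolate=True)(x)
        return out
    return BSpline.design_matrix(x, knots, degree).toarray()


def second_difference_penalty(k: int) -> np.ndarray:
    """Penalty D2'D2 with D2 the (k-2, k) second-difference operator."""
    d2 = np.diff(np.eye(k), n=2, axis=0)
    return d2.T @ d2


def _centering_constraint(basis: np.ndarray) -> np.ndarray:
    """(k, k-1) transform Z with column-sums of basis @ Z equal to zero.

    Absorbs the intercept: the constrained smooth averages to zero over the
    fitted sample.
    """
    m = basis.mean(axis=0, keepdims=True)
    return linalg.null_space(m)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Term:
    name: str
    start: int
    stop: int
    penalty: np.ndarray  # unit penalty on this block
    penalty_eigs: np.ndarray  # eigenvalues of the unit penalty
    is_random: bool

    @property
    def rank(self) -> int:
        return int(np.sum(self.penalty_eigs > 1e-10 * max(self.penalty_eigs.max(), 1.0)))


@dataclass
class GammDesign:
    """Response, offset, stacked design matrix and per-term penalty blocks."""

    y: np.ndarray
    offset: np.ndarray
    X: np.ndarray
    terms: list[_Term]
    # prediction metadata
    k: int
    knots_gdp: np.ndarray
    Z_gdp: np.ndarray
    knots_year: np.ndarray
    Z_year: np.ndarray
    levels: list[str]
    x_center: float
    years: np.ndarray
    gdp: np.ndarray
    has_random: bool

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def penalty_total(self, lambdas: dict[str, float]) -> np.ndarray:
        s = np.zeros((self.p, self.p))
        for t in self.terms:
            s[t.start : t.stop, t.start : t.stop] += lambdas[t.name] * t.penalty
        return s


def build_design(
    model_frame: pd.DataFrame,
    k: int = 10,
    k_year: int | None = None,
    random_effects: bool = True,
) -> GammDesign:
    """Build the GAMM design from a model frame.

    ``model_frame`` needs columns ``country, year, emigrants, exposure`` and
    either ``log_gdp`` or ``gdp_ppp_2017``. The offset is the natural log of
    exposure. Columns, in order: intercept, constrained log-GDP smooth
    (k-1), constrained year smooth (k_year-1), country intercept indicators,
    country x centered-log-GDP slope columns.
    """
    k_year = k if k_year is None else k_year
    df = model_frame
    y = df["emigrants"].to_numpy(dtype=float)
    exposure = df["exposure"].to_numpy(dtype=float)
    if np.any(exposure <= 0):
        raise ValueError("all exposures must be positive")
    offset = np.log(exposure)
    x = (
        df["log_gdp"].to_numpy(dtype=float)
        if "log_gdp" in df.columns
        else np.log(df["gdp_ppp_2017"].to_numpy(dtype=float))
    )
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite log GDP in model frame")
    t = df["year"].to_numpy(dtype=float)
    for name, v, dim in (("log_gdp", x, k), ("year", t, k_year)):
        if np.unique(v).size < dim:
            raise ValueError(
                f"only {np.unique(v).size} distinct {name} values for k={dim}; use a smaller k"
            )

    blocks = [np.ones((len(df), 1))]
    terms: list[_Term] = []
    col = 1

    def _smooth(values, dim, name):
        nonlocal col
        knots = bspline_knots(values.min(), values.max(), dim)
        b = bspline_basis(values, knots)
        z = _centering_constraint(b)
        s = z.T @ second_difference_penalty(dim) @ z
        blocks.append(b @ z)
        terms.append(_Term(name, col, col + z.shape[1], s, linalg.eigvalsh(s), False))
        col += z.shape[1]
        return knots, z

    knots_gdp, z_gdp = _smooth(x, k, "s(log_gdp)")
    knots_year, z_year = _smooth(t, k_year, "s(year)")

    levels: list[str] = []
    x_center = float(x.mean())
    if random_effects:
        codes, levels_idx = pd.factorize(df["country"], sort=True)
        levels = list(levels_idx)
        nc = len(levels)
        ind = np.zeros((len(df), nc))
        ind[np.arange(len(df)), codes] = 1.0
        for name, mat in (
            ("re_intercept", ind),
            ("re_slope", ind * (x - x_center)[:, None]),
        ):
            blocks.append(mat)
            eye = np.eye(nc)
            terms.append(_Term(name, col, col + nc, eye, np.ones(nc), True))
            col += nc

    return GammDesign(
        y=y,
        offset=offset,
        X=np.hstack(blocks),
        terms=terms,
        k=k,
        knots_gdp=knots_gdp,
        Z_gdp=z_gdp,
        knots_year=knots_year,
        Z_year=z_year,
        levels=levels,
        x_center=x_center,
        years=np.unique(t),
        gdp=np.exp(x),
        has_random=random_effects,
    )


# ---------------------------------------------------------------------------
# penalized IRLS
# ---------------------------------------------------------------------------


def _poisson_deviance(y, mu):
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return 2.0 * float(np.sum(term - (y - mu)))


def _nb_deviance(y, mu, theta):
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    t2 = (y + theta) * np.log((y + theta) / (mu + theta))
    return 2.0 * float(np.sum(t1 - t2))


def _pirls(design, lambdas, family="poisson", theta=None, beta0=None, maxiter=100, tol=1e-11):
    """Penalized iteratively reweighted least squares (log link).

    Returns (beta, deviance, converged flag, iterations, deviance trace,
    final IRLS weights).
    """
    X, y, offset = design.X, design.y, design.offset
    s_tot = design.penalty_total(lambdas)
    if beta0 is not None:
        beta = beta0.copy()
        eta = np.clip(X @ beta + offset, -MAX_ETA, MAX_ETA)
        mu = np.exp(eta)
    else:
        mu = y + np.mean(y) * 0.1 + 0.1
        eta = np.log(mu)
        beta = np.zeros(design.p)
    dev = np.inf
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        if family == "negative_binomial":
            w = mu / (1.0 + mu / theta)
        else:
            w = mu.copy()
        w = np.maximum(w, 1e-10)
        z = (eta - offset) + (y - mu) / mu
        wx = X * w[:, None]
        a = X.T @ wx + s_tot
        b = X.T @ (w * z)
        beta_prev = beta
        try:
            c, low = linalg.cho_factor(a, check_finite=False)
            beta = linalg.cho_solve((c, low), b, check_finite=False)
        except linalg.LinAlgError:
            beta = linalg.solve(a + 1e-8 * np.eye(design.p), b, assume_a="sym")
        step = np.max(np.abs(beta - beta_prev)) / (1.0 + np.max(np.abs(beta)))
        eta = np.clip(X @ beta + offset, -MAX_ETA, MAX_ETA)
        mu = np.exp(eta)
        new_dev = (
            _nb_deviance(y, mu, theta)
            if family == "negative_binomial"
            else _poisson_deviance(y, mu)
        )
        trace.append(new_dev)
        if np.isfinite(dev) and (
            abs(dev - new_dev) < tol * (abs(new_dev) + 0.1) or step < 1e-12
        ):
            dev = new_dev
            converged = True
            break
        dev = new_dev
    if family == "negative_binomial":
        w = np.maximum(mu / (1.0 + mu / theta), 1e-10)
    else:
        w = np.maximum(mu, 1e-10)
    return beta, dev, converged, it, trace, w


@dataclass
class GammFit:
    """A fitted penalized Poisson/NB additive mixed model."""

    design: GammDesign
    beta: np.ndarray
    lambdas: dict[str, float]
    family: str
    deviance: float
    edf: float
    converged: bool
    n_iter: int
    deviance_trace: list[float] = field(default_factory=list)
    theta: float | None = None  # negative-binomial dispersion
    scale: float = 1.0  # quasipoisson dispersion estimate

    @property
    def intercept(self) -> float:
        return float(self.beta[0])

    def linear_predictor(self, include_offset: bool = True) -> np.ndarray:
        eta = self.design.X @ self.beta
        return eta + self.design.offset if include_offset else eta

    def fitted_mean(self) -> np.ndarray:
        return np.exp(self.linear_predictor())

    def coef(self, term_name: str) -> np.ndarray:
        for t in self.design.terms:
            if t.name == term_name:
                return self.beta[t.start : t.stop]
        raise KeyError(term_name)

    def smooth_values(self, term_name: str, values: np.ndarray) -> np.ndarray:
        """Evaluate a fitted (centered) smooth at new covariate values."""
        if term_name == "s(log_gdp)":
            knots, z = self.design.knots_gdp, self.design.Z_gdp
        elif term_name == "s(year)":
            knots, z = self.design.knots_year, self.design.Z_year
        else:
            raise KeyError(term_name)
        return bspline_basis(np.asarray(values, float), knots) @ z @ self.coef(term_name)


def _edf(design, lambdas, w):
    wx = design.X * w[:, None]
    xtwx = design.X.T @ wx
    a = xtwx + design.penalty_total(lambdas)
    return float(np.trace(linalg.solve(a, xtwx, assume_a="sym")))


def fit(
    design: GammDesign,
    family: str = "poisson",
    lambdas: dict[str, float] | str = "auto",
    maxiter: int = 100,
    tol: float = 1e-11,
) -> GammFit:
    """Fit the model by penalized IRLS.

    ``lambdas`` maps term names (``s(log_gdp)``, ``s(year)``,
    ``re_intercept``, ``re_slope``) to smoothing parameters; ``"auto"``
    selects them by approximate REML. Deterministic given the data and the
    lambda path.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    theta = None
    if lambdas == "auto":
        lambdas = select_lambdas(design)
    else:
        missing = {t.name for t in design.terms} - set(lambdas)
        if missing:
            raise ValueError(f"lambdas missing for terms: {sorted(missing)}")
        if any(v < 0 for v in lambdas.values()):
            raise ValueError("smoothing parameters must be non-negative")
    if family == "negative_binomial":
        theta = _estimate_theta(design, lambdas)
    beta, dev, converged, it, trace, w = _pirls(
        design, lambdas, family=family, theta=theta, maxiter=maxiter, tol=tol
    )
    if not converged:
        raise RuntimeError(
            f"IRLS did not converge in {maxiter} iterations; deviance trace: {trace[-5:]}"
        )
    edf = _edf(design, lambdas, w)
    scale = 1.0
    if family == "quasipoisson":
        mu = np.exp(np.clip(design.X @ beta + design.offset, -MAX_ETA, MAX_ETA))
        pearson = float(np.sum((design.y - mu) ** 2 / mu))
        scale = pearson / max(design.n - edf, 1.0)
    if np.any(design.y > 1e5) or np.all(design.y == 0):
        logger.warning("degenerate counts detected; fit may be unstable")
    return GammFit(
        design=design,
        beta=beta,
        lambdas=dict(lambdas),
        family=family,
        deviance=dev,
        edf=edf,
        converged=converged,
        n_iter=it,
        deviance_trace=trace,
        theta=theta,
        scale=scale,
    )


def _estimate_theta(design, lambdas):
    """Method-of-moments NB dispersion from Pearson residuals of a Poisson fit."""
    beta, _, _, _, _, _ = _pirls(design, lambdas, family="poisson")
    mu = np.exp(np.clip(design.X @ beta + design.offset, -MAX_ETA, MAX_ETA))
    num = float(np.sum((design.y - mu) ** 2 - mu))
    den = float(np.sum(mu**2))
    inv_theta = max(num / den, 1e-8)
    return 1.0 / inv_theta


# ---------------------------------------------------------------------------
# smoothing-parameter selection (approximate REML)
# ---------------------------------------------------------------------------


def _reml_score(design, lambdas, warm=None):
    """Laplace-approximate REML at the converged working model (Poisson scale).

    -2 l_r = dev + b'Sb + log|X'WX + S| - log|S|_+ (block penalties, so the
    pseudo-determinant separates over terms); constants in the penalty null
    space dimension are kept for comparability across lambda values.
    """
    beta, dev, _, _, _, w = _pirls(design, lambdas, beta0=warm, tol=1e-9)
    s_tot = design.penalty_total(lambdas)
    pen = float(beta @ s_tot @ beta)
    a = design.X.T @ (design.X * w[:, None]) + s_tot
    sign, logdet_a = np.linalg.slogdet(a)
    if sign <= 0:
        return np.inf, beta
    logdet_s = 0.0
    for t in design.terms:
        eigs = t.penalty_eigs
        pos = eigs[eigs > 1e-10 * max(eigs.max(), 1.0)]
        logdet_s += pos.size * np.log(max(lambdas[t.name], 1e-300)) + float(
            np.sum(np.log(pos))
        )
    mp = design.p - sum(t.rank for t in design.terms)
    score = dev + pen + logdet_a - logdet_s - mp * np.log(2.0 * np.pi)
    return 0.5 * score, beta


def select_lambdas(
    design: GammDesign,
    log10_grid: np.ndarray | None = None,
    sweeps: int = 2,
) -> dict[str, float]:
    """Coordinate search over per-term log10 lambda minimizing approximate REML.

    Each coordinate is scanned on an integer log10 grid (default -4..8) and
    then refined by half- and quarter-decade steps around the best value;
    IRLS is warm-started between evaluations.
    """
    if log10_grid is None:
        log10_grid = np.arange(-4.0, 8.5, 1.0)
    current = {t.name: 1.0 for t in design.terms}
    warm = None
    cache: dict[tuple, float] = {}

    def score_of(lams):
        key = tuple(sorted((k, round(np.log10(v), 6)) for k, v in lams.items()))
        nonlocal warm
        if key in cache:
            return cache[key]
        s, beta = _reml_score(design, lams, warm=warm)
        warm = beta
        cache[key] = s
        return s

    for sweep in range(sweeps):
        for t in design.terms:
            best_v, best_s = current[t.name], score_of(current)
            for g in log10_grid:
                trial = dict(current, **{t.name: 10.0**g})
                s = score_of(trial)
                if s < best_s:
                    best_s, best_v = s, 10.0**g
            current[t.name] = best_v
    # local refinement
    for t in design.terms:
        for step in (0.5, 0.25):
            base = np.log10(current[t.name])
            best_v, best_s = current[t.name], score_of(current)
            for g in (base - step, base + step):
                trial = dict(current, **{t.name: 10.0**g})
                s = score_of(trial)
                if s < best_s:
                    best_s, best_v = s, 10.0**g
            current[t.name] = best_v
    return current


# ---------------------------------------------------------------------------
# prediction and turning point
# ---------------------------------------------------------------------------


def default_gdp_grid(fit_or_design, num: int = 400) -> np.ndarray:
    """Log-spaced GDP grid between the 1st and 99th percentiles of fitted GDP."""
    design = fit_or_design.design if isinstance(fit_or_design, GammFit) else fit_or_design
    lo, hi = np.percentile(design.gdp, [1.0, 99.0])
    return np.exp(np.linspace(np.log(lo), np.log(hi), num))


def _eta_grid(fit: GammFit, gdp_grid, average_over_year, extrapolate):
    x = np.log(np.asarray(gdp_grid, dtype=float))
    fx = (
        bspline_basis(x, fit.design.knots_gdp, extrapolate=extrapolate)
        @ fit.design.Z_gdp
        @ fit.coef("s(log_gdp)")
    )
    years = fit.design.years
    ft = (
        bspline_basis(years, fit.design.knots_year) @ fit.design.Z_year @ fit.coef("s(year)")
    )
    eta = fit.intercept + fx[:, None] + ft[None, :]  # (grid, years)
    if not average_over_year:
        eta = eta[:, [len(years) // 2]]  # year effect at the median observed year
    return eta, x


def predict_marginal(
    fit: GammFit,
    gdp_grid: np.ndarray | None = None,
    include_random: bool = False,
    average_over_year: bool = True,
    extrapolate: bool = False,
) -> pd.DataFrame:
    """Predicted emigration rate per 1,000 scholars along a GDP grid.

    Random-effect columns contribute zero unless ``include_random`` is
    requested (which requires a country; see :func:`predict_country`).
    With ``average_over_year`` the predicted rates are averaged over the
    observed years at each grid point. Predictions use unit exposure scaled
    to a per-1,000 rate.
    """
    if not fit.converged:
        raise RuntimeError("cannot predict from a non-converged fit")
    if include_random:
        raise ValueError("include_random requires a country; use predict_country")
    if gdp_grid is None:
        gdp_grid = default_gdp_grid(fit)
    eta, _ = _eta_grid(fit, gdp_grid, average_over_year, extrapolate)
    rate = 1000.0 * np.exp(eta)
    rate = rate.mean(axis=1) if average_over_year else rate[:, 0]
    return pd.DataFrame({"gdp": np.asarray(gdp_grid, float), "rate_per_1000": rate})


def predict_country(
    fit: GammFit,
    country: str,
    gdp_grid: np.ndarray | None = None,
    average_over_year: bool = True,
    extrapolate: bool = False,
) -> pd.DataFrame:
    """Per-country predicted rate curve including that country's random effects."""
    if not fit.design.has_random:
        return predict_marginal(fit, gdp_grid, False, average_over_year, extrapolate)
    if country not in fit.design.levels:
        raise KeyError(f"country {country!r} not in fitted levels")
    if gdp_grid is None:
        gdp_grid = default_gdp_grid(fit)
    i = fit.design.levels.index(country)
    u = fit.coef("re_intercept")[i]
    v = fit.coef("re_slope")[i]
    eta, x = _eta_grid(fit, gdp_grid, average_over_year, extrapolate)
    eta = eta + u + v * (x - fit.design.x_center)[:, None]
    rate = 1000.0 * np.exp(eta)
    rate = rate.mean(axis=1) if average_over_year else rate[:, 0]
    return pd.DataFrame({"gdp": np.asarray(gdp_grid, float), "rate_per_1000": rate})


def find_turning_point(curve: pd.DataFrame, min_points: int = 200) -> float | None:
    """GDP at the interior minimum of a rate-vs-GDP curve, or None.

    The curve (columns ``gdp``, ``rate_per_1000``, at least ``min_points``
    rows) must attain its minimum away from the boundary (more than two grid
    steps in) and be decreasing before and increasing after it; wiggles
    smaller than 0.5% of the curve's amplitude are tolerated. The returned
    value refines the grid argmin by parabolic interpolation in log GDP.
    """
    g = curve["gdp"].to_numpy(dtype=float)
    r = curve["rate_per_1000"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(r))):
        raise ValueError("curve contains non-finite values")
    if g.size < min_points:
        raise ValueError(f"curve needs >= {min_points} grid points, got {g.size}")
    i = int(np.argmin(r))
    n = r.size
    if i < 2 or i > n - 3:
        return None
    wiggle = 5e-3 * (r.max() - r.min())
    if not (np.all(np.diff(r[: i + 1]) <= wiggle) and np.all(np.diff(r[i:]) >= -wiggle)):
        return None
    # parabolic refinement in log-GDP
    lx = np.log(g[i - 1 : i + 2])
    ly = r[i - 1 : i + 2]
    denom = (ly[0] - 2 * ly[1] + ly[2])
    if denom <= 0:
        return float(g[i])
    shift = 0.5 * (ly[0] - ly[2]) / denom * (lx[2] - lx[1])
    return float(np.exp(np.log(g[i]) + np.clip(shift, lx[0] - lx[1], lx[2] - lx[1])))


# ---------------------------------------------------------------------------
# plain-text serialization
# ---------------------------------------------------------------------------


def fit_to_json(fit: GammFit) -> str:
    d = fit.design
    payload = {
        "family": fit.family,
        "beta": fit.beta.tolist(),
        "lambdas": fit.lambdas,
        "deviance": fit.deviance,
        "edf": fit.edf,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "deviance_trace": fit.deviance_trace,
        "theta": fit.theta,
        "scale": fit.scale,
        "design": {
            "k": d.k,
            "knots_gdp": d.knots_gdp.tolist(),
            "Z_gdp": d.Z_gdp.tolist(),
            "knots_year": d.knots_year.tolist(),
            "Z_year": d.Z_year.tolist(),
            "levels": d.levels,
            "x_center": d.x_center,
            "years": d.years.tolist(),
            "gdp": d.gdp.tolist(),
            "has_random": d.has_random,
            "terms": [
                {"name": t.name, "start": t.start, "stop": t.stop, "is_random": t.is_random}
                for t in d.terms
            ],
        },
    }
    return json.dumps(payload)


def fit_from_json(text: str) -> GammFit:
    """Rehydrate a fit for prediction (design matrices are not stored)."""
    p = json.loads(text)
    dd = p["design"]
    terms = [
        _Term(t["name"], t["start"], t["stop"], np.zeros((0, 0)), np.zeros(0), t["is_random"])
        for t in dd["terms"]
    ]
    design = GammDesign(
        y=np.zeros(0),
        offset=np.zeros(0),
        X=np.zeros((0, 0)),
        terms=terms,
        k=dd["k"],
        knots_gdp=np.array(dd["knots_gdp"]),
        Z_gdp=np.array(dd["Z_gdp"]),
        knots_year=np.array(dd["knots_year"]),
        Z_year=np.array(dd["Z_year"]),
        levels=list(dd["levels"]),
        x_center=dd["x_center"],
        years=np.array(dd["years"]),
        gdp=np.array(dd["gdp"]),
        has_random=dd["has_random"],
    )
    return GammFit(
        design=design,
        beta=np.array(p["beta"]),
        lambdas=dict(p["lambdas"]),
        family=p["family"],
        deviance=p["deviance"],
        edf=p["edf"],
        converged=p["converged"],
        n_iter=p["n_iter"],
        deviance_trace=list(p["deviance_trace"]),
        theta=p["theta"],
        scale=p["scale"],
    )
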