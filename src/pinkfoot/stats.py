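"""Flyway-level statistics.

Covers the statistical toolbox of the analysis: per-site linear trends in
spring onset; detrended cross-site predictability regressions with an
early/late period interaction (default split 1979-1999 vs 2000-2022);
within-year site differences; Pearson correlations; and mixed models with
crossed random intercepts of year and individual — Gaussian responses via
REML (statsmodels MixedLM) and binomial responses via a Laplace-
approximation logistic GLMM implemented here (spherical reparametrisation
u = sigma*b, so zero variance is an interior-boundary value and the model
degrades smoothly to an ordinary GLM).

Conventions: "scaled" covariates are z-scored within the modelled dataset;
no multiple-testing correction is applied; alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf


# ---------------------------------------------------------------------------
# results containers


@dataclass
class TrendResult:
    site_id: str
    variable: str
    slope: float
    se: float
    t: float
    p: float
    n_years: int
    degenerate: bool = False     # constant series: slope 0, p undefined


@dataclass
class PredictabilityResult:
    pair: tuple[str, str]
    slope: float                 # pooled (no periods) or early-period slope
    se: float
    p: float
    n: int
    period_slopes: dict | None = None
    interaction_p: float | None = None


@dataclass
class ComparisonResult:
    term: str
    estimate: float
    se: float
    stat: float
    p: float
    df: float | None = None      # approximate, gaussian only


@dataclass
class MixedModelSpec:
    response: str
    fixed: str                              # patsy right-hand side, e.g. "C(area) + onset_z"
    groups: tuple[str, ...] = ("year", "animal_id")
    family: str = "gaussian"
    scale_covariates: tuple[str, ...] = ()  # z-scored within the modelled data


@dataclass
class MixedFit:
    spec: MixedModelSpec
    comparisons: list[ComparisonResult]
    random_sd: dict
    n_obs: int
    converged: bool
    degraded_to_fixed: bool = False
    warnings: list[str] = field(default_factory=list)

    def term(self, name_fragment: str) -> ComparisonResult:
        for c in self.comparisons:
            if name_fragment in c.term:
                return c
        raise KeyError(name_fragment)


# ---------------------------------------------------------------------------
# annual-series analyses


def _align(a: pd.Series, b: pd.Series) -> pd.DataFrame:
    df = pd.concat({"a": a, "b": b}, axis=1).dropna()
    return df


def linear_trend(series: pd.Series, site_id: str = "", variable: str = "") -> TrendResult:
    """OLS of an annual value on calendar year."""
    s = series.dropna()
    if len(s) < 3:
        raise ValueError("need >= 3 years for a trend")
    year = s.index.to_numpy(dtype=float)
    y = s.to_numpy(dtype=float)
    if np.ptp(y) == 0.0:
        return TrendResult(site_id, variable, 0.0, np.nan, np.nan, np.nan, len(s), degenerate=True)
    X = sm.add_constant(year)
    fit = sm.OLS(y, X).fit()
    return TrendResult(site_id, variable, float(fit.params[1]), float(fit.bse[1]),
                       float(fit.tvalues[1]), float(fit.pvalues[1]), len(s))


def detrend(series: pd.Series) -> pd.Series:
    """Residuals of the linear year trend (fitted even when non-significant)."""
    s = series.dropna()
    if len(s) < 3:
        raise ValueError("need >= 3 years to detrend")
    year = s.index.to_numpy(dtype=float)
    y = s.to_numpy(dtype=float)
    X = sm.add_constant(year)
    fit = sm.OLS(y, X).fit()
    return pd.Series(fit.resid, index=s.index)


def cross_site_predictability(
    res_a: pd.Series, res_b: pd.Series,
    periods: tuple[range, range] | None = None,
    labels: tuple[str, str] = ("early", "late"),
    pair: tuple[str, str] = ("A", "B"),
) -> PredictabilityResult:
    """Regress detrended spring at site B on detrended spring at site A.

    With ``periods`` (two year collections partitioning the shared years),
    the model gains a period main effect and a slope-by-period interaction;
    per-period slopes and the interaction p-value are reported. Residual
    variance is pooled across periods in a single model.
    """
    df = _align(res_a, res_b)
    if periods is None:
        if len(df) < 3:
            raise ValueError("need >= 3 shared years")
        fit = sm.OLS(df["b"], sm.add_constant(df["a"])).fit()
        return PredictabilityResult(pair, float(fit.params["a"]), float(fit.bse["a"]),
                                    float(fit.pvalues["a"]), len(df))
    early, late = (set(p) for p in periods)
    df = df[[y in early or y in late for y in df.index]]
    df["period"] = [labels[0] if y in early else labels[1] for y in df.index]
    for lbl in labels:
        if (df["period"] == lbl).sum() < 3:
            raise ValueError(f"period {lbl!r} has fewer than 3 shared years")
    fit = smf.ols(f"b ~ a * C(period, levels={list(labels)!r})", data=df).fit()
    inter = [t for t in fit.params.index if t.startswith("a:")]
    slope_early = float(fit.params["a"])
    slope_late = slope_early + float(fit.params[inter[0]])
    return PredictabilityResult(
        pair, slope_early, float(fit.bse["a"]), float(fit.pvalues["a"]), len(df),
        period_slopes={labels[0]: slope_early, labels[1]: slope_late},
        interaction_p=float(fit.pvalues[inter[0]]),
    )


def within_year_difference(series_a: pd.Series, series_b: pd.Series,
                           term: str = "B-A") -> ComparisonResult:
    """Mean per-year difference B - A via an intercept-only OLS.

    Identical to a paired t-test on the shared years.
    """
    df = _align(series_a, series_b)
    if len(df) < 2:
        raise ValueError("need >= 2 shared years")
    d = (df["b"] - df["a"]).to_numpy()
    fit = sm.OLS(d, np.ones((len(d), 1))).fit()
    return ComparisonResult(term, float(fit.params[0]), float(fit.bse[0]),
                            float(fit.tvalues[0]), float(fit.pvalues[0]), df=float(len(d) - 1))


def correlate(series_a: pd.Series, series_b: pd.Series) -> tuple[float, float]:
    """Pearson r and two-sided p over shared years."""
    df = _align(series_a, series_b)
    if len(df) < 3:
        raise ValueError("need >= 3 shared years")
    if df["a"].std() == 0 or df["b"].std() == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(df["a"], df["b"])
    return float(r), float(p)


# ---------------------------------------------------------------------------
# mixed models


def zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot z-score a constant covariate")
    return (x - x.mean()) / sd


def _prepare_mixed_data(spec: MixedModelSpec, data: pd.DataFrame) -> tuple[pd.DataFrame, list[str], list[str]]:
    d = data.copy()
    cols = [spec.response] + list(spec.groups)
    d = d.dropna(subset=[c for c in cols if c in d])
    for c in spec.scale_covariates:
        d[c] = zscore(d[c])
    usable, msgs = [], []
    for g in spec.groups:
        if g not in d:
            raise ValueError(f"grouping factor {g!r} missing from data")
        if d[g].nunique() >= 2:
            usable.append(g)
        else:
            msgs.append(f"grouping factor {g!r} has < 2 levels; dropped")
    return d, usable, msgs


def fit_mixed(spec: MixedModelSpec, data: pd.DataFrame) -> MixedFit:
    """Fit a mixed model with crossed random intercepts.

    Gaussian responses: REML through statsmodels MixedLM, crossed
    intercepts expressed as variance components over a single trivial
    group. Binomial responses: the Laplace GLMM below (maximum
    likelihood). If every grouping factor has < 2 levels the model
    degrades to a fixed-effects fit with a logged warning.
    Non-convergence is reported on the result, never swallowed.
    """
    d, groups, msgs = _prepare_mixed_data(spec, data)
    for m in msgs:
        warnings.warn(m)
    if spec.family == "gaussian":
        fitter = _fit_gaussian_mixed if groups else _fit_gaussian_fixed
    elif spec.family == "binomial":
        fitter = _fit_binomial_mixed if groups else _fit_binomial_fixed
    else:
        raise ValueError(f"unknown family {spec.family!r}")
    fit = fitter(spec, d, groups)
    fit.warnings.extend(msgs)
    fit.degraded_to_fixed = not groups
    return fit


def _approx_df(n_obs: int, n_fixed: int, groups: list[str], d: pd.DataFrame) -> float:
    """Between-within style residual df for Gaussian mixed models."""
    lost = sum(d[g].nunique() - 1 for g in groups)
    return float(max(n_obs - n_fixed - lost, 1))


def _fit_gaussian_mixed(spec: MixedModelSpec, d: pd.DataFrame, groups: list[str]) -> MixedFit:
    d = d.copy()
    d["_one"] = 1
    vc = {g: f"0 + C({g})" for g in groups}
    model = sm.MixedLM.from_formula(f"{spec.response} ~ {spec.fixed}", data=d,
                                    groups="_one", vc_formula=vc, re_formula="0")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    k = model.k_fe
    df = _approx_df(len(d), k, groups, d)
    comps = []
    for name in res.fe_params.index:
        est, se = float(res.fe_params[name]), float(res.bse_fe[name])
        t = est / se if se > 0 else np.nan
        p = 2 * sps.t.sf(abs(t), df) if np.isfinite(t) else np.nan
        comps.append(ComparisonResult(name, est, se, t, float(p), df=df))
    random_sd = {g: float(np.sqrt(max(res.vcomp[i], 0.0))) for i, g in enumerate(sorted(vc))}
    random_sd["residual"] = float(np.sqrt(res.scale))
    return MixedFit(spec, comps, random_sd, len(d), bool(res.converged))


def _fit_gaussian_fixed(spec: MixedModelSpec, d: pd.DataFrame, groups) -> MixedFit:
    res = smf.ols(f"{spec.response} ~ {spec.fixed}", data=d).fit()
    comps = [ComparisonResult(n, float(res.params[n]), float(res.bse[n]),
                              float(res.tvalues[n]), float(res.pvalues[n]),
                              df=float(res.df_resid))
             for n in res.params.index]
    return MixedFit(spec, comps, {"residual": float(np.sqrt(res.mse_resid))}, len(d), True)


def _fit_binomial_fixed(spec: MixedModelSpec, d: pd.DataFrame, groups) -> MixedFit:
    res = smf.glm(f"{spec.response} ~ {spec.fixed}", data=d,
                  family=sm.families.Binomial()).fit()
    comps = [ComparisonResult(n, float(res.params[n]), float(res.bse[n]),
                              float(res.tvalues[n]), float(res.pvalues[n]))
             for n in res.params.index]
    return MixedFit(spec, comps, {}, len(d), bool(res.converged))


# --- Laplace-approximation binomial GLMM -----------------------------------


def _pirls(y, M, n_fixed, lam_diag, max_iter=60, tol=1e-10):
    """Penalized IRLS over c = [beta; b] with unit-normal penalty on b.

    ``lam_diag`` carries the random-effect sigma for each b entry (the
    spherical reparametrisation folds sigma into the design outside).
    Returns (c, H) with H the penalized Hessian at the optimum.
    """
    n, q = M.shape
    pen = np.zeros(q)
    pen[n_fixed:] = 1.0
    c = np.zeros(q)
    ll_prev = -np.inf
    for _ in range(max_iter):
        eta = M @ c
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = M.T @ (y - mu) - pen * c
        H = (M.T * w) @ M + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving on the penalized log-likelihood
        def pll(cv):
            e = np.clip(M @ cv, -30, 30)
            return float(y @ e - np.logaddexp(0, e).sum() - 0.5 * (pen * cv * cv).sum())
        alpha = 1.0
        base = pll(c)
        while alpha > 1e-4 and pll(c + alpha * step) < base - 1e-12:
            alpha *= 0.5
        c = c + alpha * step
        ll = pll(c)
        if abs(ll - ll_prev) < tol * (1 + abs(ll)):
            break
        ll_prev = ll
    eta = M @ c
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    w = np.clip(mu * (1 - mu), 1e-10, None)
    H = (M.T * w) @ M + np.diag(pen)
    return c, H


def _binomial_laplace_loglik(sigmas, y, X, Z_blocks):
    """Laplace-approximate marginal log-likelihood at the given sigmas."""
    n_fixed = X.shape[1]
    ZL = [s * Z for s, Z in zip(sigmas, Z_blocks)]
    M = np.hstack([X] + ZL) if ZL else X
    c, H = _pirls(y, M, n_fixed, sigmas)
    eta = np.clip(M @ c, -30, 30)
    ll = float(y @ eta - np.logaddexp(0, eta).sum())
    b = c[n_fixed:]
    ll -= 0.5 * float(b @ b)
    # Laplace correction over the random-effect block only
    Hb = H[n_fixed:, n_fixed:]
    if Hb.size:
        sign, logdet = np.linalg.slogdet(Hb)
        ll -= 0.5 * logdet
    return ll, c, H


def _fit_binomial_mixed(spec: MixedModelSpec, d: pd.DataFrame, groups: list[str]) -> MixedFit:
    y_mat, X_mat = patsy.dmatrices(f"{spec.response} ~ {spec.fixed}", d, return_type="dataframe")
    y = y_mat.to_numpy(dtype=float).ravel()
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binomial response must be 0/1")
    X = X_mat.to_numpy(dtype=float)
    names = list(X_mat.columns)
    Z_blocks, level_counts = [], []
    for g in groups:
        codes, levels = pd.factorize(d[g])
        Z = np.zeros((len(d), len(levels)))
        Z[np.arange(len(d)), codes] = 1.0
        Z_blocks.append(Z)
        level_counts.append(len(levels))

    def neg(sig):
        ll, _, _ = _binomial_laplace_loglik(np.abs(sig), y, X, Z_blocks)
        return -ll

    x0 = np.full(len(groups), 0.5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        opt = optimize.minimize(neg, x0, method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 400})
    sigmas = np.abs(opt.x)
    _, c, H = _binomial_laplace_loglik(sigmas, y, X, Z_blocks)
    n_fixed = X.shape[1]
    cov = np.linalg.inv(H)[:n_fixed, :n_fixed]
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    comps = []
    for j, name in enumerate(names):
        z = c[j] / se[j] if se[j] > 0 else np.nan
        p = 2 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        comps.append(ComparisonResult(name, float(c[j]), float(se[j]), float(z), float(p)))
    random_sd = {g: float(s) for g, s in zip(groups, sigmas)}
    return MixedFit(spec, comps, random_sd, len(d), bool(opt.success))


# ---------------------------------------------------------------------------
# assembled models of the breeding analyses


def propensity_model(data: pd.DataFrame, onset_col: str | None = "onset_day",
                     extra: str = "") -> MixedFit:
    """Binomial GLMM of nesting attempts on breeding area (and spring onset).

    ``data`` needs: attempted (0/1), area, year, animal_id, and the onset
    column (z-scored inside the model) when requested. ``extra`` appends
    further fixed-effect terms, e.g. "relative_arrival".
    """
    fixed = "C(area)"
    scale = ()
    if onset_col:
        _require(data, [onset_col])
        fixed += f" + {onset_col}"
        scale = (onset_col,)
    if extra:
        fixed += f" + {extra}"
    _require(data, ["attempted", "area", "year", "animal_id"])
    spec = MixedModelSpec("attempted", fixed, ("year", "animal_id"), "binomial", scale)
    return fit_mixed(spec, data)


def success_model(data: pd.DataFrame, onset_col: str | None = "onset_day",
                  extra: str = "") -> MixedFit:
    """Binomial GLMM of nesting success on area (and onset / relative laying)."""
    fixed = "C(area)"
    scale = ()
    if onset_col:
        _require(data, [onset_col])
        fixed += f" + {onset_col}"
        scale = (onset_col,)
    if extra:
        fixed += f" + {extra}"
    _require(data, ["success", "area", "year", "animal_id"])
    spec = MixedModelSpec("success", fixed, ("year", "animal_id"), "binomial", scale)
    return fit_mixed(spec, data)


def juvenile_model(data: pd.DataFrame) -> list[ComparisonResult]:
    """LM of autumn juvenile proportion on spring onset and population."""
    _require(data, ["juvenile_proportion", "onset_day", "population"])
    res = smf.ols("juvenile_proportion ~ onset_day + C(population)", data=data).fit()
    return [ComparisonResult(n, float(res.params[n]), float(res.bse[n]),
                             float(res.tvalues[n]), float(res.pvalues[n]),
                             df=float(res.df_resid))
            for n in res.params.index]


def _require(data: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing covariates: {missing}")
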