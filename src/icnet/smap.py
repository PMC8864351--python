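"""Multivariate, regularized S-map: time-varying interaction strengths.

The S-map (sequential locally weighted global linear map) fits, for every
target time t*, a ridge regression predicting the effect variable one step
ahead from its causal predictors, with observations weighted by their
state-space distance to the target state:

    w(t) = exp(-theta * d(x_t, x_t*) / d_mean).

The row of local coefficients at t* approximates the Jacobian row
d effect(t+1) / d predictors(t) — the time-varying interaction strengths
IS_{i->j}(t).  theta = 0 recovers a single global linear regression;
larger theta makes the fit increasingly local (state-dependent).  A ridge
penalty lambda stabilizes the weighted fits; theta and lambda can be
selected by leave-one-out cross-validation over grids.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prep import AbundanceTable, standardize

__all__ = [
    "SmapConfig",
    "SmapFit",
    "InteractionTensor",
    "fit_multivariate_smap",
    "build_interaction_tensor",
]

DEFAULT_THETA_GRID = (0.0, 0.1, 0.3, 1.0, 2.0, 4.0, 8.0)
DEFAULT_LAMBDA_GRID = (0.0, 1e-3, 1e-2, 1e-1, 1.0)


@dataclass
class SmapConfig:
    """S-map hyperparameters.

    ``theta`` (state-dependency) and ``ridge_lambda`` may be numbers or
    "cv", in which case they are selected by leave-one-out RMSE over
    ``theta_grid`` x ``lambda_grid``.  ``include_temperature_trend``
    controls whether the temperature covariate and a linear time trend
    enter every model (so coefficients reflect net interactions after
    accounting for the shared seasonal forcing).
    """

    theta: float | str = "cv"
    ridge_lambda: float | str = "cv"
    theta_grid: tuple = DEFAULT_THETA_GRID
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    include_temperature_trend: bool = True
    include_intercept: bool = True

    def __post_init__(self):
        for name, value, grid in (
            ("theta", self.theta, self.theta_grid),
            ("ridge_lambda", self.ridge_lambda, self.lambda_grid),
        ):
            if isinstance(value, str):
                if value != "cv":
                    raise ValueError(f"{name} must be a number or 'cv'")
                if not len(grid):
                    raise ValueError(f"{name} grid empty with 'cv' selection")
            elif value < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SmapFit:
    """Local coefficients and diagnostics of one S-map model."""

    coefficients: np.ndarray      # (n_targets, n_causes)
    covariate_coefficients: np.ndarray  # (n_targets, n_covariates)
    intercepts: np.ndarray        # (n_targets,)
    target_times: np.ndarray      # time index t* of each coefficient row
    loo_skill: float              # Pearson rho of LOO predictions
    loo_rmse: float
    theta: float
    ridge_lambda: float
    cause_names: list = field(default_factory=list)
    covariate_names: list = field(default_factory=list)


def _solve_weighted_ridge(Z, y, w, lam, penalty_mask):
    """beta = argmin sum_t w_t (y_t - Z_t beta)^2 + lam * |P beta|^2."""
    sw = np.sqrt(w)
    Zw = Z * sw[:, None]
    yw = y * sw
    G = Zw.T @ Zw + lam * np.diag(penalty_mask.astype(float))
    try:
        return np.linalg.solve(G, Zw.T @ yw)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular weighted design; set ridge_lambda > 0"
        )


def _smap_pass(Z, y, D, theta, lam, penalty_mask):
    """All local fits for one (theta, lambda).

    Returns (coef matrix at every target, LOO predictions).  Coefficients
    at t* use every observation (the target row has maximal weight 1), so
    theta = 0, lambda = 0 reproduces the global least-squares solution
    exactly; the LOO prediction at t* refits with the target row held out.
    """
    n, p = Z.shape
    d_mean = D.mean() if D.size else 1.0
    if d_mean == 0:
        d_mean = 1.0
    coefs = np.empty((n, p))
    loo_pred = np.empty(n)
    for i in range(n):
        w = np.exp(-theta * D[i] / d_mean)
        beta = _solve_weighted_ridge(Z, y, w, lam, penalty_mask)
        coefs[i] = beta
        w_loo = w.copy()
        w_loo[i] = 0.0
        beta_loo = _solve_weighted_ridge(Z, y, w_loo, lam, penalty_mask)
        loo_pred[i] = Z[i] @ beta_loo
    return coefs, loo_pred


def fit_multivariate_smap(
    effect,
    causes,
    covariates=None,
    config: SmapConfig | None = None,
    cause_names=None,
    covariate_names=None,
) -> SmapFit:
    """Fit a multivariate regularized S-map for one effect variable.

    ``effect`` is the (standardized) series of the target taxon;
    ``causes`` a (n, p) matrix of its causal predictors at time t
    (typically the effect's own series plus its significant causes);
    ``covariates`` an optional (n, q) matrix of exogenous terms
    (temperature, linear trend).  The model predicts effect(t+1) from
    causes(t) and covariates(t); state-space distances for the local
    weights are computed over the cause coordinates only.

    Returns a :class:`SmapFit` with one coefficient row per usable target
    time.  Rows with missing values are dropped from both library and
    targets.  With lambda = 0 a singular design (e.g. p >= n) raises.
    """
    config = config or SmapConfig()
    y_full = np.asarray(effect, dtype=float)
    X = np.atleast_2d(np.asarray(causes, dtype=float))
    if X.shape[0] != y_full.size:
        X = X.T
    n_all = y_full.size
    if covariates is None:
        V = np.empty((n_all, 0))
    else:
        V = np.atleast_2d(np.asarray(covariates, dtype=float))
        if V.shape[0] != n_all:
            V = V.T

    # predict effect(t+1) from state at t
    y = y_full[1:]
    Xt = X[:-1]
    Vt = V[:-1]
    valid = (
        ~np.isnan(y)
        & ~np.isnan(Xt).any(axis=1)
        & (~np.isnan(Vt).any(axis=1) if Vt.shape[1] else True)
    )
    times = np.where(valid)[0]
    y = y[valid]
    Xv = Xt[valid]
    Vv = Vt[valid]
    n, p_cause = Xv.shape
    cols = [Xv]
    if Vv.shape[1]:
        cols.append(Vv)
    if config.include_intercept:
        cols.append(np.ones((n, 1)))
    Z = np.column_stack(cols)
    p = Z.shape[1]
    penalty_mask = np.ones(p, dtype=bool)
    if config.include_intercept:
        penalty_mask[-1] = False  # intercept unpenalized

    if p * p > n:
        warnings.warn(
            f"number of predictors squared ({p}^2) exceeds usable length "
            f"({n}); S-map coefficients may be unreliable"
        )
    lam_given = config.ridge_lambda
    if (not isinstance(lam_given, str)) and lam_given == 0 and p >= n:
        raise ValueError("p >= n with ridge_lambda = 0; set lambda > 0")

    D = np.sqrt(
        ((Xv[:, None, :] - Xv[None, :, :]) ** 2).sum(-1)
    )

    thetas = (
        config.theta_grid if isinstance(config.theta, str) else [config.theta]
    )
    lambdas = (
        config.lambda_grid
        if isinstance(config.ridge_lambda, str)
        else [config.ridge_lambda]
    )
    best = None
    for theta in thetas:
        for lam in lambdas:
            if lam == 0 and p >= n:
                continue
            try:
                coefs, loo_pred = _smap_pass(Z, y, D, theta, lam, penalty_mask)
            except np.linalg.LinAlgError:
                if lam == 0 and len(lambdas) > 1:
                    continue
                raise
            rmse = float(np.sqrt(np.mean((loo_pred - y) ** 2)))
            if best is None or rmse < best[0] - 1e-12:
                best = (rmse, theta, lam, coefs, loo_pred)
    if best is None:
        raise ValueError("no (theta, lambda) combination produced a fit")
    rmse, theta, lam, coefs, loo_pred = best
    sd_p, sd_o = np.std(loo_pred), np.std(y)
    skill = (
        float(np.corrcoef(loo_pred, y)[0, 1])
        if sd_p > 0 and sd_o > 0
        else np.nan
    )
    q = V.shape[1]
    cov_coefs = coefs[:, p_cause:p_cause + q]
    intercepts = (
        coefs[:, -1] if config.include_intercept else np.zeros(len(coefs))
    )
    return SmapFit(
        coefficients=coefs[:, :p_cause],
        covariate_coefficients=cov_coefs,
        intercepts=intercepts,
        target_times=times,
        loo_skill=skill,
        loo_rmse=rmse,
        theta=float(theta),
        ridge_lambda=float(lam),
        cause_names=list(cause_names or range(p_cause)),
        covariate_names=list(covariate_names or range(q)),
    )


@dataclass
class InteractionTensor:
    """Time-indexed interaction matrices from per-effect S-map models.

    ``coefficients[p, t, i, j]`` is the S-map coefficient of predictor
    taxon j in effect taxon i's model at time t in plot p — the
    interaction strength IS_{j->i}(t); the diagonal holds self-regulation
    (the effect's own lag).  ``valid[p, t, i, j]`` marks fitted entries.
    Covariate coefficients and per-model metadata are stored separately.
    """

    coefficients: np.ndarray  # (n_plots, n_time, n_taxa, n_taxa)
    valid: np.ndarray         # same shape, boolean
    taxon_ids: list
    plot_ids: list
    dates: pd.DatetimeIndex
    covariate_coefficients: dict = field(default_factory=dict)
    model_info: dict = field(default_factory=dict)

    def matrix_at(self, plot, t) -> np.ndarray:
        """Interaction matrix (effect x cause) at one plot/time; entries
        never fitted are NaN."""
        p = (
            self.plot_ids.index(plot)
            if not isinstance(plot, (int, np.integer))
            else plot
        )
        M = np.where(self.valid[p, t], self.coefficients[p, t], np.nan)
        return M

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        P, T, n, _ = self.coefficients.shape
        for p in range(P):
            for t in range(T):
                ii, jj = np.where(self.valid[p, t])
                for i, j in zip(ii, jj):
                    rows.append(
                        {
                            "plot": self.plot_ids[p],
                            "date": self.dates[t],
                            "cause": self.taxon_ids[j],
                            "effect": self.taxon_ids[i],
                            "IS": self.coefficients[p, t, i, j],
                        }
                    )
        return pd.DataFrame(rows)

    def save(self, csv_path, json_path=None) -> None:
        self.to_long_frame().to_csv(csv_path, index=False)
        if json_path:
            with open(json_path, "w") as fh:
                json.dump(self.model_info, fh, indent=2, default=float)

    def static_edge_list(self, exclude_self: bool = True) -> pd.DataFrame:
        """Time-averaged |IS| per (cause, effect, plot) — the static
        network view for display and graph tools."""
        df = self.to_long_frame()
        if exclude_self:
            df = df[df["cause"] != df["effect"]]
        out = (
            df.assign(abs_IS=df["IS"].abs())
            .groupby(["plot", "cause", "effect"], as_index=False)["abs_IS"]
            .mean()
        )
        return out


def build_interaction_tensor(
    links,
    table: AbundanceTable,
    temperature=None,
    config: SmapConfig | None = None,
    standardized: bool = False,
) -> InteractionTensor:
    """Assemble the time-varying interaction tensor from detected links.

    ``links`` is an iterable of significant (cause, effect) taxon pairs
    (ids or indices) from the CCM screen.  One S-map model is fitted per
    effect taxon per plot, with predictors = the effect's own lag + its
    significant causes (+ temperature and a linear time trend when the
    config includes them).  Effects with no detected causes get a
    self-lag (+ covariate) model.  Models whose predictor count squared
    exceeds the usable series length are flagged in ``model_info``.
    """
    config = config or SmapConfig()
    n, T, P = table.n_taxa, table.n_time, table.n_plots

    def _idx(x):
        return x if isinstance(x, (int, np.integer)) else (
            table.taxon_ids.index(x)
        )

    links_idx = [( _idx(c), _idx(e)) for c, e in links]
    causes_of = {i: [] for i in range(n)}
    for c, e in links_idx:
        if c != e and c not in causes_of[e]:
            causes_of[e].append(c)

    coefficients = np.full((P, T, n, n), np.nan)
    valid = np.zeros((P, T, n, n), dtype=bool)
    cov_store = {}
    model_info = {}
    for p in range(P):
        plot = table.plot_ids[p]
        Xstd = np.empty((T, n))
        usable = np.ones(n, dtype=bool)
        for i in range(n):
            raw = table.values[:, :, p][i]
            if standardized:
                Xstd[:, i] = raw
            else:
                try:
                    Xstd[:, i] = standardize(raw)
                except ValueError:
                    Xstd[:, i] = np.nan
                    usable[i] = False
        covs, cov_names = [], []
        if config.include_temperature_trend:
            if temperature is not None:
                covs.append(standardize(np.asarray(temperature, float)[:T]))
                cov_names.append("temperature")
            covs.append(standardize(np.arange(T, dtype=float)))
            cov_names.append("linear_trend")
        V = np.column_stack(covs) if covs else None

        for i in range(n):
            if not usable[i]:
                continue
            pred_idx = [i] + [c for c in causes_of[i] if usable[c]]
            fit = fit_multivariate_smap(
                Xstd[:, i],
                Xstd[:, pred_idx],
                covariates=V,
                config=config,
                cause_names=[table.taxon_ids[c] for c in pred_idx],
                covariate_names=cov_names,
            )
            for row, t in zip(range(len(fit.target_times)), fit.target_times):
                for k, c in enumerate(pred_idx):
                    coefficients[p, t, i, c] = fit.coefficients[row, k]
                    valid[p, t, i, c] = True
            cov_store[(plot, table.taxon_ids[i])] = {
                "times": fit.target_times.tolist(),
                "covariates": fit.covariate_coefficients.tolist(),
                "intercepts": fit.intercepts.tolist(),
                "names": cov_names,
            }
            n_pred = len(pred_idx) + len(cov_names) + 1
            model_info[f"{plot}:{table.taxon_ids[i]}"] = {
                "theta": fit.theta,
                "lambda": fit.ridge_lambda,
                "loo_skill": fit.loo_skill,
                "loo_rmse": fit.loo_rmse,
                "n_predictors": n_pred,
                "n_points": int(len(fit.target_times)),
                "reliability_flag": bool(
                    n_pred**2 > len(fit.target_times)
                ),
            }
    return InteractionTensor(
        coefficients=coefficients,
        valid=valid,
        taxon_ids=list(table.taxon_ids),
        plot_ids=list(table.plot_ids),
        dates=table.dates,
        covariate_coefficients=cov_store,
        model_info=model_info,
    )
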