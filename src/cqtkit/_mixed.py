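"""Shared helpers around statsmodels MixedLM fits.

All mixed models in the package use a random subject intercept (the
compound-symmetry covariance of the analysis plans), optionally extended with
a random concentration slope. Confidence intervals for fixed-effect linear
combinations use a t distribution with (n_obs - rank of the fixed design)
degrees of freedom.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from scipy import stats

__all__ = ["fit_mixedlm", "fixed_cov", "resid_df", "linear_combination", "contrast_rows", "information_criterion"]


def fit_mixedlm(
    formula: str,
    data: pd.DataFrame,
    groups: str = "subject_id",
    re_formula: str | None = None,
    reml: bool = True,
    start_params=None,
):
    """REML/ML MixedLM fit with quiet, robust optimisation.

    ``start_params`` (a ``MixedLMParams``) warm-starts the optimisation —
    used for ML refits from the REML solution, which keeps line searches
    away from degenerate variance regions.
    """
    model = smf.mixedlm(formula, data, groups=data[groups], re_formula=re_formula)
    # variance components on the likelihood boundary can break an optimizer
    # (non-finite restricted likelihood, singular GLS solves during line
    # search); walk a chain of optimizers, return the first converged sane
    # fit, otherwise the best-likelihood sane fit seen
    last_err: Exception | None = None
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "cg", "powell"):
            try:
                res = model.fit(reml=reml, method=method, maxiter=200, start_params=start_params)
            except Exception as err:  # singular V at a line-search point
                last_err = err
                continue
            sane = (
                np.isfinite(res.llf)
                and np.all(np.isfinite(res.fe_params))
                and np.all(np.isfinite(np.asarray(res.cov_re)))
                and np.isfinite(res.scale)
            )
            if not sane:
                continue
            if res.converged:
                return res
            if best is None or res.llf > best.llf:
                best = res
    if best is None:
        raise last_err if last_err is not None else RuntimeError("mixed model fit failed")
    return best


def fixed_cov(res) -> np.ndarray:
    """GLS covariance of the fixed effects, (sum_g X_g' V_g^-1 X_g)^-1.

    Evaluated at the estimated variance components. Unlike the slices of the
    Hessian-based ``cov_params``, this stays finite when a variance component
    sits on the boundary. Cached on the results object.
    """
    cached = getattr(res, "_cqtkit_fixed_cov", None)
    if cached is not None:
        return cached
    model = res.model
    X = model.exog
    k = model.k_fe
    G = np.atleast_2d(np.asarray(res.cov_re))
    scale = float(res.scale)
    info = np.zeros((k, k))
    for ix in model.row_indices.values():
        Xg = X[ix]
        Zg = model.exog_re[ix] if model.exog_re is not None else np.ones((len(ix), 1))
        Vg = scale * np.eye(len(ix)) + Zg @ G @ Zg.T
        info += Xg.T @ np.linalg.solve(Vg, Xg)
    cov = np.linalg.pinv(info)
    res._cqtkit_fixed_cov = cov
    return cov


def robust_fixed_cov(res) -> np.ndarray:
    """Cluster-robust (sandwich) covariance of the fixed effects, CR2.

    Working in the whitened model (each subject's block scaled by
    ``V_g^-1/2``), the meat uses leverage-adjusted residuals
    ``(I - H_gg)^-1/2 r~_g`` — the Bell-McCaffrey CR2 correction, which
    counters the downward bias of the plain sandwich when there are few
    clusters and cluster-level covariates (sequence, sex). Robust to
    residual covariance the random-effects structure does not capture
    (e.g. between-subject response heterogeneity), which is what drives
    the uncertainty of a concentration slope. Cached on the results object.
    """
    cached = getattr(res, "_cqtkit_robust_cov", None)
    if cached is not None:
        return cached
    model = res.model
    X = model.exog
    y = model.endog
    k = model.k_fe
    beta = np.asarray(res.fe_params)
    G = np.atleast_2d(np.asarray(res.cov_re))
    scale = float(res.scale)

    blocks = []
    A = np.zeros((k, k))
    for ix in model.row_indices.values():
        Xg = X[ix]
        rg = y[ix] - Xg @ beta
        Zg = model.exog_re[ix] if model.exog_re is not None else np.ones((len(ix), 1))
        Vg = scale * np.eye(len(ix)) + Zg @ G @ Zg.T
        w, Q = np.linalg.eigh(Vg)
        w = np.clip(w, 1e-10, None)
        Vg_isqrt = (Q / np.sqrt(w)) @ Q.T
        Xw = Vg_isqrt @ Xg
        rw = Vg_isqrt @ rg
        A += Xw.T @ Xw
        blocks.append((Xw, rw))
    Ainv = np.linalg.pinv(A)

    B = np.zeros((k, k))
    for Xw, rw in blocks:
        H = Xw @ Ainv @ Xw.T
        w, Q = np.linalg.eigh(np.eye(len(rw)) - H)
        w = np.clip(w, 1e-10, None)
        adj = (Q / np.sqrt(w)) @ Q.T  # (I - H_gg)^(-1/2)
        u = Xw.T @ (adj @ rw)
        B += np.outer(u, u)
    cov = Ainv @ B @ Ainv
    res._cqtkit_robust_cov = cov
    return cov


def n_groups(res) -> int:
    return len(res.model.row_indices)


def resid_df(res) -> float:
    """Residual degrees of freedom: n_obs minus fixed-design rank. Cached."""
    cached = getattr(res, "_cqtkit_resid_df", None)
    if cached is not None:
        return cached
    exog = res.model.exog
    df = res.model.nobs - np.linalg.matrix_rank(exog)
    res._cqtkit_resid_df = df
    return df


def linear_combination(res, L: np.ndarray, ci_level: float = 0.90):
    """Estimate, SE and two-sided t CI for the combination ``L @ beta``."""
    beta = np.asarray(res.fe_params)
    est = float(L @ beta)
    se = float(np.sqrt(L @ fixed_cov(res) @ L))
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df=resid_df(res))
    return est, se, est - tcrit * se, est + tcrit * se


def contrast_rows(res, row_a: dict, row_b: dict) -> np.ndarray:
    """Contrast vector x(row_a) - x(row_b) built from the fit's design info."""
    design_info = res.model.data.design_info
    (xa,) = patsy.build_design_matrices([design_info], pd.DataFrame([row_a]))
    (xb,) = patsy.build_design_matrices([design_info], pd.DataFrame([row_b]))
    return np.asarray(xa)[0] - np.asarray(xb)[0]


def information_criterion(res) -> float:
    """AIC with k = fixed effects + variance parameters + residual variance.

    Computed from the fit's own log-likelihood, so REML fits yield a
    restricted-likelihood AIC and ML refits the standard one.
    """
    if not np.isfinite(res.llf):
        return float("inf")  # boundary/degenerate fit: never selected
    k = len(res.params) + 1  # + profiled residual variance
    return float(-2.0 * res.llf + 2.0 * k)
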