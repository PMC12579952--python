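"""Gamma generalized linear mixed model with a single random intercept.

Fits y ~ Gamma(shape k, mean mu), log mu = X beta + b_g, b_g ~ N(0, sigma^2)
for one grouping factor (here: bee identity), by Laplace approximation:

* inner loop — penalized Newton iterations jointly maximize the joint
  log-density over (beta, b) for fixed (k, sigma^2); the Gamma/log-link
  observed information (k * y * exp(-eta)) keeps the Hessian positive
  definite for positive responses;
* outer loop — Nelder–Mead maximizes the Laplace-approximate marginal
  log-likelihood over (log k, log sigma^2).  The random intercepts are
  independent across groups, so the Laplace correction is a sum of scalar
  log-curvatures, no sparse algebra needed.

Fixed-effect covariances come from the joint curvature at the optimum
(random-effect uncertainty propagated).  If the optimizer fails, callers can
fall back to a fixed-effects Gamma GLM (see firing_stats.fit_temporal_glmm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, special

__all__ = ["GammaGLMMResult", "fit_gamma_glmm"]

_LOG_SHAPE_BOUNDS = (-6.0, 9.0)
_LOG_SIGMA2_BOUNDS = (-12.0, 6.0)


@dataclass
class GammaGLMMResult:
    """Fitted Gamma mixed model (Laplace approximation)."""

    params: np.ndarray
    param_names: list[str]
    cov_params: np.ndarray
    shape: float
    sigma2: float
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int
    design_info: object = field(repr=False)
    random_effects: pd.Series = field(repr=False, default=None)

    @property
    def df_resid(self) -> int:
        return self.n_obs - len(self.params) - self.n_groups

    def params_series(self) -> pd.Series:
        return pd.Series(self.params, index=self.param_names)


def _joint_parts(y, X, group_idx, beta, b, shape, sigma2):
    eta = X @ beta + b[group_idx]
    # eta-dependent part of the Gamma log-likelihood
    ll_eta = -shape * np.sum(y * np.exp(-eta) + eta)
    penalty = -np.sum(b**2) / (2.0 * sigma2)
    return eta, ll_eta + penalty


def _inner_newton(y, X, group_idx, n_groups, shape, sigma2, u0, tol=1e-8, maxiter=200):
    """Maximize the joint penalized log-density over u = (beta, b)."""
    n, p = X.shape
    Z_cols = group_idx  # indicator structure handled by bincount
    u = u0.copy()
    beta, b = u[:p], u[p:]
    _, obj = _joint_parts(y, X, group_idx, beta, b, shape, sigma2)
    for _ in range(maxiter):
        eta = X @ beta + b[group_idx]
        w = shape * y * np.exp(-eta)  # observed information weights, > 0
        g_eta = shape * (y * np.exp(-eta) - 1.0)
        grad = np.concatenate(
            [X.T @ g_eta, np.bincount(Z_cols, g_eta, minlength=n_groups) - b / sigma2]
        )
        if np.max(np.abs(grad)) < tol:
            return u, True
        # full (p + m) Hessian; m is small (one intercept per bee)
        H = np.zeros((p + n_groups, p + n_groups))
        H[:p, :p] = X.T @ (X * w[:, None])
        XtWZ = np.zeros((p, n_groups))
        for j in range(p):
            XtWZ[j] = np.bincount(Z_cols, w * X[:, j], minlength=n_groups)
        H[:p, p:] = XtWZ
        H[p:, :p] = XtWZ.T
        d = np.bincount(Z_cols, w, minlength=n_groups) + 1.0 / sigma2
        H[p:, p:] = np.diag(d)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return u, False
        # step-halving line search on the joint objective
        for _ in range(30):
            u_new = u + step
            beta_n, b_n = u_new[:p], u_new[p:]
            _, obj_new = _joint_parts(y, X, group_idx, beta_n, b_n, shape, sigma2)
            if np.isfinite(obj_new) and obj_new >= obj - 1e-12:
                break
            step *= 0.5
        else:
            return u, False
        if abs(obj_new - obj) < tol * (abs(obj) + 1.0) and np.max(np.abs(step)) < 1e-6:
            u, obj = u_new, obj_new
            return u, True
        u, beta, b, obj = u_new, beta_n, b_n, obj_new
    return u, False


def _laplace_loglik(y, X, group_idx, n_groups, shape, sigma2, u):
    n = len(y)
    p = X.shape[1]
    beta, b = u[:p], u[p:]
    eta = X @ beta + b[group_idx]
    ll = np.sum(
        shape * np.log(shape)
        - special.gammaln(shape)
        + (shape - 1.0) * np.log(y)
        - shape * (y * np.exp(-eta) + eta)
    )
    curv = np.bincount(group_idx, shape * y * np.exp(-eta), minlength=n_groups) + 1.0 / sigma2
    return (
        ll
        - np.sum(b**2) / (2.0 * sigma2)
        - 0.5 * n_groups * np.log(sigma2)
        - 0.5 * np.sum(np.log(curv))
    )


def fit_gamma_glmm(
    formula: str,
    data: pd.DataFrame,
    groups: str,
    tol: float = 1e-8,
    max_inner: int = 200,
    max_outer: int = 200,
) -> GammaGLMMResult:
    """Fit a Gamma/log-link GLMM with a random intercept per level of ``groups``.

    ``formula`` describes the fixed effects (patsy syntax); the response must
    be strictly positive.  Raises ValueError on non-positive responses.
    """
    ymat, X = patsy.dmatrices(formula, data, return_type="dataframe")
    y = ymat.to_numpy().ravel()
    if np.any(y <= 0):
        raise ValueError("Gamma GLMM requires strictly positive responses")
    design_info = X.design_info
    names = list(X.columns)
    X = X.to_numpy()
    codes, levels = pd.factorize(data[groups].to_numpy(), sort=True)
    n_groups = len(levels)
    n, p = X.shape

    # start from a fixed-effects Gamma fit via one IRLS-ish least squares on log y
    beta0, *_ = np.linalg.lstsq(X, np.log(y), rcond=None)
    u0 = np.concatenate([beta0, np.zeros(n_groups)])
    resid = np.log(y) - X @ beta0
    v = max(np.var(resid), 1e-3)
    theta0 = np.array([np.log(max(1.0 / v, 0.1)), np.log(max(v / 4.0, 1e-4))])

    state = {"u": u0}

    def neg_marginal(theta):
        log_k = float(np.clip(theta[0], *_LOG_SHAPE_BOUNDS))
        log_s2 = float(np.clip(theta[1], *_LOG_SIGMA2_BOUNDS))
        k, s2 = np.exp(log_k), np.exp(log_s2)
        u, ok = _inner_newton(
            y, X, codes, n_groups, k, s2, state["u"], tol=tol, maxiter=max_inner
        )
        if not ok:
            return 1e10
        state["u"] = u
        ll = _laplace_loglik(y, X, codes, n_groups, k, s2, u)
        return -ll if np.isfinite(ll) else 1e10

    res = optimize.minimize(
        neg_marginal,
        theta0,
        method="Nelder-Mead",
        options={"maxiter": max_outer, "xatol": 1e-6, "fatol": 1e-8},
    )
    log_k = float(np.clip(res.x[0], *_LOG_SHAPE_BOUNDS))
    log_s2 = float(np.clip(res.x[1], *_LOG_SIGMA2_BOUNDS))
    shape_hat, sigma2_hat = np.exp(log_k), np.exp(log_s2)
    u, inner_ok = _inner_newton(
        y, X, codes, n_groups, shape_hat, sigma2_hat, state["u"], tol=tol,
        maxiter=max_inner,
    )
    beta, b = u[:p], u[p:]
    eta = X @ beta + b[codes]
    w = shape_hat * y * np.exp(-eta)
    H = np.zeros((p + n_groups, p + n_groups))
    H[:p, :p] = X.T @ (X * w[:, None])
    XtWZ = np.zeros((p, n_groups))
    for j in range(p):
        XtWZ[j] = np.bincount(codes, w * X[:, j], minlength=n_groups)
    H[:p, p:] = XtWZ
    H[p:, :p] = XtWZ.T
    H[p:, p:] = np.diag(np.bincount(codes, w, minlength=n_groups) + 1.0 / sigma2_hat)
    cov_full = np.linalg.pinv(H)
    loglik = _laplace_loglik(y, X, codes, n_groups, shape_hat, sigma2_hat, u)
    converged = bool(res.success or res.fun < 1e9) and inner_ok and np.isfinite(loglik)
    return GammaGLMMResult(
        params=beta,
        param_names=names,
        cov_params=cov_full[:p, :p],
        shape=shape_hat,
        sigma2=sigma2_hat,
        loglik=float(loglik),
        converged=converged,
        n_obs=n,
        n_groups=n_groups,
        design_info=design_info,
        random_effects=pd.Series(b, index=levels),
    )
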