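"""Elasticnet-penalized logistic regression by IRLS coordinate descent.

Minimizes, over coefficients ``beta`` and intercept ``b0``::

    -(1/n) loglik(beta, b0) + lambda * sum_j pf_j * P_alpha(beta_j)
    P_alpha(b) = alpha * |b| + (1 - alpha)/2 * b^2

where ``pf_j`` are per-feature penalty factors: 0 marks an unpenalized
covariate (age, sex), 1 a penalized component score.  The intercept is never
penalized.  The solver follows the glmnet recipe: an outer quadratic (IRLS)
approximation around the current fit, an inner cycle of soft-threshold
coordinate updates, and warm starts down a log-spaced lambda path from
``lambda_max`` (the smallest lambda at which every penalized coefficient is
zero) to ``lambda_max * lambda_min_ratio``.

Predictors are assumed already standardized by the caller (the pipeline
feeds standardized, PC-adjusted component scores); no internal rescaling is
performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ContractError

_ALPHA0_PROXY = 1e-3  # glmnet convention: lambda_max for alpha=0 uses this


@dataclass
class EnetPath:
    lambdas: np.ndarray  # descending
    coefs: np.ndarray  # (n_lambda, p)
    intercepts: np.ndarray  # (n_lambda,)
    alpha: float


def _soft(z: float, g: float) -> float:
    if z > g:
        return z - g
    if z < -g:
        return z + g
    return 0.0


def _irls_enet(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    pf: np.ndarray,
    beta: np.ndarray,
    b0: float,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, float]:
    """One (alpha, lambda) solve, warm-started at (beta, b0)."""
    n, p = X.shape
    eta = X @ beta + b0
    lam_l1 = lam * alpha * pf
    lam_l2 = lam * (1.0 - alpha) * pf
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-5, None)
        z = eta + (y - mu) / w
        # covariance-update coordinate descent: all inner-loop quantities are
        # O(p) once these weighted moments are cached for the IRLS iteration
        wX = w[:, None] * X
        G = wX.T @ X  # (p, p)
        q = wX.T @ z  # (p,)
        xw = wX.sum(axis=0)  # (p,)
        sz = float(w @ z)
        wsum = float(np.sum(w))
        wxx = np.diag(G) / n
        beta_old = beta.copy()
        b0_old = b0
        gb = G @ beta
        for _inner in range(1000):
            d0 = (sz - float(xw @ beta)) / wsum - b0
            b0 += d0
            max_delta = abs(d0)
            for j in range(p):
                rho = (q[j] - gb[j] + G[j, j] * beta[j] - b0 * xw[j]) / n
                if pf[j] > 0:
                    num = _soft(rho, lam_l1[j])
                    den = wxx[j] + lam_l2[j]
                else:
                    num, den = rho, wxx[j]
                new = num / den if den > 0 else 0.0
                d = new - beta[j]
                if d != 0.0:
                    gb += d * G[:, j]
                    beta[j] = new
                    if abs(d) > max_delta:
                        max_delta = abs(d)
            if max_delta < tol:
                break
        eta = X @ beta + b0
        if max(np.max(np.abs(beta - beta_old)), abs(b0 - b0_old)) < tol:
            break
    return beta, b0


def _null_fit(X, y, pf, max_iter=100):
    """Fit intercept + unpenalized covariates only (penalized coefs at 0)."""
    free = np.flatnonzero(pf == 0)
    beta = np.zeros(X.shape[1])
    b0 = float(np.log(np.mean(y) / (1.0 - np.mean(y))))
    if len(free) == 0:
        return beta, b0
    Xf = X[:, free]
    bf = np.zeros(len(free))
    for _ in range(max_iter):
        eta = Xf @ bf + b0
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-5, None)
        A = np.column_stack([np.ones(len(y)), Xf])
        H = (A * w[:, None]).T @ A
        gvec = A.T @ (y - mu)
        try:
            step = np.linalg.solve(H, gvec)
        except np.linalg.LinAlgError:
            break
        b0 += step[0]
        bf += step[1:]
        if np.max(np.abs(step)) < 1e-10:
            break
    beta[free] = bf
    return beta, b0


def lambda_max(X, y, alpha, pf) -> float:
    """Smallest lambda at which all penalized coefficients are exactly zero."""
    X = np.asarray(X, dtype=float)
    X = X - X.mean(axis=0)
    beta0, b0 = _null_fit(X, y, pf)
    mu = 1.0 / (1.0 + np.exp(-(X @ beta0 + b0)))
    grad = np.abs(X.T @ (y - mu)) / len(y)
    pen = pf > 0
    if not pen.any():
        raise ContractError("lambda_max: no penalized features")
    a = max(alpha, _ALPHA0_PROXY)
    return float(np.max(grad[pen] / (a * pf[pen])))


def enet_logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    penalty_factor: np.ndarray | None = None,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
) -> EnetPath:
    """Solve the full warm-started lambda path for one mixing parameter."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ContractError("X/y shape mismatch")
    if not np.all(np.isfinite(X)):
        raise ContractError("non-finite predictor values")
    if not 0.0 <= alpha <= 1.0:
        raise ContractError("alpha outside [0,1]")
    pf = (
        np.ones(X.shape[1])
        if penalty_factor is None
        else np.asarray(penalty_factor, dtype=float)
    )
    if lambdas is None:
        lmax = lambda_max(X, y, alpha, pf)
        lambdas = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)
    lambdas = np.asarray(lambdas, dtype=float)

    # centering decouples the intercept from the coordinate updates and does
    # not change the penalized solution; fold the means back in at the end
    xbar = X.mean(axis=0)
    Xc = X - xbar
    beta, b0 = _null_fit(Xc, y, pf)
    coefs = np.empty((len(lambdas), X.shape[1]))
    intercepts = np.empty(len(lambdas))
    for k, lam in enumerate(lambdas):
        beta, b0 = _irls_enet(Xc, y, alpha, lam, pf, beta.copy(), b0)
        coefs[k] = beta
        intercepts[k] = b0 - float(xbar @ beta)
    return EnetPath(lambdas=lambdas, coefs=coefs, intercepts=intercepts, alpha=alpha)


def enet_logistic_fit(
    X, y, alpha, lam, penalty_factor=None, warm_path: bool = True
) -> tuple[np.ndarray, float]:
    """Single (alpha, lambda) solution, warm-started down a short path for
    stability (matching how the path solutions were obtained)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    pf = (
        np.ones(X.shape[1])
        if penalty_factor is None
        else np.asarray(penalty_factor, dtype=float)
    )
    if warm_path:
        lmax = lambda_max(X, y, alpha, pf)
        if lam < lmax:
            lambdas = np.geomspace(lmax, lam, 10)
        else:
            lambdas = np.array([lam])
    else:
        lambdas = np.array([lam])
    xbar = X.mean(axis=0)
    Xc = X - xbar
    beta, b0 = _null_fit(Xc, y, pf)
    for l_ in lambdas:
        beta, b0 = _irls_enet(Xc, y, alpha, l_, pf, beta.copy(), b0)
    return beta, b0 - float(xbar @ beta)
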