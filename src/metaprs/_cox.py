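"""Fast vectorized Cox partial-likelihood machinery.

This module backs the bootstrap and simulation loops where a full
`lifelines` fit per resample would be prohibitive: a Newton solver for the
Cox proportional-hazards model with Efron tie handling, a Breslow baseline
cumulative hazard, and Harrell's concordance with an infinitesimal-jackknife
variance.  `lifelines` remains the reference implementation it is validated
against in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ContractError


@dataclass
class CoxFit:
    beta: np.ndarray
    se: np.ndarray  # sqrt of inverse-Hessian diagonal
    loglik: float
    converged: bool
    flags: list


def _group_layout(t: np.ndarray):
    """Boundaries of tied-time groups on an ascending-sorted time vector."""
    first = np.ones(len(t), dtype=bool)
    first[1:] = t[1:] != t[:-1]
    starts = np.flatnonzero(first)
    return starts


def cox_newton(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 30,
    tol: float = 1e-10,
) -> CoxFit:
    """Newton-Raphson maximization of the Efron partial likelihood."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if event.sum() == 0:
        raise ContractError("cox_newton: no events")
    if np.any(time <= 0):
        raise ContractError("cox_newton: non-positive follow-up time")

    order = np.argsort(time, kind="stable")
    X = np.ascontiguousarray(X[order])
    t = time[order]
    e = event[order]
    n, p = X.shape
    starts = _group_layout(t)

    d_g = np.add.reduceat(e.astype(float), starts)
    has_death = d_g > 0
    multi = d_g > 1

    beta = np.zeros(p)
    flags: list = []
    converged = False
    ll = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        etac = eta - eta.mean()
        w = np.exp(etac)
        wX = w[:, None] * X
        wXX = wX[:, :, None] * X[:, None, :]  # (n, p, p)

        gw = np.add.reduceat(w, starts)
        gwX = np.add.reduceat(wX, starts, axis=0)
        gwXX = np.add.reduceat(wXX.reshape(n, p * p), starts, axis=0)
        S0 = np.cumsum(gw[::-1])[::-1]
        S1 = np.cumsum(gwX[::-1], axis=0)[::-1]
        S2 = np.cumsum(gwXX[::-1], axis=0)[::-1].reshape(-1, p, p)

        we = w * e
        sd0 = np.add.reduceat(we, starts)
        sd1 = np.add.reduceat(we[:, None] * X, starts, axis=0)
        sd2 = np.add.reduceat(
            (e[:, None] * wXX.reshape(n, p * p)), starts, axis=0
        ).reshape(-1, p, p)
        xd = np.add.reduceat(e[:, None] * X, starts, axis=0)
        etad = np.add.reduceat(e * etac, starts)

        grad = np.zeros(p)
        hess = np.zeros((p, p))
        ll = 0.0

        # single-death groups (the common case): plain Breslow==Efron term
        sg = has_death & ~multi
        if sg.any():
            phi = S0[sg]
            m = S1[sg] / phi[:, None]
            grad += xd[sg].sum(axis=0) - m.sum(axis=0)
            hess += np.einsum("gij,g->ij", S2[sg], 1.0 / phi) - np.einsum(
                "gi,gj->ij", m, m
            )
            ll += float(etad[sg].sum() - np.log(phi).sum())

        # tied-death groups: Efron correction, looped (rare)
        for g in np.flatnonzero(multi):
            d = int(d_g[g])
            fr = np.arange(d) / d
            phi = S0[g] - fr * sd0[g]
            M = (S1[g][None, :] - fr[:, None] * sd1[g][None, :]) / phi[:, None]
            V = (S2[g][None, :, :] - fr[:, None, None] * sd2[g][None, :, :]) / phi[
                :, None, None
            ]
            grad += xd[g] - M.sum(axis=0)
            hess += V.sum(axis=0) - np.einsum("li,lj->ij", M, M)
            ll += float(etad[g] - np.log(phi).sum())

        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            flags.append("singular_hessian")
            break
        if np.max(np.abs(step)) > 50:
            flags.append("monotone_likelihood")
            step = np.clip(step, -5, 5)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    # final Hessian at the solution for standard errors
    se = np.full(p, np.nan)
    try:
        cov = np.linalg.inv(hess)
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        flags.append("singular_hessian")
    if not converged and "monotone_likelihood" not in flags:
        flags.append("not_converged")
    return CoxFit(beta=beta, se=se, loglik=ll, converged=converged, flags=flags)


def breslow_cumhaz(
    time: np.ndarray, event: np.ndarray, lp: np.ndarray, horizon: float
) -> float:
    """Breslow baseline cumulative hazard at ``horizon`` for the mean-lp reference."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    lp = np.asarray(lp, dtype=float)
    w = np.exp(lp - lp.mean())
    order = np.argsort(time, kind="stable")
    t, e, w = time[order], event[order], w[order]
    starts = _group_layout(t)
    gw = np.add.reduceat(w, starts)
    S0 = np.cumsum(gw[::-1])[::-1]
    d_g = np.add.reduceat(e.astype(float), starts)
    t_g = t[starts]
    keep = (d_g > 0) & (t_g <= horizon)
    return float(np.sum(d_g[keep] / S0[keep]))


def concordance(
    time: np.ndarray,
    event: np.ndarray,
    predictor: np.ndarray,
    with_influence: bool = False,
    chunk: int = 512,
) -> tuple[float, float | None]:
    """Harrell's C with an infinitesimal-jackknife standard error.

    A pair is comparable when the member with the smaller time has an event
    (higher predictor should accompany the earlier event); predictor ties
    count 1/2.  The IJ variance sums squared per-sample influences
    ``U_i = (c_i - C a_i) / D`` of the concordance ratio ``C = N/D`` with
    respect to a case weight on sample i, where ``c_i``/``a_i`` are sample
    i's concordance and comparability sums and ``D`` the total number of
    comparable (unordered) pairs.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    pred = np.asarray(predictor, dtype=float)
    n = len(time)
    # each unordered comparable pair {i, j} (earlier member an event, times
    # strictly different) is enumerated once from the earlier event's row;
    # its contribution is credited to both endpoints so that
    # sum(c_i) = 2 N and sum(a_i) = 2 D
    c_i = np.zeros(n)
    a_i = np.zeros(n)
    ev = np.flatnonzero(event)
    for lo in range(0, len(ev), chunk):
        rows = ev[lo : lo + chunk]
        later = time[None, :] > time[rows, None]
        dp = pred[rows, None] - pred[None, :]
        conc = later & (dp > 0)  # earlier event has the higher predictor
        tie = later & (dp == 0)
        row_c = conc.sum(axis=1) + 0.5 * tie.sum(axis=1)
        row_a = later.sum(axis=1)
        c_i[rows] += row_c
        a_i[rows] += row_a
        c_i += conc.sum(axis=0) + 0.5 * tie.sum(axis=0)
        a_i += later.sum(axis=0)
    total_comp = a_i.sum() / 2.0
    if total_comp == 0:
        raise ContractError("concordance: no comparable pairs")
    c = float(c_i.sum() / a_i.sum())
    if not with_influence:
        return c, None
    U = (c_i - c * a_i) / total_comp
    var = float(np.sum(U**2))
    return c, float(np.sqrt(var))
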