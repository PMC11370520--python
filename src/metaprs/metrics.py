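"""Association and discrimination statistics.

Logistic odds ratios per SD with AUC and case/control-stratified bootstrap
CIs; Cox per-SD hazard ratios (Efron ties) with Harrell's C and an
infinitesimal-jackknife SE; and the change in C-index between nested
survival models with a right-censored bootstrap (sample-level resampling
with replacement, keeping each sample's (time, event) pair intact).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._cox import concordance, cox_newton
from .exceptions import ContractError
from .scoring import ScoreVector

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054


@dataclass
class AssociationResult:
    effect: float  # OR or HR per SD
    ci_low: float
    ci_high: float
    discrimination: float  # AUC or C-index
    discrimination_ci: tuple[float, float]
    n: int
    n_cases: int
    model: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


@dataclass
class DeltaCResult:
    c_base: float
    c_augmented: float
    delta: float
    bootstrap_se: float
    ci: tuple[float, float]
    p_value: float
    n_bootstrap: int


def _as_values(score) -> np.ndarray:
    if isinstance(score, ScoreVector):
        return score.values
    return np.asarray(score, dtype=float)


# ---------------------------------------------------------------------------
# Logistic association
# ---------------------------------------------------------------------------


def logistic_association(
    score,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> AssociationResult:
    """OR per SD (Wald CI) and AUC of the fitted linear predictor.

    The AUC CI comes from ``n_boot`` case/control-stratified bootstrap
    replicates of the linear predictor (resampling within each outcome
    class) with a normal-approximation interval.  Separation or
    non-convergence is flagged, not silently swallowed.
    """
    import statsmodels.api as sm

    x = _as_values(score)
    y = np.asarray(outcome, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ContractError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ContractError("outcome has a single class")
    C = (
        covariates.to_numpy(dtype=float)
        if covariates is not None
        else np.empty((len(y), 0))
    )
    X = sm.add_constant(np.column_stack([x, C]))

    flags: list = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params = res.params
            bse = res.bse
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception as exc:  # pragma: no cover - defensive
            flags.append(f"fit_failed:{type(exc).__name__}")
            params = np.full(X.shape[1], np.nan)
            bse = np.full(X.shape[1], np.nan)
            converged = False
    for w in caught:
        if "separation" in str(w.message).lower():
            flags.append("separation")
    if not converged:
        flags.append("not_converged")
    if np.isfinite(params[1]) and abs(params[1]) > 15:
        if "separation" not in flags:
            flags.append("separation")

    if np.all(np.isfinite(params)):
        lp = X @ params
    else:
        lp = x  # score alone still ranks samples
    from sklearn.metrics import roc_auc_score

    auc = float(roc_auc_score(y, lp))

    rng = np.random.default_rng(seed)
    cases = np.flatnonzero(y == 1)
    ctrls = np.flatnonzero(y == 0)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        ic = rng.choice(cases, size=len(cases), replace=True)
        i0 = rng.choice(ctrls, size=len(ctrls), replace=True)
        idx = np.concatenate([ic, i0])
        boots[b] = roc_auc_score(y[idx], lp[idx])
    se_auc = float(np.std(boots, ddof=1))
    auc_ci = (max(0.0, auc - Z975 * se_auc), min(1.0, auc + Z975 * se_auc))

    with np.errstate(over="ignore"):
        or_ = float(np.exp(params[1]))
        ci = (
            float(np.exp(params[1] - Z975 * bse[1])),
            float(np.exp(params[1] + Z975 * bse[1])),
        )
    return AssociationResult(
        effect=or_,
        ci_low=ci[0],
        ci_high=ci[1],
        discrimination=auc,
        discrimination_ci=auc_ci,
        n=len(y),
        n_cases=int(y.sum()),
        model={
            "type": "logistic",
            "covariates": list(covariates.columns) if covariates is not None else [],
            "n_boot": n_boot,
        },
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Cox association
# ---------------------------------------------------------------------------


def cox_association(
    score,
    time: np.ndarray,
    event: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> AssociationResult:
    """Per-SD HR (Wald CI from the Efron partial likelihood, via lifelines)
    with Harrell's C of the linear predictor and its infinitesimal-jackknife
    CI attached.  Prevalent cases must already be excluded (time > 0)."""
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceWarning

    x = _as_values(score)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ContractError("cox_association: no events")
    if np.any(time <= 0):
        raise ContractError("cox_association: non-positive follow-up time")

    df = pd.DataFrame({"time": time, "event": event, "score": x})
    if covariates is not None:
        for c in covariates.columns:
            df[c] = covariates[c].to_numpy(dtype=float)

    flags: list = []
    cph = CoxPHFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(df, duration_col="time", event_col="event")
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            flags.append("monotone_likelihood")
            break

    coef = float(cph.params_["score"])
    se = float(cph.standard_errors_["score"])
    lp = df.drop(columns=["time", "event"]).to_numpy() @ cph.params_.to_numpy()
    c, c_se = concordance(time, event, lp, with_influence=True)
    return AssociationResult(
        effect=float(np.exp(coef)),
        ci_low=float(np.exp(coef - Z975 * se)),
        ci_high=float(np.exp(coef + Z975 * se)),
        discrimination=c,
        discrimination_ci=(c - Z975 * c_se, c + Z975 * c_se),
        n=len(df),
        n_cases=int(event.sum()),
        model={
            "type": "cox",
            "time_scale": "time_in_study",
            "ties": "efron",
            "covariates": list(covariates.columns) if covariates is not None else [],
        },
        flags=flags,
    )


def harrell_c(
    time: np.ndarray, event: np.ndarray, predictor: np.ndarray
) -> tuple[float, float]:
    """Harrell's concordance and its infinitesimal-jackknife SE.

    C = (concordant + 0.5 * tied-predictor) / comparable, where a pair is
    comparable when the member with the smaller time has an event.
    """
    return concordance(
        np.asarray(time, float),
        np.asarray(event, bool),
        np.asarray(predictor, float),
        with_influence=True,
    )


# ---------------------------------------------------------------------------
# Delta C-index
# ---------------------------------------------------------------------------


def delta_cindex(
    X_base: np.ndarray,
    X_augmented: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    max_redraws: int = 100,
) -> DeltaCResult:
    """C-index difference between two Cox models fit on identical samples.

    Both models are refit on every bootstrap resample (samples drawn with
    replacement, each keeping its observed (time, event) pair -- resampling
    appropriate for right-censored data); the SE of the bootstrapped deltas
    gives a first-order normal CI and two-sided p-value around the full-data
    point estimate.  Resamples without events are redrawn (logged, capped).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    Xb = np.atleast_2d(np.asarray(X_base, dtype=float))
    Xa = np.atleast_2d(np.asarray(X_augmented, dtype=float))
    if Xb.shape[0] != len(time):
        Xb = Xb.T
    if Xa.shape[0] != len(time):
        Xa = Xa.T
    n = len(time)

    def _fit_c(Xm, t, e):
        fit = cox_newton(Xm, t, e)
        lp = Xm @ fit.beta
        c, _ = concordance(t, e, lp, with_influence=False)
        return c

    c_base = _fit_c(Xb, time, event)
    c_aug = _fit_c(Xa, time, event)
    delta = c_aug - c_base

    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            if event[idx].sum() > 0:
                break
            logger.warning("bootstrap resample %d had no events; redrawing", b)
        else:
            raise ContractError("could not draw a bootstrap resample with events")
        deltas[b] = _fit_c(Xa[idx], time[idx], event[idx]) - _fit_c(
            Xb[idx], time[idx], event[idx]
        )
    se = float(np.std(deltas, ddof=1))
    if se == 0.0:
        p = 1.0
    else:
        p = float(2.0 * stats.norm.sf(abs(delta) / se))
    return DeltaCResult(
        c_base=c_base,
        c_augmented=c_aug,
        delta=delta,
        bootstrap_se=se,
        ci=(delta - Z975 * se, delta + Z975 * se),
        p_value=p,
        n_bootstrap=n_boot,
    )
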