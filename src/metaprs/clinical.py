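"""Clinical integration: absolute 10-year risk, NRI, and two-stage screening.

Absolute risk follows the standard Cox recipe ``risk = 1 - S0(h)^exp(lp -
mean lp)`` with a Breslow-type baseline survival at the horizon h (10 years).
A PRS is integrated by refitting a two-predictor Cox model (logit of the
clinical 10-year risk + standardized PRS) and recomputing absolute risk.

Categorical net reclassification improvement (NRI) at a single threshold
counts, separately in cases and non-cases, samples crossing the threshold
between the old and new risk model: case NRI% = 100 (up - down) / n_cases,
non-case NRI% = 100 (down - up) / n_noncases, with bootstrap-SE normal CIs.

The two-stage screen mirrors UK guideline practice: a cheap stage-1 score
selects samples above a first threshold (strict >) for blood tests -- the
number needed to screen (NNS) is screened / cases-among-screened -- and a
better-informed stage-2 score classifies high risk (>= threshold) within the
screened set -- the number needed to treat (NNT) is high-risk /
cases-among-high-risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._cox import breslow_cumhaz, concordance, cox_newton
from .exceptions import ContractError
from .scoring import ScoreVector

Z975 = 1.959963984540054


@dataclass
class RiskPrediction:
    sample_ids: np.ndarray
    risk10: np.ndarray
    model: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.risk10 = np.asarray(self.risk10, dtype=float)
        if np.any((self.risk10 < 0) | (self.risk10 > 1)):
            raise ContractError("risk10 outside [0,1]")


@dataclass
class NRIResult:
    threshold: float
    cases_up: int
    cases_down: int
    noncases_up: int
    noncases_down: int
    n_cases: int
    n_noncases: int
    case_nri_pct: float
    noncase_nri_pct: float
    case_se: float
    noncase_se: float
    case_ci: tuple[float, float]
    noncase_ci: tuple[float, float]
    case_p: float
    noncase_p: float
    n_bootstrap: int

    @property
    def case_up_pct(self) -> float:
        return 100.0 * self.cases_up / self.n_cases

    @property
    def case_down_pct(self) -> float:
        return 100.0 * self.cases_down / self.n_cases


@dataclass
class ScreeningResult:
    stage1_threshold: float
    n_screened: int
    cases_screened: int
    nns: float
    stage2_threshold: float
    n_highrisk: int
    cases_highrisk: int
    nnt: float
    n_total: int
    n_cases_total: int
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Absolute risk
# ---------------------------------------------------------------------------


def absolute_risk_10yr(
    lp: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    sample_ids: np.ndarray | None = None,
    horizon: float = 10.0,
    model: dict | None = None,
) -> RiskPrediction:
    """``risk = 1 - S0(h)^exp(lp - mean lp)`` with Breslow baseline at h."""
    lp = np.asarray(lp, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if float(np.max(time)) < horizon:
        raise ContractError(
            f"baseline survival at {horizon} y unavailable: all follow-up shorter"
        )
    H0 = breslow_cumhaz(time, event, lp, horizon)
    s0 = float(np.exp(-H0))
    risk = 1.0 - s0 ** np.exp(lp - lp.mean())
    ids = (
        np.asarray(sample_ids)
        if sample_ids is not None
        else np.arange(len(lp)).astype(str)
    )
    return RiskPrediction(
        sample_ids=ids,
        risk10=risk,
        model={**(model or {}), "horizon": horizon, "baseline_survival": s0},
    )


def integrate_prs(
    clinical_risk: RiskPrediction,
    prs,
    time: np.ndarray,
    event: np.ndarray,
    horizon: float = 10.0,
    force_zero_prs: bool = False,
) -> RiskPrediction:
    """Augment a clinical 10-year risk with a PRS by Cox refit.

    Fits a Cox model on [logit(clinical risk), standardized PRS] and
    recomputes the absolute risk; with ``force_zero_prs`` the PRS
    coefficient is pinned at zero, reducing the output to a recalibrated
    clinical risk (used as the null-augmentation check).
    """
    if isinstance(prs, ScoreVector):
        if prs.state != "standardized":
            raise ContractError("integrate_prs: PRS must be standardized")
        prs_vals = prs.values
    else:
        prs_vals = np.asarray(prs, dtype=float)
    r = np.clip(clinical_risk.risk10, 1e-12, 1 - 1e-12)
    if np.std(r) == 0:
        raise ContractError("integrate_prs: clinical risk is constant")
    logit_r = np.log(r / (1 - r))

    if force_zero_prs:
        X = logit_r[:, None]
        fit = cox_newton(X, time, event)
        lp = X @ fit.beta
        desc = {"model": "clinical_recalibrated"}
    else:
        X = np.column_stack([logit_r, prs_vals])
        fit = cox_newton(X, time, event)
        lp = X @ fit.beta
        desc = {
            "model": "clinical_plus_prs",
            "beta_clinical": float(fit.beta[0]),
            "beta_prs": float(fit.beta[1]),
        }
    return absolute_risk_10yr(
        lp, time, event, sample_ids=clinical_risk.sample_ids, horizon=horizon,
        model=desc,
    )


# ---------------------------------------------------------------------------
# Categorical NRI
# ---------------------------------------------------------------------------


def _reclass_counts(old_high, new_high, case_mask):
    up = int(np.sum(~old_high & new_high & case_mask))
    down = int(np.sum(old_high & ~new_high & case_mask))
    return up, down


def categorical_nri(
    risk_old: np.ndarray,
    risk_new: np.ndarray,
    outcome: np.ndarray,
    threshold: float,
    n_boot: int = 1000,
    seed: int = 0,
    km_weighted: bool = False,
    time: np.ndarray | None = None,
    horizon: float = 10.0,
) -> NRIResult:
    """Single-threshold categorical NRI with sample-resampling bootstrap.

    ``outcome`` is case status at the horizon (simple-count convention:
    censored-before-horizon non-events count as non-cases).  With
    ``km_weighted`` the expected case fraction among the censored is filled
    in from a Kaplan-Meier estimate of the event probability by horizon
    (requires ``time``).
    """
    risk_old = np.asarray(risk_old, dtype=float)
    risk_new = np.asarray(risk_new, dtype=float)
    if not 0.0 < threshold < 1.0:
        raise ContractError("threshold outside (0,1)")
    if risk_old.shape != risk_new.shape:
        raise ContractError("risk vectors differ in length")

    if km_weighted:
        if time is None:
            raise ContractError("km_weighted NRI requires event times")
        case_w = _km_case_weights(np.asarray(outcome, bool), np.asarray(time, float), horizon)
    else:
        case_w = np.asarray(outcome, dtype=float)

    old_high = risk_old > threshold
    new_high = risk_new > threshold

    def _components(w, oh, nh):
        n_cases = float(w.sum())
        n_non = float((1 - w).sum())
        if n_cases == 0 or n_non == 0:
            raise ContractError("NRI needs both cases and non-cases")
        up_c = float(np.sum(w * (~oh & nh)))
        dn_c = float(np.sum(w * (oh & ~nh)))
        up_n = float(np.sum((1 - w) * (~oh & nh)))
        dn_n = float(np.sum((1 - w) * (oh & ~nh)))
        case = 100.0 * (up_c - dn_c) / n_cases
        non = 100.0 * (dn_n - up_n) / n_non
        return case, non, up_c, dn_c, up_n, dn_n, n_cases, n_non

    case_nri, non_nri, up_c, dn_c, up_n, dn_n, n_cases, n_non = _components(
        case_w, old_high, new_high
    )

    rng = np.random.default_rng(seed)
    n = len(risk_old)
    boots = np.empty((n_boot, 2))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            cb, nb_, *_ = _components(case_w[idx], old_high[idx], new_high[idx])
        except ContractError:
            cb, nb_ = np.nan, np.nan
        boots[b] = (cb, nb_)
    case_se = float(np.nanstd(boots[:, 0], ddof=1))
    non_se = float(np.nanstd(boots[:, 1], ddof=1))

    def _p(est, se):
        if se == 0:
            return 1.0 if est == 0 else 0.0
        return float(2 * stats.norm.sf(abs(est) / se))

    return NRIResult(
        threshold=threshold,
        cases_up=int(round(up_c)),
        cases_down=int(round(dn_c)),
        noncases_up=int(round(up_n)),
        noncases_down=int(round(dn_n)),
        n_cases=int(round(n_cases)),
        n_noncases=int(round(n_non)),
        case_nri_pct=case_nri,
        noncase_nri_pct=non_nri,
        case_se=case_se,
        noncase_se=non_se,
        case_ci=(case_nri - Z975 * case_se, case_nri + Z975 * case_se),
        noncase_ci=(non_nri - Z975 * non_se, non_nri + Z975 * non_se),
        case_p=_p(case_nri, case_se),
        noncase_p=_p(non_nri, non_se),
        n_bootstrap=n_boot,
    )


def _km_case_weights(event: np.ndarray, time: np.ndarray, horizon: float) -> np.ndarray:
    """Per-sample probability of being a case by the horizon.

    Events before the horizon get weight 1; samples followed past the
    horizon get 0; samples censored earlier get the conditional KM
    probability of an event by the horizon given survival to their
    censoring time.
    """
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter().fit(time, event)
    s = km.survival_function_at_times
    s_h = float(s(horizon).iloc[0])
    w = np.zeros(len(time))
    w[(event) & (time <= horizon)] = 1.0
    cens_early = (~event) & (time < horizon)
    if cens_early.any():
        s_t = s(time[cens_early]).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            w[cens_early] = np.where(s_t > 0, 1.0 - s_h / s_t, 0.0)
    return w


# ---------------------------------------------------------------------------
# Two-stage screening
# ---------------------------------------------------------------------------


def two_stage_screen(
    stage1_risk: np.ndarray,
    stage1_threshold: float,
    stage2_risk: np.ndarray,
    stage2_threshold: float,
    outcome: np.ndarray,
) -> ScreeningResult:
    """Stage 1 selects strictly above the threshold; stage 2 classifies
    high risk at >= its threshold within the screened set.  NNS and NNT are
    exact integer ratios."""
    s1 = np.asarray(stage1_risk, dtype=float)
    s2 = np.asarray(stage2_risk, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    flags: list = []

    screened = s1 > stage1_threshold
    n_screened = int(screened.sum())
    cases_screened = int((screened & y).sum())
    if cases_screened > 0:
        nns = n_screened / cases_screened
    else:
        nns = np.nan
        flags.append("no_cases_screened")

    high = screened & (s2 >= stage2_threshold)
    n_high = int(high.sum())
    cases_high = int((high & y).sum())
    if cases_high > 0:
        nnt = n_high / cases_high
    else:
        nnt = np.nan
        flags.append("no_cases_highrisk")

    return ScreeningResult(
        stage1_threshold=stage1_threshold,
        n_screened=n_screened,
        cases_screened=cases_screened,
        nns=nns,
        stage2_threshold=stage2_threshold,
        n_highrisk=n_high,
        cases_highrisk=cases_high,
        nnt=nnt,
        n_total=len(y),
        n_cases_total=int(y.sum()),
        flags=flags,
    )


@dataclass
class ScreeningComparison:
    base: ScreeningResult
    augmented: ScreeningResult
    delta_nns: float
    delta_nnt: float
    delta_nns_se: float
    delta_nnt_se: float
    delta_nns_ci: tuple[float, float]
    delta_nnt_ci: tuple[float, float]
    delta_nns_p: float
    delta_nnt_p: float
    n_bootstrap: int


def compare_screening(
    base_stage1: np.ndarray,
    base_stage2: np.ndarray,
    aug_stage1: np.ndarray,
    aug_stage2: np.ndarray,
    stage1_threshold: float,
    stage2_threshold: float,
    outcome: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> ScreeningComparison:
    """Delta-NNS / delta-NNT between two screening protocols on the same cohort,
    with bootstrap-SE normal CIs."""
    y = np.asarray(outcome, dtype=bool)
    base = two_stage_screen(base_stage1, stage1_threshold, base_stage2,
                            stage2_threshold, y)
    aug = two_stage_screen(aug_stage1, stage1_threshold, aug_stage2,
                           stage2_threshold, y)
    d_nns = aug.nns - base.nns
    d_nnt = aug.nnt - base.nnt

    rng = np.random.default_rng(seed)
    n = len(y)
    b1, b2 = np.asarray(base_stage1, float), np.asarray(base_stage2, float)
    a1, a2 = np.asarray(aug_stage1, float), np.asarray(aug_stage2, float)
    deltas = np.full((n_boot, 2), np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        rb = two_stage_screen(b1[idx], stage1_threshold, b2[idx],
                              stage2_threshold, y[idx])
        ra = two_stage_screen(a1[idx], stage1_threshold, a2[idx],
                              stage2_threshold, y[idx])
        deltas[b] = (ra.nns - rb.nns, ra.nnt - rb.nnt)
    def _nanstd(v):
        v = v[np.isfinite(v)]
        return float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")

    se_nns = _nanstd(deltas[:, 0])
    se_nnt = _nanstd(deltas[:, 1])

    def _p(est, se):
        if not np.isfinite(se) or se == 0:
            return 1.0 if est == 0 else 0.0
        return float(2 * stats.norm.sf(abs(est) / se))

    return ScreeningComparison(
        base=base,
        augmented=aug,
        delta_nns=d_nns,
        delta_nnt=d_nnt,
        delta_nns_se=se_nns,
        delta_nnt_se=se_nnt,
        delta_nns_ci=(d_nns - Z975 * se_nns, d_nns + Z975 * se_nns),
        delta_nnt_ci=(d_nnt - Z975 * se_nnt, d_nnt + Z975 * se_nnt),
        delta_nns_p=_p(d_nns, se_nns),
        delta_nnt_p=_p(d_nnt, se_nnt),
        n_bootstrap=n_boot,
    )


def clinical_cindex(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Convenience: Harrell's C of a linear predictor (no SE)."""
    c, _ = concordance(np.asarray(time, float), np.asarray(event, bool),
                       np.asarray(lp, float), with_influence=False)
    return c
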