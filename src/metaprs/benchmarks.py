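"""Benchmark harnesses: the package's study-condition checks, recomputed.

Each function rebuilds its inputs from scratch (synthetic cohorts, or the
published integer screening counts, which are inputs in their own right) and
runs the package's own operations to measure a quantity of interest.  They
back both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ._cox import cox_newton
from .clinical import categorical_nri, two_stage_screen
from .combine import ComponentPanel, build_panel, fit_elasticnet_cv, collapse_weights
from .metrics import harrell_c, logistic_association
from .scoring import compute_prs, harmonize, standardize
from .simulate import (
    SimConfig,
    simulate_architecture,
    simulate_candidate_weights,
    simulate_genotypes,
    simulate_phenotypes,
)

# ---------------------------------------------------------------------------
# Published screening / reclassification arithmetic
# ---------------------------------------------------------------------------

#: Integer counts printed in the source study's UK-guideline screening
#: analysis (190,293 participants, 4,064 incident cases within 10 years).
PUBLISHED_COUNTS = dict(
    n_total=190_293,
    n_cases=4_064,
    screened_base=75_153,
    screened_cases_base=3_396,
    screened_aug=77_495,
    screened_cases_aug=3_517,
    highrisk_base=10_745,
    highrisk_cases_base=1_906,
    highrisk_aug=13_564,
    highrisk_cases_aug=2_167,
    nri_cases_up=468,  # 11.52% of 4,064 upgraded low -> high
    nri_cases_down=142,  # 3.5% downgraded high -> low
)


def _screening_vectors(n_total, n_cases, sel_cases, sel_total):
    """Risk vectors placing exactly the given counts above a 10% threshold."""
    r = np.zeros(n_total)
    r[:sel_cases] = 0.2
    r[n_cases : n_cases + (sel_total - sel_cases)] = 0.2
    return r


def published_screening_arithmetic() -> dict:
    """Reproduce every printed NNS/NNT/NRI figure through the package ops."""
    c = PUBLISHED_COUNTS
    y = np.r_[np.ones(c["n_cases"], bool), np.zeros(c["n_total"] - c["n_cases"], bool)]

    def protocol(sel_cases, sel_total, high_cases, high_total):
        s1 = _screening_vectors(c["n_total"], c["n_cases"], sel_cases, sel_total)
        s2 = _screening_vectors(c["n_total"], c["n_cases"], high_cases, high_total)
        return two_stage_screen(s1, 0.056, s2, 0.143, y)

    base = protocol(
        c["screened_cases_base"], c["screened_base"],
        c["highrisk_cases_base"], c["highrisk_base"],
    )
    aug = protocol(
        c["screened_cases_aug"], c["screened_aug"],
        c["highrisk_cases_aug"], c["highrisk_aug"],
    )

    # single-threshold reclassification of cases at 10% risk
    n_cases, up, down = c["n_cases"], c["nri_cases_up"], c["nri_cases_down"]
    stay_high = 2509 - down  # 2,509 cases high-risk before augmentation
    old = np.zeros(c["n_total"])
    new = np.zeros(c["n_total"])
    old[:stay_high] = 0.2; new[:stay_high] = 0.2
    old[stay_high : stay_high + down] = 0.2  # downgraded
    new[stay_high + down : stay_high + down + up] = 0.2  # upgraded
    nri = categorical_nri(old, new, y.astype(int), 0.10, n_boot=20, seed=0)

    return {
        "nns_base": base.nns,
        "nns_prs": aug.nns,
        "delta_nns": aug.nns - base.nns,
        "nnt_base": base.nnt,
        "nnt_prs": aug.nnt,
        "delta_nnt": aug.nnt - base.nnt,
        "case_up_pct": nri.case_up_pct,
        "case_down_pct": nri.case_down_pct,
        "case_net_pct": nri.case_nri_pct,
        "highrisk_case_gain_pct": 100.0
        * (c["highrisk_cases_aug"] - c["highrisk_cases_base"]) / n_cases,
        "highrisk_case_frac_base_pct": 100.0 * c["highrisk_cases_base"] / n_cases,
        "highrisk_case_frac_prs_pct": 100.0 * c["highrisk_cases_aug"] / n_cases,
    }


# ---------------------------------------------------------------------------
# Collapse identity
# ---------------------------------------------------------------------------


def collapse_identity_deviation(seed: int = 0) -> float:
    """Max deviation from constancy of (collapsed score - fitted combination)
    on a K=6, m=1,000 fixture with PC adjustment disabled."""
    cfg = SimConfig(
        n_samples=2000, n_variants=1000, n_causal=120, n_sources=6,
        n_risk_factor_sources=3, n_pcs=0, gwas_n=20_000, seed=seed,
    )
    geno = simulate_genotypes(cfg)
    arch = simulate_architecture(cfg, geno)
    sources = simulate_candidate_weights(cfg, arch, geno)
    co = simulate_phenotypes(geno, arch, cfg)
    chosen = {f"source{s}": sources[s][-1] for s in range(cfg.n_sources)}
    panel = build_panel(chosen, geno)
    y = ((co["prevalent"] == 1) | (co["event"] == 1)).to_numpy(int)
    fit = fit_elasticnet_cv(panel, y, alphas=(0.5,), n_folds=4, n_lambda=15,
                            seed=seed)
    collapsed = collapse_weights(panel, fit)
    harm, _ = harmonize(collapsed, geno)
    s_col = compute_prs(geno, harm).values
    combo = panel.standardized_scores().to_numpy() @ fit.beta.to_numpy()
    resid = s_col - combo
    return float(np.max(np.abs(resid - resid.mean())))


# ---------------------------------------------------------------------------
# Brute-force oracle agreement
# ---------------------------------------------------------------------------


def oracle_agreement(seed: int = 0) -> dict:
    """Agreement of C, AUC and NRI counts with O(n^2)/enumeration oracles."""
    rng = np.random.default_rng([seed, 7])

    # Harrell's C vs brute-force pair counting, n = 200, censored
    n = 200
    pred = np.round(rng.standard_normal(n), 1)
    t = rng.exponential(1.0, n)
    e = rng.random(n) < 0.6
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and t[i] < t[j] and e[i]:
                den += 1
                num += (pred[i] > pred[j]) + 0.5 * (pred[i] == pred[j])
    c, _ = harrell_c(t, e, pred)
    c_diff = abs(c - num / den)

    # AUC vs Mann-Whitney enumeration, n = 300.  The score carries signal so
    # the fitted coefficient is positive and the linear predictor shares the
    # raw score's orientation.
    n = 300
    score = rng.standard_normal(n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(score - 1.0)))).astype(int)
    res = logistic_association(score, y, n_boot=10, seed=seed)
    cases, ctrls = score[y == 1], score[y == 0]
    wins = sum((a > b) + 0.5 * (a == b) for a in cases for b in ctrls)
    auc_diff = abs(res.discrimination - wins / (len(cases) * len(ctrls)))

    # NRI counts vs a brute-force reclassification table, n = 500
    n = 500
    old = rng.uniform(0, 0.3, n)
    new = np.clip(old + rng.normal(0, 0.05, n), 0, 1)
    yy = (rng.random(n) < 0.3).astype(int)
    r = categorical_nri(old, new, yy, 0.10, n_boot=5, seed=seed)
    up = int(np.sum((old <= 0.10) & (new > 0.10) & (yy == 1)))
    down = int(np.sum((old > 0.10) & (new <= 0.10) & (yy == 1)))
    nri_exact = int(r.cases_up == up and r.cases_down == down)

    return {"harrell_c_abs_diff": c_diff, "auc_abs_diff": auc_diff,
            "nri_counts_exact": nri_exact}


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------


def hr_recovery(seed: int = 0, n_rep: int = 500, n: int = 5000) -> dict:
    """Mean estimated per-SD HR across replicates at true HR 1.8."""
    hrs = np.empty(n_rep)
    for rep in range(n_rep):
        cfg = SimConfig(
            n_samples=n, n_variants=150, n_causal=30, n_sources=1,
            n_risk_factor_sources=0, n_pcs=0,
            incident_hazard_log_hr_per_sd=math.log(1.8),
            seed=seed * 1000 + rep,
        )
        geno = simulate_genotypes(cfg)
        arch = simulate_architecture(cfg, geno)
        co = simulate_phenotypes(geno, arch, cfg)
        inc = co[co["prevalent"] == 0]
        fit = cox_newton(
            inc["true_liability"].to_numpy()[:, None],
            inc["time"].to_numpy(),
            inc["event"].to_numpy(bool),
        )
        hrs[rep] = math.exp(fit.beta[0])
    return {"mean_hr": float(np.mean(hrs)), "n_rep": n_rep, "true_hr": 1.8}


def noise_specificity(seed: int = 0, n: int = 10_000) -> dict:
    """Elasticnet coefficients for 15 pure-noise among 5 informative
    components; counts noise components with |beta| < 0.02."""
    rng = np.random.default_rng([seed, 11])
    lia = rng.standard_normal(n)
    scores = {f"info{j}": 0.45 * lia + rng.standard_normal(n) for j in range(5)}
    scores.update({f"noise{j}": rng.standard_normal(n) for j in range(15)})
    y = (lia + 0.7 * rng.standard_normal(n) > 1.3).astype(int)
    df = pd.DataFrame(scores)
    panel = ComponentPanel(
        component_ids=list(df.columns),
        scores=df,
        training_sd=df.std(ddof=1),
        training_mean=df.mean(),
        weight_tables={},
    )
    fit = fit_elasticnet_cv(panel, y, n_folds=10, n_lambda=25, seed=seed)
    silenced = int(sum(abs(fit.beta[f"noise{j}"]) < 0.02 for j in range(15)))
    return {"noise_components_silenced": silenced, "n_noise": 15,
            "alpha": fit.alpha}


# ---------------------------------------------------------------------------
# Meta-PRS dominance
# ---------------------------------------------------------------------------


def metaprs_dominance(seed: int = 0, n_rep: int = 50) -> dict:
    """Fraction of replicates where the collapsed meta-score beats the best
    single component out of sample (n = 10,000 per replicate)."""
    wins = 0
    for rep in range(n_rep):
        cfg = SimConfig(
            n_samples=10_000, n_variants=800, n_causal=120, n_sources=5,
            n_risk_factor_sources=2, risk_factor_rho=0.6, n_pcs=0,
            gwas_n=2_000, seed=seed * 1000 + rep,
        )
        geno = simulate_genotypes(cfg)
        arch = simulate_architecture(cfg, geno)
        sources = simulate_candidate_weights(cfg, arch, geno)
        co = simulate_phenotypes(geno, arch, cfg)
        y = ((co["prevalent"] == 1) | (co["event"] == 1)).to_numpy(int)

        n_train = 6000
        tr = np.arange(n_train)
        te = np.arange(n_train, cfg.n_samples)
        from .pipeline import _subset_geno

        g_tr, g_te = _subset_geno(geno, tr), _subset_geno(geno, te)
        chosen = {f"s{j}": sources[j][-1] for j in range(cfg.n_sources)}
        panel = build_panel(chosen, g_tr)
        fit = fit_elasticnet_cv(panel, y[tr], n_folds=10, n_lambda=25,
                                seed=seed * 1000 + rep)
        collapsed = collapse_weights(panel, fit)

        harm, _ = harmonize(collapsed, g_te)
        meta_auc = roc_auc_score(y[te], compute_prs(g_te, harm).values)
        best_single = 0.0
        for tab in chosen.values():
            h, _ = harmonize(tab, g_te)
            best_single = max(
                best_single, roc_auc_score(y[te], compute_prs(g_te, h).values)
            )
        wins += meta_auc > best_single
    return {"dominance_fraction": wins / n_rep, "n_rep": n_rep}


# ---------------------------------------------------------------------------
# Null calibration
# ---------------------------------------------------------------------------


def null_calibration(seed: int = 0, n_rep: int = 200) -> dict:
    """Permuted/null outcomes: AUC near 1/2 and nominal CI coverage of 1."""
    rng = np.random.default_rng([seed, 13])

    n = 10_000
    score = rng.standard_normal(n)
    y = (rng.random(n) < 0.1).astype(int)
    null_auc = logistic_association(score, y, n_boot=50, seed=seed).discrimination

    or_cover = hr_cover = 0
    for rep in range(n_rep):
        nn = 2000
        x = rng.standard_normal(nn)
        yy = (rng.random(nn) < 0.1).astype(int)
        import statsmodels.api as sm

        res = sm.Logit(yy, sm.add_constant(x)).fit(disp=0)
        lo = res.params[1] - 1.959963984540054 * res.bse[1]
        hi = res.params[1] + 1.959963984540054 * res.bse[1]
        or_cover += lo <= 0.0 <= hi

        t = rng.exponential(1 / 0.05, nn)
        c = np.minimum(rng.exponential(1 / 0.05, nn), 12.0)
        e = t <= c
        tt = np.minimum(t, c)
        fit = cox_newton(x[:, None], tt, e)
        lo = fit.beta[0] - 1.959963984540054 * fit.se[0]
        hi = fit.beta[0] + 1.959963984540054 * fit.se[0]
        hr_cover += lo <= 0.0 <= hi

    return {
        "null_auc": float(null_auc),
        "or_ci_coverage": or_cover / n_rep,
        "hr_ci_coverage": hr_cover / n_rep,
        "n_rep": n_rep,
    }
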