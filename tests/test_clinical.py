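"""Clinical integration: absolute risk, NRI, and screening arithmetic."""

import numpy as np
import pytest
from scipy import stats

from metaprs.clinical import (
    RiskPrediction,
    absolute_risk_10yr,
    categorical_nri,
    clinical_cindex,
    compare_screening,
    integrate_prs,
    two_stage_screen,
)
from metaprs.exceptions import ContractError


def _cohort(n, seed, beta=np.log(1.8), base=0.01, admin=12.0):
    rng = np.random.default_rng(seed)
    lia = rng.standard_normal(n)
    clin = 0.6 * lia + 0.8 * rng.standard_normal(n)
    prs = 0.5 * lia + 0.87 * rng.standard_normal(n)
    t = rng.exponential(1.0 / (base * np.exp(beta * lia)))
    c = np.minimum(rng.exponential(1 / 0.02, n), admin)
    e = t <= c
    return lia, clin, prs, np.minimum(t, c), e


class TestAbsoluteRisk:
    def test_reference_individual_risk(self):
        _, clin, _, t, e = _cohort(4000, 1)
        pred = absolute_risk_10yr(clin, t, e)
        s0 = pred.model["baseline_survival"]
        at_mean = 1.0 - s0  # lp equal to the mean lp
        i = np.argmin(np.abs(clin - clin.mean()))
        assert pred.risk10[i] == pytest.approx(at_mean, abs=0.01)

    def test_monotone_in_linear_predictor(self):
        _, clin, _, t, e = _cohort(2000, 2)
        pred = absolute_risk_10yr(clin, t, e)
        assert stats.spearmanr(clin, pred.risk10).statistic == pytest.approx(1.0)

    def test_matches_exponential_closed_form(self):
        """Known constant hazard: Breslow risk within 2% absolute of
        1 - exp(-lambda * 10 * exp(lp))."""
        rng = np.random.default_rng(3)
        n = 20_000
        lp = rng.standard_normal(n) * 0.5
        lam = 0.01
        t = rng.exponential(1.0 / (lam * np.exp(lp)))
        c = np.full(n, 12.0)
        e = t <= c
        tt = np.minimum(t, c)
        pred = absolute_risk_10yr(lp, tt, e)
        closed = 1.0 - np.exp(-lam * 10.0 * np.exp(lp - lp.mean()))
        assert np.max(np.abs(pred.risk10 - closed)) < 0.02

    def test_short_followup_is_hard_error(self):
        rng = np.random.default_rng(4)
        t = rng.uniform(0.1, 5.0, 100)
        with pytest.raises(ContractError):
            absolute_risk_10yr(rng.standard_normal(100), t, np.ones(100, bool))


class TestIntegratePrs:
    def test_null_augmentation_preserves_ranking(self):
        _, clin, prs, t, e = _cohort(3000, 5)
        clin_risk = absolute_risk_10yr(clin, t, e)
        out = integrate_prs(clin_risk, prs, t, e, force_zero_prs=True)
        rho = stats.spearmanr(out.risk10, clin_risk.risk10).statistic
        assert rho == pytest.approx(1.0)

    def test_informative_prs_never_hurts_cindex(self):
        wins = 0
        n_rep = 50
        for rep in range(n_rep):
            lia, clin, prs, t, e = _cohort(2000, 200 + rep)
            clin_risk = absolute_risk_10yr(clin, t, e)
            aug = integrate_prs(clin_risk, prs, t, e)
            c_clin = clinical_cindex(clin_risk.risk10, t, e)
            c_aug = clinical_cindex(aug.risk10, t, e)
            wins += c_aug >= c_clin
        assert wins >= 0.95 * n_rep

    def test_noise_prs_effect_vanishes_with_n(self):
        # compare against the recalibrated clinical risk (PRS forced to 0),
        # so only the noise-PRS contribution is measured
        diffs = []
        for n in (1000, 4000, 16000):
            rng = np.random.default_rng(n)
            lia, clin, _, t, e = _cohort(n, 7 + n)
            noise_prs = rng.standard_normal(n)
            clin_risk = absolute_risk_10yr(clin, t, e)
            aug = integrate_prs(clin_risk, noise_prs, t, e)
            null = integrate_prs(clin_risk, noise_prs, t, e, force_zero_prs=True)
            diffs.append(np.mean(np.abs(aug.risk10 - null.risk10)))
        assert diffs[2] < diffs[0]

    def test_constant_clinical_risk_rejected(self):
        _, _, prs, t, e = _cohort(500, 8)
        flat = RiskPrediction(np.arange(500).astype(str), np.full(500, 0.1))
        with pytest.raises(ContractError):
            integrate_prs(flat, prs, t, e)


class TestCategoricalNri:
    def test_paper_scale_reclassification_percentages(self):
        """4,064 cases, 468 upgraded, 142 downgraded at the 10% threshold."""
        n_cases, up, down = 4064, 468, 142
        n_non = 50_000
        old = np.zeros(n_cases + n_non)
        new = np.zeros_like(old)
        # cases: 2367 stay high, `up` go low->high, `down` go high->low
        old[:2367] = 0.2; new[:2367] = 0.2
        old[2367:2367 + up] = 0.05; new[2367:2367 + up] = 0.2
        old[2835:2835 + down] = 0.2; new[2835:2835 + down] = 0.05
        old[2977:n_cases] = 0.05; new[2977:n_cases] = 0.05
        old[n_cases:] = 0.01; new[n_cases:] = 0.01
        y = np.r_[np.ones(n_cases, int), np.zeros(n_non, int)]
        res = categorical_nri(old, new, y, 0.10, n_boot=20, seed=0)
        assert res.cases_up == up and res.cases_down == down
        assert res.case_up_pct == pytest.approx(100 * up / n_cases)
        assert round(res.case_up_pct, 2) == 11.52
        assert res.case_down_pct == pytest.approx(100 * down / n_cases)
        assert res.case_nri_pct == pytest.approx(res.case_up_pct - res.case_down_pct)
        assert round(res.case_nri_pct, 2) == 8.02

    def test_identical_risks_give_zero_nri(self):
        rng = np.random.default_rng(9)
        r = rng.uniform(0, 0.4, 1000)
        y = (rng.random(1000) < 0.2).astype(int)
        res = categorical_nri(r, r.copy(), y, 0.10, n_boot=50, seed=1)
        assert res.case_nri_pct == 0.0 and res.noncase_nri_pct == 0.0
        assert res.case_p == pytest.approx(1.0)

    def test_counts_match_brute_force_tables(self):
        rng = np.random.default_rng(10)
        n = 500
        old = rng.uniform(0, 0.3, n)
        new = np.clip(old + rng.normal(0, 0.05, n), 0, 1)
        y = (rng.random(n) < 0.3).astype(int)
        thr = 0.10
        res = categorical_nri(old, new, y, thr, n_boot=10, seed=2)
        for is_case, (up_got, down_got) in [
            (1, (res.cases_up, res.cases_down)),
            (0, (res.noncases_up, res.noncases_down)),
        ]:
            up = down = stay_high = stay_low = 0
            for i in range(n):
                if y[i] != is_case:
                    continue
                o, nw = old[i] > thr, new[i] > thr
                up += (not o) and nw
                down += o and (not nw)
                stay_high += o and nw
                stay_low += (not o) and (not nw)
            assert (up, down) == (up_got, down_got)
            # conservation: the four cells tile the group
            assert up + down + stay_high + stay_low == int((y == is_case).sum())

    def test_needs_both_classes(self):
        with pytest.raises(ContractError):
            categorical_nri(
                np.array([0.1, 0.2]), np.array([0.2, 0.1]),
                np.array([1, 1]), 0.15, n_boot=5,
            )


class TestScreening:
    def test_printed_two_stage_arithmetic(self):
        """NNS/NNT reproduce from the published integer counts."""
        n_total, n_cases = 190_293, 4064
        y = np.r_[np.ones(n_cases, bool), np.zeros(n_total - n_cases, bool)]

        def risks(n_sel_cases, n_sel_total, n_high_cases, n_high_total):
            s1 = np.zeros(n_total)
            s2 = np.zeros(n_total)
            # screened cases first, then screened non-cases
            s1[:n_sel_cases] = 0.10
            s1[n_cases : n_cases + (n_sel_total - n_sel_cases)] = 0.10
            s2[:n_high_cases] = 0.20
            s2[n_cases : n_cases + (n_high_total - n_high_cases)] = 0.20
            return s1, s2

        s1, s2 = risks(3396, 75_153, 1906, 10_745)
        base = two_stage_screen(s1, 0.056, s2, 0.143, y)
        assert (base.n_screened, base.cases_screened) == (75_153, 3396)
        assert round(base.nns, 2) == 22.13
        assert (base.n_highrisk, base.cases_highrisk) == (10_745, 1906)
        assert round(base.nnt, 2) == 5.64

        s1a, s2a = risks(3517, 77_495, 2167, 13_564)
        aug = two_stage_screen(s1a, 0.056, s2a, 0.143, y)
        assert round(aug.nns, 2) == 22.03
        assert round(aug.nnt, 2) == 6.26
        assert round(aug.nns - base.nns, 2) == -0.10
        assert round(aug.nnt - base.nnt, 2) == 0.62

    def test_zero_threshold_screens_everyone(self):
        rng = np.random.default_rng(11)
        n = 1000
        s = rng.uniform(0.01, 0.5, n)
        y = rng.random(n) < 0.1
        res = two_stage_screen(s, 0.0, s, 0.2, y)
        assert res.n_screened == n
        assert res.nns == pytest.approx(n / y.sum())

    def test_stage2_threshold_monotone(self):
        rng = np.random.default_rng(12)
        n = 2000
        s1 = rng.uniform(0, 0.5, n)
        s2 = rng.uniform(0, 0.5, n)
        y = rng.random(n) < 0.1
        sizes = [
            two_stage_screen(s1, 0.056, s2, t2, y).n_highrisk
            for t2 in (0.05, 0.10, 0.143, 0.25)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_no_cases_screened_is_flagged(self):
        y = np.zeros(100, bool)
        y[:5] = True
        s = np.r_[np.zeros(5), np.full(95, 0.5)]  # cases never screened
        res = two_stage_screen(s, 0.056, s, 0.143, y)
        assert "no_cases_screened" in res.flags
        assert np.isnan(res.nns)

    def test_compare_screening_bootstrap_runs(self):
        rng = np.random.default_rng(13)
        n = 3000
        lia = rng.standard_normal(n)
        y = rng.random(n) < 1 / (1 + np.exp(-(lia - 2.5)))
        base1 = 1 / (1 + np.exp(-(0.5 * lia + rng.normal(0, 1, n) - 2.5)))
        aug1 = 1 / (1 + np.exp(-(0.8 * lia + rng.normal(0, 0.6, n) - 2.5)))
        cmp_ = compare_screening(base1, base1, aug1, aug1, 0.056, 0.143, y,
                                 n_boot=40, seed=3)
        assert cmp_.n_bootstrap == 40
        assert cmp_.delta_nns_ci[0] <= cmp_.delta_nns <= cmp_.delta_nns_ci[1]
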