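"""Survival-statistics unit tests against hand computations, brute-force
oracles and lifelines cross-checks."""

import numpy as np
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
from lifelines.utils import concordance_index as ll_cindex
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from milsurv.survival import (
    CoxPH,
    SurvivalData,
    breslow_baseline_survival,
    concordance_index,
    cox_fit,
    decision_curve,
    kaplan_meier,
    log_rank_test,
    optimal_cutoff,
    time_dependent_auc,
)

from conftest import (
    auc_bruteforce,
    cindex_bruteforce,
    cox_partial_loglik,
    km_by_hand,
    logrank_by_hand,
)


def _random_surv(rng, n, censor=0.3):
    t = rng.exponential(10, n) + 0.01
    e = (rng.random(n) > censor).astype(int)
    e[rng.integers(n)] = 1  # guarantee an event
    return t, e


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

class TestConcordance:
    def test_perfectly_antitone_scores_give_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert concordance_index(-t, (t, np.ones(4, int))) == 1.0

    def test_all_tied_scores_give_half(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert concordance_index(np.zeros(4), (t, np.ones(4, int))) == 0.5

    def test_matches_bruteforce_with_censoring(self):
        t = np.array([3.0, 1.0, 5.0, 2.0, 4.0, 6.0])
        e = np.array([1, 1, 0, 1, 0, 1])
        s = np.array([0.2, 0.9, 0.1, 0.9, 0.5, 0.3])
        assert concordance_index(s, (t, e)) == pytest.approx(
            cindex_bruteforce(s, t, e))

    @pytest.mark.parametrize("transform", [np.exp, lambda x: x**3, lambda x: 2 * x + 5])
    def test_invariant_under_monotone_transform(self, transform):
        rng = np.random.default_rng(1)
        t, e = _random_surv(rng, 50)
        s = rng.normal(size=50)
        assert concordance_index(s, (t, e)) == pytest.approx(
            concordance_index(transform(s), (t, e)))

    def test_agrees_with_lifelines(self):
        rng = np.random.default_rng(2)
        t, e = _random_surv(rng, 80)
        s = rng.normal(size=80)
        # lifelines' convention: higher predicted time = concordant with longer time
        assert concordance_index(s, (t, e)) == pytest.approx(
            ll_cindex(t, -s, e))

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(ValueError):
            concordance_index([1, 2], ([3.0, 3.0], [0, 0]))


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

class TestKaplanMeier:
    def test_single_event_of_four(self):
        curve = kaplan_meier(([1.0, 2.0, 3.0, 4.0], [1, 0, 0, 0]))
        assert curve.survival[0] == pytest.approx(0.75)

    def test_all_censored_gives_flat_one(self):
        curve = kaplan_meier(([1.0, 2.0], [0, 0]))
        assert curve.event_times.size == 0
        assert curve.at(5.0) == 1.0

    def test_matches_hand_product_limit(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([1, 1, 0, 1, 0])
        curve = kaplan_meier((t, e))
        ht, hs = km_by_hand(t, e)
        np.testing.assert_allclose(curve.event_times, ht)
        np.testing.assert_allclose(curve.survival, hs)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 30) + 0.1
        curve = kaplan_meier((t, np.ones(30, int)))
        for ut, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx((t > ut).mean())

    def test_agrees_with_lifelines(self):
        rng = np.random.default_rng(4)
        t, e = _random_surv(rng, 60)
        curve = kaplan_meier((t, e))
        kmf = KaplanMeierFitter().fit(t, e)
        for ut, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(
                kmf.survival_function_at_times(ut).iloc[0])


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

class TestLogRank:
    def test_identical_groups_give_zero(self):
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([1, 1, 0])
        chi2, p = log_rank_test((t, e), (t.copy(), e.copy()))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computation(self):
        ta, ea = np.array([1.0, 3.0, 5.0, 7.0]), np.array([1, 1, 0, 1])
        tb, eb = np.array([2.0, 4.0, 6.0, 8.0]), np.array([1, 0, 1, 1])
        chi2, _ = log_rank_test((ta, ea), (tb, eb))
        assert chi2 == pytest.approx(logrank_by_hand(ta, ea, tb, eb))

    def test_time_scaling_invariance(self):
        rng = np.random.default_rng(5)
        ta, ea = _random_surv(rng, 25)
        tb, eb = _random_surv(rng, 25)
        c1, _ = log_rank_test((ta, ea), (tb, eb))
        c2, _ = log_rank_test((ta * 7.3, ea), (tb * 7.3, eb))
        assert c1 == pytest.approx(c2)

    def test_p_is_chi2_of_normal_deviate(self):
        rng = np.random.default_rng(6)
        ta, ea = _random_surv(rng, 30)
        tb, eb = _random_surv(rng, 30)
        chi2, p = log_rank_test((ta, ea), (tb, eb))
        z = np.sqrt(chi2)
        assert p == pytest.approx(2 * stats.norm.sf(z))

    def test_agrees_with_lifelines(self):
        rng = np.random.default_rng(7)
        ta, ea = _random_surv(rng, 40)
        tb, eb = _random_surv(rng, 35)
        chi2, p = log_rank_test((ta, ea), (tb, eb))
        res = ll_logrank(ta, tb, ea, eb)
        assert chi2 == pytest.approx(res.test_statistic)
        assert p == pytest.approx(res.p_value)

    def test_zero_events_raise(self):
        with pytest.raises(ValueError):
            log_rank_test(([1.0], [0]), ([2.0], [0]))


# ---------------------------------------------------------------------------
# Cox fits
# ---------------------------------------------------------------------------

class TestCoxFit:
    def test_null_covariate_small_z(self):
        rng = np.random.default_rng(8)
        t, e = _random_surv(rng, 200)
        x = rng.normal(size=200)
        fit = cox_fit(x, (t, e))
        assert abs(fit.coefficients[0] / fit.standard_errors[0]) < 3

    def test_binary_covariate_matches_grid_search(self):
        t = np.array([2.0, 4.0, 1.0, 5.0, 3.0, 6.0, 7.0, 2.5])
        e = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        fit = cox_fit(x, (t, e))
        grid = np.linspace(-4, 4, 160001)
        ll = [cox_partial_loglik(b, x - x.mean(), t, e) for b in grid]
        assert fit.coefficients[0] == pytest.approx(grid[int(np.argmax(ll))], abs=1e-4)

    def test_hr_and_ci_are_definitional(self):
        rng = np.random.default_rng(9)
        t, e = _random_surv(rng, 100)
        x = rng.normal(size=(100, 2))
        fit = cox_fit(x, (t, e))
        np.testing.assert_array_equal(fit.hazard_ratios, np.exp(fit.coefficients))
        np.testing.assert_array_equal(
            fit.ci95,
            np.stack([np.exp(fit.coefficients - 1.96 * fit.standard_errors),
                      np.exp(fit.coefficients + 1.96 * fit.standard_errors)], axis=1))

    def test_agrees_with_lifelines(self):
        rng = np.random.default_rng(10)
        n = 150
        x = rng.normal(size=(n, 2))
        eta = 0.8 * x[:, 0] - 0.5 * x[:, 1]
        t = rng.exponential(np.exp(-eta)) + 1e-3   # continuous: no ties
        e = (rng.random(n) > 0.2).astype(int)
        e[0] = 1
        fit = cox_fit(x, (t, e))
        df = pd.DataFrame({"t": t, "e": e, "x0": x[:, 0], "x1": x[:, 1]})
        cph = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.coefficients, cph.params_.values, rtol=1e-4)
        np.testing.assert_allclose(fit.standard_errors,
                                   cph.standard_errors_.values, rtol=1e-3)

    def test_recovers_planted_coefficient_within_ci(self):
        rng = np.random.default_rng(11)
        n, beta = 800, 0.7
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-beta * x)) + 1e-3
        e = np.ones(n, int)
        fit = cox_fit(x, (t, e))
        lo, hi = np.log(fit.ci95[0])
        assert lo < beta < hi

    def test_zero_variance_covariate_raises(self):
        with pytest.raises(ValueError):
            cox_fit(np.ones(10), (np.arange(1.0, 11.0), np.ones(10, int)))

    def test_estimator_wrapper_and_baseline(self):
        rng = np.random.default_rng(12)
        t, e = _random_surv(rng, 120)
        x = rng.normal(size=(120, 1))
        est = CoxPH().fit(x, (t, e))
        assert est.converged_
        # baseline survival is a proper non-increasing curve from <=1
        s = est.baseline_.survival
        assert np.all(np.diff(s) <= 1e-12) and s.max() <= 1.0
        p = est.predict_survival(x, horizon=float(np.median(t)))
        assert np.all((p > 0) & (p <= 1))


# ---------------------------------------------------------------------------
# time-dependent AUC
# ---------------------------------------------------------------------------

class TestTimeDependentAUC:
    def test_perfect_separation(self):
        t = np.array([1.0, 2.0, 10.0, 12.0])
        e = np.array([1, 1, 0, 0])
        s = np.array([9.0, 8.0, 1.0, 0.5])
        assert time_dependent_auc(s, (t, e), horizon=5.0) == 1.0

    def test_all_tied_scores(self):
        t = np.array([1.0, 2.0, 10.0, 12.0])
        e = np.array([1, 1, 0, 0])
        assert time_dependent_auc(np.ones(4), (t, e), horizon=5.0) == 0.5

    def test_matches_exhaustive_pairs_with_censoring(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 6.0, 7.0, 8.0, 9.0])
        e = np.array([1, 0, 1, 1, 0, 1, 0, 1])
        s = np.array([0.9, 0.8, 0.3, 0.7, 0.2, 0.5, 0.1, 0.4])
        assert time_dependent_auc(s, (t, e), horizon=5.0) == pytest.approx(
            auc_bruteforce(s, t, e, 5.0))

    def test_reduces_to_classical_auc_beyond_last_event(self):
        rng = np.random.default_rng(13)
        t = rng.exponential(5, 40) + 0.1
        e = np.ones(40, int)
        # label = event before horizon h; with no censoring and h beyond the
        # last event... instead use an interior horizon with no censoring
        h = float(np.median(t))
        s = rng.normal(size=40)
        y = (t <= h).astype(int)
        assert time_dependent_auc(s, (t, e), h) == pytest.approx(
            roc_auc_score(y, s))

    def test_errors_without_cases_or_controls(self):
        with pytest.raises(ValueError, match="horizon"):
            time_dependent_auc([1, 2], ([5.0, 6.0], [1, 1]), horizon=1.0)


# ---------------------------------------------------------------------------
# optimal cutoff
# ---------------------------------------------------------------------------

class TestOptimalCutoff:
    def test_cutoff_lands_between_separated_clusters(self):
        rng = np.random.default_rng(14)
        n = 60
        s = np.concatenate([rng.normal(0, 0.3, n // 2), rng.normal(5, 0.3, n // 2)])
        # strongly different survival: low-score cluster lives 100x longer
        t = np.concatenate([rng.uniform(50, 100, n // 2),
                            rng.uniform(0.5, 1.0, n // 2)]) + 0.01
        e = np.ones(n, int)
        res = optimal_cutoff(s, (t, e))
        # the maximally selected statistic can peak a patient or two off the
        # exact gap; the cutoff must still split the clusters almost perfectly
        assert s[:n // 2].mean() < res.cutoff < s[n // 2:].mean()
        assert abs(res.n_low - n // 2) <= 2

    def test_matches_exhaustive_scan_with_lifelines_statistic(self):
        rng = np.random.default_rng(15)
        n = 50
        s = rng.normal(size=n)
        t = rng.exponential(np.exp(-s)) + 0.01
        e = (rng.random(n) > 0.2).astype(int)
        res = optimal_cutoff(s, (t, e), min_prop=0.1)
        uniq = np.unique(s)
        best_z, best_c = -1, None
        for c in (uniq[:-1] + uniq[1:]) / 2:
            low = s <= c
            if low.sum() < 0.1 * n or (~low).sum() < 0.1 * n:
                continue
            r = ll_logrank(t[low], t[~low], e[low], e[~low])
            z = np.sqrt(r.test_statistic)
            if z > best_z + 1e-12:
                best_z, best_c = z, c
        assert res.cutoff == pytest.approx(best_c)
        assert res.statistic == pytest.approx(best_z)

    def test_min_prop_half_forces_median_split(self):
        rng = np.random.default_rng(16)
        n = 20
        s = rng.normal(size=n)
        t = rng.exponential(5, n) + 0.01
        e = np.ones(n, int)
        res = optimal_cutoff(s, (t, e), min_prop=0.5)
        ss = np.sort(s)
        assert res.cutoff == pytest.approx((ss[n // 2 - 1] + ss[n // 2]) / 2)
        assert res.n_low == res.n_high == n // 2

    def test_constant_scores_raise(self):
        with pytest.raises(ValueError):
            optimal_cutoff(np.ones(10), (np.arange(1.0, 11.0), np.ones(10, int)))


# ---------------------------------------------------------------------------
# decision curves
# ---------------------------------------------------------------------------

class TestDecisionCurve:
    def test_treat_none_is_zero(self):
        curve = decision_curve([0.2, 0.8], [0, 1], thresholds=[0.1, 0.5, 0.9])
        np.testing.assert_array_equal(curve.treat_none, 0.0)

    def test_treat_all_closed_form(self):
        y = np.array([1, 0, 0, 1, 1])
        th = np.array([0.2, 0.4, 0.6])
        curve = decision_curve(np.full(5, 0.5), y, th)
        prev = y.mean()
        np.testing.assert_allclose(curve.treat_all, prev - (1 - prev) * th / (1 - th))

    def test_matches_direct_counting(self):
        p = np.array([0.1, 0.9, 0.4, 0.6, 0.3, 0.8, 0.2, 0.7, 0.5, 0.05])
        y = np.array([0, 1, 0, 1, 0, 1, 0, 0, 1, 0])
        th = [0.25, 0.5, 0.75]
        curve = decision_curve(p, y, th)
        for i, pt in enumerate(th):
            tp = sum(1 for pi, yi in zip(p, y) if pi >= pt and yi == 1)
            fp = sum(1 for pi, yi in zip(p, y) if pi >= pt and yi == 0)
            nb = tp / 10 - fp / 10 * pt / (1 - pt)
            assert curve.model[i] == pytest.approx(nb)

    def test_net_benefit_bounded_by_prevalence(self):
        rng = np.random.default_rng(17)
        p = rng.random(50)
        y = rng.integers(0, 2, 50)
        curve = decision_curve(p, y, np.linspace(0.05, 0.95, 19))
        assert np.all(curve.model <= y.mean() + 1e-12)

    def test_bad_thresholds_raise(self):
        with pytest.raises(ValueError):
            decision_curve([0.5], [1], thresholds=[0.0, 0.5])


def test_breslow_baseline_no_covariate_matches_nelson_aalen_form():
    rng = np.random.default_rng(18)
    t = rng.exponential(5, 50) + 0.1
    e = np.ones(50, int)
    curve = breslow_baseline_survival(np.zeros(50), (t, e))
    # with eta=0, H0(t) = sum d_i / n_at_risk: the Nelson-Aalen estimator
    na = 0.0
    for ut in np.sort(t):
        na += 1 / (t >= ut).sum()
        assert curve.at(ut) == pytest.approx(np.exp(-na))
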