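"""Survival statistics for right-censored time-to-event data.

Implements the full evaluation stack used around the multimodal survival
network: Harrell's concordance index, the Kaplan-Meier product-limit estimator,
the two-group log-rank test, Cox proportional-hazards fits (Newton-Raphson on
the Breslow partial likelihood), the cumulative/dynamic time-dependent AUC,
the maximally-selected log-rank cutpoint (survminer-style), and decision-curve
analysis.  All estimators are written directly against their definitions so
that exhaustive brute-force oracles can pin them in the test suite.

Conventions
-----------
* ``times`` are positive follow-up durations (months); ``events`` are 0/1
  indicators (1 = event observed, 0 = right-censored).
* Risk scores follow the "higher risk, shorter survival" convention.
* Ties among event times use the Breslow approximation throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalData",
    "CoxFit",
    "SurvivalCurve",
    "CutoffResult",
    "NetBenefitCurve",
    "concordance_index",
    "kaplan_meier",
    "log_rank_test",
    "cox_fit",
    "CoxPH",
    "breslow_baseline_survival",
    "time_dependent_auc",
    "optimal_cutoff",
    "decision_curve",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalData:
    """Aligned follow-up times (months, > 0) and event indicators (0/1)."""

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("times and events must be aligned 1-D arrays")
        if t.size and t.min() <= 0:
            raise ValueError("survival times must be positive")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("events must be 0/1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)

    def __len__(self):
        return self.times.size


@dataclass
class CoxFit:
    coefficients: np.ndarray
    standard_errors: np.ndarray
    hazard_ratios: np.ndarray
    ci95: np.ndarray          # (p, 2) on the hazard-ratio scale
    p_values: np.ndarray      # Wald
    log_likelihood: float
    converged: bool
    n_iter: int


@dataclass
class SurvivalCurve:
    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        """Step-function evaluation S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CutoffResult:
    cutoff: float
    statistic: float          # standardized log-rank statistic |Z| at the cutoff
    n_low: int
    n_high: int


@dataclass
class NetBenefitCurve:
    thresholds: np.ndarray
    model: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.treat_none is None:
            self.treat_none = np.zeros_like(np.asarray(self.thresholds, float))


def _as_data(data) -> SurvivalData:
    if isinstance(data, SurvivalData):
        return data
    times, events = data
    return SurvivalData(np.asarray(times, float), np.asarray(events, int))


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def concordance_index(scores, data) -> float:
    """Harrell's C for risk scores against right-censored outcomes.

    A pair (i, j) is comparable when the shorter observed time carries an
    event.  Among comparable pairs, the pair is concordant when the patient
    with the shorter time has the higher risk score; score ties count 1/2.
    """
    data = _as_data(data)
    s = np.asarray(scores, float)
    t, e = data.times, data.events
    # i indexes the (earlier, event) member of each candidate pair
    ti = t[:, None]
    comparable = (ti < t[None, :]) & (e[:, None] == 1)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    si = s[:, None]
    conc = (si > s[None, :]) & comparable
    tied = (si == s[None, :]) & comparable
    return float((conc.sum() + 0.5 * tied.sum()) / n_comp)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def kaplan_meier(data) -> SurvivalCurve:
    """Product-limit estimate of the survival function.

    Censored-only times reduce the at-risk count without producing a step.
    """
    data = _as_data(data)
    t, e = data.times, data.events
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    utimes = np.unique(t[e == 1])
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for ut in utimes:
        n_risk = int((t >= ut).sum())
        d = int(((t == ut) & (e == 1)).sum())
        s *= (n_risk - d) / n_risk
        surv.append(s)
        at_risk.append(n_risk)
        n_ev.append(d)
    return SurvivalCurve(
        event_times=utimes,
        survival=np.asarray(surv, float),
        at_risk=np.asarray(at_risk, int),
        n_events=np.asarray(n_ev, int),
    )


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def _logrank_oe(times_a, events_a, times_b, events_b):
    """Observed-minus-expected events in group A and its hypergeometric
    variance, summed over pooled event times."""
    t = np.concatenate([times_a, times_b])
    e = np.concatenate([events_a, events_b])
    grp = np.concatenate([np.zeros(len(times_a), int), np.ones(len(times_b), int)])
    o_minus_e = 0.0
    var = 0.0
    for ut in np.unique(t[e == 1]):
        at_risk = t >= ut
        n = at_risk.sum()
        n_a = (at_risk & (grp == 0)).sum()
        d = ((t == ut) & (e == 1)).sum()
        d_a = ((t == ut) & (e == 1) & (grp == 0)).sum()
        exp_a = d * n_a / n
        o_minus_e += d_a - exp_a
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e, var


def log_rank_test(group_a, group_b):
    """Two-group log-rank test; returns (chi-square statistic, p) with 1 df."""
    a, b = _as_data(group_a), _as_data(group_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if a.events.sum() + b.events.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    oe, var = _logrank_oe(a.times, a.events, b.times, b.events)
    if var == 0:
        return 0.0, 1.0
    chi2 = oe * oe / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow partial likelihood, Newton-Raphson)
# ---------------------------------------------------------------------------

def _cox_quantities(X, t, e, beta):
    """Log partial likelihood, score vector and observed information under
    the Breslow tie convention."""
    n, p = X.shape
    eta = X @ beta
    shift = eta.max()  # guards overflow; restored inside log below
    w = np.exp(eta - shift)
    order = np.argsort(-t, kind="stable")  # descending time
    Xo, to, eo, wo = X[order], t[order], e[order], w[order]
    etao = eta[order]
    # reverse-in-time cumulative sums give risk-set aggregates at each time
    S0 = np.cumsum(wo)
    S1 = np.cumsum(wo[:, None] * Xo, axis=0)
    S2 = np.cumsum(wo[:, None, None] * (Xo[:, :, None] * Xo[:, None, :]), axis=0)
    ll, U, info = 0.0, np.zeros(p), np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and to[j] == to[i]:
            j += 1
        # risk set at time to[i] = entries 0..j-1 (descending sort)
        dmask = eo[i:j] == 1
        d = int(dmask.sum())
        if d > 0:
            s0, s1, s2 = S0[j - 1], S1[j - 1], S2[j - 1]
            xbar = s1 / s0
            ll += etao[i:j][dmask].sum() - d * (np.log(s0) + shift)
            U += Xo[i:j][dmask].sum(axis=0) - d * xbar
            info += d * (s2 / s0 - np.outer(xbar, xbar))
        i = j
    return ll, U, info


def cox_fit(covariates, data, max_iter: int = 100, tol: float = 1e-8) -> CoxFit:
    """Cox proportional-hazards fit via Newton-Raphson on the Breslow partial
    likelihood, with Wald standard errors from the inverse observed
    information and 95% CIs ``exp(beta +/- 1.96 se)``.
    """
    data = _as_data(data)
    X = np.asarray(covariates, float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n != len(data):
        raise ValueError("covariate rows must align with survival data")
    if data.events.sum() < p:
        raise ValueError("need at least as many events as covariates")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("zero-variance covariate")

    # center columns for numerical stability (shift-invariant likelihood)
    Xc = X - X.mean(axis=0)
    beta = np.zeros(p)
    ll, U, info = _cox_quantities(Xc, data.times, data.events, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, U)
        except np.linalg.LinAlgError:
            break
        # step halving keeps the likelihood non-decreasing
        factor = 1.0
        for _ in range(30):
            beta_new = beta + factor * step
            ll_new, U_new, info_new = _cox_quantities(Xc, data.times, data.events, beta_new)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        delta = np.max(np.abs(beta_new - beta))
        beta, ll, U, info = beta_new, ll_new, U_new, info_new
        if delta < tol:
            converged = True
            break

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    z = np.divide(beta, se, out=np.full(p, np.nan), where=se > 0)
    pvals = 2 * stats.norm.sf(np.abs(z))
    hr = np.exp(beta)
    ci = np.stack([np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)], axis=1)
    return CoxFit(
        coefficients=beta,
        standard_errors=se,
        hazard_ratios=hr,
        ci95=ci,
        p_values=pvals,
        log_likelihood=float(ll),
        converged=converged,
        n_iter=it,
    )


class CoxPH:
    """scikit-learn-style wrapper around :func:`cox_fit`.

    Parameters
    ----------
    max_iter, tol : Newton-Raphson controls.

    Attributes (after ``fit``)
    --------------------------
    coef_, se_, hazard_ratios_, ci95_, p_values_, converged_, baseline_ :
        fit results; ``baseline_`` holds the Breslow baseline survival curve.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-8):
        self.max_iter = max_iter
        self.tol = tol

    def get_params(self, deep=True):
        return {"max_iter": self.max_iter, "tol": self.tol}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        data = _as_data(y)
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        res = cox_fit(X, data, max_iter=self.max_iter, tol=self.tol)
        self.result_ = res
        self.coef_ = res.coefficients
        self.se_ = res.standard_errors
        self.hazard_ratios_ = res.hazard_ratios
        self.ci95_ = res.ci95
        self.p_values_ = res.p_values
        self.converged_ = res.converged
        self._mean_ = X.mean(axis=0)
        eta = (X - self._mean_) @ res.coefficients
        self.baseline_ = breslow_baseline_survival(eta, data)
        return self

    def predict(self, X):
        """Linear predictor (log relative hazard, centered at training means)."""
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        return (X - self._mean_) @ self.coef_

    def predict_survival(self, X, horizon: float):
        """P(survive past ``horizon``) via the Breslow baseline: S0(h)^exp(eta)."""
        eta = self.predict(X)
        s0 = self.baseline_.at(horizon)
        return s0 ** np.exp(eta)


def breslow_baseline_survival(eta, data) -> SurvivalCurve:
    """Breslow estimate of the baseline survival S0(t) = exp(-H0(t)) with
    H0(t) = sum over event times <= t of d_i / sum_{j at risk} exp(eta_j)."""
    data = _as_data(data)
    t, e = data.times, data.events
    eta = np.asarray(eta, float)
    w = np.exp(eta)
    utimes = np.unique(t[e == 1])
    h0 = []
    cum = 0.0
    at_risk, n_ev = [], []
    for ut in utimes:
        risk = w[t >= ut].sum()
        d = int(((t == ut) & (e == 1)).sum())
        cum += d / risk
        h0.append(cum)
        at_risk.append(int((t >= ut).sum()))
        n_ev.append(d)
    return SurvivalCurve(
        event_times=utimes,
        survival=np.exp(-np.asarray(h0)),
        at_risk=np.asarray(at_risk, int),
        n_events=np.asarray(n_ev, int),
    )


# ---------------------------------------------------------------------------
# time-dependent AUC (cumulative/dynamic)
# ---------------------------------------------------------------------------

def time_dependent_auc(scores, data, horizon: float) -> float:
    """Cumulative/dynamic AUC at ``horizon``.

    Cases: event with time <= horizon.  Controls: time > horizon.  Patients
    censored at or before the horizon are excluded.  AUC is the pairwise
    probability that a case scores above a control, ties counting 1/2.
    """
    data = _as_data(data)
    s = np.asarray(scores, float)
    case = (data.times <= horizon) & (data.events == 1)
    control = data.times > horizon
    if case.sum() == 0 or control.sum() == 0:
        raise ValueError(f"no cases or no controls at horizon {horizon}")
    sc, sk = s[case][:, None], s[control][None, :]
    wins = (sc > sk).sum() + 0.5 * (sc == sk).sum()
    return float(wins / (case.sum() * control.sum()))


# ---------------------------------------------------------------------------
# maximally selected cutpoint
# ---------------------------------------------------------------------------

def _standardized_logrank(scores, data, cutoff) -> float:
    low = scores <= cutoff
    oe, var = _logrank_oe(
        data.times[low], data.events[low], data.times[~low], data.events[~low]
    )
    if var <= 0:
        return 0.0
    return abs(oe) / np.sqrt(var)


def optimal_cutoff(scores, data, min_prop: float = 0.1) -> CutoffResult:
    """Maximally selected log-rank cutpoint (the surv_cutpoint idea).

    Candidates are midpoints between adjacent sorted unique scores; a
    candidate is admissible when both resulting groups contain at least
    ``min_prop`` of the patients.  Returns the admissible cutoff with the
    largest standardized log-rank statistic; ties break to the smaller cutoff.
    """
    data = _as_data(data)
    s = np.asarray(scores, float)
    n = s.size
    uniq = np.unique(s)
    if uniq.size < 2:
        raise ValueError("scores are constant; no admissible cutoff")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    for c in candidates:
        n_low = int((s <= c).sum())
        n_high = n - n_low
        if n_low < min_prop * n or n_high < min_prop * n:
            continue
        z = _standardized_logrank(s, data, c)
        if best is None or z > best[1] + 1e-12:
            best = (c, z, n_low, n_high)
    if best is None:
        raise ValueError("no admissible cutoff under the min_prop constraint")
    return CutoffResult(cutoff=float(best[0]), statistic=float(best[1]),
                        n_low=best[2], n_high=best[3])


# ---------------------------------------------------------------------------
# decision-curve analysis
# ---------------------------------------------------------------------------

def decision_curve(probabilities, outcomes, thresholds) -> NetBenefitCurve:
    """Net benefit of classifying positive when probability >= threshold.

    NB(p_t) = TP/N - FP/N * p_t / (1 - p_t); treat-all and treat-none
    reference policies are included.
    """
    p = np.asarray(probabilities, float)
    y = np.asarray(outcomes, int)
    th = np.asarray(thresholds, float)
    if np.any((th <= 0) | (th >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    n = y.size
    prev = y.mean()
    model = np.empty_like(th)
    for i, pt in enumerate(th):
        pos = p >= pt
        tp = (pos & (y == 1)).sum() / n
        fp = (pos & (y == 0)).sum() / n
        model[i] = tp - fp * pt / (1 - pt)
    treat_all = prev - (1 - prev) * th / (1 - th)
    return NetBenefitCurve(thresholds=th, model=model, treat_all=treat_all)
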