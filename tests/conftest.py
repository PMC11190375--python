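"""Shared fixtures: tiny seeded cohorts and independent brute-force oracles.

Oracles here are written straight from the statistical definitions (explicit
pair loops, hand product-limit computation, direct O-E tallies) so they stay
independent of the vectorized implementations they check.
"""

import numpy as np
import pytest

from milsurv.synthetic import SyntheticCohortSpec, generate_cohort


# ---------------------------------------------------------------------------
# cohort fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_cohort():
    """40-patient cohort with mild signal in all modalities; fast tests."""
    spec = SyntheticCohortSpec(
        n_patients=40, n_genes=20, n_prognostic_genes=3, feature_dim=8,
        bag_size_range=(4, 8), signal_fraction=0.8,
        beta_image=2.0, beta_gene=1.0, beta_clinical=1.0,
        censoring_rate=0.25, seed=7,
    )
    return generate_cohort(spec)


def cohort_matrices(cohort):
    t, e = cohort.survival_arrays()
    gene = cohort.expression_matrix().to_numpy().T
    clinical = np.stack([p.clinical for p in cohort.patients])
    return t, e, gene, clinical


# study conditions for the end-to-end recovery checks: a 200-patient cohort
# with a strong image signal (image-only oracle C ~0.77) plus gene and
# clinical signals, and the training configuration used with it
PLANTED_SPEC = dict(
    n_patients=200, n_genes=30, n_prognostic_genes=3, feature_dim=32,
    bag_size_range=(16, 16), signal_fraction=1.0,
    beta_image=5.0, beta_gene=3.0, beta_clinical=2.0,
    censoring_rate=0.25,
)
TRAINER_KWARGS = dict(
    hidden_dim=64, embed_dim=32, attn_dim=16,
    max_epochs=300, learning_rate=3e-3, batch_size=64, seed=1,
)


def train_and_heldout_cindex(cohort, use_covariates=True, trainer_kwargs=None):
    """Train on the cohort's seeded 8:2 split; return the validation C-index
    of the risk -log(score)."""
    from milsurv.model import MILSurvivalModel
    from milsurv.survival import concordance_index

    t, e, gene, clinical = cohort_matrices(cohort)
    kwargs = dict(TRAINER_KWARGS)
    if trainer_kwargs:
        kwargs.update(trainer_kwargs)
    model = MILSurvivalModel(
        use_gene=use_covariates, use_clinical=use_covariates, **kwargs)
    bags = cohort.bags()
    model.fit(bags, (t, e),
              gene=gene if use_covariates else None,
              clinical=clinical if use_covariates else None)
    vi = model.val_idx_
    risk = model.predict_risk(
        [bags[i] for i in vi],
        gene=gene[vi] if use_covariates else None,
        clinical=clinical[vi] if use_covariates else None)
    return concordance_index(risk, (t[vi], e[vi]))


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def cindex_bruteforce(scores, times, events):
    """Explicit pair loop for Harrell's C."""
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


def km_by_hand(times, events):
    """Product-limit computed step by step; returns (event_times, survival)."""
    s = 1.0
    out_t, out_s = [], []
    for ut in sorted(set(t for t, e in zip(times, events) if e == 1)):
        n_risk = sum(1 for t in times if t >= ut)
        d = sum(1 for t, e in zip(times, events) if t == ut and e == 1)
        s = s * (n_risk - d) / n_risk
        out_t.append(ut)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def logrank_by_hand(ta, ea, tb, eb):
    """Direct O-E and hypergeometric-variance tally; returns chi-square."""
    t = list(ta) + list(tb)
    e = list(ea) + list(eb)
    grp = [0] * len(ta) + [1] * len(tb)
    oe = var = 0.0
    for ut in sorted({ti for ti, ei in zip(t, e) if ei == 1}):
        n = sum(1 for ti in t if ti >= ut)
        na = sum(1 for ti, g in zip(t, grp) if ti >= ut and g == 0)
        d = sum(1 for ti, ei in zip(t, e) if ti == ut and ei == 1)
        da = sum(1 for ti, ei, g in zip(t, e, grp) if ti == ut and ei == 1 and g == 0)
        oe += da - d * na / n
        if n > 1:
            var += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    return oe * oe / var


def cox_partial_loglik(beta, x, times, events):
    """Breslow log partial likelihood for a single covariate (for grid search)."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


def auc_bruteforce(scores, times, events, horizon):
    """Exhaustive case-control pair count for the cumulative/dynamic AUC."""
    cases = [i for i in range(len(times)) if times[i] <= horizon and events[i] == 1]
    controls = [i for i in range(len(times)) if times[i] > horizon]
    wins = 0.0
    for i in cases:
        for j in controls:
            if scores[i] > scores[j]:
                wins += 1
            elif scores[i] == scores[j]:
                wins += 0.5
    return wins / (len(cases) * len(controls))
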