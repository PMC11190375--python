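"""Gene panel construction: cross-cohort intersection, univariate Cox
screening and random-forest importance ranking.

The screen fits one single-covariate Cox proportional-hazards model per gene
(Newton-Raphson on the Breslow partial likelihood) on per-gene z-scored
expression, keeps genes whose Wald p-value clears a stringent threshold
(default alpha = 0.0116), then ranks the survivors by impurity-based
random-forest importance for the event-status label.  The resulting panel is
what the multimodal network consumes as its gene covariate vector.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .survival import SurvivalData, cox_fit

__all__ = [
    "DEFAULT_ALPHA",
    "intersect_genes",
    "univariate_cox_screen",
    "random_forest_select",
    "UnivariateCoxScreen",
    "RandomForestGeneSelector",
    "zscore_genes",
]

DEFAULT_ALPHA = 0.0116


def intersect_genes(genes_a, genes_b) -> list:
    """Deterministic sorted intersection of two gene-identifier lists.

    An empty intersection is returned (with a warning) rather than raised;
    downstream stages must reject it.
    """
    if len(genes_a) == 0 or len(genes_b) == 0:
        raise ValueError("gene lists must be non-empty")
    common = sorted(set(genes_a) & set(genes_b))
    if not common:
        warnings.warn("gene intersection is empty", UserWarning, stacklevel=2)
    return common


def zscore_genes(values: np.ndarray) -> np.ndarray:
    """Per-gene (row-wise) z-scoring; zero-variance rows are left centered."""
    v = np.asarray(values, float)
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (v - mu) / sd


class UnivariateCoxScreen:
    """Per-gene univariate Cox screen, scikit-learn transformer style.

    ``fit`` expects ``X`` with patients as rows and genes as columns (gene
    names supplied separately or taken from a DataFrame) and ``y`` as
    ``(times, events)`` or :class:`SurvivalData`.

    Attributes after fit
    --------------------
    results_ : DataFrame with per-gene coefficient, hazard_ratio, p_value,
        selected and estimable columns.
    selected_genes_ : list of gene identifiers with p < alpha.
    """

    def __init__(self, alpha: float = DEFAULT_ALPHA):
        self.alpha = alpha

    def get_params(self, deep=True):
        return {"alpha": self.alpha}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y, gene_ids=None):
        if isinstance(X, pd.DataFrame):
            gene_ids = list(X.columns)
            X = X.to_numpy()
        X = np.asarray(X, float)
        n, g = X.shape
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(g)]
        data = y if isinstance(y, SurvivalData) else SurvivalData(*y)
        if len(data) != n:
            raise ValueError("X rows must align with survival data")
        if data.events.sum() < 1:
            raise ValueError("screening requires at least one event")

        Xz = zscore_genes(X.T).T  # z-score per gene across patients
        coefs = np.full(g, np.nan)
        ses = np.full(g, np.nan)
        pvals = np.full(g, np.nan)
        estimable = np.zeros(g, bool)
        for j in range(g):
            col = Xz[:, j]
            if np.std(X[:, j]) == 0:
                continue  # zero-variance: unestimable, never selected
            try:
                fit = cox_fit(col[:, None], data)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if not fit.converged or not np.isfinite(fit.p_values[0]):
                continue
            coefs[j] = fit.coefficients[0]
            ses[j] = fit.standard_errors[0]
            pvals[j] = fit.p_values[0]
            estimable[j] = True
        selected = estimable & (pvals < self.alpha)
        self.results_ = pd.DataFrame({
            "gene": gene_ids,
            "coefficient": coefs,
            "hazard_ratio": np.exp(coefs),
            "se": ses,
            "p_value": pvals,
            "estimable": estimable,
            "selected": selected,
        })
        self.gene_ids_ = list(gene_ids)
        self.selected_mask_ = selected
        self.selected_genes_ = [gid for gid, s in zip(gene_ids, selected) if s]
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.selected_genes_]
        return np.asarray(X)[:, self.selected_mask_]


class RandomForestGeneSelector:
    """Random-forest importance ranking of screened genes.

    Fits a seeded random-forest classifier of event status on gene expression
    (patients x genes) and ranks genes by impurity-based importance, ties
    broken by gene identifier.  ``n_top=None`` keeps the whole ranking.
    """

    def __init__(self, n_top=None, n_estimators: int = 500, seed: int = 0):
        self.n_top = n_top
        self.n_estimators = n_estimators
        self.seed = seed

    def get_params(self, deep=True):
        return {"n_top": self.n_top, "n_estimators": self.n_estimators,
                "seed": self.seed}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, events, gene_ids=None):
        if isinstance(X, pd.DataFrame):
            gene_ids = list(X.columns)
            X = X.to_numpy()
        X = np.asarray(X, float)
        if X.shape[1] == 0:
            raise ValueError("screened gene set is empty")
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(X.shape[1])]
        events = np.asarray(events, int)
        rf = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.seed, n_jobs=1
        )
        rf.fit(X, events)
        imp = rf.feature_importances_
        order = sorted(range(len(gene_ids)), key=lambda j: (-imp[j], gene_ids[j]))
        n_top = self.n_top
        if n_top is not None and n_top > len(gene_ids):
            warnings.warn(
                f"n_top={n_top} exceeds the {len(gene_ids)} screened genes; "
                "returning all", UserWarning, stacklevel=2)
            n_top = len(gene_ids)
        keep = order if n_top is None else order[:n_top]
        self.importances_ = imp
        self.ranking_ = [gene_ids[j] for j in order]
        self.selected_genes_ = [gene_ids[j] for j in keep]
        self.selected_idx_ = keep
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.selected_genes_]
        return np.asarray(X)[:, self.selected_idx_]


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def univariate_cox_screen(expr, times, events, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Screen a genes x patients expression table; returns the per-gene
    results frame (coefficient, hazard_ratio, p_value, selected)."""
    if isinstance(expr, pd.DataFrame):
        gene_ids = list(expr.index)
        X = expr.to_numpy().T
    else:
        X = np.asarray(expr, float).T
        gene_ids = None
    screen = UnivariateCoxScreen(alpha=alpha).fit(X, (times, events), gene_ids=gene_ids)
    return screen.results_


def random_forest_select(expr, events, n_top=None, seed: int = 0) -> pd.DataFrame:
    """Rank genes (rows of ``expr``) by random-forest importance for event
    status; returns a frame ordered by rank with importances."""
    if isinstance(expr, pd.DataFrame):
        gene_ids = list(expr.index)
        X = expr.to_numpy().T
    else:
        X = np.asarray(expr, float).T
        gene_ids = None
    sel = RandomForestGeneSelector(n_top=n_top, seed=seed).fit(
        X, events, gene_ids=gene_ids)
    ids = gene_ids if gene_ids is not None else [f"g{i}" for i in range(X.shape[1])]
    by_id = dict(zip(ids, sel.importances_))
    return pd.DataFrame({
        "gene": sel.selected_genes_,
        "importance": [by_id[g] for g in sel.selected_genes_],
        "rank": np.arange(1, len(sel.selected_genes_) + 1),
    })
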