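"""Multimodal attention-MIL survival network and its Cox training loop.

Architecture
------------
Each slide is a bag of patch feature vectors.  Instances are embedded by two
linear layers with ReLU activations, pooled by gated attention

    a_k = softmax_k( w^T ( tanh(V h_k) * sigm(U h_k) ) ),   z = sum_k a_k h_k,

with two parallel attention heads whose pooled vectors are concatenated.  The
pooled slide representation is fused with the gene covariate vector and the
clinical covariate vector and passed through a final fully connected head that
emits three raw outputs: two are squashed by the logistic function into
survival probabilities p1, p2 and the third by softplus into a positive
survival-time estimate t_hat.  The survival score is their product
``score = p1 * p2 * t_hat``; the model's risk is ``eta = -log(score)`` (higher
score = longer predicted survival = lower hazard).

Training minimizes the negative log Cox partial likelihood (Breslow ties) of
the risks over minibatches, with Adam or SGD, L2 weight decay and dropout in
the embedder.  All computation is numpy via the package's reverse-mode
autodiff engine; gradients are pinned by finite-difference tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._autograd import Tensor, parameter
from .survival import SurvivalData, concordance_index
from .wsi import PatchBag

__all__ = [
    "AttentionParams",
    "AttentionOutput",
    "ModelOutput",
    "TrainConfig",
    "MILSurvivalModel",
    "embed_instances",
    "gated_attention_pool",
    "model_forward",
    "cox_nll",
    "cox_nll_grad",
    "train_model",
    "predict_cohort",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AttentionParams:
    """One gated-attention head: w in R^L, U and V in R^{L x M}."""

    w: np.ndarray
    U: np.ndarray
    V: np.ndarray

    def __post_init__(self):
        self.w = np.asarray(self.w, float).reshape(-1)
        self.U = np.asarray(self.U, float)
        self.V = np.asarray(self.V, float)
        L = self.w.shape[0]
        if self.U.shape[0] != L or self.V.shape[0] != L or self.U.shape != self.V.shape:
            raise ValueError("attention parameter shapes inconsistent")


@dataclass
class AttentionOutput:
    """Per-head attention weights (each sums to 1) and pooled embeddings."""

    weights: list   # list of (K,) arrays, one per head
    pooled: list    # list of (M,) arrays, one per head

    @property
    def pooled_concat(self) -> np.ndarray:
        return np.concatenate(self.pooled)


@dataclass
class ModelOutput:
    p1: float
    p2: float
    t_hat: float

    @property
    def score(self) -> float:
        return self.p1 * self.p2 * self.t_hat

    @property
    def risk(self) -> float:
        return -float(np.log(self.score))


@dataclass
class TrainConfig:
    """Training hyperparameters (published-configuration defaults)."""

    max_epochs: int = 30
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    optimizer: str = "adam"          # "adam" | "sgd"
    dropout: float = 0.25
    seed: int = 1
    k_folds: int = 10
    k_start: int = -1
    k_end: int = -1
    early_stopping: bool = False
    weighted_sample: bool = False
    use_gene: bool = True
    use_clinical: bool = True
    batch_size: int = 64
    val_fraction: float = 0.2        # the 8:2 train/validation split

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


# ---------------------------------------------------------------------------
# functional building blocks (plain numpy, mirrored by the training graph)
# ---------------------------------------------------------------------------

def embed_instances(features: np.ndarray, W1, b1, W2, b2) -> np.ndarray:
    """Two linear layers with ReLU after each, applied independently per
    instance: H_k = relu(relu(x_k W1 + b1) W2 + b2)."""
    X = np.asarray(features, float)
    if X.shape[-1] != np.asarray(W1).shape[0]:
        raise ValueError("bag feature dimension does not match the embedder")
    h = np.maximum(X @ W1 + b1, 0.0)
    return np.maximum(h @ W2 + b2, 0.0)


def gated_attention_pool(H: np.ndarray, params) -> AttentionOutput:
    """Gated-attention pooling of an embedded bag.

    ``params`` is one :class:`AttentionParams` or a list of heads; each head
    computes logit_k = w^T(tanh(V h_k) * sigm(U h_k)), softmax over instances,
    and pools z = sum_k a_k h_k.  Heads are returned separately (callers
    concatenate the pooled vectors).
    """
    H = np.asarray(H, float)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValueError("H must be a non-empty K x M matrix")
    heads = params if isinstance(params, (list, tuple)) else [params]
    weights, pooled = [], []
    for p in heads:
        gate = np.tanh(H @ p.V.T) * (1.0 / (1.0 + np.exp(-(H @ p.U.T))))
        logits = gate @ p.w
        logits = logits - logits.max()
        a = np.exp(logits)
        a /= a.sum()
        weights.append(a)
        pooled.append(a @ H)
    return AttentionOutput(weights=weights, pooled=pooled)


def _squash(raw: np.ndarray):
    """Map three raw head outputs to (p1, p2, t_hat)."""
    p1 = 1.0 / (1.0 + np.exp(-raw[..., 0]))
    p2 = 1.0 / (1.0 + np.exp(-raw[..., 1]))
    r3 = raw[..., 2]
    t_hat = np.maximum(r3, 0.0) + np.log1p(np.exp(-np.abs(r3)))  # softplus
    return p1, p2, t_hat


# ---------------------------------------------------------------------------
# Cox partial-likelihood loss
# ---------------------------------------------------------------------------

def _risk_matrix(times, events):
    """Rows: events, in time order; columns: patients at risk (t_j >= t_i)."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    ev_idx = np.flatnonzero(e == 1)
    R = (t[ev_idx][:, None] <= t[None, :]).astype(float)
    return ev_idx, R


def cox_nll(scores, times, events) -> float:
    """Negative log Cox partial likelihood (Breslow ties), averaged over
    events: -(1/E) sum_i [eta_i - log sum_{t_j >= t_i} exp(eta_j)].

    ``scores`` are per-patient risk log-hazards.  Zero events yield 0.0 with
    a warning.
    """
    eta = np.asarray(scores, float)
    e = np.asarray(events, int)
    if e.sum() == 0:
        warnings.warn("no events: Cox loss defined as 0", UserWarning, stacklevel=2)
        return 0.0
    if not np.isfinite(eta).all():
        raise ValueError("risk scores must be finite")
    ev_idx, R = _risk_matrix(times, e)
    shift = eta.max()
    log_risk = np.log(R @ np.exp(eta - shift)) + shift
    return float(-(eta[ev_idx] - log_risk).mean())


def cox_nll_grad(scores, times, events) -> np.ndarray:
    """Analytic gradient of :func:`cox_nll` with respect to the risks."""
    eta = np.asarray(scores, float)
    e = np.asarray(events, int)
    n = eta.size
    if e.sum() == 0:
        return np.zeros(n)
    ev_idx, R = _risk_matrix(times, e)
    w = np.exp(eta - eta.max())
    denom = R @ w                      # (E,)
    # soft membership of each patient in each event's risk set
    frac = (R / denom[:, None]) * w[None, :]
    grad = frac.sum(axis=0)
    grad[ev_idx] -= 1.0
    return grad / len(ev_idx)


def _cox_nll_tensor(eta: Tensor, times, events) -> Tensor:
    """Autograd version of the loss used by the training loop."""
    e = np.asarray(events, int)
    ev_idx, R = _risk_matrix(times, e)
    shift = float(eta.value.max())
    w = (eta - shift).exp()                       # (n, 1)
    log_risk = Tensor(R).matmul(w).log() + shift  # (E, 1)
    return (log_risk - eta.take_rows(ev_idx)).mean()


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class MILSurvivalModel:
    """Gated-attention MIL network for multimodal survival prediction,
    scikit-learn estimator style.

    Parameters
    ----------
    hidden_dim, embed_dim, attn_dim, n_heads :
        Embedder and attention sizes (defaults 512 / 256 / 128 / 2; instance
        input dimension is inferred from the bags at fit time).
    use_gene, use_clinical :
        Whether the gene / clinical covariate vectors are fused into the head.
    max_epochs, learning_rate, weight_decay, optimizer, dropout, batch_size,
    seed, val_fraction, early_stopping, patience, weighted_sample :
        Training controls; defaults follow the published configuration
        (30 epochs, lr 1e-4, weight decay 1e-5, Adam, dropout 0.25, seed 1,
        8:2 train/validation split).

    Attributes after fit
    --------------------
    params_ : dict of parameter arrays.
    history_ : DataFrame with per-epoch train and validation loss.
    train_idx_, val_idx_ : the seeded split.
    """

    def __init__(self, hidden_dim=512, embed_dim=256, attn_dim=128, n_heads=2,
                 use_gene=True, use_clinical=True,
                 max_epochs=30, learning_rate=1e-4, weight_decay=1e-5,
                 optimizer="adam", dropout=0.25, batch_size=64, seed=1,
                 val_fraction=0.2, early_stopping=False, patience=5,
                 weighted_sample=False):
        self.hidden_dim = hidden_dim
        self.embed_dim = embed_dim
        self.attn_dim = attn_dim
        self.n_heads = n_heads
        self.use_gene = use_gene
        self.use_clinical = use_clinical
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.optimizer = optimizer
        self.dropout = dropout
        self.batch_size = batch_size
        self.seed = seed
        self.val_fraction = val_fraction
        self.early_stopping = early_stopping
        self.patience = patience
        self.weighted_sample = weighted_sample

    # -- sklearn plumbing ---------------------------------------------------

    _param_names = (
        "hidden_dim embed_dim attn_dim n_heads use_gene use_clinical "
        "max_epochs learning_rate weight_decay optimizer dropout batch_size "
        "seed val_fraction early_stopping patience weighted_sample"
    ).split()

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- parameter initialization --------------------------------------------

    def _init_params(self, rng, in_dim, gene_dim, clinical_dim):
        def glorot(shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-lim, lim, size=shape)

        M, L = self.embed_dim, self.attn_dim
        p = {
            "W1": glorot((in_dim, self.hidden_dim)),
            "b1": np.zeros(self.hidden_dim),
            "W2": glorot((self.hidden_dim, M)),
            "b2": np.zeros(M),
        }
        for h in range(self.n_heads):
            p[f"V{h}"] = glorot((M, L))   # stored transposed: H @ V{h}
            p[f"U{h}"] = glorot((M, L))
            p[f"w{h}"] = glorot((L, 1))
        fuse = self.n_heads * M + (gene_dim if self.use_gene else 0) \
            + (clinical_dim if self.use_clinical else 0)
        p["Wh"] = glorot((fuse, 3))
        p["bh"] = np.zeros(3)
        return p

    # -- graph forward --------------------------------------------------------

    def _forward_graph(self, params, X, gene, clin, training, drop_rng):
        """Forward a (m, K, D) stacked batch; returns dict of Tensors.

        ``params`` maps names to Tensors; gene/clin are (m, dim) arrays or
        None.  Dropout masks come from ``drop_rng`` when training.
        """
        Xt = Tensor(X)
        h1 = (Xt @ params["W1"] + params["b1"]).relu()
        if training and self.dropout > 0:
            keep = 1.0 - self.dropout
            h1 = h1 * (drop_rng.random(h1.shape) < keep).astype(float) * (1.0 / keep)
        H = (h1 @ params["W2"] + params["b2"]).relu()
        if training and self.dropout > 0:
            keep = 1.0 - self.dropout
            H = H * (drop_rng.random(H.shape) < keep).astype(float) * (1.0 / keep)

        pooled, attn_w = [], []
        for h in range(self.n_heads):
            gate = (H @ params[f"V{h}"]).tanh() * (H @ params[f"U{h}"]).sigmoid()
            logits = gate @ params[f"w{h}"]          # (m, K, 1)
            a = logits.softmax(axis=1)
            pooled.append((a * H).sum(axis=1))       # (m, M)
            attn_w.append(a)
        parts = [Tensor.concat(pooled, axis=-1)]
        if self.use_gene:
            parts.append(Tensor(gene))
        if self.use_clinical:
            parts.append(Tensor(clin))
        fused = Tensor.concat(parts, axis=-1) if len(parts) > 1 else parts[0]
        raw = fused @ params["Wh"] + params["bh"]    # (m, 3)
        r1 = raw.slice_cols(0, 1)
        r2 = raw.slice_cols(1, 2)
        r3 = raw.slice_cols(2, 3)
        # risk eta = -log(p1 p2 t_hat) = softplus(-r1) + softplus(-r2) - log softplus(r3)
        eta = (-r1).softplus() + (-r2).softplus() - r3.softplus().log()
        return {"raw": raw, "eta": eta, "attention": attn_w}

    # -- data marshalling ------------------------------------------------------

    @staticmethod
    def _bag_features(bag):
        if isinstance(bag, PatchBag):
            return np.asarray(bag.features, float)
        return np.asarray(bag, float)

    def _check_modalities(self, n, gene, clinical):
        if self.use_gene:
            if gene is None:
                raise ValueError("use_gene is on but no gene matrix was provided")
            gene = np.asarray(gene, float)
            if gene.shape[0] != n:
                raise ValueError("gene matrix rows must match the number of patients")
        else:
            gene = None
        if self.use_clinical:
            if clinical is None:
                raise ValueError("use_clinical is on but no clinical matrix was provided")
            clinical = np.asarray(clinical, float)
            if clinical.shape[0] != n:
                raise ValueError("clinical matrix rows must match the number of patients")
        else:
            clinical = None
        return gene, clinical

    def _scale(self, name, mat):
        if mat is None or name not in getattr(self, "scalers_", {}):
            return mat
        mu, sd = self.scalers_[name]
        return (mat - mu) / sd

    def _group_by_bag_size(self, feats):
        groups = {}
        for i, f in enumerate(feats):
            groups.setdefault(f.shape[0], []).append(i)
        return groups

    def _batch_eta(self, params_t, feats, gene, clin, idx, training, drop_rng):
        """Risk tensor for patients ``idx``, assembled across bag-size groups
        and re-ordered to match ``idx``."""
        sub_feats = [feats[i] for i in idx]
        groups = self._group_by_bag_size(sub_feats)
        etas, positions = [], []
        for k, local in groups.items():
            X = np.stack([sub_feats[j] for j in local])
            g = gene[[idx[j] for j in local]] if gene is not None else None
            c = clin[[idx[j] for j in local]] if clin is not None else None
            out = self._forward_graph(params_t, X, g, c, training, drop_rng)
            etas.append(out["eta"])
            positions.extend(local)
        eta_cat = Tensor.concat(etas, axis=0)
        # invert the grouping permutation so rows align with idx order
        inv = np.empty(len(positions), dtype=int)
        inv[np.asarray(positions)] = np.arange(len(positions))
        return eta_cat.take_rows(inv)

    # -- fitting ---------------------------------------------------------------

    def fit(self, bags, y, gene=None, clinical=None, val_idx=None):
        data = y if isinstance(y, SurvivalData) else SurvivalData(*y)
        feats = [self._bag_features(b) for b in bags]
        n = len(feats)
        if n != len(data):
            raise ValueError("bags must align with survival data")
        gene, clinical = self._check_modalities(n, gene, clinical)
        # z-score covariate modalities (stored; re-applied at predict time)
        self.scalers_ = {}
        for name, mat in (("gene", gene), ("clinical", clinical)):
            if mat is None:
                continue
            mu, sd = mat.mean(axis=0), mat.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            self.scalers_[name] = (mu, sd)
        gene = self._scale("gene", gene)
        clinical = self._scale("clinical", clinical)
        in_dim = feats[0].shape[1]
        gene_dim = gene.shape[1] if gene is not None else 0
        clin_dim = clinical.shape[1] if clinical is not None else 0

        rng = np.random.default_rng(self.seed)
        drop_rng = np.random.default_rng(rng.integers(2**31))

        if val_idx is None:
            perm = rng.permutation(n)
            n_val = int(round(self.val_fraction * n))
            val_idx = np.sort(perm[:n_val])
            train_idx = np.sort(perm[n_val:])
        else:
            val_idx = np.asarray(val_idx, int)
            train_idx = np.setdiff1d(np.arange(n), val_idx)
        if data.events[train_idx].sum() < 2:
            raise ValueError("training split must contain at least 2 events")

        params = self._init_params(rng, in_dim, gene_dim, clin_dim)
        params_t = {k: parameter(v) for k, v in params.items()}
        opt_m = {k: np.zeros_like(v) for k, v in params.items()}
        opt_v = {k: np.zeros_like(v) for k, v in params.items()}
        step = 0

        def adam_update(k, g):
            g = g + self.weight_decay * params_t[k].value
            opt_m[k] = 0.9 * opt_m[k] + 0.1 * g
            opt_v[k] = 0.999 * opt_v[k] + 0.001 * g * g
            mhat = opt_m[k] / (1 - 0.9 ** step)
            vhat = opt_v[k] / (1 - 0.999 ** step)
            params_t[k].value -= self.learning_rate * mhat / (np.sqrt(vhat) + 1e-8)

        history = {"epoch": [], "train_loss": [], "val_loss": []}
        best_val, best_params, since_best = np.inf, None, 0
        t_all, e_all = data.times, data.events

        for epoch in range(1, self.max_epochs + 1):
            if self.weighted_sample:
                ev = e_all[train_idx]
                w = np.where(ev == 1, 0.5 / max(ev.mean(), 1e-12),
                             0.5 / max(1 - ev.mean(), 1e-12))
                order = rng.choice(len(train_idx), size=len(train_idx),
                                   replace=True, p=w / w.sum())
            else:
                order = rng.permutation(len(train_idx))
            for start in range(0, len(order), self.batch_size):
                batch = train_idx[order[start:start + self.batch_size]]
                if e_all[batch].sum() == 0:
                    continue  # no events: zero partial-likelihood contribution
                eta = self._batch_eta(params_t, feats, gene, clinical,
                                      list(batch), True, drop_rng)
                loss = _cox_nll_tensor(eta, t_all[batch], e_all[batch])
                for p in params_t.values():
                    p.grad = None
                loss.backward()
                step += 1
                for k, p in params_t.items():
                    if p.grad is None:
                        continue
                    if self.optimizer == "adam":
                        adam_update(k, p.grad)
                    else:  # sgd
                        p.value -= self.learning_rate * (
                            p.grad + self.weight_decay * p.value)

            train_loss = self._eval_loss(params_t, feats, gene, clinical,
                                         train_idx, t_all, e_all)
            val_loss = self._eval_loss(params_t, feats, gene, clinical,
                                       val_idx, t_all, e_all)
            history["epoch"].append(epoch)
            history["train_loss"].append(train_loss)
            history["val_loss"].append(val_loss)

            if val_loss < best_val - 1e-12:
                best_val, since_best = val_loss, 0
                best_params = {k: p.value.copy() for k, p in params_t.items()}
            else:
                since_best += 1
            if self.early_stopping and since_best >= self.patience:
                break

        if self.early_stopping and best_params is not None:
            final = best_params
        else:
            final = {k: p.value.copy() for k, p in params_t.items()}
        self.params_ = final
        self.in_dim_, self.gene_dim_, self.clinical_dim_ = in_dim, gene_dim, clin_dim
        self.history_ = pd.DataFrame(history)
        self.train_idx_, self.val_idx_ = train_idx, val_idx
        return self

    def _eval_loss(self, params_t, feats, gene, clin, idx, t, e):
        if len(idx) == 0 or e[idx].sum() == 0:
            return np.nan
        eta = self._batch_eta(params_t, feats, gene, clin, list(idx), False, None)
        return cox_nll(eta.value.ravel(), t[idx], e[idx])

    # -- prediction -------------------------------------------------------------

    def _require_fitted(self):
        if not hasattr(self, "params_"):
            raise ValueError("model is not fitted")

    def predict(self, bags, gene=None, clinical=None) -> pd.DataFrame:
        """Per-patient outputs (evaluation mode, dropout off): p1, p2, t_hat,
        score = p1*p2*t_hat, and risk = -log(score).  Outputs are independent
        of batch composition and patient order."""
        self._require_fitted()
        feats = [self._bag_features(b) for b in bags]
        gene, clinical = self._check_modalities(len(feats), gene, clinical)
        gene = self._scale("gene", gene)
        clinical = self._scale("clinical", clinical)
        params_t = {k: Tensor(v) for k, v in self.params_.items()}
        rows = []
        for i, f in enumerate(feats):
            if f.shape[1] != self.in_dim_:
                raise ValueError("bag feature dimension does not match the model")
            g = gene[i:i + 1] if gene is not None else None
            c = clinical[i:i + 1] if clinical is not None else None
            out = self._forward_graph(params_t, f[None], g, c, False, None)
            p1, p2, t_hat = _squash(out["raw"].value[0])
            rows.append((float(p1), float(p2), float(t_hat)))
        df = pd.DataFrame(rows, columns=["p1", "p2", "t_hat"])
        df["score"] = df.p1 * df.p2 * df.t_hat
        df["risk"] = -np.log(df.score)
        return df

    def predict_risk(self, bags, gene=None, clinical=None) -> np.ndarray:
        return self.predict(bags, gene, clinical)["risk"].to_numpy()

    def forward_one(self, bag, gene_vec=None, clinical_vec=None):
        """Single-patient forward pass returning (ModelOutput, AttentionOutput)."""
        self._require_fitted()
        f = self._bag_features(bag)
        g = np.asarray(gene_vec, float)[None] if gene_vec is not None else None
        c = np.asarray(clinical_vec, float)[None] if clinical_vec is not None else None
        if self.use_gene and g is None:
            raise ValueError("use_gene is on but no gene vector was provided")
        if self.use_clinical and c is None:
            raise ValueError("use_clinical is on but no clinical vector was provided")
        g = self._scale("gene", g)
        c = self._scale("clinical", c)
        params_t = {k: Tensor(v) for k, v in self.params_.items()}
        out = self._forward_graph(params_t, f[None], g, c, False, None)
        p1, p2, t_hat = _squash(out["raw"].value[0])
        attn = AttentionOutput(
            weights=[a.value[0, :, 0].copy() for a in out["attention"]],
            pooled=[(a.value[0, :, 0] @ _embed_numpy(self.params_, f))
                    for a in out["attention"]],
        )
        return ModelOutput(p1=float(p1), p2=float(p2), t_hat=float(t_hat)), attn

    def attention_params(self):
        """The fitted attention heads as :class:`AttentionParams` (w, U, V in
        the printed L x M orientation)."""
        self._require_fitted()
        return [
            AttentionParams(w=self.params_[f"w{h}"].ravel(),
                            U=self.params_[f"U{h}"].T,
                            V=self.params_[f"V{h}"].T)
            for h in range(self.n_heads)
        ]


def _embed_numpy(params, feats):
    return embed_instances(feats, params["W1"], params["b1"],
                           params["W2"], params["b2"])


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def model_forward(model: MILSurvivalModel, bag, gene_vec=None, clinical_vec=None):
    """Forward one patient through a fitted model; returns
    (ModelOutput, AttentionOutput)."""
    return model.forward_one(bag, gene_vec, clinical_vec)


def train_model(bags, times, events, gene=None, clinical=None,
                config: TrainConfig | None = None, **overrides) -> MILSurvivalModel:
    """Train a model with a :class:`TrainConfig`; returns the fitted estimator
    (training history in ``model.history_``)."""
    cfg = config or TrainConfig()
    model = MILSurvivalModel(
        max_epochs=cfg.max_epochs, learning_rate=cfg.learning_rate,
        weight_decay=cfg.weight_decay, optimizer=cfg.optimizer,
        dropout=cfg.dropout, seed=cfg.seed, batch_size=cfg.batch_size,
        val_fraction=cfg.val_fraction, early_stopping=cfg.early_stopping,
        weighted_sample=cfg.weighted_sample,
        use_gene=cfg.use_gene and gene is not None,
        use_clinical=cfg.use_clinical and clinical is not None,
        **overrides,
    )
    return model.fit(bags, (times, events), gene=gene, clinical=clinical)


def predict_cohort(model: MILSurvivalModel, bags, gene=None, clinical=None) -> pd.DataFrame:
    """Per-patient ModelOutput table for a fitted model."""
    return model.predict(bags, gene=gene, clinical=clinical)


def cross_validated_cindex(bags, times, events, gene=None, clinical=None,
                           k_folds=10, k_start=None, k_end=None,
                           seed=1, **model_kwargs):
    """Seeded k-fold cross-validation; trains one model per fold and returns
    the held-out concordance index of each evaluated fold."""
    n = len(bags)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k_folds)
    lo = 0 if not k_start or k_start < 0 else k_start - 1
    hi = k_folds if not k_end or k_end < 0 else k_end
    out = []
    for f in range(lo, hi):
        test = np.sort(folds[f])
        model = MILSurvivalModel(seed=seed, use_gene=gene is not None,
                                 use_clinical=clinical is not None,
                                 **model_kwargs)
        model.fit([bags[i] for i in np.setdiff1d(np.arange(n), test)],
                  (np.delete(times, test), np.delete(events, test)),
                  gene=np.delete(gene, test, axis=0) if gene is not None else None,
                  clinical=np.delete(clinical, test, axis=0) if clinical is not None else None)
        risk = model.predict_risk(
            [bags[i] for i in test],
            gene=gene[test] if gene is not None else None,
            clinical=clinical[test] if clinical is not None else None)
        out.append(concordance_index(risk, (times[test], events[test])))
    return out


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_model(model: MILSurvivalModel, path) -> None:
    model._require_fitted()
    arrays = {f"param__{k}": v for k, v in model.params_.items()}
    for name, (mu, sd) in getattr(model, "scalers_", {}).items():
        arrays[f"scaler__{name}__mu"] = mu
        arrays[f"scaler__{name}__sd"] = sd
    meta = model.get_params()
    meta.update(in_dim=model.in_dim_, gene_dim=model.gene_dim_,
                clinical_dim=model.clinical_dim_)
    np.savez(path, __config__=json.dumps(meta), **arrays)


def load_model(path) -> MILSurvivalModel:
    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["__config__"]))
        params = {k[len("param__"):]: f[k] for k in f.files if k.startswith("param__")}
        scalers = {}
        for k in f.files:
            if k.startswith("scaler__") and k.endswith("__mu"):
                name = k[len("scaler__"):-len("__mu")]
                scalers[name] = (f[k], f[f"scaler__{name}__sd"])
    in_dim = meta.pop("in_dim")
    gene_dim = meta.pop("gene_dim")
    clin_dim = meta.pop("clinical_dim")
    model = MILSurvivalModel(**meta)
    model.params_ = params
    model.scalers_ = scalers
    model.in_dim_, model.gene_dim_, model.clinical_dim_ = in_dim, gene_dim, clin_dim
    model.history_ = pd.DataFrame()
    return model
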