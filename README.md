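# milsurv

Attention-based multiple-instance learning (MIL) for multimodal
disease-free-survival (DFS) prediction in oncology cohorts.

Digitized histopathology slides are gigapixel images with labels (recurrence,
death, censoring) only at the patient level. `milsurv` implements the standard
weakly supervised recipe end to end: a slide is segmented into tissue, tiled
into 256×256 patches, each patch mapped to a feature vector, and the resulting
*bag* of instances H = {h₁, …, h_K} pooled by **gated attention**

```
a_k = softmax_k( wᵀ ( tanh(V h_k) ⊙ sigm(U h_k) ) ),      z = Σ_k a_k h_k
```

with w ∈ ℝᴸ and U, V ∈ ℝ^{L×M} learned parameters and two parallel attention
heads whose pooled vectors are concatenated. The slide representation z is
fused with a screened gene-expression panel and clinical covariates (stage,
age, intrinsic subtype, immune-cell scores) and passed through a final fully
connected head emitting three outputs: two survival probabilities p₁, p₂ and a
positive time estimate t̂. The survival score is their product
s = p₁·p₂·t̂, and the model's risk is η = −log s. Training minimizes the
negative log Cox partial likelihood of η (Breslow ties, DeepSurv-style),

```
L(η) = −(1/E) Σ_{i: event} [ η_i − log Σ_{j: t_j ≥ t_i} exp(η_j) ]
```

The package also provides, from scratch: Harrell's C-index, Kaplan–Meier,
the two-group log-rank test, Newton–Raphson Cox fits with Wald CIs, the
cumulative/dynamic time-dependent AUC, the maximally selected log-rank
cutpoint (the `surv_cutpoint` idea), decision-curve analysis, a univariate
Cox gene screen (default α = 0.0116) with random-forest importance ranking,
and attention-percentage heatmaps. A synthetic-cohort generator plants known
proportional-hazards signal in all three modalities so the whole pipeline is
testable without any external data.

There is no deep-learning framework dependency: the network and its training
loop run on NumPy through a small reverse-mode autodiff engine whose gradients
are pinned by finite-difference tests.

## Worked example

```python
import numpy as np
from milsurv import (SyntheticCohortSpec, generate_cohort, MILSurvivalModel,
                     concordance_index, optimal_cutoff, log_rank_test)

spec = SyntheticCohortSpec(
    n_patients=200, n_genes=30, n_prognostic_genes=3, feature_dim=32,
    bag_size_range=(16, 16), signal_fraction=1.0,
    beta_image=5.0, beta_gene=3.0, beta_clinical=2.0,
    censoring_rate=0.25, seed=1)
cohort = generate_cohort(spec)
t, e = cohort.survival_arrays()
gene = cohort.expression_matrix().to_numpy().T
clinical = np.stack([p.clinical for p in cohort.patients])

model = MILSurvivalModel(hidden_dim=64, embed_dim=32, attn_dim=16,
                         max_epochs=300, learning_rate=3e-3,
                         batch_size=64, seed=1)
model.fit(cohort.bags(), (t, e), gene=gene, clinical=clinical)

vi = model.val_idx_                      # the seeded 8:2 validation split
risk = model.predict_risk([cohort.bags()[i] for i in vi],
                          gene=gene[vi], clinical=clinical[vi])
print("held-out C-index:", round(concordance_index(risk, (t[vi], e[vi])), 3))

cut = optimal_cutoff(risk, (t[vi], e[vi]))
high = risk > cut.cutoff
chi2, p = log_rank_test((t[vi][~high], e[vi][~high]), (t[vi][high], e[vi][high]))
print("risk cutoff:", round(cut.cutoff, 3), " log-rank p:", f"{p:.2g}")
```

Output:

```
held-out C-index: 0.791
risk cutoff: 13.686  log-rank p: 3e-10
```

A held-out C-index of 0.79 against an oracle of 0.92 (the C-index of the true
planted linear predictor) shows the network recovering most of the planted
multimodal signal from 160 training patients; the maximally selected cutpoint
splits the validation cohort into risk groups whose survival differs at
p ≈ 3×10⁻¹⁰ by the log-rank test.

The `milsurv` CLI exposes the same pipeline from a shell:
`milsurv simulate cohort`, `segment`, `tile`, `featurize`, `screen-genes`,
`train`, `predict`, `evaluate`, `heatmap`. See `milsurv --help`.

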