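# Methods

## Model

`milsurv` predicts disease-free survival from three modalities: a bag of
whole-slide-image (WSI) patch features, a gene-expression covariate vector,
and a clinical covariate vector.

**Instance embedding.** Each patch feature x_k (D-dimensional; D = 1024 under
the ResNet50-stage-3 extractor contract, arbitrary for synthetic bags) passes
through two linear layers with ReLU activations,
h_k = relu(W₂ relu(W₁ x_k + b₁) + b₂), giving an M-dimensional instance
embedding. Dropout (default rate 0.25) is applied after each ReLU during
training only.

**Gated attention pooling.** Per head, instance logits are
wᵀ(tanh(V h_k) ⊙ sigm(U h_k)) with w ∈ ℝᴸ, U, V ∈ ℝ^{L×M}; a softmax over the
K instances yields weights a (non-negative, summing to 1) and the pooled
representation z = Σ a_k h_k, a convex combination of the embeddings. Two
parallel heads with independent (w, U, V) are used and their pooled vectors
concatenated. We read "two attention blocks" as parallel heads rather than
stacked layers: each head is then exactly the published scoring equation,
whereas stacking would require inventing an inter-block map the equation does
not define.

**Fusion and the three-output head.** Gene and clinical covariates are
z-scored at fit time (the scalers are stored with the model and re-applied at
prediction); otherwise raw clinical scales such as age would dominate the head
at initialization. The fused vector
[z-heads ‖ gene ‖ clinical] feeds a single fully connected layer with three
raw outputs. Two are squashed by the logistic function into survival
probabilities p₁, p₂ ∈ (0,1); the third by softplus into a positive time
estimate t̂ (months scale). These are the smallest-assumption maps satisfying
the outputs' stated ranges. The survival score is s = p₁·p₂·t̂, so
0 < s < t̂ always.

**Loss.** Training maximizes the Cox partial likelihood (Breslow tie
convention) of the risk η = −log s: a higher survival score means a lower
hazard. The three outputs receive no separate supervision; the product score
is the single trained quantity. The loss is averaged over events and is
invariant to adding a constant to all risks. Minibatches form their own risk
sets (batches without events contribute nothing and are skipped); the default
batch size is 64. Optimization uses Adam (default) or SGD with L2 weight
decay; defaults follow the published configuration: 30 epochs, learning rate
1e-4, weight decay 1e-5, dropout 0.25, seed 1, 8:2 train/validation split,
optional early stopping on validation loss and optional inverse-event-
frequency weighted sampling. All computation is NumPy via a compact
reverse-mode autodiff engine (`milsurv/_autograd.py`); its gradients are
pinned against central finite differences in the test suite.

**Patients with several slides** are handled by concatenating their bags into
one patient-level bag before pooling.

## Preprocessing

Tissue segmentation thresholds HSV saturation (default 8/255) after median
filtering (kernel 7), closes the binary mask (kernel 4) and removes connected
components under 512 px² — CLAM-like defaults. Tiling enumerates grid-aligned
256×256 patches (0-based, half-open footprints in level-0 pixels, row-major)
whose tissue fraction is at least 0.5 by default. Feature extraction is a
pluggable contract; tests and synthetic pipelines use a deterministic
byte-hashing extractor, and a truncated ResNet50 (through the third residual
stage, 1024 channels, global average pooling — the standard reading of a
1024-d "earlier convolution layer") is available as an optional adapter when
torch is installed. Bags are stored as HDF5 (`features` K×D float32, `coords`
K×2 int64, attributes `slide_id`, `patch_size`, `extractor_id`).

## Gene screening

Expression is z-scored per gene, then each gene gets a univariate Cox fit
(Newton–Raphson on the Breslow partial likelihood); genes with Wald
p < α are kept, with α = 0.0116 by default — an opaque published constant
retained as a configurable threshold. Zero-variance or non-converging genes
are marked unestimable and never selected. Survivors are ranked by
impurity-based random-forest importance for the binary event label (the only
label available before model training), ties broken by gene identifier;
`n_top` defaults to keeping every selected gene.

## Survival statistics

All evaluation statistics are implemented directly from their definitions so
brute-force oracles can pin them: Harrell's C (score ties count ½; a pair is
comparable when the shorter time carries an event); Kaplan–Meier; the
two-group log-rank test with hypergeometric variance; Cox fits with Wald
standard errors from the inverse observed information (convergence when
max |Δβ| < 1e-8 or 100 iterations, step-halving on likelihood decrease;
separation and non-convergence are reported, zero-variance covariates
rejected); the cumulative/dynamic time-dependent AUC (cases: event by the
horizon; controls: time beyond it; censored-before-horizon excluded —
inverse-probability-of-censoring weighting is deliberately not applied);
the maximally selected log-rank cutpoint over midpoints of adjacent unique
scores with a minimum group proportion (default 0.1), ties resolved to the
smaller cutoff; and decision-curve net benefit
TP/N − FP/N · p_t/(1−p_t) with treat-all/treat-none references. For
decision curves on survival data, risks map to event probabilities at a
horizon through the Breslow baseline, 1 − S₀(h)^exp(η−η̄).

## Synthetic data

The generator emulates the five pipeline inputs with known planted structure.
Survival times are exponential proportional hazards: the linear predictor
combines the per-bag signal-instance fraction (instances shifted by a fixed
unit direction in feature space), a sparse unit-norm aggregate of planted
prognostic genes over iid standard-normal expression, and standardized TNM
stage; censoring is independent exponential with its rate solved by bisection
to hit the target censored proportion. Clinical covariates mirror the
32-covariate fusion input: age, ordinal cT/cN/cTNM stages with mixed-stage
marginals, one-hot intrinsic subtype, and Beta(2,5) immune-cell scores.
Synthetic slides render non-overlapping saturated ellipses on a uniform
near-white background and return the exact rasterized mask, so segmentation
and tiling have analytic oracles.

What the generator does **not** emulate: histology texture, staining
variation, batch effects, correlated gene co-expression, informative
censoring, or multiple slides per patient. Passing tests therefore establish
the correctness of the algorithms and the learnability of planted
proportional-hazards signal at desk scale — not clinical performance on real
cohorts.

## Study conditions used by the tests and the acceptance script

The end-to-end recovery fixture uses n = 200 patients, bags of 16 instances
of dimension 32, signal fractions uniform on [0,1], effect sizes
(β_image, β_gene, β_clinical) = (5, 3, 2) — image-only oracle C ≈ 0.77, full
oracle C ≈ 0.92 — and 25% censoring. At this scale the published training
defaults (30 epochs at learning rate 1e-4) make too few gradient updates to
converge, so the fixture trains 300 epochs at 3e-3 with batch 64 and network
sizes 64/32/16; the package defaults are unchanged. Calibration studies use
20 replicates each: Cox CI coverage at n = 2000 (planted β = 0.6) and the
gene screen at n = 400 with 200 null genes plus one planted β = 1 gene.

## Known limitations

* The Cox engine targets small-to-moderate covariate counts (dense O(p²)
  information matrix); it is not a sparse high-dimensional solver.
* Attention-percentage heatmaps are rendered per patch footprint at a fixed
  downsample; no vector overlays or viewer integration.
* The time-dependent AUC estimator ignores censoring within the horizon
  beyond excluding those patients, which biases it when censoring is heavy
  and outcome-dependent.
* Real-WSI reading (pyramidal formats) and the ImageNet feature extractor are
  optional adapters, exercised only when their dependencies are installed.
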