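"""Synthetic cohorts and slides with known planted structure.

Every downstream stage — segmentation, tiling, feature bags, gene screening,
the attention network and the survival statistics — is testable against the
ground truth this module plants:

* survival times follow an exponential proportional-hazards model whose linear
  predictor combines an image signal (the fraction of bag instances shifted
  along a fixed unit "signal direction"), a gene signal (a sparse linear
  aggregate of planted prognostic genes) and a clinical signal (standardized
  TNM stage);
* right-censoring is independent exponential, with its rate solved by
  bisection so the realized censored proportion approximates the target;
* synthetic slides render saturated elliptical tissue blobs on a uniform
  near-white background together with the exact ground-truth mask.

Identical spec + seed reproduces cohorts and slides bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .wsi import PatchBag, save_bag

__all__ = [
    "SyntheticCohortSpec",
    "PatientRecord",
    "SyntheticCohort",
    "SyntheticSlide",
    "generate_cohort",
    "generate_tissue_image",
    "write_cohort",
    "write_slide",
    "CLINICAL_NAMES",
]

PAM50 = ["LumA", "LumB", "HER2", "Basal", "Normal"]
N_IMMUNE = 23  # fills the 32-covariate clinical vector: 4 + 5 + 23

CLINICAL_NAMES = (
    ["age", "ct_stage", "cn_stage", "ctnm_stage"]
    + [f"pam50_{s}" for s in PAM50]
    + [f"immune_{i:02d}" for i in range(1, N_IMMUNE + 1)]
)

# marginal stage frequencies loosely shaped like a mixed-stage breast cohort
_P_CT = [0.27, 0.58, 0.13, 0.02]      # cT 1..4
_P_CN = [0.51, 0.33, 0.10, 0.06]      # cN 0..3
_P_TNM = [0.19, 0.60, 0.21]           # cTNM I..III
_P_PAM50 = [0.45, 0.20, 0.10, 0.15, 0.10]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generation parameters for a planted proportional-hazards cohort."""

    n_patients: int = 200
    n_genes: int = 200
    n_prognostic_genes: int = 5
    feature_dim: int = 1024
    bag_size_range: tuple = (16, 64)
    signal_fraction: float = 0.5       # max per-bag proportion of signal instances
    beta_gene: float = 1.0
    beta_image: float = 1.0
    beta_clinical: float = 0.5
    baseline_scale: float = 60.0       # months
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.n_prognostic_genes > self.n_genes:
            raise ValueError("n_prognostic_genes cannot exceed n_genes")
        if not 0 <= self.signal_fraction <= 1:
            raise ValueError("signal_fraction must lie in [0, 1]")
        if self.bag_size_range[0] < 1 or self.bag_size_range[0] > self.bag_size_range[1]:
            raise ValueError("bag_size_range must satisfy 1 <= K_min <= K_max")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")


@dataclass
class PatientRecord:
    patient_id: str
    time: float                # observed follow-up, months
    event: int                 # 1 = event, 0 = censored
    gene_expression: np.ndarray
    clinical: np.ndarray       # aligned with CLINICAL_NAMES
    bags: list                 # list[PatchBag]


@dataclass
class SyntheticCohort:
    spec: SyntheticCohortSpec
    patients: list
    gene_ids: list
    truth: dict                # eta, gene_coefficients, signal_fraction, ...

    def survival_arrays(self):
        t = np.array([p.time for p in self.patients])
        e = np.array([p.event for p in self.patients])
        return t, e

    def expression_matrix(self) -> pd.DataFrame:
        """Genes x patients normalized expression table."""
        vals = np.stack([p.gene_expression for p in self.patients], axis=1)
        return pd.DataFrame(vals, index=self.gene_ids,
                            columns=[p.patient_id for p in self.patients])

    def clinical_frame(self) -> pd.DataFrame:
        vals = np.stack([p.clinical for p in self.patients])
        df = pd.DataFrame(vals, columns=CLINICAL_NAMES)
        df.insert(0, "patient_id", [p.patient_id for p in self.patients])
        return df

    def survival_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patient_id": [p.patient_id for p in self.patients],
            "time_months": [p.time for p in self.patients],
            "event": [p.event for p in self.patients],
        })

    def bags(self) -> list:
        return [p.bags[0] for p in self.patients]


@dataclass
class SyntheticSlide:
    image: np.ndarray          # H x W x 3 uint8
    tissue_mask: np.ndarray    # H x W bool, exact render footprint
    blob_params: list          # dicts: cx, cy, a, b, theta


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _censoring_rate_for(times: np.ndarray, target: float) -> float:
    """Bisection on the exponential censoring rate c so that the expected
    censored proportion E_i[1 - exp(-c T_i)] hits ``target``."""
    if target <= 0:
        return 0.0

    def frac(c):
        return np.mean(1.0 - np.exp(-c * times))

    lo, hi = 0.0, 1.0
    while frac(hi) < target:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Draw a cohort from the planted proportional-hazards model.

    The linear predictor is
    ``eta = beta_image * (bag signal fraction, centered)
          + beta_gene * (planted-gene aggregate)
          + beta_clinical * (standardized TNM stage)``
    and event times are exponential with scale ``baseline_scale * exp(-eta)``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    # --- genes: iid standard normal expression, sparse planted coefficients
    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    expr = rng.standard_normal((spec.n_genes, n))
    coef = np.zeros(spec.n_genes)
    planted = rng.choice(spec.n_genes, size=spec.n_prognostic_genes, replace=False)
    if spec.n_prognostic_genes > 0:
        coef[planted] = 1.0 / np.sqrt(spec.n_prognostic_genes)
    gene_score = coef @ expr  # ~ unit variance

    # --- clinical covariates (32 total: 4 ordinal/continuous + 5 PAM50 + 23 immune)
    age = np.clip(rng.normal(57, 10, size=n), 25, 90)
    ct = rng.choice([1, 2, 3, 4], size=n, p=_P_CT)
    cn = rng.choice([0, 1, 2, 3], size=n, p=_P_CN)
    tnm = rng.choice([1, 2, 3], size=n, p=_P_TNM)
    pam = rng.choice(len(PAM50), size=n, p=_P_PAM50)
    pam_onehot = np.eye(len(PAM50))[pam]
    immune = rng.beta(2, 5, size=(n, N_IMMUNE))
    clinical = np.column_stack([age, ct, cn, tnm, pam_onehot, immune])
    tnm_sd = tnm.std()
    clin_score = (tnm - tnm.mean()) / (tnm_sd if tnm_sd > 0 else 1.0)

    # --- image bags: noise instances, a subset shifted by a fixed unit direction
    direction = rng.standard_normal(spec.feature_dim)
    direction /= np.linalg.norm(direction)
    k_lo, k_hi = spec.bag_size_range
    bag_sizes = rng.integers(k_lo, k_hi + 1, size=n)
    sig_frac = rng.uniform(0.0, spec.signal_fraction, size=n)
    bags, signal_indices, realized_frac = [], [], np.zeros(n)
    for i in range(n):
        k = int(bag_sizes[i])
        feats = rng.standard_normal((k, spec.feature_dim)).astype(np.float32)
        n_sig = int(round(sig_frac[i] * k))
        idx = rng.choice(k, size=n_sig, replace=False) if n_sig else np.array([], int)
        feats[idx] += direction.astype(np.float32)
        realized_frac[i] = n_sig / k
        side = int(np.ceil(np.sqrt(k)))
        coords = np.array([(256 * (j % side), 256 * (j // side)) for j in range(k)],
                          dtype=np.int64)
        bags.append(PatchBag(slide_id=f"P{i:04d}-S0", features=feats,
                             coords=coords, extractor_id="synthetic"))
        signal_indices.append(np.sort(idx).tolist())

    # --- proportional-hazards outcome
    img_signal = realized_frac - realized_frac.mean()
    eta = (spec.beta_image * img_signal
           + spec.beta_gene * gene_score
           + spec.beta_clinical * clin_score)
    t_event = rng.exponential(scale=spec.baseline_scale * np.exp(-eta))
    t_event = np.maximum(t_event, 1e-3)
    c_rate = _censoring_rate_for(t_event, spec.censoring_rate)
    if c_rate > 0:
        t_cens = rng.exponential(scale=1.0 / c_rate, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, int)
    time = np.maximum(time, 1e-3)

    patients = [
        PatientRecord(
            patient_id=f"P{i:04d}",
            time=float(time[i]),
            event=int(event[i]),
            gene_expression=expr[:, i].copy(),
            clinical=clinical[i].copy(),
            bags=[bags[i]],
        )
        for i in range(n)
    ]
    truth = {
        "eta": eta,
        "gene_coefficients": coef,
        "planted_genes": [gene_ids[g] for g in sorted(planted)],
        "gene_score": gene_score,
        "signal_fraction": realized_frac,
        "signal_indices": signal_indices,
        "clinical_score": clin_score,
        "censoring_rate_realized": float(1 - event.mean()),
    }
    return SyntheticCohort(spec=spec, patients=patients, gene_ids=gene_ids, truth=truth)


# ---------------------------------------------------------------------------
# slide generation
# ---------------------------------------------------------------------------

_BACKGROUND = (242, 240, 239)
_TISSUE_PALETTE = [(186, 85, 150), (158, 60, 120), (200, 110, 160), (140, 70, 130)]


def generate_tissue_image(width: int, height: int, n_blobs: int, seed: int) -> SyntheticSlide:
    """Render ``n_blobs`` non-overlapping saturated ellipses on a uniform
    near-white background, returning the exact rasterized ground-truth mask."""
    if width < 64 or height < 64:
        raise ValueError("width and height must be >= 64")
    if n_blobs < 0:
        raise ValueError("n_blobs must be non-negative")
    rng = np.random.default_rng(seed)
    short = min(width, height)
    image = np.empty((height, width, 3), dtype=np.uint8)
    image[:] = _BACKGROUND
    mask = np.zeros((height, width), dtype=bool)
    yy, xx = np.mgrid[0:height, 0:width]
    blobs = []
    r_hi = short / 6.0
    r_lo = max(short / 12.0, 4.0)
    for b in range(n_blobs):
        placed = False
        a = rng.uniform(r_lo, r_hi)
        bb = rng.uniform(r_lo, r_hi)
        for attempt in range(400):
            theta = rng.uniform(0, np.pi)
            r = max(a, bb)
            if width - 2 * (r + 2) <= 0 or height - 2 * (r + 2) <= 0:
                a *= 0.8
                bb *= 0.8
                continue
            cx = rng.uniform(r + 2, width - r - 2)
            cy = rng.uniform(r + 2, height - r - 2)
            ok = all(
                np.hypot(cx - p["cx"], cy - p["cy"]) > r + max(p["a"], p["b"]) + 2
                for p in blobs
            )
            if ok:
                placed = True
                break
            if attempt % 50 == 49:  # crowded: shrink and retry
                a *= 0.8
                bb *= 0.8
        if not placed:
            continue
        dx, dy = xx - cx, yy - cy
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        inside = (u / a) ** 2 + (v / bb) ** 2 <= 1.0
        mask |= inside
        image[inside] = _TISSUE_PALETTE[b % len(_TISSUE_PALETTE)]
        blobs.append({"cx": cx, "cy": cy, "a": a, "b": bb, "theta": theta})
    return SyntheticSlide(image=image, tissue_mask=mask, blob_params=blobs)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Persist a cohort as patients.csv, expression.tsv, clinical.csv,
    bags/*.h5 and truth.json."""
    out = Path(outdir)
    (out / "bags").mkdir(parents=True, exist_ok=True)
    cohort.survival_frame().to_csv(out / "patients.csv", index=False)
    cohort.expression_matrix().to_csv(out / "expression.tsv", sep="\t")
    cohort.clinical_frame().to_csv(out / "clinical.csv", index=False)
    for p in cohort.patients:
        for bag in p.bags:
            save_bag(bag, out / "bags" / f"{bag.slide_id}.h5")
    truth = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in cohort.truth.items()
    }
    truth["spec"] = asdict(cohort.spec)
    (out / "truth.json").write_text(json.dumps(truth, indent=1))


def write_slide(slide: SyntheticSlide, image_path, mask_path=None) -> None:
    from PIL import Image

    Image.fromarray(slide.image).save(image_path)
    if mask_path is not None:
        Image.fromarray((slide.tissue_mask * 255).astype(np.uint8)).save(mask_path)
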