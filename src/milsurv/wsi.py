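"""Whole-slide-image preprocessing: tissue segmentation, grid tiling and
patch-feature bag assembly.

The pipeline mirrors the standard MIL preparation for histopathology: detect
tissue by HSV-saturation thresholding (median-filtered, morphologically
closed, small components removed), tile the tissue into non-overlapping
256x256 patches at the working magnification, and run each patch through a
feature extractor to build the slide's instance bag H = {h_1, ..., h_K}.

Feature extraction is a pluggable contract (`FeatureExtractor`): anything with
a ``dim``, an ``extractor_id`` and a call mapping one RGB patch to a fixed-
length vector.  Tests and synthetic pipelines use the deterministic
:class:`HashingFeatureExtractor`; a truncated ResNet50 (1024-d, third residual
stage + global average pooling) is available as an optional adapter when torch
is installed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Protocol, runtime_checkable

import h5py
import numpy as np
from skimage import filters, measure, morphology
from skimage.color import rgb2hsv

__all__ = [
    "TissueMask",
    "PatchGrid",
    "PatchBag",
    "FeatureExtractor",
    "HashingFeatureExtractor",
    "segment_tissue",
    "tile_grid",
    "extract_features",
    "save_bag",
    "load_bag",
    "resnet50_extractor",
]

DEFAULT_PATCH_SIZE = 256
DEFAULT_FEATURE_DIM = 1024


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TissueMask:
    """Binary tissue raster at ``downsample_factor`` relative to level 0."""

    mask: np.ndarray                # bool, H x W at the working downsample
    downsample_factor: float = 1.0
    contours: list = field(default_factory=list)  # closed (N,2) xy polygons


@dataclass
class PatchGrid:
    """Grid-aligned patch corners in level-0 pixels, half-open footprints."""

    patch_size: int
    coords: np.ndarray              # (K, 2) int64 top-left (x, y)
    tissue_fraction: np.ndarray     # (K,) in [0, 1]

    def __len__(self):
        return len(self.coords)


@dataclass
class PatchBag:
    """One slide's instance features plus aligned patch coordinates."""

    slide_id: str
    features: np.ndarray            # (K, D) float32
    coords: np.ndarray              # (K, 2) int64
    extractor_id: str = ""
    patch_size: int = DEFAULT_PATCH_SIZE

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float32)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if self.features.ndim != 2 or len(self.features) < 1:
            raise ValueError("bag must contain at least one K x D feature row")
        if self.coords.shape != (len(self.features), 2):
            raise ValueError("coords must align with feature rows")

    @property
    def n_instances(self) -> int:
        return len(self.features)

    @property
    def dim(self) -> int:
        return self.features.shape[1]


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_tissue(
    image: np.ndarray,
    saturation_threshold: float = 8 / 255,
    median_kernel: int = 7,
    close_kernel: int = 4,
    min_area: int = 512,
    downsample_factor: float = 1.0,
) -> TissueMask:
    """Segment tissue from background on an RGB raster.

    Foreground = pixels whose HSV saturation, after median filtering, exceeds
    ``saturation_threshold``; the binary mask is morphologically closed and
    connected components smaller than ``min_area`` pixels are dropped.
    A fully-background image yields an empty mask (not an error).
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    sat = rgb2hsv(image)[..., 1]
    if median_kernel and median_kernel > 1:
        sat = filters.median(sat, footprint=np.ones((median_kernel, median_kernel)))
    mask = sat > saturation_threshold
    if close_kernel and close_kernel > 1:
        mask = morphology.closing(mask, footprint=np.ones((close_kernel, close_kernel)))
    if min_area and min_area > 0:
        labels = measure.label(mask, connectivity=2)
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_area)
        mask = mask & ~np.isin(labels, small[small > 0])
    contours = [c[:, ::-1] for c in measure.find_contours(mask.astype(float), 0.5)]
    return TissueMask(mask=mask, downsample_factor=downsample_factor, contours=contours)


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def tile_grid(
    mask: TissueMask,
    patch_size: int = DEFAULT_PATCH_SIZE,
    min_tissue_fraction: float = 0.5,
) -> PatchGrid:
    """Enumerate grid-aligned patches whose tissue fraction clears the bar.

    Coordinates are 0-based top-left corners in level-0 pixels, emitted in
    row-major order (x fastest within each row of patches).  The tissue
    fraction of a patch is the mean of the mask over the patch footprint at
    the mask's resolution.
    """
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    if not 0 <= min_tissue_fraction <= 1:
        raise ValueError("min_tissue_fraction must lie in [0, 1]")
    m = np.asarray(mask.mask, dtype=bool)
    ds = float(mask.downsample_factor)
    h0, w0 = int(round(m.shape[0] * ds)), int(round(m.shape[1] * ds))
    step = patch_size
    coords, fracs = [], []
    # integral image for O(1) footprint sums
    integral = np.zeros((m.shape[0] + 1, m.shape[1] + 1), dtype=np.int64)
    integral[1:, 1:] = np.cumsum(np.cumsum(m, axis=0), axis=1)
    for y in range(0, h0 - patch_size + 1, step):
        my0 = int(round(y / ds))
        my1 = int(round((y + patch_size) / ds))
        for x in range(0, w0 - patch_size + 1, step):
            mx0 = int(round(x / ds))
            mx1 = int(round((x + patch_size) / ds))
            area = (my1 - my0) * (mx1 - mx0)
            if area <= 0:
                continue
            s = (integral[my1, mx1] - integral[my0, mx1]
                 - integral[my1, mx0] + integral[my0, mx0])
            frac = s / area
            if frac >= min_tissue_fraction:
                coords.append((x, y))
                fracs.append(frac)
    return PatchGrid(
        patch_size=patch_size,
        coords=np.asarray(coords, dtype=np.int64).reshape(-1, 2),
        tissue_fraction=np.asarray(fracs, dtype=float),
    )


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

@runtime_checkable
class FeatureExtractor(Protocol):
    """Maps one patch (P x P x 3 uint8) to a fixed-length feature vector."""

    dim: int
    extractor_id: str

    def __call__(self, patch: np.ndarray) -> np.ndarray: ...


class HashingFeatureExtractor:
    """Deterministic stand-in extractor: hashes patch bytes into a seeded
    pseudo-random Gaussian vector.

    Identical patches always map to identical vectors, which makes bag
    assembly reproducible and lets tests recompute rows independently.  The
    default dimensionality matches the 1024-d contract of the truncated
    ResNet50 extractor it stands in for.
    """

    def __init__(self, dim: int = DEFAULT_FEATURE_DIM, seed: int = 0):
        self.dim = int(dim)
        self.seed = int(seed)
        self.extractor_id = f"hash-v1-d{self.dim}-s{self.seed}"

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        patch = np.ascontiguousarray(patch)
        h = hashlib.blake2b(patch.tobytes(), digest_size=8,
                            key=self.seed.to_bytes(8, "little"))
        rng = np.random.default_rng(int.from_bytes(h.digest(), "little"))
        return rng.standard_normal(self.dim).astype(np.float32)


def extract_features(
    source,
    grid: PatchGrid,
    extractor: FeatureExtractor,
    slide_id: str = "slide",
) -> PatchBag:
    """Assemble a slide's feature bag by running ``extractor`` over the grid.

    ``source`` is either a full-resolution H x W x 3 array (patches are
    cropped from it) or a callable ``(x, y, size) -> patch``.
    """
    if len(grid) == 0:
        raise ValueError("grid is empty; nothing to extract")
    if callable(source) and not isinstance(source, np.ndarray):
        read = source
    else:
        img = np.asarray(source)

        def read(x, y, size):
            return img[y:y + size, x:x + size]

    rows = []
    for x, y in grid.coords:
        vec = np.asarray(extractor(read(int(x), int(y), grid.patch_size)))
        if vec.ndim != 1:
            raise ValueError("extractor must return a 1-D vector")
        if rows and vec.shape[0] != rows[0].shape[0]:
            raise ValueError("extractor output length inconsistent across patches")
        rows.append(vec)
    return PatchBag(
        slide_id=slide_id,
        features=np.stack(rows).astype(np.float32),
        coords=grid.coords.copy(),
        extractor_id=getattr(extractor, "extractor_id", ""),
        patch_size=grid.patch_size,
    )


# ---------------------------------------------------------------------------
# HDF5 bag I/O
# ---------------------------------------------------------------------------

def save_bag(bag: PatchBag, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=bag.features.astype(np.float32))
        f.create_dataset("coords", data=bag.coords.astype(np.int64))
        f.attrs["slide_id"] = bag.slide_id
        f.attrs["patch_size"] = bag.patch_size
        f.attrs["extractor_id"] = bag.extractor_id


def load_bag(path) -> PatchBag:
    with h5py.File(path, "r") as f:
        return PatchBag(
            slide_id=str(f.attrs.get("slide_id", "")),
            features=f["features"][()],
            coords=f["coords"][()],
            extractor_id=str(f.attrs.get("extractor_id", "")),
            patch_size=int(f.attrs.get("patch_size", DEFAULT_PATCH_SIZE)),
        )


# ---------------------------------------------------------------------------
# optional real extractor (requires torch/torchvision; untested adapter)
# ---------------------------------------------------------------------------

def resnet50_extractor(device: str = "cpu"):
    """ResNet50 truncated after the third residual stage (1024 channels) with
    global average pooling, using ImageNet weights.  Optional adapter:
    requires torch + torchvision at call time."""
    try:
        import torch
        import torchvision
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "the ResNet50 extractor requires torch and torchvision; "
            "install them or use HashingFeatureExtractor"
        ) from exc

    net = torchvision.models.resnet50(weights="IMAGENET1K_V1")
    trunk = torch.nn.Sequential(
        net.conv1, net.bn1, net.relu, net.maxpool,
        net.layer1, net.layer2, net.layer3,
        torch.nn.AdaptiveAvgPool2d(1),
    ).to(device).eval()
    mean = torch.tensor([0.485, 0.456, 0.406]).view(1, 3, 1, 1)
    std = torch.tensor([0.229, 0.224, 0.225]).view(1, 3, 1, 1)

    class _ResNetExtractor:  # pragma: no cover - optional dependency
        dim = 1024
        extractor_id = "resnet50-stage3-gap-imagenet"

        def __call__(self, patch):
            x = torch.from_numpy(np.asarray(patch)).float().permute(2, 0, 1)[None] / 255.0
            x = (x - mean) / std
            with torch.no_grad():
                out = trunk(x.to(device))
            return out.squeeze().cpu().numpy().astype(np.float32)

    return _ResNetExtractor()
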