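"""Attention-map interpretation: percentage conversion and heatmap rendering.

Raw attention values for a slide's K patches are converted to percentages by
softmax (so they sum to 100), then painted over the patch footprints with a
cool-to-warm colormap — warm for high influence, cool for low — on a thumbnail
of the slide.  Rendering is deterministic and monotone in percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

__all__ = ["AttentionMap", "attention_percentages", "render_heatmap"]

_BACKGROUND_GRAY = 230


@dataclass
class AttentionMap:
    """Per-patch attention percentages (sum to 100) aligned with coords."""

    coords: np.ndarray       # (K, 2) top-left patch corners, level-0 pixels
    percentages: np.ndarray  # (K,) nonnegative, sums to 100
    head_id: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        self.percentages = np.asarray(self.percentages, dtype=float).reshape(-1)
        if len(self.coords) != len(self.percentages):
            raise ValueError("coords and percentages must align")


def attention_percentages(values, coords=None, head_id: int = 0) -> AttentionMap:
    """Softmax the K raw attention values (weights or logits) and scale to
    percentages summing to 100."""
    v = np.asarray(values, float).reshape(-1)
    if v.size == 0:
        raise ValueError("attention input is empty")
    s = np.exp(v - v.max())
    pct = 100.0 * s / s.sum()
    if coords is None:
        coords = np.zeros((v.size, 2), dtype=np.int64)
    return AttentionMap(coords=coords, percentages=pct, head_id=head_id)


def render_heatmap(
    amap: AttentionMap,
    slide_dims,
    patch_size: int,
    downsample: int = 16,
    colormap: str = "coolwarm",
    image: np.ndarray | None = None,
    alpha: float = 0.5,
) -> np.ndarray:
    """Paint patch footprints with the colormap at the per-slide min-max
    normalized percentage; un-tiled background stays neutral gray.

    ``slide_dims`` is (width, height) in level-0 pixels; the output raster is
    ``(height // downsample, width // downsample, 3)`` uint8.  When ``image``
    is given it is blended under the heatmap with weight ``1 - alpha``.
    """
    w0, h0 = int(slide_dims[0]), int(slide_dims[1])
    coords = amap.coords
    bad = [(int(c[0]), int(c[1])) for c in coords
           if c[0] < 0 or c[1] < 0 or c[0] + patch_size > w0 or c[1] + patch_size > h0]
    if bad:
        raise ValueError(f"patch coords outside slide bounds: {bad}")
    hw, ww = h0 // downsample, w0 // downsample
    out = np.full((hw, ww, 3), _BACKGROUND_GRAY, dtype=np.uint8)

    pct = amap.percentages
    lo, hi = pct.min(), pct.max()
    norm = np.full_like(pct, 0.5) if hi == lo else (pct - lo) / (hi - lo)
    cmap = colormaps[colormap]
    colors = (np.asarray(cmap(norm))[:, :3] * 255).astype(np.uint8)

    base = None
    if image is not None:
        from PIL import Image

        base = np.asarray(
            Image.fromarray(np.asarray(image)).resize((ww, hw), Image.BILINEAR)
        )
        out = base.copy()

    for (x, y), color in zip(coords, colors):
        x0, y0 = x // downsample, y // downsample
        x1 = min((x + patch_size) // downsample, ww)
        y1 = min((y + patch_size) // downsample, hw)
        if base is None:
            out[y0:y1, x0:x1] = color
        else:
            blend = (alpha * color + (1 - alpha) * base[y0:y1, x0:x1]).astype(np.uint8)
            out[y0:y1, x0:x1] = blend
    return out
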