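"""Fused leaf construction: RGB appearance with the vein map in the red plane.

The fused image keeps the source's green and blue channels untouched and
replaces the red channel with the binary vein map scaled to full intensity,
so the venation is carried losslessly (thresholding the red plane recovers
the mask exactly) while appearance cues stay in the remaining channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import as_binary, ensure_rgb, value_range

__all__ = ["FusedLeaf", "crop_to_leaf_bbox", "compose_fused"]


@dataclass(frozen=True)
class FusedLeaf:
    pixels: np.ndarray
    provenance: tuple = ("", "")


def crop_to_leaf_bbox(img: np.ndarray, leaf: np.ndarray) -> np.ndarray:
    """Crop to the tight axis-aligned bounding box of the leaf mask.

    The same box applies identically to any image co-registered with the
    mask (RGB, vein map, truth masks).
    """
    m = as_binary(leaf)
    if m.sum() == 0:
        raise ValueError("cannot crop to an empty leaf mask")
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    return img[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]


def _resize_mask_nearest(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resample keeping the mask strictly two-valued."""
    h, w = mask.shape
    H, W = shape
    rows = np.minimum((np.arange(H) + 0.5) * h / H, h - 1).astype(int)
    cols = np.minimum((np.arange(W) + 0.5) * w / W, w - 1).astype(int)
    out = mask[rows][:, cols]
    return (out > 0.5).astype(np.uint8)


def compose_fused(rgb: np.ndarray, vein: np.ndarray,
                  provenance: tuple = ("", "")) -> FusedLeaf:
    """Replace the red channel with the vein map at full intensity."""
    ensure_rgb(rgb)
    v = as_binary(vein)
    if v.shape != rgb.shape[:2]:
        v = _resize_mask_nearest(v, rgb.shape[:2])
    out = rgb.copy()
    out[..., 0] = (v * value_range(rgb)).astype(out.dtype)
    return FusedLeaf(pixels=out, provenance=provenance)
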