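"""Raster-image conventions shared across the package.

Images are plain numpy arrays with a dtype-encoded range tag:

* ``uint8`` arrays live in ``[0, 255]``,
* floating arrays live in ``[0, 1]``.

All pipelines compute in float and convert at I/O boundaries. Binary masks
are 2-D arrays whose values are exactly ``{0, 1}`` (any integer or bool
dtype); they are written to disk as 8-bit PNGs with values ``{0, 255}``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "value_range",
    "to_float",
    "to_uint8",
    "as_binary",
    "is_binary",
    "ensure_gray",
    "ensure_rgb",
]


def value_range(img: np.ndarray) -> float:
    """Maximum representable intensity for the image's range tag."""
    return 255.0 if img.dtype == np.uint8 else 1.0


def to_float(img: np.ndarray) -> np.ndarray:
    """Convert to float64 in [0, 1], respecting the range tag."""
    if img.dtype == np.uint8:
        return img.astype(np.float64) / 255.0
    out = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(out)):
        raise ValueError("image contains non-finite values")
    return out


def to_uint8(img: np.ndarray) -> np.ndarray:
    """Convert to uint8 in [0, 255], respecting the range tag."""
    if img.dtype == np.uint8:
        return img
    return np.clip(np.rint(np.asarray(img, dtype=np.float64) * 255.0), 0, 255).astype(np.uint8)


def is_binary(mask: np.ndarray) -> bool:
    vals = np.unique(mask)
    return vals.size <= 2 and np.all(np.isin(vals, (0, 1)))


def as_binary(mask: np.ndarray) -> np.ndarray:
    """Validate and return a {0,1} uint8 mask."""
    m = np.asarray(mask)
    if m.dtype == bool:
        return m.astype(np.uint8)
    if not is_binary(m):
        raise ValueError("mask is not strictly two-valued in {0, 1}")
    return m.astype(np.uint8)


def ensure_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim != 2:
        raise ValueError(f"expected a single-channel image, got shape {img.shape}")
    return img


def ensure_rgb(img: np.ndarray) -> np.ndarray:
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected a 3-channel image, got shape {img.shape}")
    return img
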