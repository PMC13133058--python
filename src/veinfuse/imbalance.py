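"""Class-frequency-aware augmentation tiers and balanced class weighting.

Classes whose sample count falls below a threshold (800 by default) are
treated as minority classes and receive the strong augmentation tier
(higher rotation limits, elastic distortion, additive Gaussian noise);
majority classes receive light geometric augmentation only, preserving
their original data characteristics. Class weights follow the balanced
inverse-frequency scheme ``w_c = N / (K * N_c)``, whose sample-weighted
mean is exactly 1.

Augmentation is applied online during training rather than by inflating
the dataset, so split counts stay fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .images import to_float, to_uint8

__all__ = [
    "MEDICINAL_LEAF_COUNTS",
    "MINORITY_THRESHOLD",
    "ClassFrequencyTable",
    "AugmentationPolicy",
    "LIGHT_POLICY",
    "STRONG_POLICY",
    "minority_classes",
    "policy_for_class",
    "class_weights",
    "augment",
    "augment_pair",
]

# Per-class image counts of the seven-species medicinal-leaf corpus the
# method was designed around; used as the reference imbalance profile.
MEDICINAL_LEAF_COUNTS: dict[str, int] = {
    "Guava": 450,
    "Arjun": 347,
    "Indian pennywort": 1044,
    "Malabar": 889,
    "Neem": 1412,
    "Mint": 1164,
    "Tulsi": 1866,
}

MINORITY_THRESHOLD = 800


@dataclass(frozen=True)
class ClassFrequencyTable:
    counts: dict
    minority_threshold: int = MINORITY_THRESHOLD

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("class counts must be non-negative")


@dataclass(frozen=True)
class AugmentationPolicy:
    """Stochastic transform magnitudes for one augmentation tier."""

    tier: str  # strong | light
    rotation_limit_deg: float = 15.0
    flip: bool = True
    shift_fraction: float = 0.05
    elastic: bool = False
    elastic_alpha: float = 40.0
    elastic_sigma: float = 6.0
    gaussian_noise_var_range: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.tier not in ("strong", "light"):
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.tier == "light" and (self.elastic or max(self.gaussian_noise_var_range) > 0):
            raise ValueError("elastic distortion and noise are reserved for the strong tier")


LIGHT_POLICY = AugmentationPolicy(tier="light", rotation_limit_deg=15.0,
                                  flip=True, shift_fraction=0.05)
STRONG_POLICY = AugmentationPolicy(tier="strong", rotation_limit_deg=40.0,
                                   flip=True, shift_fraction=0.10, elastic=True,
                                   elastic_alpha=40.0, elastic_sigma=6.0,
                                   gaussian_noise_var_range=(0.005, 0.02))


def minority_classes(table: ClassFrequencyTable) -> set:
    """Classes with strictly fewer samples than the minority threshold."""
    if not table.counts:
        raise ValueError("class frequency table is empty")
    return {c for c, n in table.counts.items() if n < table.minority_threshold}


def policy_for_class(cls: str, table: ClassFrequencyTable,
                     light: AugmentationPolicy = LIGHT_POLICY,
                     strong: AugmentationPolicy = STRONG_POLICY) -> AugmentationPolicy:
    if cls not in table.counts:
        raise KeyError(f"unknown class {cls!r}")
    return strong if cls in minority_classes(table) else light


def class_weights(table: ClassFrequencyTable) -> dict:
    """Balanced inverse-frequency weights ``w_c = N_total / (K * N_c)``."""
    if any(n == 0 for n in table.counts.values()):
        raise ValueError("class weights undefined for zero-count classes")
    total = sum(table.counts.values())
    k = len(table.counts)
    return {c: total / (k * n) for c, n in table.counts.items()}


# ---------------------------------------------------------------------------
# online augmentation
# ---------------------------------------------------------------------------

def _draw_params(policy: AugmentationPolicy, rng: np.random.Generator,
                 shape: tuple[int, int]) -> dict:
    h, w = shape
    params = {
        "angle": float(rng.uniform(-policy.rotation_limit_deg, policy.rotation_limit_deg))
        if policy.rotation_limit_deg > 0 else 0.0,
        "hflip": bool(policy.flip and rng.random() < 0.5),
        "vflip": bool(policy.flip and policy.tier == "strong" and rng.random() < 0.5),
        "shift": (float(rng.uniform(-policy.shift_fraction, policy.shift_fraction) * h),
                  float(rng.uniform(-policy.shift_fraction, policy.shift_fraction) * w))
        if policy.shift_fraction > 0 else (0.0, 0.0),
        "disp": None,
        "noise_var": 0.0,
    }
    if policy.elastic:
        dy = ndi.gaussian_filter(rng.uniform(-1, 1, size=shape), policy.elastic_sigma,
                                 mode="reflect") * policy.elastic_alpha
        dx = ndi.gaussian_filter(rng.uniform(-1, 1, size=shape), policy.elastic_sigma,
                                 mode="reflect") * policy.elastic_alpha
        params["disp"] = (dy, dx)
    lo, hi = policy.gaussian_noise_var_range
    if hi > 0:
        params["noise_var"] = float(rng.uniform(lo, hi))
    return params


def _apply_geometric(arr: np.ndarray, params: dict, order: int) -> np.ndarray:
    out = arr
    if params["hflip"]:
        out = out[:, ::-1]
    if params["vflip"]:
        out = out[::-1, :]
    angle, (sy, sx) = params["angle"], params["shift"]
    if angle != 0.0 or sy != 0.0 or sx != 0.0:
        h, w = out.shape[:2]
        th = np.deg2rad(angle)
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        # inverse map: rotate about the center, then shift
        y0, x0 = yy - cy - sy, xx - cx - sx
        src_y = np.cos(th) * y0 - np.sin(th) * x0 + cy
        src_x = np.sin(th) * y0 + np.cos(th) * x0 + cx
        coords = np.stack([src_y, src_x])
        if out.ndim == 3:
            # white fill matches the uniform-white background convention
            out = np.stack([ndi.map_coordinates(out[..., c], coords, order=order,
                                                mode="constant", cval=1.0)
                            for c in range(out.shape[2])], axis=2)
        else:
            out = ndi.map_coordinates(out, coords, order=order, mode="constant", cval=0.0)
    if params["disp"] is not None:
        dy, dx = params["disp"]
        h, w = out.shape[:2]
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        coords = np.stack([yy + dy, xx + dx])
        if out.ndim == 3:
            out = np.stack([ndi.map_coordinates(out[..., c], coords, order=order,
                                                mode="reflect")
                            for c in range(out.shape[2])], axis=2)
        else:
            out = ndi.map_coordinates(out, coords, order=order, mode="reflect")
    return out


def augment(img: np.ndarray, policy: AugmentationPolicy, rng_seed: int) -> np.ndarray:
    """Apply the tier's stochastic transforms; deterministic under the seed.

    Dimensions and range tag are preserved; with all magnitudes zero the
    image is returned unchanged.
    """
    rng = np.random.default_rng(rng_seed)
    params = _draw_params(policy, rng, img.shape[:2])
    arr = to_float(img)
    out = _apply_geometric(arr, params, order=1)
    if params["noise_var"] > 0:
        out = out + rng.normal(0.0, np.sqrt(params["noise_var"]), size=out.shape)
    out = np.clip(out, 0.0, 1.0)
    return to_uint8(out) if img.dtype == np.uint8 else out


def augment_pair(rgb: np.ndarray, mask: np.ndarray, policy: AugmentationPolicy,
                 rng_seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Augment an RGB image and its vein mask with synchronized geometry.

    The mask receives the geometric transforms only (nearest-neighbor
    resampling, re-binarized); photometric noise applies to the RGB image
    alone.
    """
    rng = np.random.default_rng(rng_seed)
    params = _draw_params(policy, rng, rgb.shape[:2])
    arr = to_float(rgb)
    out = _apply_geometric(arr, params, order=1)
    if params["noise_var"] > 0:
        out = out + rng.normal(0.0, np.sqrt(params["noise_var"]), size=out.shape)
    out = np.clip(out, 0.0, 1.0)
    m = _apply_geometric(np.asarray(mask, np.float64), params, order=0)
    m = (m > 0.5).astype(np.uint8)
    return (to_uint8(out) if rgb.dtype == np.uint8 else out), m
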