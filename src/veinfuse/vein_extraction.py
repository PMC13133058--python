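"""Classical vein-binarization pipeline.

Converts an RGB leaf photograph on a clean background into a binary vein
map through eight stages: leaf segmentation (Otsu + largest contour +
morphological closing), contrast-limited adaptive histogram equalization,
homomorphic illumination correction, an oriented Gabor filter bank with
pixel-wise maximum response, weighted fusion of the frequency- and
texture-enhanced images, interior-restricted unsharp sharpening, local
mean adaptive thresholding with percentile contrast stretching, and a
final cleanup pass (small-object removal, morphological opening, median
smoothing).

Veins are treated as the locally *bright* structures of the enhanced
image: the Gabor maximum response renders line-like structures bright
regardless of their raw polarity, so the adaptive threshold marks pixels
above the local mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .images import (
    as_binary,
    ensure_gray,
    ensure_rgb,
    to_float,
    value_range,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StructuringElement",
    "VeinPipelineConfig",
    "VeinPipelineError",
    "to_grayscale",
    "otsu_threshold",
    "leaf_mask",
    "clahe",
    "homomorphic_filter",
    "gabor_kernel",
    "gabor_max_response",
    "weighted_fuse",
    "unsharp_sharpen",
    "adaptive_binarize",
    "clean_mask",
    "extract_veins",
    "band_precision_recall",
]


class VeinPipelineError(RuntimeError):
    """Raised when a pipeline stage cannot produce a valid result."""


@dataclass(frozen=True)
class StructuringElement:
    """Morphological structuring element (symbol B of the opening/closing ops)."""

    shape: str = "ellipse"  # ellipse | disk | square
    size: int = 3  # odd side / diameter in pixels

    def __post_init__(self) -> None:
        if self.shape not in ("ellipse", "disk", "square"):
            raise ValueError(f"unknown structuring element shape {self.shape!r}")
        if self.size < 1 or self.size % 2 == 0:
            raise ValueError("structuring element size must be odd and >= 1")

    def footprint(self) -> np.ndarray:
        r = self.size // 2
        if self.shape == "square":
            return np.ones((self.size, self.size), dtype=bool)
        if self.shape == "disk":
            return morphology.disk(r).astype(bool)
        return morphology.ellipse(r, r).astype(bool) if r > 0 else np.ones((1, 1), bool)


@dataclass(frozen=True)
class VeinPipelineConfig:
    """Every free parameter of the binarization flow.

    Intensity-valued parameters (``adapt_C``) are expressed on the 0-255
    scale regardless of the image's range tag. Defaults are conventional
    values for ~224 px leaf images and are part of the config surface,
    not calibrated truth.
    """

    # CLAHE
    clahe_tiles: int = 8
    clahe_clip: float = 2.0  # multiples of the mean histogram bin height
    # homomorphic filter H(u,v) = B + A(1 - exp(-k D^2 / D0^2))
    homo_A: float = 1.5
    homo_B: float = 0.5
    homo_k: float = 1.0
    homo_D0: float = 30.0
    # Gabor bank
    gabor_orientations_deg: tuple = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)
    gabor_scales: tuple = (15, 21)
    gabor_lambda: float = 8.0
    gabor_sigma: float = 4.0
    gabor_gamma_aspect: float = 0.5
    gabor_psi: float = 0.0
    # weighted fusion of homomorphic + Gabor images
    fuse_w1: float = 0.5
    fuse_w2: float = 0.5
    fuse_bias: float = 0.0
    # unsharp masking
    unsharp_alpha: float = 1.0
    unsharp_sigma: float = 2.0
    # adaptive threshold: mark pixels exceeding the local mean by adapt_C
    adapt_window: int = 25
    adapt_C: float = 5.0
    stretch_percentiles: tuple = (2.0, 98.0)
    # cleanup; the default opening element is the identity because at this
    # working resolution (~3 px veins) any nontrivial opening erases the
    # detected centerlines — enlarge it for thicker-vein imagery
    min_object_area: int = 30
    opening_se: StructuringElement = field(default_factory=lambda: StructuringElement("ellipse", 1))
    median_kernel: int = 3
    closing_se: StructuringElement = field(default_factory=lambda: StructuringElement("ellipse", 7))

    def __post_init__(self) -> None:
        if abs(self.fuse_w1 + self.fuse_w2 - 1.0) > 1e-9:
            raise ValueError("fusion weights must sum to 1")
        if self.adapt_window % 2 == 0 or self.median_kernel % 2 == 0:
            raise ValueError("windows and kernels must be odd")
        lo, hi = self.stretch_percentiles
        if not lo < hi:
            raise ValueError("stretch percentiles must satisfy p_low < p_high")

    def with_overrides(self, **kwargs) -> "VeinPipelineConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# individual stages
# ---------------------------------------------------------------------------

def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """BT.601 luminance 0.299 R + 0.587 G + 0.114 B; preserves the range tag."""
    ensure_rgb(rgb)
    w = np.array([0.299, 0.587, 0.114])
    gray = np.tensordot(np.asarray(rgb, dtype=np.float64), w, axes=([2], [0]))
    if rgb.dtype == np.uint8:
        return np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    return gray


def _levels256(gray: np.ndarray) -> np.ndarray:
    """Quantize intensities to the 0..255 histogram levels."""
    if gray.dtype == np.uint8:
        return gray.astype(np.int64)
    return np.clip(np.rint(np.asarray(gray, np.float64) * 255.0), 0, 255).astype(np.int64)


def otsu_threshold(gray: np.ndarray) -> tuple[float, np.ndarray]:
    """Global threshold maximizing between-class variance on the 256-bin histogram.

    Returns ``(threshold, mask)`` with ``mask = gray > threshold`` in the
    image's native intensity units. A constant image yields that constant
    as threshold and an all-zero mask.
    """
    ensure_gray(gray)
    levels = _levels256(gray)
    hist = np.bincount(levels.ravel(), minlength=256).astype(np.float64)
    n = hist.sum()
    if np.count_nonzero(hist) <= 1:
        logger.warning("otsu_threshold: constant image, returning degenerate threshold")
        const = float(np.asarray(gray).flat[0])
        return const, np.zeros(gray.shape, dtype=np.uint8)
    # cumulative moments; class 0 = levels <= t, class 1 = levels > t
    w0 = np.cumsum(hist)
    m0 = np.cumsum(hist * np.arange(256))
    w1 = n - w0
    mu0 = np.where(w0 > 0, m0 / np.maximum(w0, 1e-300), 0.0)
    mu1 = np.where(w1 > 0, (m0[-1] - m0) / np.maximum(w1, 1e-300), 0.0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[w1 == 0] = -1.0
    # the variance is flat across empty histogram gaps; take the midpoint
    # of the maximizing set so the threshold centers between the modes
    maximizers = np.flatnonzero(sigma_b == sigma_b.max())
    t_level = int(round(maximizers.mean()))
    threshold = float(t_level) if gray.dtype == np.uint8 else t_level / 255.0
    mask = (np.asarray(gray, np.float64) > threshold).astype(np.uint8)
    return threshold, mask


def _border_occupancy(mask: np.ndarray) -> float:
    border = np.concatenate([mask[0], mask[-1], mask[:, 0], mask[:, -1]])
    return float(border.mean())


def leaf_mask(rgb: np.ndarray, closing_se: StructuringElement | None = None) -> np.ndarray:
    """Segment the leaf silhouette.

    Otsu-binarizes the grayscale image, picks the threshold side with the
    smaller border occupancy as foreground (the leaf is central while the
    background touches the frame), keeps the largest connected component,
    applies morphological closing with an elliptical element and fills
    enclosed holes.
    """
    ensure_rgb(rgb)
    closing_se = closing_se or StructuringElement("ellipse", 7)
    gray = to_grayscale(rgb)
    _, hi = otsu_threshold(gray)
    lo = 1 - hi
    fg = hi if _border_occupancy(hi) <= _border_occupancy(lo) else lo
    if fg.sum() == 0:
        raise VeinPipelineError("empty foreground after Otsu segmentation")
    labels, nlab = ndi.label(fg)
    if nlab > 1:
        sizes = ndi.sum_labels(np.ones_like(fg), labels, index=np.arange(1, nlab + 1))
        fg = (labels == (1 + int(np.argmax(sizes)))).astype(np.uint8)
    closed = ndi.binary_closing(fg.astype(bool), structure=closing_se.footprint())
    filled = ndi.binary_fill_holes(closed)
    return filled.astype(np.uint8)


def clahe(gray: np.ndarray, tiles: int = 8, clip: float = 2.0) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The image is divided into a ``tiles x tiles`` grid; each tile's 256-bin
    histogram is clipped at ``clip`` times the mean bin height, with the
    clipped excess redistributed uniformly, then equalized; per-pixel output
    bilinearly interpolates the mappings of the four nearest tile centers.
    A constant image is returned unchanged. Output preserves the range tag.
    """
    ensure_gray(gray)
    if clip <= 0:
        raise ValueError("clip limit must be > 0")
    rng_max = value_range(gray)
    arr = to_float(gray)
    if arr.max() - arr.min() == 0.0:
        return gray.copy()
    H, W = arr.shape
    ty = tx = int(tiles)
    if ty > H or tx > W:
        ty, tx = max(1, min(ty, H)), max(1, min(tx, W))
        logger.warning("clahe: tile grid reduced to %dx%d for a %dx%d image", ty, tx, H, W)
    levels = _levels256(arr)
    ybounds = np.linspace(0, H, ty + 1).astype(int)
    xbounds = np.linspace(0, W, tx + 1).astype(int)
    luts = np.empty((ty, tx, 256), dtype=np.float64)
    for i in range(ty):
        for j in range(tx):
            tile = levels[ybounds[i]:ybounds[i + 1], xbounds[j]:xbounds[j + 1]]
            npix = tile.size
            hist = np.bincount(tile.ravel(), minlength=256).astype(np.float64)
            limit = clip * npix / 256.0
            excess = np.sum(np.maximum(hist - limit, 0.0))
            hist = np.minimum(hist, limit) + excess / 256.0
            cdf = np.cumsum(hist)
            luts[i, j] = cdf / cdf[-1]
    # bilinear blend of tile-center mappings
    cy = (ybounds[:-1] + ybounds[1:]) / 2.0
    cx = (xbounds[:-1] + xbounds[1:]) / 2.0
    fy = np.interp(np.arange(H), cy, np.arange(ty)) if ty > 1 else np.zeros(H)
    fx = np.interp(np.arange(W), cx, np.arange(tx)) if tx > 1 else np.zeros(W)
    i0 = np.floor(fy).astype(int)
    j0 = np.floor(fx).astype(int)
    i1 = np.minimum(i0 + 1, ty - 1)
    j1 = np.minimum(j0 + 1, tx - 1)
    wy = (fy - i0)[:, None]
    wx = (fx - j0)[None, :]
    I0 = i0[:, None]
    I1 = i1[:, None]
    J0 = j0[None, :]
    J1 = j1[None, :]
    out = ((1 - wy) * (1 - wx) * luts[I0, J0, levels]
           + (1 - wy) * wx * luts[I0, J1, levels]
           + wy * (1 - wx) * luts[I1, J0, levels]
           + wy * wx * luts[I1, J1, levels])
    if gray.dtype == np.uint8:
        return np.clip(np.rint(out * rng_max), 0, 255).astype(np.uint8)
    return out


def homomorphic_filter(gray: np.ndarray, A: float = 1.5, B: float = 0.5,
                       k: float = 1.0, D0: float = 30.0) -> np.ndarray:
    """Log-domain frequency filtering separating illumination from reflectance.

    Applies ``H(u,v) = B + A (1 - exp(-k D(u,v)^2 / D0^2))`` to the Fourier
    transform of ``log(1 + I)``, where ``D`` is the distance (in frequency
    index units) from the centered zero frequency; the result is
    exponentiated and min-max normalized back to the input range.
    """
    ensure_gray(gray)
    if D0 <= 0:
        raise ValueError("cutoff frequency D0 must be > 0")
    rng_max = value_range(gray)
    arr = to_float(gray)
    logimg = np.log1p(arr)
    F = np.fft.fft2(logimg)
    h, w = arr.shape
    u = np.fft.fftfreq(h) * h
    v = np.fft.fftfreq(w) * w
    D2 = u[:, None] ** 2 + v[None, :] ** 2
    Huv = B + A * (1.0 - np.exp(-k * D2 / (D0 ** 2)))
    out = np.real(np.fft.ifft2(F * Huv))
    out = np.expm1(out)
    span = out.max() - out.min()
    if span > 0:
        out = (out - out.min()) / span
    else:
        out = np.zeros_like(out)
    if gray.dtype == np.uint8:
        return np.clip(np.rint(out * rng_max), 0, 255).astype(np.uint8)
    return out


def gabor_kernel(size: int, theta_deg: float, lam: float, sigma: float,
                 gamma: float, psi: float = 0.0) -> np.ndarray:
    """Oriented Gaussian-windowed cosine kernel.

    ``g(x,y) = exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2)) cos(2 pi x'/lam + psi)``
    with ``x' = x cos(theta) + y sin(theta)``, ``y' = -x sin(theta) + y cos(theta)``.
    """
    if size % 2 == 0 or size < 1:
        raise ValueError("Gabor kernel size must be odd")
    half = size // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(np.float64)
    th = np.deg2rad(theta_deg)
    xp = x * np.cos(th) + y * np.sin(th)
    yp = -x * np.sin(th) + y * np.cos(th)
    return np.exp(-(xp ** 2 + gamma ** 2 * yp ** 2) / (2 * sigma ** 2)) * np.cos(2 * np.pi * xp / lam + psi)


def gabor_max_response(gray: np.ndarray, cfg: VeinPipelineConfig) -> np.ndarray:
    """Pixel-wise maximum over the oriented Gabor bank, rescaled to the input range.

    The maximum over orientations preserves the strongest vein evidence at
    every pixel whatever the local vein direction.
    """
    ensure_gray(gray)
    if not cfg.gabor_orientations_deg:
        raise ValueError("orientation list must be non-empty")
    rng_max = value_range(gray)
    arr = to_float(gray)
    best = None
    for size in cfg.gabor_scales:
        for theta in cfg.gabor_orientations_deg:
            ker = gabor_kernel(int(size), float(theta), cfg.gabor_lambda,
                               cfg.gabor_sigma, cfg.gabor_gamma_aspect, cfg.gabor_psi)
            resp = ndi.correlate(arr, ker, mode="reflect")
            best = resp if best is None else np.maximum(best, resp)
    span = best.max() - best.min()
    out = (best - best.min()) / span if span > 0 else np.zeros_like(best)
    if gray.dtype == np.uint8:
        return np.clip(np.rint(out * rng_max), 0, 255).astype(np.uint8)
    return out


def weighted_fuse(img1: np.ndarray, img2: np.ndarray, w1: float = 0.5,
                  w2: float = 0.5, bias: float = 0.0) -> np.ndarray:
    """Linear combination ``w1 I1 + w2 I2 + bias``, clipped to the shared range."""
    if img1.shape != img2.shape:
        raise ValueError(f"shape mismatch: {img1.shape} vs {img2.shape}")
    if abs(w1 + w2 - 1.0) > 1e-9:
        raise ValueError("fusion weights must sum to 1")
    rng_max = value_range(img1)
    out = w1 * np.asarray(img1, np.float64) + w2 * np.asarray(img2, np.float64) + bias
    out = np.clip(out, 0.0, rng_max)
    if img1.dtype == np.uint8:
        return np.rint(out).astype(np.uint8)
    return out


def unsharp_sharpen(img: np.ndarray, alpha: float = 1.0, sigma: float = 2.0,
                    interior: np.ndarray | None = None) -> np.ndarray:
    """``I + alpha (I - gaussian_blur(I))`` applied only inside ``interior``.

    Pixels outside the interior mask are bit-identical to the input,
    preventing halo artifacts at the leaf boundary.
    """
    ensure_gray(img)
    if alpha < 0:
        raise ValueError("sharpening strength alpha must be >= 0")
    rng_max = value_range(img)
    arr = np.asarray(img, np.float64)
    blur = ndi.gaussian_filter(arr, sigma=sigma, mode="reflect")
    sharp = np.clip(arr + alpha * (arr - blur), 0.0, rng_max)
    if interior is not None:
        if interior.shape != img.shape:
            raise ValueError("interior mask dimensions must match the image")
        sharp = np.where(as_binary(interior) == 1, sharp, arr)
    if img.dtype == np.uint8:
        return np.rint(sharp).astype(np.uint8)
    return sharp


def adaptive_binarize(img: np.ndarray, window: int = 25, C: float = 5.0,
                      percentiles: tuple = (2.0, 98.0)) -> np.ndarray:
    """Percentile contrast stretch followed by local-mean thresholding.

    After stretching so percentiles ``(p_low, p_high)`` map to the range
    ends, a pixel is marked 1 when its value exceeds the mean of its
    ``window x window`` neighborhood (reflect-padded) by more than ``C``
    (given on the 0-255 scale). Veins are the locally bright structures of
    the enhanced image, so a positive ``C`` demands they stand out above
    the local mean by that margin; an input whose dynamic range is below
    one 8-bit intensity unit short-circuits to an all-zero mask.
    """
    ensure_gray(img)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window >= min(img.shape):
        raise ValueError("window must be smaller than the image")
    rng_max = value_range(img)
    arr = np.asarray(img, np.float64)
    if arr.max() - arr.min() < rng_max / 255.0:
        return np.zeros(img.shape, dtype=np.uint8)
    lo, hi = np.percentile(arr, percentiles)
    if hi <= lo:
        lo, hi = arr.min(), arr.max()
    stretched = np.clip((arr - lo) / (hi - lo), 0.0, 1.0) * rng_max
    local_mean = ndi.uniform_filter(stretched, size=window, mode="reflect")
    threshold = local_mean + C * rng_max / 255.0
    return (stretched > threshold).astype(np.uint8)


def clean_mask(mask: np.ndarray, min_area: int = 30,
               opening_se: StructuringElement | None = None,
               median_kernel: int = 3) -> np.ndarray:
    """Remove components below ``min_area``, open, then median-smooth."""
    m = as_binary(mask).astype(bool)
    if min_area > 0:
        labels, nlab = ndi.label(m, structure=np.ones((3, 3)))
        if nlab:
            sizes = np.bincount(labels.ravel())
            keep = sizes >= min_area
            keep[0] = False
            m = keep[labels]
    if opening_se is not None and opening_se.size > 1:
        m = ndi.binary_opening(m, structure=opening_se.footprint())
    if median_kernel and median_kernel > 1:
        m = ndi.median_filter(m.astype(np.uint8), size=median_kernel, mode="reflect") > 0
    return m.astype(np.uint8)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

_STAGES = ("grayscale", "leaf_mask", "clahe", "homomorphic", "gabor",
           "fused", "sharpened", "binarized", "masked", "cleaned")


def extract_veins(rgb: np.ndarray, cfg: VeinPipelineConfig | None = None,
                  thin: bool = False) -> tuple[np.ndarray, np.ndarray, dict]:
    """Run the full eight-stage binarization flow.

    Returns ``(vein_mask, leaf_mask, intermediates)`` where intermediates
    maps stage names to the image produced at that stage. With ``thin=True``
    a final morphological skeletonization reduces veins to 1-px centerlines.
    """
    cfg = cfg or VeinPipelineConfig()
    inter: dict[str, np.ndarray] = {}

    def stage(name, fn, *args, **kwargs):
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise VeinPipelineError(f"stage '{name}': {exc}") from exc
        inter[name] = out
        return out

    gray = stage("grayscale", to_grayscale, rgb)
    leaf = stage("leaf_mask", leaf_mask, rgb, cfg.closing_se)
    eq = stage("clahe", clahe, gray, cfg.clahe_tiles, cfg.clahe_clip)
    homo = stage("homomorphic", homomorphic_filter, eq, cfg.homo_A, cfg.homo_B,
                 cfg.homo_k, cfg.homo_D0)
    gab = stage("gabor", gabor_max_response, homo, cfg)
    fused = stage("fused", weighted_fuse, homo, gab, cfg.fuse_w1, cfg.fuse_w2, cfg.fuse_bias)
    # restrict sharpening and the final intersection to the eroded interior:
    # the silhouette edge is itself a strong oriented structure and would
    # otherwise dominate the response along the margin
    interior = ndi.binary_erosion(leaf.astype(bool),
                                  structure=cfg.closing_se.footprint()).astype(np.uint8)
    sharp = stage("sharpened", unsharp_sharpen, fused, cfg.unsharp_alpha,
                  cfg.unsharp_sigma, interior)
    binar = stage("binarized", adaptive_binarize, sharp, cfg.adapt_window,
                  cfg.adapt_C, cfg.stretch_percentiles)
    masked = stage("masked", lambda b: (b & interior).astype(np.uint8), binar)
    veins = stage("cleaned", clean_mask, masked, cfg.min_object_area,
                  cfg.opening_se, cfg.median_kernel)
    if thin:
        veins = morphology.skeletonize(veins.astype(bool)).astype(np.uint8)
        inter["thinned"] = veins
    return veins, leaf, inter


def band_precision_recall(pred: np.ndarray, truth: np.ndarray,
                          tolerance_px: int = 2) -> tuple[float, float]:
    """Precision/recall with a spatial tolerance band.

    A predicted pixel counts as correct if a true vein pixel lies within
    ``tolerance_px``; a true pixel counts as recovered if a predicted pixel
    lies within the same distance.
    """
    p = as_binary(pred).astype(bool)
    t = as_binary(truth).astype(bool)
    if p.shape != t.shape:
        raise ValueError("prediction and truth must share dimensions")
    selem = morphology.disk(tolerance_px)
    t_band = ndi.binary_dilation(t, structure=selem)
    p_band = ndi.binary_dilation(p, structure=selem)
    precision = float((p & t_band).sum() / p.sum()) if p.sum() else 0.0
    recall = float((t & p_band).sum() / t.sum()) if t.sum() else 0.0
    return precision, recall
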