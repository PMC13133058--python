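"""Frozen convolutional feature extractors for the two branches.

Three forward-only convolutional backbones echo the design idioms of the
architectures they are named after — an inverted-residual depthwise-
separable stack ("mobilenet_v2", 1280-d output), a dense-concatenation
stack ("densenet121", 1024-d output) and an expand/depthwise/project
stack ("efficientnet_b0", 1280-d output) — each ending in global average
pooling. Weights are He-initialized from a fixed per-architecture seed
and never trained: the package follows the random-features paradigm,
where a frozen random convolutional embedding plus a trained head is the
reference operating mode, and the published feature dimensions (1280 RGB,
1024 skeleton) are preserved exactly.

Every extractor takes a float image in [0, 1], H x W x 3 with H, W >= 32,
applies its own normalization convention, and returns the pooled feature
vector.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["RandomConvBackbone", "get_backbone", "BACKBONE_DIMS"]

BACKBONE_DIMS = {"mobilenet_v2": 1280, "densenet121": 1024, "efficientnet_b0": 1280}

_ARCH_SEEDS = {"mobilenet_v2": 20101, "densenet121": 20202, "efficientnet_b0": 20303}

def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1) -> np.ndarray:
    """'same'-padded convolution; x is (H, W, Cin), w is (k, k, Cin, Cout)."""
    k = w.shape[0]
    p = k // 2
    xp = np.pad(x, ((p, p), (p, p), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(0, 1))[::stride, ::stride]
    # win: (H', W', Cin, k, k); contract over (Cin, k, k)
    return np.tensordot(win, w, axes=([2, 3, 4], [2, 0, 1]))


def _depthwise2d(x: np.ndarray, w: np.ndarray, stride: int = 1) -> np.ndarray:
    """Per-channel convolution; w is (k, k, C)."""
    k = w.shape[0]
    p = k // 2
    xp = np.pad(x, ((p, p), (p, p), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(0, 1))[::stride, ::stride]
    return np.einsum("hwckl,klc->hwc", win, w)


def _he(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class RandomConvBackbone:
    """Forward-only convolutional embedding with frozen random weights."""

    def __init__(self, arch: str):
        if arch not in BACKBONE_DIMS:
            raise ValueError(f"unknown backbone architecture {arch!r}")
        self.arch = arch
        self.out_dim = BACKBONE_DIMS[arch]
        rng = np.random.default_rng(_ARCH_SEEDS[arch])
        self._layers = self._build(arch, rng)

    # -- construction -------------------------------------------------
    def _build(self, arch: str, rng: np.random.Generator) -> list:
        layers: list[tuple] = []

        def conv(cin, cout, k=3, stride=1):
            layers.append(("conv", _he(rng, (k, k, cin, cout), k * k * cin), stride))

        def dw(c, k=3, stride=1):
            layers.append(("dw", _he(rng, (k, k, c), k * k), stride))

        def concat_conv(cin, growth, k=3):
            layers.append(("dense", _he(rng, (k, k, cin, growth), k * k * cin)))

        def pool():
            layers.append(("pool",))

        if arch == "mobilenet_v2":
            conv(3, 32, stride=2)
            cin = 32
            for cout in (64, 128, 256):
                dw(cin, stride=2)
                conv(cin, cout, k=1)
                cin = cout
            conv(cin, self.out_dim, k=1)
        elif arch == "efficientnet_b0":
            conv(3, 32, stride=2)
            cin = 32
            for cout in (48, 96, 192):
                conv(cin, 2 * cin, k=1)  # expansion
                dw(2 * cin, stride=2)
                conv(2 * cin, cout, k=1)  # projection
                cin = cout
            conv(cin, self.out_dim, k=1)
        else:  # densenet121-style dense concatenation + transitions
            conv(3, 32, stride=2)
            cin = 32
            for _ in range(3):
                concat_conv(cin, cin)  # growth = cin, concat doubles width
                cin = 2 * cin
                conv(cin, cin // 2, k=1)  # transition
                cin = cin // 2
                pool()
            conv(cin, self.out_dim, k=1)
        return layers

    # -- inference -----------------------------------------------------
    def preprocess(self, img: np.ndarray) -> np.ndarray:
        """Map a float [0,1] RGB image to the backbone's expected scaling."""
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("backbone input must be H x W x 3")
        if self.arch == "mobilenet_v2":
            return img * 2.0 - 1.0
        mean = np.array([0.485, 0.456, 0.406])
        std = np.array([0.229, 0.224, 0.225])
        return (img - mean) / std

    def feature_map(self, img: np.ndarray) -> np.ndarray:
        if min(img.shape[:2]) < 32:
            raise ValueError("backbone input must be at least 32 x 32 pixels")
        x = self.preprocess(np.asarray(img, dtype=np.float64))
        for layer in self._layers:
            kind = layer[0]
            if kind == "conv":
                _, w, stride = layer
                x = _relu(_conv2d(x, w, stride))
            elif kind == "dw":
                _, w, stride = layer
                x = _relu(_depthwise2d(x, w, stride))
            elif kind == "dense":
                _, w = layer
                x = np.concatenate([x, _relu(_conv2d(x, w))], axis=2)
            elif kind == "pool":
                h, w_ = x.shape[:2]
                x = x[: h - h % 2, : w_ - w_ % 2]
                x = 0.25 * (x[::2, ::2] + x[1::2, ::2] + x[::2, 1::2] + x[1::2, 1::2])
        return x

    def features(self, img: np.ndarray) -> np.ndarray:
        """Global-average-pooled feature vector of length ``out_dim``."""
        fmap = self.feature_map(img)
        return fmap.mean(axis=(0, 1))

    def state_fingerprint(self) -> float:
        """Checksum of all frozen weights (used to verify immutability)."""
        return float(sum(np.abs(w[1]).sum() for w in self._layers if w[0] != "pool"))


_CACHE: dict[str, RandomConvBackbone] = {}


def get_backbone(arch: str) -> RandomConvBackbone:
    """Shared backbone instance per architecture (weights are frozen)."""
    if arch not in _CACHE:
        _CACHE[arch] = RandomConvBackbone(arch)
    return _CACHE[arch]
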