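"""Dual-branch appearance + venation classifier and its four baselines.

The dual model extracts a 1280-d appearance embedding from the RGB image
(MobileNetV2-style branch) and a 1024-d structural embedding from the
jet-colormapped binary vein map (DenseNet121-style branch), concatenates
them into a 2304-d joint representation, and classifies with a shared
head: dense(128, ReLU, L2) -> dropout(0.5) -> dense(C) -> softmax,
trained with label-smoothed, class-weighted categorical cross-entropy
under Adam with early stopping and learning-rate reduction on plateau.

Backbones are frozen (see :mod:`veinfuse.backbones`); only the head has
trainable state, so per-record branch features are computed once and the
optimization runs over cached feature vectors.

Variants
--------
``dual``                  RGB + skeleton branches, concatenated (2304-d)
``rgb_only``              MobileNetV2-style branch on RGB (1280-d)
``skeleton_densenet``     DenseNet121-style branch on jet-mapped masks (1024-d)
``skeleton_efficientnet`` EfficientNetB0-style branch on jet-mapped masks (1280-d)
``fused_densenet``        DenseNet121-style branch on fused images (1024-d)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import transform as sktransform

from .backbones import BACKBONE_DIMS, get_backbone
from .fused_image import compose_fused
from .images import as_binary, to_float

logger = logging.getLogger(__name__)

__all__ = [
    "FusionModelConfig",
    "FeatureVector",
    "PredictionBatch",
    "VARIANTS",
    "jet_colormap",
    "branch_features",
    "fuse_features",
    "smoothed_crossentropy",
    "build_model",
    "train",
    "predict",
    "DualBranchModel",
]

VARIANTS = ("dual", "rgb_only", "skeleton_densenet", "skeleton_efficientnet",
            "fused_densenet")

SOURCE_DIMS = {"rgb": 1280, "skeleton": 1024, "skeleton_b0": 1280, "fused": 2304}

_BRANCH_ARCH = {"rgb": "mobilenet_v2", "skeleton": "densenet121",
                "skeleton_b0": "efficientnet_b0"}


@dataclass(frozen=True)
class FusionModelConfig:
    """Training regime and architecture selection."""

    num_classes: int = 7
    image_size: int = 224
    batch_size: int = 16
    max_epochs: int = 50
    learning_rate: float = 1e-5
    label_smoothing_eps: float = 0.01
    dropout_rate: float = 0.5
    head_units: int = 128
    l2_lambda: float = 1e-4
    class_weighting: bool = True
    rgb_backbone: str = "mobilenet_v2"
    skeleton_backbone: str = "densenet121"
    weights_mode: str = "random-frozen"  # pretrained-frozen | random-frozen | random-trainable
    early_stopping_patience: int = 10
    lr_plateau_factor: float = 0.5
    lr_plateau_patience: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout rate must lie in [0, 1]")
        if not 0.0 <= self.label_smoothing_eps < 1.0:
            raise ValueError("label smoothing epsilon must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.num_classes < 2:
            raise ValueError("need at least two classes")
        if self.weights_mode == "pretrained-frozen":
            raise ValueError(
                "no pretrained weight source exists for the built-in backbones; "
                "use weights_mode='random-frozen'")
        if self.weights_mode == "random-trainable":
            raise NotImplementedError(
                "backbone fine-tuning is not supported; backbones are frozen "
                "feature extractors (weights_mode='random-frozen')")
        if self.weights_mode != "random-frozen":
            raise ValueError(f"unknown weights_mode {self.weights_mode!r}")


@dataclass(frozen=True)
class FeatureVector:
    """Pooled branch embedding with a provenance tag fixing its length."""

    values: np.ndarray
    source: str

    def __post_init__(self) -> None:
        expected = SOURCE_DIMS.get(self.source)
        if expected is None:
            raise ValueError(f"unknown feature source {self.source!r}")
        if self.values.shape != (expected,):
            raise ValueError(
                f"{self.source} features must have length {expected}, "
                f"got {self.values.shape}")


@dataclass(frozen=True)
class PredictionBatch:
    probabilities: np.ndarray  # n x C, rows on the simplex
    labels_pred: np.ndarray  # argmax indices

    def __post_init__(self) -> None:
        p = self.probabilities
        if np.any(p < 0) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("probability rows must be non-negative and sum to 1")


def jet_colormap(mask: np.ndarray) -> np.ndarray:
    """Map a {0,1} mask to the jet colormap's endpoint colors.

    Restricted to a binary domain the classic jet mapping reduces to its
    two endpoints: 0 -> dark blue (0, 0, 128) and 1 -> dark red
    (128, 0, 0), giving the single-channel vein map the 3-channel form the
    pretrained-style backbones expect.
    """
    m = as_binary(mask)
    out = np.zeros(m.shape + (3,), dtype=np.uint8)
    out[..., 2] = np.where(m == 0, 128, 0)
    out[..., 0] = np.where(m == 1, 128, 0)
    return out


def _resized(img: np.ndarray, size: int) -> np.ndarray:
    arr = to_float(img)
    if arr.shape[:2] != (size, size):
        arr = sktransform.resize(arr, (size, size), order=1, mode="reflect",
                                 anti_aliasing=True)
    return arr


def branch_features(img: np.ndarray, branch: str,
                    cfg: FusionModelConfig | None = None) -> FeatureVector:
    """Globally pooled backbone features of one branch.

    ``branch`` selects the extractor: ``rgb`` (MobileNetV2-style, 1280-d),
    ``skeleton`` (DenseNet121-style, 1024-d) or ``skeleton_b0``
    (EfficientNetB0-style, 1280-d). The image is resized to the configured
    input size and normalized per the backbone's convention.
    """
    cfg = cfg or FusionModelConfig()
    if branch not in _BRANCH_ARCH:
        raise ValueError(f"unknown branch {branch!r}")
    arch = {"rgb": cfg.rgb_backbone, "skeleton": cfg.skeleton_backbone,
            "skeleton_b0": "efficientnet_b0"}[branch]
    backbone = get_backbone(arch)
    values = backbone.features(_resized(img, cfg.image_size))
    return FeatureVector(values=values, source=branch)


def fuse_features(z_rgb: FeatureVector, z_skel: FeatureVector) -> FeatureVector:
    """Late feature-level fusion: concatenation, RGB coordinates first."""
    if z_rgb.source != "rgb" or z_skel.source != "skeleton":
        raise ValueError("fusion expects an rgb and a skeleton feature vector")
    return FeatureVector(values=np.concatenate([z_rgb.values, z_skel.values]),
                         source="fused")


def smoothed_crossentropy(y_true: np.ndarray, probs: np.ndarray, eps: float = 0.01,
                          sample_weights: np.ndarray | None = None) -> float:
    """Label-smoothed categorical cross-entropy.

    ``L = -(1/N) sum_i w_i sum_c [y_ic (1 - eps) + eps / C] log p_ic``.
    Probabilities are floored at 1e-12 before the log.
    """
    if not 0.0 <= eps < 1.0:
        raise ValueError("eps must lie in [0, 1)")
    p = np.asarray(probs, dtype=np.float64)
    if np.any(p <= 0) or np.any(p > 1):
        logger.warning("probabilities outside (0, 1] clamped before log")
    p = np.clip(p, 1e-12, 1.0)
    n, c = p.shape
    target = y_true * (1.0 - eps) + eps / c
    per_sample = -(target * np.log(p)).sum(axis=1)
    if sample_weights is not None:
        per_sample = per_sample * sample_weights
    return float(per_sample.mean())


# ---------------------------------------------------------------------------
# classification head
# ---------------------------------------------------------------------------

class ClassificationHead:
    """dense(128, ReLU, L2) -> dropout -> dense(C) -> softmax, Adam-trained.

    Incoming pooled features pass through a fixed standardization layer
    (per-dimension mean/scale frozen from the training set, times a fixed
    gain) — the GAP -> normalization -> dense idiom — which places the
    head's operating point where the small published learning rate makes
    productive progress.
    """

    FEATURE_GAIN = 10.0

    def __init__(self, in_dim: int, cfg: FusionModelConfig, rng: np.random.Generator):
        u, c = cfg.head_units, cfg.num_classes
        self.cfg = cfg
        self.mu = np.zeros(in_dim)
        self.sigma = np.ones(in_dim)
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, u))
        self.b1 = np.zeros(u)
        self.W2 = rng.normal(0.0, np.sqrt(2.0 / u), size=(u, c))
        self.b2 = np.zeros(c)
        self._adam = {k: [np.zeros_like(v), np.zeros_like(v)]
                      for k, v in self._params().items()}
        self._adam_t = 0

    def fit_standardizer(self, X: np.ndarray) -> None:
        """Freeze the standardization constants from training features."""
        self.mu = X.mean(axis=0)
        self.sigma = np.maximum(X.std(axis=0), 1e-8)

    def _params(self) -> dict:
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2}

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def forward(self, z: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> tuple[np.ndarray, dict]:
        z = (z - self.mu) / self.sigma * self.FEATURE_GAIN
        h = np.maximum(z @ self.W1 + self.b1, 0.0)
        if train and self.cfg.dropout_rate > 0:
            keep = 1.0 - self.cfg.dropout_rate
            mask = (rng.random(h.shape) < keep) / keep
            h_drop = h * mask
        else:
            mask = None
            h_drop = h
        probs = self._softmax(h_drop @ self.W2 + self.b2)
        return probs, {"z": z, "h": h, "mask": mask, "h_drop": h_drop}

    def train_step(self, z: np.ndarray, target: np.ndarray, weights: np.ndarray,
                   lr: float, rng: np.random.Generator) -> float:
        """One Adam update on a batch; returns the batch loss."""
        cfg = self.cfg
        probs, cache = self.forward(z, train=True, rng=rng)
        n = z.shape[0]
        loss = float((-(target * np.log(np.clip(probs, 1e-12, 1.0))).sum(axis=1)
                      * weights).mean())
        loss += cfg.l2_lambda * float((self.W1 ** 2).sum() + (self.W2 ** 2).sum())
        dlogits = (probs - target) * weights[:, None] / n
        gW2 = cache["h_drop"].T @ dlogits + 2 * cfg.l2_lambda * self.W2
        gb2 = dlogits.sum(axis=0)
        dh = dlogits @ self.W2.T
        if cache["mask"] is not None:
            dh = dh * cache["mask"]
        dh = dh * (cache["h"] > 0)
        gW1 = cache["z"].T @ dh + 2 * cfg.l2_lambda * self.W1
        gb1 = dh.sum(axis=0)
        self._adam_t += 1
        grads = {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}
        b1m, b2m, epsm = 0.9, 0.999, 1e-8
        for name, param in self._params().items():
            m, v = self._adam[name]
            g = grads[name]
            m[:] = b1m * m + (1 - b1m) * g
            v[:] = b2m * v + (1 - b2m) * g * g
            mhat = m / (1 - b1m ** self._adam_t)
            vhat = v / (1 - b2m ** self._adam_t)
            param -= lr * mhat / (np.sqrt(vhat) + epsm)
        return loss


# ---------------------------------------------------------------------------
# model handle
# ---------------------------------------------------------------------------

class DualBranchModel:
    """Trainable classifier handle for one architecture variant."""

    def __init__(self, variant: str, cfg: FusionModelConfig, classes: list[str] | None = None):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
        self.variant = variant
        self.cfg = cfg
        self.classes = classes
        self.head: ClassificationHead | None = None
        self.history: dict | None = None

    @property
    def feature_dim(self) -> int:
        return {"dual": 2304, "rgb_only": 1280, "skeleton_densenet": 1024,
                "skeleton_efficientnet": 1280, "fused_densenet": 1024}[self.variant]

    def _branch_input(self, record, key: str) -> np.ndarray:
        if key == "rgb":
            return record.rgb
        if key in ("skeleton", "skeleton_b0"):
            return jet_colormap(record.vein_truth)
        return compose_fused(record.rgb, record.vein_truth).pixels  # fused image

    def _branch_values(self, record, branch: str, input_key: str,
                       cache: dict | None) -> np.ndarray:
        ckey = (branch, input_key, id(record))
        if cache is not None and ckey in cache:
            return cache[ckey]
        z = branch_features(self._branch_input(record, input_key), branch, self.cfg).values
        if cache is not None:
            cache[ckey] = z
        return z

    def featurize(self, record, cache: dict | None = None) -> np.ndarray:
        """Pooled branch features for one record; cached per (branch, record)."""
        if self.variant == "dual":
            return np.concatenate([
                self._branch_values(record, "rgb", "rgb", cache),
                self._branch_values(record, "skeleton", "skeleton", cache)])
        if self.variant == "rgb_only":
            return self._branch_values(record, "rgb", "rgb", cache)
        if self.variant == "skeleton_densenet":
            return self._branch_values(record, "skeleton", "skeleton", cache)
        if self.variant == "skeleton_efficientnet":
            return self._branch_values(record, "skeleton_b0", "skeleton_b0", cache)
        return self._branch_values(record, "skeleton", "fused_image", cache)

    def featurize_all(self, records, cache: dict | None = None) -> np.ndarray:
        out = np.empty((len(records), self.feature_dim))
        for i, rec in enumerate(records):
            out[i] = self.featurize(rec, cache)
        return out


    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        """Serialize head weights + metadata to an .npz archive."""
        if self.head is None:
            raise ValueError("nothing to save: model has not been trained")
        import json
        from dataclasses import asdict
        meta = json.dumps({"variant": self.variant, "classes": self.classes,
                           "cfg": asdict(self.cfg)})
        np.savez(path, meta=np.array(meta), mu=self.head.mu, sigma=self.head.sigma,
                 W1=self.head.W1, b1=self.head.b1, W2=self.head.W2, b2=self.head.b2)

    @classmethod
    def load(cls, path) -> "DualBranchModel":
        import json
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            model = cls(meta["variant"], FusionModelConfig(**meta["cfg"]),
                        classes=meta["classes"])
            model.head = ClassificationHead(model.feature_dim, model.cfg,
                                            np.random.default_rng(0))
            for name in ("mu", "sigma", "W1", "b1", "W2", "b2"):
                getattr(model.head, name)[:] = data[name]
        return model


def build_model(variant: str, cfg: FusionModelConfig) -> DualBranchModel:
    """Instantiate one of the five classifier variants."""
    return DualBranchModel(variant, cfg)


def _onehot(labels: np.ndarray, classes: list[str]) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    out = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        out[i, idx[lab]] = 1.0
    return out


def train(model: DualBranchModel, records, cfg: FusionModelConfig | None = None,
          rng_seed: int = 0, feature_cache: dict | None = None) -> tuple[DualBranchModel, dict]:
    """Train the head on the records' train split, validating on the val split.

    Backbone features are computed once per record (backbones are frozen);
    the head is optimized with Adam at the configured learning rate with
    label smoothing, optional balanced class weighting, early stopping on
    validation loss and learning-rate reduction on plateau. Deterministic
    under ``rng_seed``.
    """
    cfg = cfg or model.cfg
    train_recs = [r for r in records if r.split == "train"]
    val_recs = [r for r in records if r.split == "val"]
    if not train_recs or not val_recs:
        raise ValueError("records must carry non-empty train and val split tags")
    classes = sorted({r.label for r in records})
    if len(classes) != cfg.num_classes:
        raise ValueError(f"config expects {cfg.num_classes} classes, records have {len(classes)}")
    model.classes = classes
    rng = np.random.default_rng(rng_seed)
    model.head = ClassificationHead(model.feature_dim, cfg, rng)

    Xtr = model.featurize_all(train_recs, feature_cache)
    Xva = model.featurize_all(val_recs, feature_cache)
    model.head.fit_standardizer(Xtr)
    ytr = _onehot(np.array([r.label for r in train_recs]), classes)
    yva = _onehot(np.array([r.label for r in val_recs]), classes)
    eps = cfg.label_smoothing_eps
    ttr = ytr * (1 - eps) + eps / len(classes)

    if cfg.class_weighting:
        counts = {c: sum(1 for r in train_recs if r.label == c) for c in classes}
        total = sum(counts.values())
        wmap = {c: total / (len(classes) * n) for c, n in counts.items()}
        wtr = np.array([wmap[r.label] for r in train_recs])
    else:
        wtr = np.ones(len(train_recs))

    lr = cfg.learning_rate
    best_val = np.inf
    best_state = None
    since_best = 0
    since_plateau = 0
    history = {"epoch": [], "lr": [], "train_loss": [], "train_acc": [],
               "val_loss": [], "val_acc": []}
    n = len(train_recs)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            losses.append(model.head.train_step(Xtr[idx], ttr[idx], wtr[idx], lr, rng))
        ptr, _ = model.head.forward(Xtr)
        pva, _ = model.head.forward(Xva)
        tl = smoothed_crossentropy(ytr, ptr, eps, wtr)
        vl = smoothed_crossentropy(yva, pva, eps)
        ta = float((ptr.argmax(1) == ytr.argmax(1)).mean())
        va = float((pva.argmax(1) == yva.argmax(1)).mean())
        history["epoch"].append(epoch)
        history["lr"].append(lr)
        history["train_loss"].append(tl)
        history["train_acc"].append(ta)
        history["val_loss"].append(vl)
        history["val_acc"].append(va)
        logger.info("epoch %d: lr %.2e train loss %.4f acc %.3f | val loss %.4f acc %.3f",
                    epoch, lr, tl, ta, vl, va)
        if vl < best_val - 1e-6:
            best_val = vl
            best_state = {k: v.copy() for k, v in model.head._params().items()}
            since_best = 0
            since_plateau = 0
        else:
            since_best += 1
            since_plateau += 1
            if since_plateau >= cfg.lr_plateau_patience:
                lr *= cfg.lr_plateau_factor
                since_plateau = 0
                logger.info("epoch %d: reducing learning rate to %.2e", epoch, lr)
            if since_best >= cfg.early_stopping_patience:
                logger.info("early stopping at epoch %d", epoch)
                break
    if best_state is not None:
        for k, v in best_state.items():
            getattr(model.head, k)[:] = v
    model.history = history
    return model, history


def predict(model: DualBranchModel, records, feature_cache: dict | None = None) -> PredictionBatch:
    """Eval-mode class probabilities and argmax labels for a record list."""
    if model.head is None:
        raise ValueError("model has not been trained")
    X = model.featurize_all(records, feature_cache)
    probs, _ = model.head.forward(X, train=False)
    return PredictionBatch(probabilities=probs, labels_pred=probs.argmax(axis=1))
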