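"""Dataset manifests, image I/O and leakage-free stratified splitting.

A dataset on disk is one directory per class of 8-bit PNG/JPEG images,
a mirrored ``masks/`` tree of binary vein maps, and a ``manifest.csv``
with columns ``path, mask_path, label, instance_id[, split]`` (paths
relative to the manifest's directory).

Splitting is stratified by class and grouped by leaf instance: all
renders of one physical leaf land in the same subset, so no appearance
leaks across train/val/test. Subset sizes per class are apportioned over
instance groups by largest remainder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .synthetic_leaf import LeafRecord

logger = logging.getLogger(__name__)

__all__ = ["SplitSpec", "stratified_group_split", "load_manifest",
           "write_manifest", "write_dataset", "read_image", "write_image"]

MANIFEST_COLUMNS = ("path", "mask_path", "label", "instance_id", "split")


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple = (0.8, 0.1, 0.1)  # train, val, test
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fractions) != 3 or any(f <= 0 for f in self.fractions):
            raise ValueError("need three positive fractions (train, val, test)")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def _apportion(n_groups: int, fractions: tuple) -> list[int]:
    """Largest-remainder apportionment of groups to the three subsets."""
    quotas = [f * n_groups for f in fractions]
    counts = [int(q) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    for _ in range(n_groups - sum(counts)):
        i = int(np.argmax(remainders))
        counts[i] += 1
        remainders[i] = -1.0
    # every subset must hold at least one group
    while min(counts) == 0:
        counts[int(np.argmax(counts))] -= 1
        counts[counts.index(0)] += 1
    return counts


def stratified_group_split(records: list[LeafRecord], spec: SplitSpec) -> list[LeafRecord]:
    """Assign train/val/test tags, stratified by class, grouped by instance.

    Deterministic under the spec's seed and invariant to the input record
    order (groups are sorted before the seeded shuffle). A class with
    fewer than 3 instance groups cannot populate all three subsets and is
    rejected.
    """
    by_class: dict[str, dict[str, list[LeafRecord]]] = {}
    for rec in records:
        if not rec.label or not rec.instance_id:
            raise ValueError("every record needs a label and an instance_id")
        by_class.setdefault(rec.label, {}).setdefault(rec.instance_id, []).append(rec)
    for ci, label in enumerate(sorted(by_class)):
        groups = sorted(by_class[label])
        if len(groups) < 3:
            raise ValueError(
                f"class {label!r} has only {len(groups)} instance group(s); "
                "at least 3 are needed to populate train/val/test")
        rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, ci]))
        order = list(rng.permutation(groups))
        n_train, n_val, _ = _apportion(len(groups), spec.fractions)
        for gi, gid in enumerate(order):
            tag = "train" if gi < n_train else ("val" if gi < n_train + n_val else "test")
            for rec in by_class[label][gid]:
                rec.split = tag
    return records


# ---------------------------------------------------------------------------
# image + manifest I/O
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Decode an 8-bit image; RGB kept 3-channel, masks binarized to {0,1}."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB") if im.mode not in ("L", "1") else im)
    return arr


def read_mask(path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr > 127).astype(np.uint8)


def write_image(path, img: np.ndarray) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(img).save(path)


def write_mask(path, mask: np.ndarray) -> None:
    write_image(path, (np.asarray(mask, np.uint8) * 255))


def write_dataset(records: list[LeafRecord], root) -> Path:
    """Write images, vein masks and manifest.csv under ``root``."""
    root = Path(root)
    for i, rec in enumerate(records):
        if rec.path is None:
            rec.path = f"{rec.label}/{rec.instance_id}_{i:04d}.png"
            rec.mask_path = f"masks/{rec.path}"
        write_image(root / rec.path, rec.rgb)
        write_mask(root / rec.mask_path, rec.vein_truth)
    manifest = root / "manifest.csv"
    write_manifest(records, manifest)
    return manifest


def write_manifest(records: list[LeafRecord], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"path": r.path, "mask_path": r.mask_path, "label": r.label,
          "instance_id": r.instance_id, "split": r.split} for r in records]
    ).to_csv(path, index=False)


def load_manifest(path, load_images: bool = True, validate: bool = True) -> list[LeafRecord]:
    """Load records from a manifest CSV; file problems name the offending row."""
    path = Path(path)
    root = path.parent
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks required columns: {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        img_path = root / str(row["path"])
        msk_path = root / str(row["mask_path"])
        if validate and not img_path.is_file():
            raise FileNotFoundError(f"manifest row {i}: missing image {img_path}")
        if validate and not msk_path.is_file():
            raise FileNotFoundError(f"manifest row {i}: missing mask {msk_path}")
        rgb = vein = None
        if load_images:
            try:
                rgb = read_image(img_path)
                vein = read_mask(msk_path)
            except Exception as exc:
                raise ValueError(f"manifest row {i}: cannot decode {img_path}: {exc}") from exc
        records.append(LeafRecord(
            rgb=rgb, vein_truth=vein, leaf_mask_truth=None,
            label=str(row["label"]), instance_id=str(row["instance_id"]),
            split=str(row.get("split", "unassigned")) if "split" in df.columns else "unassigned",
            path=str(row["path"]), mask_path=str(row["mask_path"])))
    return records
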