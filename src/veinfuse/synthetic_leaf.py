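"""Procedural leaf-image generator with ground-truth vein masks.

Renders single leaves on a uniform white background from a species
archetype describing the blade outline (shape, serration), pigmentation
(HSV base color with per-leaf jitter and multiplicative texture) and a
parametric venation tree (midrib, paired secondaries at a fixed insertion
angle and spacing, optional short tertiaries). Appearance and venation
parameters are independent, so archetype pairs can be built that differ
in exactly one of the two cue families — the property the dual-branch
classifier experiments rely on.

Every leaf comes with exact vein and silhouette masks, so the classical
binarization pipeline and the classifiers are testable without any
downloaded imagery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import draw as skdraw
from skimage import morphology, transform

__all__ = ["SpeciesArchetype", "LeafRecord", "generate_leaf", "generate_dataset",
           "DEFAULT_ARCHETYPES", "appearance_trio_archetypes",
           "venation_trio_archetypes"]

VALID_SHAPES = ("ovate", "lanceolate", "round", "lobed")
VALID_SPLITS = ("train", "val", "test", "unassigned")


def DEFAULT_ARCHETYPES() -> list:
    """Seven stand-in species spanning distinct appearance and venation cues.

    Named after the seven medicinal species of the reference corpus; the
    parameters are synthetic stand-ins, not measurements of those plants.
    """
    return [
        SpeciesArchetype(name="Guava", blade_shape="ovate", margin_serration=0,
                         base_color_hsv=(115.0, 0.50, 0.45), vein_order_count=2,
                         secondary_vein_angle_deg=55.0, secondary_vein_spacing_px=22.0,
                         vein_width_px=3),
        SpeciesArchetype(name="Arjun", blade_shape="lanceolate", margin_serration=0,
                         base_color_hsv=(95.0, 0.45, 0.50), vein_order_count=2,
                         secondary_vein_angle_deg=40.0, secondary_vein_spacing_px=18.0,
                         vein_width_px=2),
        SpeciesArchetype(name="Indian pennywort", blade_shape="round", margin_serration=14,
                         base_color_hsv=(130.0, 0.60, 0.42), vein_order_count=3,
                         secondary_vein_angle_deg=35.0, secondary_vein_spacing_px=30.0,
                         vein_width_px=3),
        SpeciesArchetype(name="Malabar", blade_shape="ovate", margin_serration=0,
                         base_color_hsv=(105.0, 0.55, 0.38), vein_order_count=3,
                         secondary_vein_angle_deg=50.0, secondary_vein_spacing_px=26.0,
                         vein_width_px=3),
        SpeciesArchetype(name="Neem", blade_shape="lanceolate", margin_serration=20,
                         base_color_hsv=(120.0, 0.65, 0.48), vein_order_count=2,
                         secondary_vein_angle_deg=45.0, secondary_vein_spacing_px=14.0,
                         vein_width_px=2),
        SpeciesArchetype(name="Mint", blade_shape="ovate", margin_serration=24,
                         base_color_hsv=(140.0, 0.55, 0.52), vein_order_count=2,
                         secondary_vein_angle_deg=60.0, secondary_vein_spacing_px=20.0,
                         vein_width_px=2),
        SpeciesArchetype(name="Tulsi", blade_shape="lobed", margin_serration=10,
                         base_color_hsv=(85.0, 0.50, 0.44), vein_order_count=2,
                         secondary_vein_angle_deg=50.0, secondary_vein_spacing_px=24.0,
                         vein_width_px=3),
    ]


def appearance_trio_archetypes() -> list:
    """Three classes separable by appearance cues (pigment and blade shape)."""
    return [
        SpeciesArchetype(name="A", base_color_hsv=(110.0, 0.55, 0.45)),
        SpeciesArchetype(name="B", base_color_hsv=(60.0, 0.50, 0.55),
                         blade_shape="lanceolate"),
        SpeciesArchetype(name="C", base_color_hsv=(140.0, 0.70, 0.35),
                         blade_shape="round"),
    ]


def venation_trio_archetypes() -> list:
    """Three classes with identical appearance parameters, differing only in
    venation — the condition under which the skeleton branch carries all the
    class signal."""
    base = dict(blade_shape="ovate", base_color_hsv=(110.0, 0.55, 0.45),
                color_jitter=(2.0, 0.01, 0.01), vein_contrast=0.04,
                texture_amp=0.02, illum_gradient_amp=0.03)
    return [
        SpeciesArchetype(name="V1", vein_order_count=2, secondary_vein_angle_deg=30.0,
                         secondary_vein_spacing_px=14.0, vein_width_px=2, **base),
        SpeciesArchetype(name="V2", vein_order_count=2, secondary_vein_angle_deg=65.0,
                         secondary_vein_spacing_px=28.0, vein_width_px=4, **base),
        SpeciesArchetype(name="V3", vein_order_count=3, secondary_vein_angle_deg=45.0,
                         secondary_vein_spacing_px=20.0, vein_width_px=2, **base),
    ]


@dataclass(frozen=True)
class SpeciesArchetype:
    """Generative parameters of one synthetic species."""

    name: str
    blade_shape: str = "ovate"
    margin_serration: int = 0
    base_color_hsv: tuple = (110.0, 0.55, 0.45)  # h in degrees, s/v in [0,1]
    color_jitter: tuple = (4.0, 0.04, 0.04)  # per-channel std-devs (h, s, v)
    vein_order_count: int = 2  # 1 midrib, 2 +secondaries, 3 +tertiaries
    secondary_vein_angle_deg: float = 45.0
    secondary_vein_spacing_px: float = 25.0
    vein_width_px: int = 3
    vein_contrast: float = 0.12  # brightness offset of veins in the V channel
    texture_amp: float = 0.06  # multiplicative blade-texture amplitude
    illum_gradient_amp: float = 0.10  # across-blade illumination gradient amplitude

    def __post_init__(self) -> None:
        if self.blade_shape not in VALID_SHAPES:
            raise ValueError(f"unknown blade shape {self.blade_shape!r}")
        if self.margin_serration < 0:
            raise ValueError("margin_serration must be >= 0")
        if not 0.0 < self.secondary_vein_angle_deg < 90.0:
            raise ValueError("secondary vein angle must lie strictly in (0, 90) degrees")
        if self.secondary_vein_spacing_px <= self.vein_width_px:
            raise ValueError("vein spacing must exceed vein width")
        if self.vein_width_px < 1:
            raise ValueError("vein width must be >= 1 px")
        if self.vein_order_count not in (1, 2, 3):
            raise ValueError("vein_order_count must be 1, 2 or 3")
        if any(j < 0 for j in self.color_jitter):
            raise ValueError("color jitter std-devs must be >= 0")


@dataclass
class LeafRecord:
    """One sample: RGB render, truth masks, label, leaf-instance identity."""

    rgb: np.ndarray
    vein_truth: np.ndarray
    leaf_mask_truth: np.ndarray | None
    label: str
    instance_id: str
    split: str = "unassigned"
    path: str | None = None
    mask_path: str | None = None

    def __post_init__(self) -> None:
        if self.split not in VALID_SPLITS:
            raise ValueError(f"unknown split tag {self.split!r}")
        if self.rgb is not None:
            if self.rgb.shape[:2] != self.vein_truth.shape:
                raise ValueError("rgb and vein mask must share dimensions")
            if self.leaf_mask_truth is not None:
                if self.rgb.shape[:2] != self.leaf_mask_truth.shape:
                    raise ValueError("rgb and leaf mask must share dimensions")
                if np.any(self.vein_truth & ~self.leaf_mask_truth.astype(bool)):
                    raise ValueError("vein pixels found outside the leaf silhouette")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _blade_polygon(arch: SpeciesArchetype, half_len: float, rng: np.random.Generator,
                   n_vertices: int = 720) -> np.ndarray:
    """Blade boundary as (y, x) offsets from the center; axis along -y (tip up)."""
    phi = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    a = half_len
    if arch.blade_shape == "round":
        b, egg = a, 0.0
    elif arch.blade_shape == "ovate":
        b, egg = 0.62 * a, 0.18
    elif arch.blade_shape == "lanceolate":
        b, egg = 0.32 * a, 0.10
    else:  # lobed
        b, egg = 0.70 * a, 0.0
    # egg asymmetry: wider toward the base (phi = pi)
    width = b * (1.0 + egg * (1.0 - np.cos(phi)) / 2.0 * 2.0 - egg) if egg else np.full_like(phi, b)
    r_y = a * np.cos(phi)
    r_x = width * np.sin(phi)
    if arch.blade_shape == "lobed":
        mod = 1.0 + 0.22 * np.cos(5.0 * phi)
        r_y, r_x = r_y * mod, r_x * mod
    if arch.margin_serration > 0:
        teeth = (np.mod(arch.margin_serration * phi / (2 * np.pi), 1.0) * 2.0 - 1.0)
        mod = 1.0 + 0.030 * teeth
        r_y, r_x = r_y * mod, r_x * mod
    # mild per-leaf shape jitter (low-order harmonic)
    amp = rng.uniform(0.0, 0.02)
    ph = rng.uniform(0, 2 * np.pi)
    mod = 1.0 + amp * np.cos(2 * phi + ph)
    return np.stack([-r_y * mod, r_x * mod], axis=1)


def _march_inside(start: np.ndarray, direction: np.ndarray, mask: np.ndarray,
                  max_len: float) -> np.ndarray | None:
    """Endpoint of a straight segment from start staying inside the mask."""
    h, w = mask.shape
    step = direction / np.linalg.norm(direction)
    end = start.copy()
    for t in range(1, int(max_len) + 1):
        p = start + step * t
        yy, xx = int(round(p[0])), int(round(p[1]))
        if not (0 <= yy < h and 0 <= xx < w) or not mask[yy, xx]:
            break
        end = p
    if np.allclose(end, start):
        return None
    return end


def _vein_skeleton(arch: SpeciesArchetype, leaf: np.ndarray, center: np.ndarray,
                   half_len: float, rng: np.random.Generator) -> np.ndarray:
    """Accumulate anti-aliased vein polylines, binarized at 0.5."""
    h, w = leaf.shape
    acc = np.zeros((h, w), dtype=np.float64)

    def draw_segment(p0, p1):
        rr, cc, val = skdraw.line_aa(int(round(p0[0])), int(round(p0[1])),
                                     int(round(p1[0])), int(round(p1[1])))
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        np.maximum.at(acc, (rr[ok], cc[ok]), val[ok])

    # midrib: base (bottom) to tip (top) with a gentle bend
    base = center + np.array([half_len * 0.96, 0.0])
    tip = center - np.array([half_len * 0.96, 0.0])
    bend = rng.uniform(-0.04, 0.04) * half_len
    ts = np.linspace(0.0, 1.0, 48)
    midrib = np.stack([base[0] + (tip[0] - base[0]) * ts,
                       base[1] + bend * np.sin(np.pi * ts)], axis=1)
    # clip midrib endpoints into the silhouette
    inside = [p for p in midrib if 0 <= int(p[0]) < h and 0 <= int(p[1]) < w
              and leaf[int(p[0]), int(p[1])]]
    if len(inside) < 2:
        raise ValueError("silhouette too small to hold a midrib")
    midrib = np.asarray(inside)
    for p0, p1 in zip(midrib[:-1], midrib[1:]):
        draw_segment(p0, p1)

    secondaries: list[tuple[np.ndarray, np.ndarray]] = []
    if arch.vein_order_count >= 2:
        arc = np.linalg.norm(np.diff(midrib, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(arc)])
        total = cum[-1]
        s = arch.secondary_vein_spacing_px
        positions = np.arange(s, total - s * 0.25, s)
        ang = math.radians(arch.secondary_vein_angle_deg)
        for pos in positions:
            i = int(np.searchsorted(cum, pos))
            i = min(max(i, 1), len(midrib) - 1)
            p = midrib[i]
            tangent = midrib[i] - midrib[i - 1]
            tangent = tangent / (np.linalg.norm(tangent) + 1e-12)
            for side in (-1.0, 1.0):
                c, sn = math.cos(side * ang), math.sin(side * ang)
                d = np.array([tangent[0] * c - tangent[1] * sn,
                              tangent[0] * sn + tangent[1] * c])
                end = _march_inside(p, d, leaf.astype(bool), max_len=2.2 * half_len)
                if end is not None:
                    draw_segment(p, end)
                    secondaries.append((p, end))

    if arch.vein_order_count >= 3:
        for p0, p1 in secondaries:
            mid = (p0 + p1) / 2.0
            d = p1 - p0
            n = np.linalg.norm(d)
            if n < 6:
                continue
            d = d / n
            normal = np.array([-d[1], d[0]])
            for side in (-1.0, 1.0):
                end = _march_inside(mid, side * normal, leaf.astype(bool),
                                    max_len=0.45 * arch.secondary_vein_spacing_px)
                if end is not None:
                    draw_segment(mid, end)

    return (acc >= 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _render_leaf(arch: SpeciesArchetype, canvas: tuple[int, int],
                 instance_rng: np.random.Generator,
                 render_rng: np.random.Generator | None = None) -> LeafRecord:
    h, w = canvas
    if h < 64 or w < 64:
        raise ValueError(f"canvas {canvas} too small: minimum blade needs 64x64")
    half_len = 0.42 * min(h, w)
    center = np.array([h / 2.0, w / 2.0]) + instance_rng.uniform(-3, 3, size=2)

    poly = _blade_polygon(arch, half_len, instance_rng) + center
    leaf = np.zeros((h, w), dtype=np.uint8)
    rr, cc = skdraw.polygon(poly[:, 0], poly[:, 1], shape=(h, w))
    leaf[rr, cc] = 1
    if leaf.sum() == 0:
        raise ValueError("canvas too small to hold the minimum blade")

    skel = _vein_skeleton(arch, leaf, center, half_len, instance_rng)
    radius = (arch.vein_width_px - 1) // 2
    veins = skel.astype(bool)
    if radius > 0:
        veins = ndi.binary_dilation(veins, structure=morphology.disk(radius))
    veins = (veins & leaf.astype(bool)).astype(np.uint8)

    # pigment: jittered HSV base + smooth multiplicative texture on V
    hh = (arch.base_color_hsv[0] + instance_rng.normal(0.0, arch.color_jitter[0])) % 360.0
    ss = float(np.clip(arch.base_color_hsv[1] + instance_rng.normal(0.0, arch.color_jitter[1]), 0.05, 1.0))
    vv = float(np.clip(arch.base_color_hsv[2] + instance_rng.normal(0.0, arch.color_jitter[2]), 0.05, 0.92))
    noise = instance_rng.normal(0.0, 1.0, size=(h, w))
    texture = ndi.gaussian_filter(noise, sigma=6.0, mode="reflect")
    texture = texture / (texture.std() + 1e-12)
    # smooth illumination gradient across the blade (exercises homomorphic stage)
    gdir = instance_rng.uniform(0.0, 2.0 * np.pi)
    yy_, xx_ = np.mgrid[0:h, 0:w].astype(np.float64)
    grad = ((yy_ - h / 2) * math.cos(gdir) + (xx_ - w / 2) * math.sin(gdir)) / max(h, w)
    illum = 1.0 + arch.illum_gradient_amp * grad

    vfield = np.clip(vv * (1.0 + arch.texture_amp * texture) * illum, 0.02, 1.0)
    vfield = np.where(veins.astype(bool), np.clip(vfield + arch.vein_contrast, 0.0, 1.0), vfield)
    hsv = np.stack([np.full((h, w), hh / 360.0),
                    np.full((h, w), ss),
                    vfield], axis=2)
    rgb = skcolor.hsv2rgb(hsv)
    rgb = np.where(leaf.astype(bool)[..., None], rgb, 1.0)

    if render_rng is not None:
        angle = float(render_rng.uniform(-8.0, 8.0))
        brightness = float(render_rng.uniform(0.95, 1.05))
        rgb = np.clip(rgb * brightness, 0.0, 1.0)
        rgb = np.where(leaf.astype(bool)[..., None], rgb, 1.0)
        rgb = transform.rotate(rgb, angle, order=1, mode="constant", cval=1.0)
        leaf = transform.rotate(leaf.astype(float), angle, order=0, mode="constant",
                                cval=0.0) > 0.5
        veins = transform.rotate(veins.astype(float), angle, order=0, mode="constant",
                                 cval=0.0) > 0.5
        veins = (veins & leaf).astype(np.uint8)
        leaf = leaf.astype(np.uint8)

    rgb8 = np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)
    return LeafRecord(rgb=rgb8, vein_truth=veins.astype(np.uint8),
                      leaf_mask_truth=leaf.astype(np.uint8),
                      label=arch.name, instance_id="", split="unassigned")


def generate_leaf(archetype: SpeciesArchetype, canvas: tuple[int, int] = (224, 224),
                  rng_seed: int = 0) -> LeafRecord:
    """Render one canonical (unrotated) leaf; deterministic in all arguments."""
    rng = np.random.default_rng(rng_seed)
    rec = _render_leaf(archetype, canvas, rng, render_rng=None)
    rec.instance_id = f"{archetype.name}-{rng_seed}"
    return rec


def generate_dataset(archetypes: list[SpeciesArchetype],
                     counts_per_class: dict[str, int],
                     renders_per_instance: int = 1,
                     rng_seed: int = 0,
                     canvas: tuple[int, int] = (224, 224)) -> list[LeafRecord]:
    """Generate a labelled dataset with exact per-class counts.

    Each physical leaf instance is rendered ``renders_per_instance`` times
    (the last instance of a class may receive fewer renders to hit the exact
    count); renders of one instance share geometry and pigment and differ by
    a small rotation and illumination jitter.
    """
    names = [a.name for a in archetypes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate class names in archetype list")
    by_name = {a.name: a for a in archetypes}
    if renders_per_instance < 1:
        raise ValueError("renders_per_instance must be >= 1")
    for label, cnt in counts_per_class.items():
        if cnt < 1:
            raise ValueError(f"count for class {label!r} must be >= 1")
        if label not in by_name:
            raise ValueError(f"no archetype for class {label!r}")

    records: list[LeafRecord] = []
    for ci, label in enumerate(sorted(counts_per_class)):
        arch = by_name[label]
        n = counts_per_class[label]
        n_instances = -(-n // renders_per_instance)
        ss = np.random.SeedSequence([int(rng_seed), ci])
        inst_seeds = ss.spawn(n_instances)
        produced = 0
        for ii in range(n_instances):
            k = min(renders_per_instance, n - produced)
            render_seeds = inst_seeds[ii].spawn(k + 1)
            for r in range(k):
                # fresh instance stream per render so geometry matches across renders
                inst_rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), ci, ii]))
                render_rng = np.random.default_rng(render_seeds[r + 1])
                rec = _render_leaf(arch, canvas, inst_rng, render_rng)
                rec.instance_id = f"{label}-{ii:04d}"
                rec.path = f"{label}/{label}-{ii:04d}_{r:02d}.png"
                rec.mask_path = f"masks/{label}/{label}-{ii:04d}_{r:02d}.png"
                records.append(rec)
                produced += 1
    return records
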