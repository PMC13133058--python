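# veinfuse

Dual-branch medicinal-leaf identification: appearance **and** venation.

Leaf pigment and texture vary with maturity, lighting and season, while the
vein network is anatomically stable and species-characteristic — but a
venation-only representation throws away the color cues that separate
look-alike species. `veinfuse` keeps both cue families in play:

* a **classical vein-binarization pipeline** turns an RGB leaf photo into a
  binary vein map — Otsu segmentation with morphological closing, CLAHE,
  homomorphic illumination correction, an oriented Gabor filter bank with
  pixel-wise maximum response, weighted fusion, interior-restricted unsharp
  masking, percentile-stretched adaptive thresholding, and small-object /
  median cleanup;
* a **fused-image constructor** writes the vein map into the red channel of
  the RGB image (green/blue untouched, red ∈ {0, 255});
* a **dual-branch classifier** embeds the RGB image (1280-d) and the
  jet-colormapped vein map (1024-d) through frozen convolutional backbones,
  concatenates the pooled embeddings (2304-d) and classifies with a shared
  head — dense(128, ReLU, L2 1e-4) → dropout(0.5) → softmax — trained with
  Adam (1e-5), label smoothing (ε = 0.01), class weighting, early stopping
  and LR reduction on plateau. Four single-stream baselines (RGB-only,
  two skeleton-only variants, fused-image) share the head design;
* **class-frequency-aware augmentation**: classes under 800 samples get the
  strong tier (rotation ≤ 40°, flips, shifts, elastic distortion, Gaussian
  noise), the rest a light tier; balanced class weights `w_c = N/(K·N_c)`;
* a **procedural leaf generator** producing paired RGB images and exact
  vein/silhouette masks with independently controllable appearance and
  venation — so every stage is testable offline;
* **leakage-free splitting**: stratified by class, grouped by leaf instance,
  largest-remainder apportionment.

The head's label-smoothed, class-weighted objective is

```
L = -(1/N) Σ_i w_i Σ_c [ y_ic (1-ε) + ε/C ] log p_ic ,   ε = 0.01
```

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

## Worked example

```python
import numpy as np
from veinfuse import (SpeciesArchetype, generate_leaf, extract_veins,
                      band_precision_recall, compose_fused)
from veinfuse.model import branch_features, fuse_features, jet_colormap

arch = SpeciesArchetype(name="demo", blade_shape="ovate", vein_order_count=2,
                        secondary_vein_angle_deg=45, secondary_vein_spacing_px=25,
                        vein_width_px=3, vein_contrast=0.15)
leaf = generate_leaf(arch, canvas=(224, 224), rng_seed=0)
veins, mask, stages = extract_veins(leaf.rgb)
precision, recall = band_precision_recall(veins, leaf.vein_truth, tolerance_px=2)
print(f"leaf area: {int(mask.sum())} px, vein pixels: {int(veins.sum())}")
print(f"vein recovery vs ground truth (2 px band): precision={precision:.3f} recall={recall:.3f}")

z_rgb = branch_features(leaf.rgb, "rgb")
z_skel = branch_features(jet_colormap(veins), "skeleton")
z = fuse_features(z_rgb, z_skel)
print(f"feature dims: rgb={z_rgb.values.size} skeleton={z_skel.values.size} fused={z.values.size}")

fused = compose_fused(leaf.rgb, veins).pixels
print(f"fused red plane values: {sorted(int(v) for v in np.unique(fused[..., 0]))}")
```

prints

```
leaf area: 17230 px, vein pixels: 2645
vein recovery vs ground truth (2 px band): precision=0.832 recall=0.966
feature dims: rgb=1280 skeleton=1024 fused=2304
fused red plane values: [0, 255]
```

The pipeline recovers 96.6% of the true vein skeleton within a 2-px band
at 83% precision on this leaf, and the feature dimension chain
1280 + 1024 = 2304 holds by construction.

## Command line

```bash
veinfuse synth --out data/ --per-class 30 --renders-per-instance 2 --seed 0
veinfuse split --manifest data/manifest.csv --seed 0
veinfuse extract-veins --in data/ --out veins/ [--config cfg.yaml] [--thin]
veinfuse fuse --rgb data/ --veins veins/ --out fused/
veinfuse train --variant dual --data data/manifest.csv --seed 0 --out run/
veinfuse evaluate --run run/ --split test
```

`evaluate` writes `report.json`, `confusion.csv`, per-class PR/ROC curve
CSVs and a rendered plot.

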