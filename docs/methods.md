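# Methods

## Problem and approach

Medicinal-plant species identification from leaf photographs is hard when it
relies on appearance alone: pigment and texture vary with maturity, lighting
and season, while visually similar species (e.g. mint-like herbs) can share
their RGB statistics almost entirely. Leaf venation — the vascular network —
is anatomically stable and species-characteristic, but a venation-only
representation discards the color and texture cues that separate
morphologically similar species. `veinfuse` implements a dual-stream design
that keeps both cue families separate until late in the model: one branch
embeds the RGB image, the other embeds a binary vein map extracted from the
same image by a classical pipeline, and the two pooled embeddings are
concatenated before a shared classifier.

## Vein binarization pipeline

The vein map is produced from an RGB leaf photo on a clean background by a
fixed sequence of classical operations:

1. **Leaf segmentation** — Otsu thresholding on the BT.601 grayscale image
   (exhaustive 256-bin between-class-variance scan), keeping the side of the
   threshold with lower image-border occupancy as foreground, retaining the
   largest connected component, morphological closing with an elliptical
   element (default 7×7) and hole filling. Otsu's objective is flat across
   empty histogram gaps; the threshold is taken at the midpoint of the
   maximizing set so well-separated bimodal images threshold between the
   modes.
2. **CLAHE** — per-tile (default 8×8) histogram equalization with the
   histogram clipped at `clip` (default 2.0) times the mean bin height,
   clipped excess redistributed uniformly, and bilinear blending of the four
   nearest tile mappings per pixel. A constant image short-circuits to
   itself. This is the standard clip-redistribute algorithm; with one tile
   and an unbounded clip it reduces exactly to plain histogram equalization
   with the `cdf(l)/n` mapping.
3. **Homomorphic filtering** — `log(1+I)` (the +1 offset handles zero
   pixels), 2-D FFT, multiplication by
   `H(u,v) = B + A·(1 − exp(−k·D²/D0²))` with `D` the distance from the
   centered zero frequency in index units (defaults A=1.5, B=0.5, k=1,
   D0=30), inverse transform, `expm1`, min-max normalization. High spatial
   frequencies (reflectance detail, veins) gain by `A+B` while the
   illumination field is attenuated to `B`.
4. **Gabor bank** — oriented Gaussian-windowed cosine kernels
   (λ=8, σ=4, γ=0.5, ψ=0) at orientations {0,30,60,90,120,150}° and kernel
   sizes {15, 21}; the pixel-wise maximum over the bank preserves the
   strongest vein evidence whatever the local vein direction, and is
   approximately invariant to rotating the input by one orientation step.
5. **Weighted fusion** — `0.5·homomorphic + 0.5·gabor` (equal weighting),
   optional bias, clipped to range.
6. **Unsharp masking** — `I + α(I − G_σ(I))` (α=1, σ=2) applied only on the
   eroded leaf interior so the silhouette edge produces no halo.
7. **Adaptive thresholding** — percentile contrast stretch (2nd/98th) then
   `value > local_mean(window) + C` with a 25-px window and C=5 (0–255
   scale). Veins are the locally *bright* structures of the enhanced image
   (the Gabor maximum renders them bright regardless of raw polarity), so
   the offset is demanded *above* the local mean; a constant input yields an
   empty mask by a dynamic-range short-circuit.
8. **Cleanup** — 8-connected components below 30 px removed, optional
   morphological opening, 3×3 median filter. The default opening element is
   the identity: at the working resolution (~3-px veins) any nontrivial
   opening erases the detected centerlines, which are typically 2 px wide;
   for higher-resolution imagery the element should be enlarged via the
   config.

The final mask is intersected with the eroded leaf interior — the
silhouette edge is itself a strong oriented structure and would otherwise
dominate the margin. All neighborhood operations use reflect padding.
Every numeric parameter lives in `VeinPipelineConfig` and is declared, not
fitted; the defaults are conventional choices for ~224-px leaf images.
An optional `--thin` flag applies morphological skeletonization (1-px
centerlines); it is off by default because the pipeline as described ends
at median filtering.

## Fused image

The fused leaf keeps the source's green and blue channels bit-identical and
replaces the red channel with the vein map at full intensity, so
thresholding the red plane recovers the mask exactly. Vein maps of
mismatched size are resampled by nearest neighbor and re-binarized at 0.5.

## Classifier

Both branches resize to 224×224 and normalize per the backbone convention
([-1,1] for the MobileNetV2-style branch; ImageNet mean/std for the
DenseNet/EfficientNet-style branches). The vein map is lifted to three
channels by the jet colormap, which on a binary domain reduces to its two
endpoints (0 → (0,0,128), 1 → (128,0,0)).

The backbones are forward-only convolutional stacks written in numpy that
echo the design idioms of the architectures they are named after —
depthwise-separable (1280-d output), dense-concatenation (1024-d),
expand/depthwise/project (1280-d) — with He-initialized weights drawn once
from a fixed per-architecture seed and **never trained** (the
random-features paradigm: a frozen random convolutional embedding plus a
trained readout). The published dimension chain is preserved exactly:
1280 (RGB) + 1024 (skeleton) = 2304 fused.

The trainable head is dense(128, ReLU, L2 λ=1e-4) → dropout(0.5) →
dense(C) → softmax. Pooled features first pass a fixed standardization
layer (per-dimension mean/scale frozen from the training set, times a gain
of 10) — the GAP → normalization → dense idiom — which places the head's
operating point where the small configured learning rate (Adam, 1e-5)
makes productive progress. Training uses batch size 16, label-smoothed
(ε=0.01) class-weighted categorical cross-entropy, early stopping on
validation loss (patience 10), learning-rate halving on plateau
(patience 5), and restores the best-validation weights. With frozen
backbones, per-record branch features are computed once and cached; only
the head iterates.

Five variants share this head: `dual` (both branches), `rgb_only`,
`skeleton_densenet`, `skeleton_efficientnet` (1280-d), and
`fused_densenet` (DenseNet-style branch on fused images).
`weights_mode='random-frozen'` is the only operating mode:
no pretrained weight source exists for these from-scratch backbones, and
backbone fine-tuning is out of scope.

## Class imbalance

Classes with fewer than 800 samples (strict `<`) are minority classes and
receive the strong augmentation tier: rotation up to 40°, horizontal and
vertical flips, shifts up to 10%, elastic distortion (α=40, σ=6) and
additive Gaussian noise with variance drawn from [0.005, 0.02]. Majority
classes receive the light tier: rotation ≤ 15°, horizontal flip, shift
≤ 5%, no elastic or noise. Magnitudes are package defaults (the transform
families are fixed, their strengths are configurable). Augmentation is
applied online — paired geometric transforms for RGB+mask, photometric
noise for RGB only — rather than by inflating the dataset, so split counts
stay fixed. Class weights are balanced inverse frequencies
`w_c = N/(K·N_c)`, whose sample-weighted mean is exactly 1.

## Splitting

Train/val/test assignment (default 0.8/0.1/0.1) is stratified by class and
grouped by leaf instance: all renders of one physical leaf land in the same
subset, preventing appearance leakage. Per class, instance groups are
apportioned to the three subsets by largest remainder (with a final
adjustment guaranteeing each subset at least one group), after a seeded
shuffle of the sorted group list — so the split is deterministic under the
seed and invariant to input record order. A class with fewer than three
instance groups is rejected.

## Synthetic data generator

The generator renders single leaves on a uniform white background. The
blade outline is a parametric polar curve (ovate, lanceolate, round or
lobed, with optional sawtooth serration and a small random harmonic
perturbation). The venation tree is drawn as anti-aliased polylines
re-binarized at 0.5 and dilated to the requested width: a gently curved
midrib, paired secondaries inserted at a fixed angle and spacing that
extend to the blade margin, and optional short tertiaries. Pigment is a
jittered HSV base color with smooth multiplicative texture and a mild
linear illumination gradient (which exercises the homomorphic stage);
veins are brightened by a configurable contrast in the value channel.
Renders of one instance share geometry and pigment and differ by a small
rotation (±8°) and brightness factor (±5%).

Appearance (color, texture, serration) and venation (order count, angle,
spacing, width) parameters are independent, so archetype sets can be built
that differ in exactly one cue family. Two such sets ship with the package:
an appearance-separable trio and a venation-only trio whose classes share
all appearance parameters (with tight jitter, so per-channel mean colors
agree to < 2/255 over 50 canonical renders) and differ only in venation —
the condition under which the skeleton branch carries all class signal.

What the generator does **not** emulate: photorealistic texture, specular
highlights, disease states, background clutter, shadows, occlusion, or 3-D
pose. Passing tests therefore demonstrate that the pipeline and the
classifiers behave as specified under controlled conditions, not that the
reported field accuracies transfer to photographs.

## Problem sizes and experiment design

The learning experiments use three-class datasets of 210 leaves
(150 train / 30 val / 30 test, 50/10/10 per class) at 224×224, trained for
up to 30 epochs; vein recovery is measured on 30 leaves with 3-px veins at
25-px spacing against ground truth with a 2-px tolerance band; statements
about variant orderings use the median over 3 training seeds. These sizes
were chosen so the full suite and the acceptance script run comfortably on
a single CPU while leaving the measured effects (e.g. a ≥ 15-point accuracy
gap between venation-aware and RGB-only variants on venation-only data)
far from their thresholds.

## Known limitations

* The frozen random backbones are far weaker feature extractors than
  ImageNet-pretrained networks; absolute accuracies on hard synthetic
  conditions are not comparable with published numbers on curated
  photographic corpora.
* The vein pipeline assumes a single leaf on a near-uniform light
  background (the corpus convention); multi-leaf scenes and cluttered
  backgrounds are out of scope.
* Opening with the default identity element makes stage 8 effectively
  area-filter + median at 224-px scale; at higher resolutions the opening
  element and `min_object_area` should be scaled with vein width.
* Online augmentation with frozen backbones implies re-extracting features
  for augmented copies; the trainer therefore trains on unaugmented cached
  features by default, and the augmentation module is exposed for pipelines
  that precompute augmented variants.
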