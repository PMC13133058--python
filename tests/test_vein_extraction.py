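"""Stage-level oracles and pipeline properties for vein binarization."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from veinfuse.vein_extraction import (
    StructuringElement,
    VeinPipelineConfig,
    VeinPipelineError,
    adaptive_binarize,
    band_precision_recall,
    clahe,
    clean_mask,
    extract_veins,
    gabor_kernel,
    gabor_max_response,
    homomorphic_filter,
    leaf_mask,
    otsu_threshold,
    to_grayscale,
    unsharp_sharpen,
    weighted_fuse,
)


# ---------------------------------------------------------------------------
# grayscale
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("rgb,expected", [
    ((255, 255, 255), 255),
    ((255, 0, 0), 76),  # 0.299 * 255, rounded
    ((0, 255, 0), 150),
    ((40, 40, 40), 40),
])
def test_grayscale_bt601(rgb, expected):
    img = np.full((4, 4, 3), rgb, dtype=np.uint8)
    assert np.all(to_grayscale(img) == expected)


def test_grayscale_rejects_single_channel():
    with pytest.raises(ValueError):
        to_grayscale(np.zeros((4, 4), dtype=np.uint8))


# ---------------------------------------------------------------------------
# Otsu
# ---------------------------------------------------------------------------

def brute_force_otsu(levels: np.ndarray) -> int:
    """Independent exhaustive scan over all 256 candidate thresholds.

    Ties (the variance is flat across empty histogram gaps) resolve to the
    midpoint of the maximizing set, matching the shipped convention.
    """
    vals = levels.ravel()
    variances = np.full(256, -1.0)
    for t in range(256):
        lo, hi = vals[vals <= t], vals[vals > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / vals.size, hi.size / vals.size
        variances[t] = w0 * w1 * (lo.mean() - hi.mean()) ** 2
    maximizers = np.flatnonzero(variances == variances.max())
    return int(round(maximizers.mean()))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_otsu_matches_exhaustive_scan(seed):
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, size=(40, 40)).astype(np.uint8)
    t, mask = otsu_threshold(img)
    assert t == brute_force_otsu(img.astype(np.int64))
    assert np.array_equal(mask, (img > t).astype(np.uint8))


def test_otsu_separates_half_and_half():
    img = np.zeros((10, 10), dtype=np.uint8)
    img[:, 5:] = 255
    t, mask = otsu_threshold(img)
    assert t == brute_force_otsu(img.astype(np.int64))
    assert mask.sum() == 50


def test_otsu_bimodal_mixture():
    rng = np.random.default_rng(0)
    samples = np.concatenate([rng.normal(60, 10, 500), rng.normal(200, 10, 500)])
    img = np.clip(samples, 0, 255).astype(np.uint8).reshape(25, 40)
    t, _ = otsu_threshold(img)
    assert abs(t - 130) <= 15


def test_otsu_constant_image_degenerate():
    img = np.full((8, 8), 77, dtype=np.uint8)
    t, mask = otsu_threshold(img)
    assert t == 77.0
    assert mask.sum() == 0


# ---------------------------------------------------------------------------
# leaf mask
# ---------------------------------------------------------------------------

def test_leaf_mask_recovers_synthetic_silhouette(sample_leaf):
    mask = leaf_mask(sample_leaf.rgb, StructuringElement("ellipse", 7))
    truth = sample_leaf.leaf_mask_truth.astype(bool)
    inter = (mask.astype(bool) & truth).sum()
    union = (mask.astype(bool) | truth).sum()
    assert inter / union >= 0.95


def test_leaf_mask_keeps_largest_blob_only():
    img = np.full((60, 60, 3), 255, dtype=np.uint8)
    img[10:35, 10:30] = 30  # 500 px blob
    img[45:50, 45:49] = 30  # 20 px blob
    mask = leaf_mask(img, StructuringElement("ellipse", 3))
    assert mask[12, 12] == 1
    assert mask[47, 47] == 0


def test_leaf_mask_fills_interior_hole():
    img = np.full((60, 60, 3), 255, dtype=np.uint8)
    img[10:40, 10:40] = 30
    img[20, 20] = 255  # 1-px hole
    mask = leaf_mask(img, StructuringElement("ellipse", 3))
    assert mask[20, 20] == 1


def test_leaf_mask_blank_image_fails():
    img = np.full((60, 60, 3), 255, dtype=np.uint8)
    with pytest.raises(VeinPipelineError, match="empty foreground"):
        leaf_mask(img)


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------

def test_clahe_constant_is_identity():
    img = np.full((64, 64), 90, dtype=np.uint8)
    assert np.array_equal(clahe(img, tiles=8, clip=2.0), img)


def test_clahe_expands_low_contrast_ramp():
    ramp = np.tile(np.linspace(100, 130, 64).astype(np.uint8), (64, 1))
    out = clahe(ramp, tiles=4, clip=2.0)
    assert int(out.max()) - int(out.min()) > int(ramp.max()) - int(ramp.min())


def test_clahe_unclipped_single_tile_equals_equalization():
    rng = np.random.default_rng(1)
    img = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
    out = clahe(img, tiles=1, clip=1e9)
    # independent equalization oracle: map level l to cdf(l)/n
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(hist) / img.size
    expected = np.clip(np.rint(cdf[img.astype(int)] * 255), 0, 255).astype(np.uint8)
    assert np.array_equal(out, expected)


def test_clahe_oversized_tile_grid_reduced():
    img = np.tile(np.linspace(0, 255, 16).astype(np.uint8), (8, 1))
    out = clahe(img, tiles=64, clip=2.0)  # grid larger than the image
    assert out.shape == img.shape


# ---------------------------------------------------------------------------
# homomorphic filter
# ---------------------------------------------------------------------------

def test_homomorphic_boosts_stripes_over_gradient():
    """High-frequency reflectance must gain relative to low-frequency shading."""
    h = w = 128
    yy, xx = np.mgrid[0:h, 0:w]
    gradient = 0.5 + 0.4 * (xx / w - 0.5)  # one-cycle illumination ramp
    stripes = 1.0 + 0.2 * np.cos(2 * np.pi * xx / 8.0)  # 16 cycles
    img = np.clip(gradient * stripes, 0, 1)
    out = homomorphic_filter(img, A=1.5, B=0.5, k=1.0, D0=30.0)

    def amplitude(im, cycles):
        return np.abs(np.fft.fft2(im)[0, cycles])

    stripe_gain = amplitude(out, 16) / amplitude(img, 16)
    gradient_gain = amplitude(out, 1) / amplitude(img, 1)
    assert stripe_gain > gradient_gain


def test_homomorphic_rejects_bad_cutoff():
    with pytest.raises(ValueError):
        homomorphic_filter(np.ones((16, 16)) * 0.5, D0=0.0)


# ---------------------------------------------------------------------------
# Gabor bank
# ---------------------------------------------------------------------------

def test_gabor_kernel_origin_value_is_one():
    ker = gabor_kernel(15, theta_deg=30.0, lam=8.0, sigma=4.0, gamma=0.5, psi=0.0)
    assert ker[7, 7] == pytest.approx(1.0)


def test_gabor_kernel_even_size_rejected():
    with pytest.raises(ValueError):
        gabor_kernel(14, 0.0, 8.0, 4.0, 0.5)


def test_gabor_theta0_prefers_vertical_lines():
    cfg = VeinPipelineConfig(gabor_orientations_deg=(0.0,), gabor_scales=(15,))
    vert = np.zeros((64, 64))
    vert[:, 31:33] = 1.0
    horz = vert.T.copy()
    rv = gabor_max_response(vert, cfg)
    rh = gabor_max_response(horz, cfg)
    assert rv[32, 31:33].mean() >= rh[31:33, 32].mean()


def test_gabor_bank_rotation_invariance(sample_leaf):
    """Max over the 6-orientation bank is stable under 30-degree rotation."""
    from skimage import transform

    cfg = VeinPipelineConfig()
    gray = to_grayscale(sample_leaf.rgb).astype(np.float64) / 255.0
    rot = transform.rotate(gray, 30.0, mode="edge")
    resp_then_rot = transform.rotate(gabor_max_response(gray, cfg), 30.0, mode="edge")
    rot_then_resp = gabor_max_response(rot, cfg)
    center = (slice(60, 164), slice(60, 164))  # ignore rotation borders
    diff = np.abs(resp_then_rot[center] - rot_then_resp[center]).mean()
    assert diff < 0.03


# ---------------------------------------------------------------------------
# fusion / sharpening
# ---------------------------------------------------------------------------

def test_weighted_fuse_identity_and_selection():
    img = np.random.default_rng(0).random((16, 16))
    assert np.allclose(weighted_fuse(img, img, 0.5, 0.5, 0.0), img)
    other = np.zeros_like(img)
    assert np.allclose(weighted_fuse(img, other, 1.0, 0.0, 0.0), img)


def test_weighted_fuse_arithmetic():
    a = np.full((8, 8), 100, dtype=np.uint8)
    b = np.full((8, 8), 200, dtype=np.uint8)
    assert np.all(weighted_fuse(a, b, 0.5, 0.5, 10.0) == 160)


def test_weighted_fuse_rejects_bad_weights_and_shapes():
    img = np.zeros((8, 8))
    with pytest.raises(ValueError):
        weighted_fuse(img, img, 0.7, 0.5)
    with pytest.raises(ValueError):
        weighted_fuse(img, np.zeros((8, 9)))


def test_unsharp_constant_unchanged():
    img = np.full((32, 32), 0.5)
    out = unsharp_sharpen(img, alpha=1.0, sigma=2.0)
    assert np.allclose(out, img)


def test_unsharp_outside_interior_untouched_and_edge_enhanced():
    img = np.zeros((32, 32))
    img[:, 16:] = 0.8  # step edge
    interior = np.zeros((32, 32), dtype=np.uint8)
    interior[8:24, 8:24] = 1
    out = unsharp_sharpen(img, alpha=1.0, sigma=2.0, interior=interior)
    assert np.array_equal(out[interior == 0], img[interior == 0])
    band = (slice(8, 24), slice(13, 19))
    assert out[band].max() - out[band].min() > img[band].max() - img[band].min()


def test_unsharp_rejects_negative_alpha():
    with pytest.raises(ValueError):
        unsharp_sharpen(np.zeros((8, 8)), alpha=-1.0)


# ---------------------------------------------------------------------------
# adaptive threshold
# ---------------------------------------------------------------------------

def brute_force_adaptive(img: np.ndarray, window: int, C: float,
                         percentiles: tuple) -> np.ndarray:
    """O(N^2 window^2) double-loop reimplementation with symmetric padding."""
    arr = np.asarray(img, np.float64)
    lo, hi = np.percentile(arr, percentiles)
    stretched = np.clip((arr - lo) / (hi - lo), 0, 1)
    half = window // 2
    padded = np.pad(stretched, half, mode="symmetric")
    out = np.zeros(arr.shape, dtype=np.uint8)
    for y in range(arr.shape[0]):
        for x in range(arr.shape[1]):
            mean = padded[y:y + window, x:x + window].mean()
            out[y, x] = stretched[y, x] > mean + C / 255.0
    return out


@pytest.mark.parametrize("seed,window", [(0, 5), (1, 9), (2, 15)])
def test_adaptive_binarize_matches_double_loop(seed, window):
    rng = np.random.default_rng(seed)
    img = rng.random((32, 32))
    got = adaptive_binarize(img, window=window, C=5.0, percentiles=(2, 98))
    expected = brute_force_adaptive(img, window, 5.0, (2, 98))
    assert np.array_equal(got, expected)


def test_adaptive_binarize_marks_bright_line_only():
    img = np.full((40, 40), 100, dtype=np.uint8)
    img[:, 20] = 200
    mask = adaptive_binarize(img, window=15, C=5.0, percentiles=(0, 100))
    assert np.all(mask[:, 20] == 1)
    assert np.all(mask[:, :10] == 0)


def test_adaptive_binarize_constant_gives_empty_mask():
    img = np.full((32, 32), 0.4)
    assert adaptive_binarize(img, window=5, C=5.0).sum() == 0


def test_adaptive_binarize_rejects_bad_window():
    img = np.zeros((16, 16))
    with pytest.raises(ValueError):
        adaptive_binarize(img, window=4)
    with pytest.raises(ValueError):
        adaptive_binarize(img, window=17)


# ---------------------------------------------------------------------------
# cleanup
# ---------------------------------------------------------------------------

def test_clean_mask_removes_isolated_pixel():
    mask = np.zeros((20, 20), dtype=np.uint8)
    mask[10, 10] = 1
    assert clean_mask(mask, min_area=5, opening_se=None, median_kernel=1).sum() == 0


def test_clean_mask_opening_idempotent():
    rng = np.random.default_rng(3)
    mask = (rng.random((48, 48)) > 0.6).astype(np.uint8)
    se = StructuringElement("ellipse", 3)
    once = clean_mask(mask, min_area=0, opening_se=se, median_kernel=1)
    twice = clean_mask(once, min_area=0, opening_se=se, median_kernel=1)
    assert np.array_equal(once, twice)


def test_clean_mask_keeps_line_drops_speckles():
    rng = np.random.default_rng(7)
    mask = np.zeros((64, 64), dtype=np.uint8)
    mask[30:33, 5:60] = 1  # 3-px-wide line
    speckles = 0
    while speckles < 50:
        y, x = rng.integers(0, 64, 2)
        if not mask[max(0, y - 2):y + 3, max(0, x - 2):x + 3].any():
            mask[y, x] = 1
            speckles += 1
    out = clean_mask(mask, min_area=30, opening_se=None, median_kernel=1)
    assert np.array_equal(out[30:33, 5:60], np.ones((3, 55), dtype=np.uint8))
    assert out.sum() == 3 * 55


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def test_extract_veins_recovers_truth(vein_archetype):
    from veinfuse.synthetic_leaf import generate_leaf

    precs, recs = [], []
    for seed in range(4):
        rec = generate_leaf(vein_archetype, (224, 224), rng_seed=seed)
        veins, leaf, _ = extract_veins(rec.rgb)
        p, r = band_precision_recall(veins, rec.vein_truth, tolerance_px=2)
        precs.append(p)
        recs.append(r)
        assert not np.any(veins.astype(bool) & ~leaf.astype(bool))
        assert set(np.unique(veins)).issubset({0, 1})
    assert np.mean(recs) >= 0.7
    assert np.mean(precs) >= 0.6


def test_extract_veins_stage_dimensions(sample_leaf):
    veins, leaf, inter = extract_veins(sample_leaf.rgb)
    for name, img in inter.items():
        assert img.shape[:2] == sample_leaf.rgb.shape[:2], name
    assert veins.shape == leaf.shape == sample_leaf.rgb.shape[:2]


def test_extract_veins_blank_image_reports_stage():
    blank = np.full((96, 96, 3), 255, dtype=np.uint8)
    with pytest.raises(VeinPipelineError, match="empty foreground"):
        extract_veins(blank)


def test_extract_veins_thin_flag_produces_thinner_mask(sample_leaf):
    veins, _, _ = extract_veins(sample_leaf.rgb)
    thinned, _, _ = extract_veins(sample_leaf.rgb, thin=True)
    assert 0 < thinned.sum() < veins.sum()


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_otsu_scan_equivalence_property(seed):
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
    t, _ = otsu_threshold(img)
    assert t == brute_force_otsu(img.astype(np.int64))


@settings(max_examples=10, deadline=None)
@given(st.integers(0, 2**32 - 1), st.sampled_from([3, 7, 11]))
def test_adaptive_binarize_oracle_property(seed, window):
    rng = np.random.default_rng(seed)
    img = rng.random((20, 20))
    got = adaptive_binarize(img, window=window, C=5.0, percentiles=(2, 98))
    assert np.array_equal(got, brute_force_adaptive(img, window, 5.0, (2, 98)))
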