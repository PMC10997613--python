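"""Object detection (eggs, black feces) and damage segmentation on single leaves.

The detection contract is backend-agnostic: a backend takes a leaf image
with its mask and physical scale and returns scored detections (eggs,
feces) or a per-pixel mask (damage).  Confidences live in [0, 1] and are
filtered by user-adjustable significance levels — eggs within [0.8, 0.95],
black feces within [0.5, 0.95]; the damage threshold is fixed and not a
user level.  This module implements the deterministic classical backend;
:mod:`mitescan.trainable` provides a trainable one with the same contract.

Classical backend:

* eggs — band-pass (difference-of-Gaussians) response of luminance at the
  egg scale; local maxima with hysteresis support; kept when the support's
  equivalent diameter is 70–200 µm and circularity ≥ 0.6.  Confidence maps
  the band-pass contrast onto [0, 1].  On the adaxial side, air-bubble
  confounders (bright rim, darker core) are rejected by their
  rim-versus-core polarity, and support must lie on the leaf;
* black feces — darkness map (local background luminance minus pixel
  luminance; background via large-scale grey closing inside the leaf);
  connected dark components with equivalent diameter 40–250 µm; confidence
  from normalised mean contrast;
* damage — per-pixel chlorosis score (loss of green chroma plus brightness
  shift relative to the leaf's median colour), fixed threshold,
  morphological opening at the 100 µm scale, small-speck removal.

Also here: the patch/split machinery used when training a backend
(128×128 tiling with per-patch standardisation, 5-iteration mask dilation,
and the deterministic 80-10-10 dataset split).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology
from skimage.filters import rank

from .scan_io import ABAXIAL, ADAXIAL, SIDES

__all__ = [
    "Detection",
    "DamageMask",
    "SignificanceLevels",
    "ClassicalParams",
    "detect_eggs",
    "detect_feces",
    "segment_damage",
    "make_patches",
    "dilate_mask",
    "split_dataset",
]

EGG_LEVEL_RANGE = (0.8, 0.95)
FECES_LEVEL_RANGE = (0.5, 0.95)


@dataclass(frozen=True)
class SignificanceLevels:
    """Detector confidence cutoffs.  Damage has no user level (fixed)."""

    eggs: float = 0.90
    black_feces: float = 0.75

    def __post_init__(self) -> None:
        lo, hi = EGG_LEVEL_RANGE
        if not lo <= self.eggs <= hi:
            raise ValueError(f"egg significance level must be within [{lo}, {hi}]")
        lo, hi = FECES_LEVEL_RANGE
        if not lo <= self.black_feces <= hi:
            raise ValueError(f"black-feces significance level must be within [{lo}, {hi}]")


@dataclass
class Detection:
    """One detected egg or black-feces object on a leaf side."""

    klass: str  # "egg" | "black_feces"
    box: tuple[int, int, int, int]  # half-open (r0, c0, r1, c1), image coords
    confidence: float
    side: str
    leaf_index: int = -1
    area_mm2: float = 0.0  # support area; counts are the measure for eggs
    center: tuple[float, float] = (0.0, 0.0)
    object_id: str = ""
    manual: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")


@dataclass
class DamageMask:
    """Per-pixel feeding-damage segmentation of one leaf side."""

    leaf_index: int
    side: str
    mask: np.ndarray  # bool, cropped to the leaf bbox
    bbox: tuple[int, int, int, int]
    area_mm2: float


@dataclass(frozen=True)
class ClassicalParams:
    """Tunables of the classical backend (sizes in µm, contrasts in 8-bit DN)."""

    egg_diameter_um: tuple[float, float] = (70.0, 200.0)
    egg_scale_um: float = 125.0  # nominal egg diameter setting the DoG scale
    egg_min_circularity: float = 0.6
    egg_contrast_span: tuple[float, float] = (3.0, 11.0)  # DoG DN -> conf 0..1
    egg_support_frac: float = 0.3  # hysteresis low level as fraction of high
    egg_min_chroma: float = 12.0  # below this the support is neutral tape/glue
    egg_min_warmth: float = 15.0  # R−B of the egg core; bubbles are neutral
    egg_core_min_lum: float = 165.0  # glossy egg centre; chlorosis is dimmer
    bubble_rim_margin: float = 8.0  # DN by which a rim must beat the core
    feces_diameter_um: tuple[float, float] = (40.0, 250.0)
    feces_min_contrast: float = 25.0  # darkness DN for support pixels
    feces_contrast_span: tuple[float, float] = (20.0, 60.0)
    feces_background_um: float = 600.0  # grey-closing window
    damage_threshold: float = 40.0  # fixed chlorosis-score cutoff
    damage_opening_um: float = 100.0
    damage_min_area_mm2: float = 0.05  # specks below this are not feeding lesions


DEFAULT_PARAMS = ClassicalParams()


def _luminance(pixels: np.ndarray) -> np.ndarray:
    return pixels.astype(np.float64).mean(axis=2)


def _check_inputs(pixels: np.ndarray, mask: np.ndarray, um_per_px: float) -> None:
    if mask is None or not np.any(mask):
        raise ValueError("leaf mask is empty")
    if not (um_per_px and um_per_px > 0):
        raise ValueError("um_per_px must be provided and positive")
    if pixels.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes differ")


def detect_eggs(
    pixels: np.ndarray,
    mask: np.ndarray,
    side: str,
    um_per_px: float,
    levels: SignificanceLevels = SignificanceLevels(),
    params: ClassicalParams = DEFAULT_PARAMS,
    leaf_index: int = -1,
) -> list[Detection]:
    """Detect mite eggs on one leaf crop.  Deterministic.

    ``pixels``/``mask`` are the leaf's bbox crop; returned boxes and centres
    are in crop coordinates.
    """
    _check_inputs(pixels, mask, um_per_px)
    L = _luminance(pixels)
    pxf = pixels.astype(np.float64)
    chroma = pxf.max(axis=2) - pxf.min(axis=2)
    r_px = params.egg_scale_um / um_per_px / 2.0
    s1 = max(r_px / math.sqrt(2.0), 0.6)
    dog = ndi.gaussian_filter(L, s1) - ndi.gaussian_filter(L, 1.6 * s1)

    inside = dog[mask]
    med = np.median(inside)
    noise = 1.4826 * np.median(np.abs(inside - med)) + 1e-9
    thr_high = max(5.0 * noise, params.egg_contrast_span[0])
    support = filters.apply_hysteresis_threshold(
        dog, params.egg_support_frac * thr_high, thr_high)
    support &= mask

    labels, n = ndi.label(support)
    dets: list[Detection] = []
    lo_d, hi_d = params.egg_diameter_um
    for prop in measure.regionprops(labels, intensity_image=dog):
        eq_d_um = prop.equivalent_diameter_area * um_per_px
        if not lo_d <= eq_d_um <= hi_d:
            continue
        perim = prop.perimeter_crofton or prop.perimeter or 1.0
        circ = 4.0 * math.pi * prop.area / (perim**2)
        if min(circ, 1.5) < params.egg_min_circularity:
            continue
        peak = float(prop.intensity_max)
        c0_, c1_ = params.egg_contrast_span
        conf = float(np.clip((peak - c0_) / (c1_ - c0_), 0.0, 1.0))
        if conf < levels.eggs:
            continue
        # the egg core (brightest quartile of the support) must be both
        # bright (glossy chorion) and coloured — bare tape is neutral and
        # chlorotic tissue never reaches egg-core luminance
        rs, cs = prop.coords[:, 0], prop.coords[:, 1]
        svals = L[rs, cs]
        bright = svals >= np.quantile(svals, 0.9)
        if float(svals[bright].mean()) < params.egg_core_min_lum:
            continue
        if float(np.median(chroma[rs[bright], cs[bright]])) < params.egg_min_chroma:
            continue
        # chorion has a warm cast (R > B); air bubbles stay neutral even
        # when optical blur tints them with the surrounding leaf
        warmth = pxf[:, :, 0] - pxf[:, :, 2]
        if float(np.median(warmth[rs[bright], cs[bright]])) < params.egg_min_warmth:
            continue
        cr, cc = prop.centroid
        if side == ADAXIAL and _is_bubble(L, mask, (cr, cc),
                                          prop.equivalent_diameter_area / 2.0,
                                          params.bubble_rim_margin):
            continue
        r0, c0b, r1, c1b = prop.bbox
        dets.append(Detection(
            klass="egg", box=(r0, c0b, r1, c1b), confidence=conf, side=side,
            leaf_index=leaf_index, area_mm2=prop.area * (um_per_px / 1000.0) ** 2,
            center=(float(cr), float(cc)),
            object_id=f"egg_{side[:2]}_{leaf_index}_{r0}_{c0b}"))
    return dets


def _is_bubble(L: np.ndarray, mask: np.ndarray, center: tuple[float, float],
               r_px: float, rim_margin: float) -> bool:
    """Air-bubble check: a bubble ring is brighter at its rim than its core,
    while an egg is brightest in the middle; support off the leaf also marks
    a bubble."""
    cr, cc = center
    R = max(r_px, 2.0)
    w = int(math.ceil(1.5 * R)) + 1
    r0, r1 = int(cr) - w, int(cr) + w + 1
    c0, c1 = int(cc) - w, int(cc) + w + 1
    if r0 < 0 or c0 < 0 or r1 > L.shape[0] or c1 > L.shape[1]:
        return True  # support at the image border is never an on-leaf egg
    sub = L[r0:r1, c0:c1]
    msub = mask[r0:r1, c0:c1]
    rows, cols = np.mgrid[r0:r1, c0:c1]
    rho = np.hypot(rows - cr, cols - cc) / R
    core = rho <= 0.5
    rim = (rho >= 0.85) & (rho <= 1.25)
    if msub[core].size and not msub[core].all():
        return True  # support extends outside the leaf
    if not core.any() or not rim.any():
        return False
    core_mean = float(sub[core].mean())
    rim_vals = np.sort(sub[rim].ravel())
    rim_bright = float(rim_vals[int(0.75 * len(rim_vals)):].mean())
    return rim_bright > core_mean + rim_margin


def detect_feces(
    pixels: np.ndarray,
    mask: np.ndarray,
    side: str,
    um_per_px: float,
    levels: SignificanceLevels = SignificanceLevels(),
    params: ClassicalParams = DEFAULT_PARAMS,
    leaf_index: int = -1,
) -> list[Detection]:
    """Detect black fecal pellets on one leaf crop.  Deterministic."""
    _check_inputs(pixels, mask, um_per_px)
    L = _luminance(pixels)
    leaf_med = float(np.median(L[mask]))
    Lf = np.where(mask, L, leaf_med)
    win = max(int(round(params.feces_background_um / um_per_px)), 3)
    # local background by a true running median: robust both to the dark
    # pellets themselves and to bright structures (chlorosis, tape at the
    # petiole notch) that would bias a morphological estimate
    Lu = np.clip(Lf, 0, 255).astype(np.uint8)
    background = rank.median(Lu, footprint=np.ones((win, win), bool)).astype(np.float64)
    darkness = background - Lf

    # support must be dark both relative to the local background and in
    # absolute terms: green tissue enclosed by bright chlorosis is locally
    # dark but is not a pellet
    support = ((darkness > params.feces_min_contrast)
               & (Lf < leaf_med - params.feces_min_contrast) & mask)
    # bridge 1-px gaps so one pellet is one component
    support = ndi.binary_closing(support, structure=np.ones((3, 3), bool)) & mask
    labels, n = ndi.label(support)
    dets: list[Detection] = []
    lo_d, hi_d = params.feces_diameter_um
    px_area = (um_per_px / 1000.0) ** 2
    for prop in measure.regionprops(labels, intensity_image=darkness):
        # refine the support at half the object's peak contrast: optical blur
        # smears a dark pellet into a halo and the low absolute threshold
        # would overstate its area
        r0, c0b, r1, c1b = prop.bbox
        sub_dark = darkness[r0:r1, c0b:c1b]
        sub_lab = labels[r0:r1, c0b:c1b] == prop.label
        peak = float(prop.intensity_max)
        refined = sub_lab & (sub_dark >= max(params.feces_min_contrast, 0.5 * peak))
        area_px = int(np.count_nonzero(refined))
        if area_px == 0:
            continue
        eq_d_um = 2.0 * math.sqrt(area_px / math.pi) * um_per_px
        if not lo_d <= eq_d_um <= hi_d:
            continue
        c0_, c1_ = params.feces_contrast_span
        mean_contrast = float(sub_dark[refined].mean())
        conf = float(np.clip((mean_contrast - c0_) / (c1_ - c0_), 0.0, 1.0))
        if conf < levels.black_feces:
            continue
        rr, cc_ = np.nonzero(refined)
        cr, cc = float(rr.mean()) + r0, float(cc_.mean()) + c0b
        box = (int(rr.min()) + r0, int(cc_.min()) + c0b,
               int(rr.max()) + r0 + 1, int(cc_.max()) + c0b + 1)
        dets.append(Detection(
            klass="black_feces", box=box, confidence=conf,
            side=side, leaf_index=leaf_index, area_mm2=area_px * px_area,
            center=(cr, cc),
            object_id=f"fec_{side[:2]}_{leaf_index}_{box[0]}_{box[1]}"))
    return dets


def segment_damage(
    pixels: np.ndarray,
    mask: np.ndarray,
    side: str,
    um_per_px: float,
    params: ClassicalParams = DEFAULT_PARAMS,
    leaf_index: int = -1,
) -> DamageMask:
    """Segment chlorotic feeding damage on one leaf crop.  Deterministic.

    The chlorosis score is yellowness (mean of R and G minus B) plus half
    the brightness deviation, both relative to the leaf's median colour;
    healthy green tissue scores near zero, yellowed tissue high.  The
    threshold is fixed (damage has no user-adjustable significance level).
    """
    _check_inputs(pixels, mask, um_per_px)
    px = pixels.astype(np.float64)
    L = px.mean(axis=2)
    yell = (px[:, :, 0] + px[:, :, 1]) / 2.0 - px[:, :, 2]
    med_y = float(np.median(yell[mask]))
    med_l = float(np.median(L[mask]))
    score = (yell - med_y) + 0.5 * (L - med_l)

    dmg = (score > params.damage_threshold) & mask
    radius = max(int(round(params.damage_opening_um / um_per_px / 2.0)), 1)
    dmg = ndi.binary_opening(dmg, structure=morphology.disk(radius))
    dmg &= mask
    # tiny bright specks (e.g. eggs) are not feeding lesions
    px_area = (um_per_px / 1000.0) ** 2
    min_px = int(params.damage_min_area_mm2 / px_area)
    if min_px > 1 and dmg.any():
        lab, n = ndi.label(dmg)
        sizes = np.bincount(lab.ravel())
        keep = sizes >= min_px
        keep[0] = False
        dmg = keep[lab]
    rows = np.any(dmg, axis=1)
    cols = np.any(dmg, axis=0)
    if rows.any():
        r0, r1 = np.flatnonzero(rows)[[0, -1]]
        c0, c1 = np.flatnonzero(cols)[[0, -1]]
        bbox = (int(r0), int(c0), int(r1) + 1, int(c1) + 1)
    else:
        bbox = (0, 0, 0, 0)
    return DamageMask(
        leaf_index=leaf_index, side=side, mask=dmg, bbox=bbox,
        area_mm2=float(np.count_nonzero(dmg)) * px_area,
    )


# --------------------------------------------------------------------------
# patch machinery for trainable backends


def dilate_mask(mask: np.ndarray, iterations: int = 5) -> np.ndarray:
    """Binary dilation with a 3×3 structuring element, iterated.

    Five iterations grow a single pixel into an 11×11 square; this is the
    mask-expansion step applied to annotation masks before training.
    """
    if iterations <= 0 or not mask.any():
        return mask.astype(bool).copy()
    return ndi.binary_dilation(mask, structure=np.ones((3, 3), bool),
                               iterations=iterations)


def make_patches(
    image: np.ndarray,
    mask: np.ndarray,
    patch_px: int = 128,
    dilation_iters: int = 5,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Tile an image and its annotation mask into standardized patches.

    Non-overlapping ``patch_px`` × ``patch_px`` tiles; right/bottom
    remainders are padded by reflection.  Each image patch is standardized
    to zero mean and unit variance per channel; the mask is dilated
    (``dilation_iters`` iterations of a 3×3 element) before tiling.
    """
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("image is empty")
    img = image.astype(np.float64)
    if img.ndim == 2:
        img = img[:, :, None]
    m = dilate_mask(np.asarray(mask, bool), dilation_iters)
    H, W = img.shape[:2]
    pad_r = (-H) % patch_px
    pad_c = (-W) % patch_px
    img = np.pad(img, ((0, pad_r), (0, pad_c), (0, 0)), mode="reflect")
    m = np.pad(m, ((0, pad_r), (0, pad_c)), mode="reflect")
    out = []
    for r in range(0, img.shape[0], patch_px):
        for c in range(0, img.shape[1], patch_px):
            p = img[r:r + patch_px, c:c + patch_px].copy()
            mu = p.mean(axis=(0, 1))
            sd = p.std(axis=(0, 1))
            sd[sd == 0] = 1.0
            p = (p - mu) / sd
            out.append((p, m[r:r + patch_px, c:c + patch_px].copy()))
    return out


def split_dataset(
    items: Sequence,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list, list, list]:
    """Deterministic train/validation/test split.

    Partition sizes are ⌊n·r⌋ with the remainder assigned train-first; the
    permutation is drawn from ``seed``.  The three parts are disjoint and
    exhaustive.
    """
    if not math.isclose(sum(ratios), 1.0, abs_tol=1e-9):
        raise ValueError("ratios must sum to 1")
    n = len(items)
    if n < 3:
        raise ValueError("need at least 3 items to form three partitions")
    sizes = [int(n * r) for r in ratios]
    rem = n - sum(sizes)
    for i in range(rem):
        sizes[i % 3] += 1
    perm = np.random.default_rng(seed).permutation(n)
    items = list(items)
    train = [items[i] for i in perm[: sizes[0]]]
    val = [items[i] for i in perm[sizes[0]: sizes[0] + sizes[1]]]
    test = [items[i] for i in perm[sizes[0] + sizes[1]:]]
    return train, val, test
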