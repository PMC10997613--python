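"""Leaf segmentation, layout ordering, and abaxial/adaxial pairing.

Leaves are non-touching green objects on a bright tape background.
Separation uses the excess-green index (2G − R − B) with an Otsu threshold,
followed by morphological closing and hole filling (feeding damage can
punch "holes" of non-green colour inside a blade; they belong to the leaf).
Components shorter than the mounting minimum (4 mm major axis) are debris
and discarded.

Ordering follows the mounting convention: two rows, numbered from the left
of the upper row and then from the left of the lower row, index 0 being the
youngest leaf.  Rows are found by 2-means on the centroid row coordinate;
if the between-row gap is smaller than one mean leaf height the plate is a
single row.

Pairing matches each abaxial leaf with its adaxial counterpart after
mirroring the adaxial scan back (the plate is turned over between
exposures), greedily by mask IOU; pairs below 0.5 IOU are flagged unpaired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology

from .scan_io import ABAXIAL, ADAXIAL, SIDES, ScanImage

__all__ = ["LeafRegion", "LeafPair", "segment_leaves", "order_leaves", "pair_sides"]


@dataclass
class LeafRegion:
    """One segmented leaf on one side of the plate."""

    side: str
    mask: np.ndarray  # bool, cropped to bbox
    bbox: tuple[int, int, int, int]  # half-open (r0, c0, r1, c1) in image coords
    centroid: tuple[float, float]  # (row, col) in image coords
    area_mm2: float
    um_per_px: float
    leaf_index: int = -1  # assigned by order_leaves

    @property
    def area_px(self) -> int:
        return int(np.count_nonzero(self.mask))

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out


@dataclass
class LeafPair:
    """An abaxial leaf with its adaxial counterpart (either may be missing)."""

    leaf_index: int
    abaxial: LeafRegion | None
    adaxial: LeafRegion | None
    iou: float = 0.0
    unpaired: bool = False


def segment_leaves(
    scan: ScanImage,
    min_leaf_length_mm: float = 4.0,
    closing_radius_um: float = 150.0,
) -> list[LeafRegion]:
    """Segment individual leaves from a plate scan.

    Returns unordered regions (use :func:`order_leaves`).  An empty plate
    yields an empty list with a warning rather than an error.
    """
    px = scan.pixels.astype(np.int16)
    exg = 2 * px[:, :, 1] - px[:, :, 0] - px[:, :, 2]
    try:
        thr = filters.threshold_otsu(exg)
    except ValueError:
        thr = None
    # Otsu needs a bimodal histogram; a blank plate degenerates
    if thr is None or thr <= 0:
        warnings.warn("no leaf-like foreground found on the plate", stacklevel=2)
        return []
    fg = exg > thr
    radius_px = max(int(round(closing_radius_um / scan.um_per_px)), 1)
    fg = ndi.binary_closing(fg, structure=morphology.disk(radius_px))
    fg = ndi.binary_fill_holes(fg)

    labels, n = ndi.label(fg)
    if n == 0:
        warnings.warn("no leaf-like foreground found on the plate", stacklevel=2)
        return []
    regions = []
    min_len_px = min_leaf_length_mm * 1000.0 / scan.um_per_px
    for prop in measure.regionprops(labels):
        # physical length = longest caliper (Feret) diameter, robust for the
        # blade-plus-petiole shape where the inertia axis under-reads
        if prop.feret_diameter_max < min_len_px:
            continue
        r0, c0, r1, c1 = prop.bbox
        regions.append(
            LeafRegion(
                side=scan.side,
                mask=prop.image.copy(),
                bbox=(r0, c0, r1, c1),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                area_mm2=float(prop.area) * scan.px_area_mm2,
                um_per_px=scan.um_per_px,
            )
        )
    if not regions:
        warnings.warn("plate contains foreground but no leaf-sized object", stacklevel=2)
    return regions


def order_leaves(regions: list[LeafRegion]) -> list[LeafRegion]:
    """Assign ``leaf_index`` following the mounting convention.

    Top row left→right first, then bottom row left→right; index 0 is the
    youngest leaf (mounted first, top-left).  The result is a new list
    sorted by index; assignment is invariant to the input order.
    """
    if not regions:
        return []
    regs = sorted(regions, key=lambda r: (r.centroid[0], r.centroid[1]))
    rows = np.array([r.centroid[0] for r in regs])
    heights = np.array([r.bbox[2] - r.bbox[0] for r in regs], dtype=float)

    if len(regs) == 1:
        assignment = [0]
    else:
        # 1-D 2-means on the row coordinate == split at the widest gap,
        # scanning split points for the minimal within-cluster variance
        best_split, best_cost = None, np.inf
        for s in range(1, len(regs)):
            top, bot = rows[:s], rows[s:]
            cost = ((top - top.mean()) ** 2).sum() + ((bot - bot.mean()) ** 2).sum()
            if cost < best_cost:
                best_cost, best_split = cost, s
        top, bot = rows[:best_split], rows[best_split:]
        gap = bot.mean() - top.mean()
        if gap < heights.mean():  # rows closer than one leaf height: single row
            groups = [list(range(len(regs)))]
        else:
            groups = [list(range(best_split)), list(range(best_split, len(regs)))]
        assignment = [0] * len(regs)
        idx = 0
        for grp in groups:
            for j in sorted(grp, key=lambda j: (regs[j].centroid[1], regs[j].centroid[0])):
                assignment[j] = idx
                idx += 1

    out = []
    for j, r in enumerate(regs):
        r.leaf_index = assignment[j]
        out.append(r)
    out.sort(key=lambda r: r.leaf_index)
    return out


def _mask_iou(a: LeafRegion, b_flipped_bbox: tuple, b_mask_flipped: np.ndarray) -> float:
    ar0, ac0, ar1, ac1 = a.bbox
    br0, bc0, br1, bc1 = b_flipped_bbox
    r0, c0 = max(ar0, br0), max(ac0, bc0)
    r1, c1 = min(ar1, br1), min(ac1, bc1)
    if r0 >= r1 or c0 >= c1:
        return 0.0
    a_sub = a.mask[r0 - ar0:r1 - ar0, c0 - ac0:c1 - ac0]
    b_sub = b_mask_flipped[r0 - br0:r1 - br0, c0 - bc0:c1 - bc0]
    inter = int(np.count_nonzero(a_sub & b_sub))
    union = a.area_px + int(np.count_nonzero(b_mask_flipped)) - inter
    return inter / union if union else 0.0


def pair_sides(
    abaxial: list[LeafRegion],
    adaxial: list[LeafRegion],
    plate_width_px: int,
    iou_threshold: float = 0.5,
) -> list[LeafPair]:
    """Match abaxial leaves to adaxial leaves after mirroring the adaxial view.

    Adaxial masks are reflected about the vertical axis (col → width−1−col)
    into the abaxial frame, then matched greedily by decreasing mask IOU,
    one-to-one.  Leaves with best IOU below ``iou_threshold`` are flagged
    unpaired.  Indices of the returned pairs follow the abaxial ordering;
    adaxial leaves with no partner are appended as unpaired entries.
    """
    flipped = []
    for b in adaxial:
        r0, c0, r1, c1 = b.bbox
        fb = (r0, plate_width_px - c1, r1, plate_width_px - c0)
        flipped.append((fb, b.mask[:, ::-1]))

    scores = np.zeros((len(abaxial), len(adaxial)))
    for i, a in enumerate(abaxial):
        for j, (fb, fm) in enumerate(flipped):
            scores[i, j] = _mask_iou(a, fb, fm)

    pairs: list[LeafPair] = []
    used_b: set = set()
    order = np.dstack(np.unravel_index(np.argsort(-scores, axis=None), scores.shape))[0] \
        if scores.size else []
    matched_a: dict = {}
    for i, j in order:
        if scores[i, j] < iou_threshold:
            break
        if i in matched_a or j in used_b:
            continue
        matched_a[i] = (j, scores[i, j])
        used_b.add(j)
    for i, a in enumerate(abaxial):
        if i in matched_a:
            j, iou = matched_a[i]
            pairs.append(LeafPair(leaf_index=a.leaf_index, abaxial=a,
                                  adaxial=adaxial[j], iou=float(iou)))
        else:
            pairs.append(LeafPair(leaf_index=a.leaf_index, abaxial=a, adaxial=None,
                                  unpaired=True))
    for j, b in enumerate(adaxial):
        if j not in used_b:
            pairs.append(LeafPair(leaf_index=b.leaf_index, abaxial=None, adaxial=b,
                                  unpaired=True))
    return pairs
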