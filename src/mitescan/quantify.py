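"""Aggregation of detections and masks into per-leaf and per-plant results.

All physical quantities are in mm² (areas) or counts; pixel areas convert
via (µm-per-pixel / 1000)².  Feeding damage detected on the two leaf
surfaces overlaps only partially, so the per-leaf damage figure of merit is
the area of the *union* of the two masks after registering the adaxial mask
onto the abaxial frame (mirror flip + translation aligning leaf centroids +
rotation aligning principal axes) — the overlapping portion is counted once.

Manual corrections (adding missed eggs/feces, removing false detections)
are applied as an ordered edit list and logged; totals are recomputed from
scratch after every edit so the bookkeeping invariant — plant totals equal
leaf sums plus off-leaf additional eggs — holds at all times.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from skimage import transform as sktransform
from skimage import measure

from .detect import DamageMask, Detection
from .leaves import LeafPair, LeafRegion
from .scan_io import ABAXIAL, ADAXIAL, SIDES, ScanMeta

__all__ = [
    "LeafResult",
    "PlantResult",
    "CorrectionEdit",
    "merge_damage",
    "quantify_leaf",
    "summarize_plant",
    "apply_corrections",
]


@dataclass
class LeafResult:
    """Quantified symptoms of one leaf, both sides plus the merged damage."""

    leaf_index: int
    leaf_area_mm2: dict = field(default_factory=dict)  # side -> mm²
    damage_area_mm2: dict = field(default_factory=dict)
    egg_count: dict = field(default_factory=dict)
    feces_count: dict = field(default_factory=dict)
    feces_area_mm2: dict = field(default_factory=dict)
    merged_damage_area_mm2: float = 0.0
    unpaired: bool = False

    def total(self, trait: str) -> float:
        return sum(getattr(self, trait).values())

    def validate(self) -> None:
        d_ab = self.damage_area_mm2.get(ABAXIAL, 0.0)
        d_ad = self.damage_area_mm2.get(ADAXIAL, 0.0)
        if self.merged_damage_area_mm2 > d_ab + d_ad + 1e-9:
            raise AssertionError("merged damage exceeds the sum of the two sides")
        if self.merged_damage_area_mm2 < max(d_ab, d_ad) - 1e-9:
            raise AssertionError("merged damage below the larger single side")


@dataclass
class PlantResult:
    """Whole-plant summary with per-leaf breakdown and detection registry."""

    meta: ScanMeta | None
    leaf_results: list[LeafResult]
    detections: list[Detection] = field(default_factory=list)
    additional_eggs: int = 0  # eggs shed off-leaf; not attributable to a leaf
    n_females: int = 10
    infestation_hours: float = 72.0
    audit_log: list[dict] = field(default_factory=list)

    @property
    def totals(self) -> dict:
        t = {
            "egg_count": sum(lr.total("egg_count") for lr in self.leaf_results)
            + self.additional_eggs,
            "feces_count": sum(lr.total("feces_count") for lr in self.leaf_results),
            "feces_area_mm2": sum(lr.total("feces_area_mm2") for lr in self.leaf_results),
            "damage_area_mm2": sum(lr.merged_damage_area_mm2 for lr in self.leaf_results),
            "leaf_area_mm2": sum(
                lr.leaf_area_mm2.get(ABAXIAL, lr.leaf_area_mm2.get(ADAXIAL, 0.0))
                for lr in self.leaf_results),
        }
        for side in SIDES:
            t[f"egg_count_{side}"] = sum(
                lr.egg_count.get(side, 0) for lr in self.leaf_results)
            t[f"feces_area_{side}"] = sum(
                lr.feces_area_mm2.get(side, 0.0) for lr in self.leaf_results)
        return t

    @property
    def oviposition_rate(self) -> float:
        """Eggs per female over the whole infestation window."""
        return self.totals["egg_count"] / self.n_females

    def validate(self) -> None:
        for lr in self.leaf_results:
            lr.validate()
        if self.additional_eggs < 0:
            raise AssertionError("additional_eggs must be >= 0")


def _rigid_registration(ab: LeafRegion, ad: LeafRegion,
                        plate_width_px: int) -> sktransform.EuclideanTransform:
    """Rigid transform taking mirrored-adaxial coordinates to abaxial ones.

    After the mirror flip the two views of a flat taped leaf differ only by
    a small translation and rotation; centroids align translation and the
    leaf masks' principal axes align rotation.
    """
    def _props(reg: LeafRegion, flip: bool):
        mask = reg.mask[:, ::-1] if flip else reg.mask
        r0, c0 = reg.bbox[0], (plate_width_px - reg.bbox[3]) if flip else reg.bbox[1]
        p = measure.regionprops(mask.astype(np.uint8))[0]
        cen = (p.centroid[0] + r0, p.centroid[1] + c0)
        return cen, p.orientation
    cen_ab, ori_ab = _props(ab, False)
    cen_ad, ori_ad = _props(ad, True)
    dtheta = ori_ab - ori_ad
    if dtheta > math.pi / 2:
        dtheta -= math.pi
    elif dtheta < -math.pi / 2:
        dtheta += math.pi
    # map (row, col) -> rotate about adaxial centroid, then translate
    cos, sin = math.cos(dtheta), math.sin(dtheta)

    def apply(rc: np.ndarray) -> np.ndarray:
        rel = rc - np.asarray(cen_ad)
        rot = rel @ np.array([[cos, -sin], [sin, cos]]).T
        return rot + np.asarray(cen_ab)

    return apply


def merge_damage(
    damage_ab: DamageMask | None,
    damage_ad: DamageMask | None,
    pair: LeafPair | None = None,
    plate_width_px: int | None = None,
    um_per_px: float | None = None,
) -> tuple[float, np.ndarray | None]:
    """Union damage area across the two sides of a paired leaf.

    The adaxial mask is mirrored and rigidly registered onto the abaxial
    frame; the merged area is |A ∪ B′| in mm², counted once though it is
    attributable to both sides.  For unpaired leaves the single available
    side is returned unchanged.  Commutative in the sense that the union
    does not depend on which side contributes which pixels; idempotent for
    identical masks.
    """
    if damage_ab is None and damage_ad is None:
        return 0.0, None
    if damage_ab is None or damage_ad is None or pair is None \
            or pair.abaxial is None or pair.adaxial is None:
        present = damage_ab if damage_ab is not None else damage_ad
        return present.area_mm2, present.mask.copy()
    if um_per_px is None:
        raise ValueError("um_per_px required to report mm²")
    if plate_width_px is None:
        raise ValueError("plate_width_px required for the mirror flip")

    ab_reg, ad_reg = pair.abaxial, pair.adaxial
    # abaxial-frame accumulation canvas over the abaxial leaf bbox
    r0, c0, r1, c1 = ab_reg.bbox
    canvas = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    canvas |= damage_ab.mask[: r1 - r0, : c1 - c0] if damage_ab.mask.shape == canvas.shape \
        else _paste(damage_ab, ab_reg)

    apply = _rigid_registration(ab_reg, ad_reg, plate_width_px)
    rr, cc = np.nonzero(damage_ad.mask)
    if len(rr):
        ar0, ac0 = ad_reg.bbox[0], ad_reg.bbox[1]
        # adaxial-image coords -> mirrored plate coords
        rows = rr + ar0
        cols = plate_width_px - 1 - (cc + ac0)
        mapped = apply(np.stack([rows, cols], axis=1))
        mr = np.round(mapped[:, 0]).astype(int) - r0
        mc = np.round(mapped[:, 1]).astype(int) - c0
        keep = (mr >= 0) & (mr < canvas.shape[0]) & (mc >= 0) & (mc < canvas.shape[1])
        canvas[mr[keep], mc[keep]] = True
    area = float(np.count_nonzero(canvas)) * (um_per_px / 1000.0) ** 2
    return area, canvas


def _paste(dm: DamageMask, reg: LeafRegion) -> np.ndarray:
    out = np.zeros((reg.bbox[2] - reg.bbox[0], reg.bbox[3] - reg.bbox[1]), dtype=bool)
    h = min(out.shape[0], dm.mask.shape[0])
    w = min(out.shape[1], dm.mask.shape[1])
    out[:h, :w] = dm.mask[:h, :w]
    return out


def quantify_leaf(
    pair: LeafPair,
    detections: Sequence[Detection],
    damage_masks: dict,
    um_per_px: float,
    plate_width_px: int | None = None,
) -> LeafResult:
    """Counts and areas of one leaf from already-filtered detections.

    ``damage_masks`` maps side -> :class:`DamageMask` (either may be
    missing).  Detections are assumed filtered by their significance levels
    upstream.
    """
    if not (um_per_px and um_per_px > 0):
        raise ValueError("um_per_px (physical scale) is required")
    lr = LeafResult(leaf_index=pair.leaf_index, unpaired=pair.unpaired)
    for side, reg in ((ABAXIAL, pair.abaxial), (ADAXIAL, pair.adaxial)):
        if reg is None:
            continue
        lr.leaf_area_mm2[side] = reg.area_mm2
        lr.egg_count[side] = sum(
            1 for d in detections if d.klass == "egg" and d.side == side)
        fec = [d for d in detections if d.klass == "black_feces" and d.side == side]
        lr.feces_count[side] = len(fec)
        lr.feces_area_mm2[side] = sum(d.area_mm2 for d in fec)
        dm = damage_masks.get(side)
        lr.damage_area_mm2[side] = dm.area_mm2 if dm is not None else 0.0
    merged, _ = merge_damage(damage_masks.get(ABAXIAL), damage_masks.get(ADAXIAL),
                             pair, plate_width_px, um_per_px)
    lr.merged_damage_area_mm2 = merged
    lr.validate()
    return lr


def summarize_plant(
    leaf_results: Sequence[LeafResult],
    meta: ScanMeta | None = None,
    detections: Sequence[Detection] = (),
    n_females: int = 10,
    additional_eggs: int = 0,
    infestation_hours: float = 72.0,
) -> PlantResult:
    """Whole-plant totals and the oviposition rate (eggs per female)."""
    if n_females <= 0:
        raise ValueError("n_females must be positive")
    if additional_eggs < 0:
        raise ValueError("additional_eggs must be >= 0")
    pr = PlantResult(
        meta=meta,
        leaf_results=sorted(leaf_results, key=lambda lr: lr.leaf_index),
        detections=list(detections),
        additional_eggs=additional_eggs,
        n_females=n_females,
        infestation_hours=infestation_hours,
    )
    pr.validate()
    return pr


# --------------------------------------------------------------------------
# manual corrections


@dataclass(frozen=True)
class CorrectionEdit:
    """One manual edit: add a missed object or remove a false detection."""

    action: str  # "add" | "remove"
    klass: str = "egg"  # "egg" | "black_feces"
    side: str = ABAXIAL
    leaf_index: int = -1
    box: tuple[int, int, int, int] | None = None  # required for add
    object_id: str | None = None  # required for remove

    def __post_init__(self) -> None:
        if self.action not in ("add", "remove"):
            raise ValueError("action must be 'add' or 'remove'")
        if self.action == "add" and self.box is None:
            raise ValueError("add edits need a box")
        if self.action == "remove" and not self.object_id:
            raise ValueError("remove edits need an object_id")

    def to_json(self) -> dict:
        return {
            "action": self.action, "klass": self.klass, "side": self.side,
            "leaf_index": self.leaf_index,
            "box": list(self.box) if self.box else None,
            "object_id": self.object_id,
        }

    @classmethod
    def from_json(cls, d: dict) -> "CorrectionEdit":
        return cls(action=d["action"], klass=d.get("klass", "egg"),
                   side=d.get("side", ABAXIAL), leaf_index=d.get("leaf_index", -1),
                   box=tuple(d["box"]) if d.get("box") else None,
                   object_id=d.get("object_id"))


def apply_corrections(
    plant: PlantResult,
    edits: Iterable[CorrectionEdit],
    um_per_px: float | None = None,
) -> PlantResult:
    """Apply manual edits in order and recompute all counts and areas.

    Removing an id that does not exist raises a ``KeyError`` naming the id.
    Every applied edit is appended to the plant's audit log.  The input
    object is not modified; an updated copy is returned.
    """
    dets = list(plant.detections)
    log = list(plant.audit_log)
    for edit in edits:
        if edit.action == "remove":
            idx = [i for i, d in enumerate(dets) if d.object_id == edit.object_id]
            if not idx:
                raise KeyError(f"no detection with object_id {edit.object_id!r}")
            dets.pop(idx[0])
        else:
            r0, c0, r1, c1 = edit.box
            area = 0.0
            if um_per_px and edit.klass == "black_feces":
                area = (r1 - r0) * (c1 - c0) * (um_per_px / 1000.0) ** 2
            new_id = f"man_{edit.klass[:3]}_{edit.side[:2]}_{edit.leaf_index}_{r0}_{c0}"
            dets.append(Detection(
                klass=edit.klass, box=edit.box, confidence=1.0, side=edit.side,
                leaf_index=edit.leaf_index, area_mm2=area,
                center=((r0 + r1) / 2.0, (c0 + c1) / 2.0),
                object_id=new_id, manual=True))
        log.append({"edit": edit.to_json()})

    # rebuild per-leaf counts from the updated detection registry, keeping
    # leaf areas and damage (corrections cover countable objects only)
    new_leaves = []
    for lr in plant.leaf_results:
        nl = LeafResult(
            leaf_index=lr.leaf_index,
            leaf_area_mm2=dict(lr.leaf_area_mm2),
            damage_area_mm2=dict(lr.damage_area_mm2),
            merged_damage_area_mm2=lr.merged_damage_area_mm2,
            unpaired=lr.unpaired,
        )
        for side in SIDES:
            mine = [d for d in dets if d.leaf_index == lr.leaf_index and d.side == side]
            if side not in lr.leaf_area_mm2 and side not in lr.egg_count and not mine:
                continue
            nl.egg_count[side] = sum(1 for d in mine if d.klass == "egg")
            fec = [d for d in mine if d.klass == "black_feces"]
            nl.feces_count[side] = len(fec)
            nl.feces_area_mm2[side] = sum(d.area_mm2 for d in fec)
        nl.validate()
        new_leaves.append(nl)

    out = PlantResult(
        meta=plant.meta, leaf_results=new_leaves, detections=dets,
        additional_eggs=plant.additional_eggs, n_females=plant.n_females,
        infestation_hours=plant.infestation_hours, audit_log=log,
    )
    out.validate()
    return out
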