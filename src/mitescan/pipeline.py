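"""End-to-end analysis of scan pairs and CSV export.

The pipeline takes a directory (or explicit paths) of plate-scan TIFFs,
pairs the abaxial scan of each plant with its adaxial scan by filename
metadata, and runs: leaf segmentation → layout ordering → side pairing →
egg/feces detection and damage segmentation per leaf side → physical-unit
quantification with cross-side damage de-duplication → per-plant summary.
Results are written as one JSON per plant plus a cumulative CSV; plants
already analysed are skipped unless forced.  With the classical backend
the pipeline is deterministic end to end.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .detect import (DamageMask, Detection, detect_eggs, detect_feces,
                     segment_damage)
from .leaves import LeafPair, order_leaves, pair_sides, segment_leaves
from .quantify import LeafResult, PlantResult, quantify_leaf, summarize_plant
from .scan_io import ABAXIAL, ADAXIAL, SIDES, ScanImage, parse_scan_filename, read_scan

logger = logging.getLogger("mitescan")

__all__ = ["analyze_plant", "run_pipeline", "export_csv", "read_results_csv",
           "CSV_COLUMNS"]

CSV_COLUMNS = [
    "ecotype", "plant_number", "batch", "row_type", "leaf_index", "leaf_side",
    "leaf_area_mm2", "damage_area_mm2", "egg_count", "feces_count",
    "feces_area_mm2", "merged_damage_area_mm2", "oviposition_rate",
    "additional_eggs",
]


def analyze_plant(
    scan_ab: ScanImage,
    scan_ad: ScanImage,
    config: RunConfig | None = None,
    damage_backend=None,
) -> PlantResult:
    """Run the full per-plant analysis on a pair of scans.

    ``damage_backend`` may supply a trained model with a
    ``segment_damage``-compatible method; the classical backend is used
    otherwise.  Detection coordinates are reported in the coordinates of
    the scan the object was found on.
    """
    config = config or RunConfig()
    levels = config.levels
    params = config.params

    regs = {}
    for scan in (scan_ab, scan_ad):
        found = order_leaves(segment_leaves(scan, config.min_leaf_length_mm))
        regs[scan.side] = found
        declared = scan.meta.declared_leaf_count if scan.meta else None
        if declared is not None and declared != len(found):
            warnings.warn(
                f"{scan.side} scan declares {declared} leaves but {len(found)} were found",
                stacklevel=2)

    width_ad = scan_ad.shape[1]
    pairs = pair_sides(regs[ABAXIAL], regs[ADAXIAL], width_ad)
    # adaxial indices follow their abaxial partner (the mounting order is
    # defined on the abaxial exposure, which is taken first)
    for p in pairs:
        if p.abaxial is not None and p.adaxial is not None:
            p.adaxial.leaf_index = p.abaxial.leaf_index
            p.leaf_index = p.abaxial.leaf_index

    scans = {ABAXIAL: scan_ab, ADAXIAL: scan_ad}
    all_dets: list[Detection] = []
    leaf_results: list[LeafResult] = []
    for p in pairs:
        dets_leaf: list[Detection] = []
        dmasks: dict = {}
        for side, reg in ((ABAXIAL, p.abaxial), (ADAXIAL, p.adaxial)):
            if reg is None:
                continue
            scan = scans[side]
            r0, c0, r1, c1 = reg.bbox
            crop = scan.pixels[r0:r1, c0:c1]
            eggs = detect_eggs(crop, reg.mask, side, scan.um_per_px, levels,
                               params, leaf_index=p.leaf_index)
            feces = detect_feces(crop, reg.mask, side, scan.um_per_px, levels,
                                 params, leaf_index=p.leaf_index)
            for d in eggs + feces:
                b = d.box
                d.box = (b[0] + r0, b[1] + c0, b[2] + r0, b[3] + c0)
                d.center = (d.center[0] + r0, d.center[1] + c0)
            if damage_backend is not None:
                dm = damage_backend.segment_damage(
                    crop, reg.mask, side, scan.um_per_px, leaf_index=p.leaf_index)
            else:
                dm = segment_damage(crop, reg.mask, side, scan.um_per_px,
                                    params, leaf_index=p.leaf_index)
            dmasks[side] = dm
            dets_leaf.extend(eggs + feces)
        lr = quantify_leaf(p, dets_leaf, dmasks, scans[ABAXIAL].um_per_px,
                           plate_width_px=width_ad)
        leaf_results.append(lr)
        all_dets.extend(dets_leaf)
        logger.info("leaf %d: %d eggs, %d feces, %.3f mm² damage",
                    p.leaf_index,
                    lr.total("egg_count"), lr.total("feces_count"),
                    lr.merged_damage_area_mm2)

    return summarize_plant(leaf_results, meta=scan_ab.meta, detections=all_dets,
                           n_females=config.n_females,
                           infestation_hours=config.infestation_hours)


# --------------------------------------------------------------------------
# batch driver


def _plant_json(plant: PlantResult) -> dict:
    return {
        "meta": dataclasses.asdict(plant.meta) if plant.meta else None,
        "totals": plant.totals,
        "oviposition_rate": plant.oviposition_rate,
        "additional_eggs": plant.additional_eggs,
        "n_females": plant.n_females,
        "leaves": [
            {
                "leaf_index": lr.leaf_index,
                "unpaired": lr.unpaired,
                "merged_damage_area_mm2": lr.merged_damage_area_mm2,
                "per_side": {
                    side: {
                        "leaf_area_mm2": lr.leaf_area_mm2.get(side),
                        "damage_area_mm2": lr.damage_area_mm2.get(side),
                        "egg_count": lr.egg_count.get(side),
                        "feces_count": lr.feces_count.get(side),
                        "feces_area_mm2": lr.feces_area_mm2.get(side),
                    }
                    for side in SIDES
                },
            }
            for lr in plant.leaf_results
        ],
        "detections": [dataclasses.asdict(d) for d in plant.detections],
        "audit_log": plant.audit_log,
    }


def run_pipeline(
    inputs: str | list[str],
    out_dir: str,
    config: RunConfig | None = None,
    force: bool = False,
) -> list[PlantResult]:
    """Analyse every matched abaxial/adaxial scan pair under ``inputs``.

    Unmatched scans are listed and skipped; a corrupt file fails that plant
    only.  Per-plant JSON goes to ``out_dir``; the cumulative CSV is
    rewritten from all JSON present at the end of the run (so re-runs are
    idempotent).  Returns the plants analysed in this invocation.
    """
    config = config or RunConfig()
    os.makedirs(out_dir, exist_ok=True)
    if isinstance(inputs, str):
        paths = sorted(
            os.path.join(inputs, f) for f in os.listdir(inputs)
            if f.lower().endswith((".tif", ".tiff")))
    else:
        paths = list(inputs)

    by_plant: dict = {}
    for path in paths:
        try:
            meta = parse_scan_filename(path, config.template)
        except Exception as exc:
            logger.warning("skipping %s: %s", path, exc)
            continue
        by_plant.setdefault(meta.plant_key, {})[meta.side] = path

    results = []
    for key, sides in sorted(by_plant.items()):
        if set(sides) != set(SIDES):
            logger.warning("plant %s: missing %s scan, skipped", key,
                           (set(SIDES) - set(sides)).pop())
            continue
        stem = os.path.splitext(os.path.basename(sides[ABAXIAL]))[0]
        out_json = os.path.join(out_dir, stem + ".json")
        if os.path.exists(out_json) and not force:
            logger.info("plant %s already analysed, skipping", key)
            continue
        try:
            scan_ab = read_scan(sides[ABAXIAL], default_dpi=config.dpi,
                                template=config.template)
            scan_ad = read_scan(sides[ADAXIAL], default_dpi=config.dpi,
                                template=config.template)
            plant = analyze_plant(scan_ab, scan_ad, config)
        except Exception as exc:
            logger.error("plant %s failed: %s", key, exc)
            continue
        with open(out_json, "w") as fh:
            json.dump(_plant_json(plant), fh, indent=1)
        results.append(plant)

    _rewrite_csv(out_dir)
    return results


def _rewrite_csv(out_dir: str) -> str:
    plants = []
    for f in sorted(os.listdir(out_dir)):
        if f.endswith(".json"):
            with open(os.path.join(out_dir, f)) as fh:
                plants.append(json.load(fh))
    path = os.path.join(out_dir, "results.csv")
    export_csv_from_json(plants, path)
    return path


# --------------------------------------------------------------------------
# CSV schema


def _csv_rows(meta: dict | None, leaves: list[dict], totals: dict,
              oviposition_rate: float, additional_eggs: int) -> list[dict]:
    eco = meta.get("ecotype_label") if meta else ""
    rep = meta.get("replicate") if meta else 0
    batch = meta.get("batch") if meta else ""
    rows = []
    for lv in leaves:
        for side in SIDES:
            ps = lv["per_side"][side]
            if ps["leaf_area_mm2"] is None and ps["egg_count"] is None:
                continue
            rows.append({
                "ecotype": eco, "plant_number": rep, "batch": batch,
                "row_type": "leaf", "leaf_index": lv["leaf_index"],
                "leaf_side": side,
                "leaf_area_mm2": ps["leaf_area_mm2"] or 0.0,
                "damage_area_mm2": ps["damage_area_mm2"] or 0.0,
                "egg_count": ps["egg_count"] or 0,
                "feces_count": ps["feces_count"] or 0,
                "feces_area_mm2": ps["feces_area_mm2"] or 0.0,
                "merged_damage_area_mm2": "", "oviposition_rate": "",
                "additional_eggs": "",
            })
    rows.append({
        "ecotype": eco, "plant_number": rep, "batch": batch,
        "row_type": "plant", "leaf_index": "", "leaf_side": "plant",
        "leaf_area_mm2": totals["leaf_area_mm2"],
        "damage_area_mm2": totals["damage_area_mm2"],
        "egg_count": totals["egg_count"],
        "feces_count": totals["feces_count"],
        "feces_area_mm2": totals["feces_area_mm2"],
        "merged_damage_area_mm2": totals["damage_area_mm2"],
        "oviposition_rate": oviposition_rate,
        "additional_eggs": additional_eggs,
    })
    return rows


def export_csv(results: list[PlantResult], path: str) -> str:
    """Write analysed plants to the canonical CSV schema.

    One row per leaf per side plus one summary row per plant; numeric
    values survive a read-back at full precision (period decimal separator,
    comma delimiter, UTF-8).
    """
    rows = []
    for plant in results:
        leaves = _plant_json(plant)["leaves"]
        rows.extend(_csv_rows(
            dataclasses.asdict(plant.meta) if plant.meta else None,
            leaves, plant.totals, plant.oviposition_rate, plant.additional_eggs))
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")
    return path


def export_csv_from_json(plants: list[dict], path: str) -> str:
    rows = []
    for p in plants:
        rows.extend(_csv_rows(p.get("meta"), p["leaves"], p["totals"],
                              p["oviposition_rate"], p["additional_eggs"]))
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")
    return path


def read_results_csv(path: str) -> pd.DataFrame:
    """Read the canonical CSV back; numeric columns restored to full precision."""
    return pd.read_csv(path, encoding="utf-8")
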