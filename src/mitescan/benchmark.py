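"""The default synthetic detection benchmark: pipeline versus ground truth.

Generates plants with the default symptom load, runs the full classical
pipeline on the rendered scan pairs, and scores the result against the
generator's exact truth: object-level egg precision/recall/F1 (centre
matching within two egg radii), relative errors of the recovered feces and
damage areas, per-plant egg-count recovery, and the mean object-level
efficiency (program / truth × 100%) per plant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .pipeline import analyze_plant
from .scan_io import ABAXIAL, ADAXIAL, SIDES
from .synthetic import DEFAULT_RENDER, RenderSettings, default_plant_spec, generate_plant
from .validate import match_objects, object_efficiency

__all__ = ["BenchmarkResult", "run_detection_benchmark"]


@dataclass
class BenchmarkResult:
    n_plants: int
    n_leaves_total: int
    egg_tp: int
    egg_fp: int
    egg_fn: int
    feces_area_true_mm2: float
    feces_area_detected_mm2: float
    damage_area_true_mm2: float
    damage_area_detected_mm2: float
    egg_counts_true: list
    egg_counts_detected: list
    damage_true_per_plant: list
    damage_detected_per_plant: list

    @property
    def egg_precision(self) -> float:
        d = self.egg_tp + self.egg_fp
        return self.egg_tp / d if d else 0.0

    @property
    def egg_recall(self) -> float:
        d = self.egg_tp + self.egg_fn
        return self.egg_tp / d if d else 0.0

    @property
    def egg_f1(self) -> float:
        p, r = self.egg_precision, self.egg_recall
        return 2 * p * r / (p + r) if p + r else 0.0

    @property
    def feces_area_rel_error(self) -> float:
        return abs(self.feces_area_detected_mm2 - self.feces_area_true_mm2) \
            / self.feces_area_true_mm2

    @property
    def damage_area_rel_error(self) -> float:
        return abs(self.damage_area_detected_mm2 - self.damage_area_true_mm2) \
            / self.damage_area_true_mm2

    @property
    def egg_count_rel_error(self) -> float:
        t = sum(self.egg_counts_true)
        d = sum(self.egg_counts_detected)
        return abs(d - t) / t if t else 0.0

    def egg_efficiency(self):
        """Per-plant object-level efficiency report for egg counts."""
        return object_efficiency(self.egg_counts_detected, self.egg_counts_true,
                                 trait="egg_count")


def run_detection_benchmark(
    n_plants: int = 10,
    n_leaves: int = 10,
    seed: int = 0,
    settings: RenderSettings = DEFAULT_RENDER,
    config: RunConfig | None = None,
) -> BenchmarkResult:
    """Generate ``n_plants`` default plants, analyse them, score vs truth."""
    config = config or RunConfig()
    rng = np.random.default_rng([int(seed), 17])
    egg_tp = egg_fp = egg_fn = 0
    fec_t = fec_d = dmg_t = dmg_d = 0.0
    eggs_t_pp, eggs_d_pp, dmg_t_pp, dmg_d_pp = [], [], [], []
    n_leaves_total = 0

    for _ in range(n_plants):
        spec = default_plant_spec(n_leaves=n_leaves,
                                  seed=int(rng.integers(0, 2**31 - 1)))
        scan_ab, scan_ad, truth = generate_plant(spec, settings)
        plant = analyze_plant(scan_ab, scan_ad, config)
        n_leaves_total += len(plant.leaf_results)

        # object-level egg matching per side, in image coordinates
        scans = {ABAXIAL: scan_ab, ADAXIAL: scan_ad}
        for side in SIDES:
            pred = np.array([d.center for d in plant.detections
                             if d.klass == "egg" and d.side == side]).reshape(-1, 2)
            true = np.array([o.center for o in truth.objects_of("egg", side)]
                            ).reshape(-1, 2)
            max_dist = 2 * (settings.egg_diameter_um[0] + settings.egg_diameter_um[1]) \
                / 2.0 / scans[side].um_per_px / 2.0
            m, up, ut = match_objects(pred, true, max_dist)
            egg_tp += len(m)
            egg_fp += len(up)
            egg_fn += len(ut)

        t = plant.totals
        fec_d += t["feces_area_mm2"]
        fec_t += truth.plant_totals["feces_area_mm2"]
        dmg_d += t["damage_area_mm2"]
        dmg_t += truth.plant_totals["damage_area_mm2"]
        eggs_d_pp.append(t["egg_count"])
        eggs_t_pp.append(truth.plant_totals["egg_count"])
        dmg_d_pp.append(t["damage_area_mm2"])
        dmg_t_pp.append(truth.plant_totals["damage_area_mm2"])

    return BenchmarkResult(
        n_plants=n_plants, n_leaves_total=n_leaves_total,
        egg_tp=egg_tp, egg_fp=egg_fp, egg_fn=egg_fn,
        feces_area_true_mm2=fec_t, feces_area_detected_mm2=fec_d,
        damage_area_true_mm2=dmg_t, damage_area_detected_mm2=dmg_d,
        egg_counts_true=eggs_t_pp, egg_counts_detected=eggs_d_pp,
        damage_true_per_plant=dmg_t_pp, damage_detected_per_plant=dmg_d_pp,
    )
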