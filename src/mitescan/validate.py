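"""Validation of detection quality: pixel-level overlap and object-level efficiency.

Two complementary views of agreement between the program and a reference
(expert annotation, or generator ground truth on synthetic plates):

* pixel level — Jaccard IOU between predicted and reference masks (pixel
  accuracy is emitted alongside, clearly labelled, since the two are easy to
  conflate);
* object level — "efficiency", the program's measurement divided by the
  reference measurement × 100% per item, summarised by mean and range and
  accompanied by a paired two-sided t-test of program vs reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "pixel_iou",
    "pixel_accuracy",
    "EfficiencyReport",
    "object_efficiency",
    "match_objects",
]


def _check_masks(pred: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    if pred.shape != ref.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {ref.shape}")
    return pred, ref


def pixel_iou(pred: np.ndarray, ref: np.ndarray) -> float:
    """Jaccard index |pred ∩ ref| / |pred ∪ ref| between two binary masks.

    Two empty masks agree perfectly on the absence of signal: defined as 1.0.
    """
    pred, ref = _check_masks(pred, ref)
    union = np.count_nonzero(pred | ref)
    if union == 0:
        return 1.0
    inter = np.count_nonzero(pred & ref)
    return inter / union


def pixel_accuracy(pred: np.ndarray, ref: np.ndarray) -> float:
    """Fraction of pixels labelled identically in the two masks."""
    pred, ref = _check_masks(pred, ref)
    return float(np.count_nonzero(pred == ref) / pred.size)


@dataclass
class EfficiencyReport:
    """Object-level program-vs-reference comparison for one trait."""

    trait: str
    per_item: pd.DataFrame  # columns: item, program, expert, efficiency_pct
    mean_efficiency: float
    range: tuple[float, float]
    p_value: float
    alpha: float = 0.05
    excluded_items: list = field(default_factory=list)

    @property
    def significant(self) -> bool:
        """True if program and reference differ significantly at ``alpha``."""
        return self.p_value <= self.alpha

    def to_frame(self) -> pd.DataFrame:
        return self.per_item.copy()


def object_efficiency(
    program: Sequence[float],
    expert: Sequence[float],
    *,
    trait: str = "trait",
    items: Sequence | None = None,
    alpha: float = 0.05,
) -> EfficiencyReport:
    """Per-item efficiency (program/expert × 100%) with a paired t-test.

    Items with a zero reference value have no defined efficiency; they are
    excluded with a warning (and also left out of the paired test so both
    summaries describe the same items).
    """
    program = np.asarray(program, dtype=float)
    expert = np.asarray(expert, dtype=float)
    if program.shape != expert.shape or program.ndim != 1:
        raise ValueError("program and expert must be 1-D sequences of equal length")
    if items is None:
        items = list(range(len(program)))
    items = list(items)

    ok = expert > 0
    excluded = [items[i] for i in np.flatnonzero(~ok)]
    if excluded:
        warnings.warn(
            f"{trait}: excluded {len(excluded)} item(s) with zero reference value: "
            f"{excluded}",
            stacklevel=2,
        )
    if not ok.any():
        raise ValueError(f"{trait}: no item has a positive reference value")
    prog, exp = program[ok], expert[ok]
    eff = prog / exp * 100.0
    diffs = prog - exp
    if np.allclose(diffs, 0.0):
        p_value = 1.0  # identical measurements: no evidence of difference
    elif len(diffs) < 2 or np.allclose(diffs, diffs[0]):
        p_value = float("nan")
    else:
        p_value = float(sps.ttest_rel(prog, exp).pvalue)

    per_item = pd.DataFrame(
        {
            "item": [items[i] for i in np.flatnonzero(ok)],
            "program": prog,
            "expert": exp,
            "efficiency_pct": eff,
        }
    )
    return EfficiencyReport(
        trait=trait,
        per_item=per_item,
        mean_efficiency=float(eff.mean()),
        range=(float(eff.min()), float(eff.max())),
        p_value=p_value,
        alpha=alpha,
        excluded_items=excluded,
    )


def match_objects(
    pred_centers: np.ndarray,
    true_centers: np.ndarray,
    max_dist_px: float,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy one-to-one matching of detections to reference objects.

    Pairs are formed in order of increasing centre distance; a pair is
    accepted if the distance is ≤ ``max_dist_px`` and neither member is
    already matched.  Returns (matches, unmatched_pred, unmatched_true),
    with matches as (pred_idx, true_idx).
    """
    pred_centers = np.atleast_2d(np.asarray(pred_centers, dtype=float))
    true_centers = np.atleast_2d(np.asarray(true_centers, dtype=float))
    if pred_centers.size == 0 or true_centers.size == 0:
        return [], list(range(len(pred_centers))), list(range(len(true_centers)))
    d = np.linalg.norm(pred_centers[:, None, :] - true_centers[None, :, :], axis=2)
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    used_p: set = set()
    used_t: set = set()
    matches: list[tuple[int, int]] = []
    for i, j in order:
        if d[i, j] > max_dist_px:
            break
        if i in used_p or j in used_t:
            continue
        matches.append((int(i), int(j)))
        used_p.add(int(i))
        used_t.add(int(j))
    unmatched_p = [i for i in range(len(pred_centers)) if i not in used_p]
    unmatched_t = [j for j in range(len(true_centers)) if j not in used_t]
    return matches, unmatched_p, unmatched_t
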