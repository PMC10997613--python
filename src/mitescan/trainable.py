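"""A lightweight trainable damage-segmentation backend.

Pixel-level gradient-boosted classifier over multiscale colour features,
trained on the 128×128 standardized patches from
:func:`mitescan.detect.make_patches`.
It satisfies the same call contract as the classical damage backend — a
per-pixel probability thresholded into a mask — so significance-level
semantics (monotone thresholds) carry over unchanged.  Training a model of
this size takes well under a minute on one CPU; it exists to exercise the
backend contract and the patch/split machinery end to end, not to compete
with large detection architectures.

Features per pixel: the three standardized channels, two Gaussian-smoothed
copies (1.5 px and 4 px), and the yellowness index, computed per patch.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from sklearn.ensemble import HistGradientBoostingClassifier

from .detect import DamageMask

__all__ = ["PatchModel", "train_patch_model", "pixel_features", "mask_background"]


def mask_background(pixels: np.ndarray, leaf_mask: np.ndarray) -> np.ndarray:
    """Replace off-leaf pixels with the leaf's median colour.

    Bright tape background would otherwise dominate per-patch
    standardization statistics and shift the leaf/damage colour classes
    from patch to patch."""
    px = pixels.astype(np.float64).copy()
    med = np.median(px[leaf_mask], axis=0)
    px[~leaf_mask] = med
    return px

FORMAT_VERSION = 1


def pixel_features(patch: np.ndarray) -> np.ndarray:
    """Per-pixel feature stack (H, W, F) for one standardized patch."""
    p = patch.astype(np.float64)
    if p.ndim == 2:
        p = p[:, :, None]
    feats = [p]
    for sigma in (1.5, 4.0):
        feats.append(np.stack(
            [ndi.gaussian_filter(p[:, :, c], sigma) for c in range(p.shape[2])],
            axis=2))
    if p.shape[2] >= 3:
        yell = (p[:, :, 0] + p[:, :, 1]) / 2.0 - p[:, :, 2]
        feats.append(yell[:, :, None])
    return np.concatenate(feats, axis=2)


@dataclass
class PatchModel:
    """Trained per-pixel classifier with the damage-backend call contract."""

    clf: HistGradientBoostingClassifier
    threshold: float = 0.5

    def predict_proba_map(self, patch: np.ndarray) -> np.ndarray:
        f = pixel_features(patch)
        H, W, F = f.shape
        proba = self.clf.predict_proba(f.reshape(-1, F))[:, 1]
        return proba.reshape(H, W)

    def predict_mask(self, patch: np.ndarray, threshold: float | None = None) -> np.ndarray:
        thr = self.threshold if threshold is None else threshold
        return self.predict_proba_map(patch) >= thr

    def segment_damage(self, pixels: np.ndarray, mask: np.ndarray, side: str,
                       um_per_px: float, leaf_index: int = -1,
                       threshold: float | None = None) -> DamageMask:
        """Classical-backend-compatible damage segmentation of a leaf crop."""
        p = mask_background(pixels, mask)
        mu = p.mean(axis=(0, 1))
        sd = p.std(axis=(0, 1))
        sd[sd == 0] = 1.0
        proba = self.predict_proba_map((p - mu) / sd)
        thr = self.threshold if threshold is None else threshold
        dmg = (proba >= thr) & mask
        px_area = (um_per_px / 1000.0) ** 2
        rows = np.any(dmg, axis=1)
        if rows.any():
            cols = np.any(dmg, axis=0)
            r0, r1 = np.flatnonzero(rows)[[0, -1]]
            c0, c1 = np.flatnonzero(cols)[[0, -1]]
            bbox = (int(r0), int(c0), int(r1) + 1, int(c1) + 1)
        else:
            bbox = (0, 0, 0, 0)
        return DamageMask(leaf_index=leaf_index, side=side, mask=dmg, bbox=bbox,
                          area_mm2=float(np.count_nonzero(dmg)) * px_area)

    def save(self, path: str) -> str:
        with open(path, "wb") as fh:
            pickle.dump({"format_version": FORMAT_VERSION,
                         "threshold": self.threshold, "clf": self.clf}, fh)
        return path

    @classmethod
    def load(cls, path: str) -> "PatchModel":
        with open(path, "rb") as fh:
            d = pickle.load(fh)
        if d.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported model file version {d.get('format_version')}")
        return cls(clf=d["clf"], threshold=d["threshold"])


def train_patch_model(
    train_patches: list[tuple[np.ndarray, np.ndarray]],
    val_patches: list[tuple[np.ndarray, np.ndarray]] | None = None,
    *,
    max_pixels: int = 200_000,
    seed: int = 0,
    n_epochs: int = 3,
) -> PatchModel:
    """Fit the pixel classifier on (patch, mask) pairs from ``make_patches``.

    A class-balanced subsample of at most ``max_pixels`` pixels is drawn
    for fitting.  If validation patches are given, the decision threshold
    is tuned on them to maximise pixel IOU.
    """
    if not train_patches:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    X, y = [], []
    for patch, mask in train_patches:
        f = pixel_features(patch)
        F = f.shape[2]
        X.append(f.reshape(-1, F))
        y.append(np.asarray(mask, bool).ravel())
    X = np.concatenate(X)
    y = np.concatenate(y)
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    n_half = max_pixels // 2
    take_pos = rng.choice(pos, size=min(len(pos), n_half), replace=False) if len(pos) \
        else np.empty(0, dtype=int)
    take_neg = rng.choice(neg, size=min(len(neg), max(n_half, max_pixels - len(take_pos))),
                          replace=False)
    idx = np.concatenate([take_pos, take_neg])
    rng.shuffle(idx)
    clf = HistGradientBoostingClassifier(max_iter=50 * n_epochs,
                                         random_state=int(seed))
    clf.fit(X[idx], y[idx])
    model = PatchModel(clf=clf)

    if val_patches:
        probs, refs = [], []
        for patch, mask in val_patches:
            probs.append(model.predict_proba_map(patch).ravel())
            refs.append(np.asarray(mask, bool).ravel())
        probs = np.concatenate(probs)
        refs = np.concatenate(refs)
        best_thr, best_iou = 0.5, -1.0
        for thr in np.linspace(0.2, 0.98, 27):
            pred = probs >= thr
            union = np.count_nonzero(pred | refs)
            iou = (np.count_nonzero(pred & refs) / union) if union else 1.0
            if iou > best_iou:
                best_iou, best_thr = iou, float(thr)
        model.threshold = best_thr
    return model
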