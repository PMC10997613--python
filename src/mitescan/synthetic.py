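"""Synthetic two-sided plate scans of mite-infested leaves, with exact ground truth.

The generator emulates the study material this package is built to measure:
detached *Arabidopsis*-like rosette leaves taped to a plate in two rows
(youngest first, top-left onward), scanned once from the abaxial (lower)
surface and once — after turning the plate over — from the adaxial (upper)
surface, so the second scan is a left-right mirror of the first.

Rendered features, all parameterised and all recorded in the ground truth:

* green leaf blades with petioles and a trichome texture that is densest on
  the youngest leaves;
* spider-mite eggs as bright 100–150 µm ellipsoids in three age tints
  (transparent, straw-yellow, orange), laid mostly on the abaxial side;
* black fecal pellets as near-black irregular blobs;
* chlorotic feeding damage as irregular yellowed patches that only partially
  overlap between the two leaf surfaces;
* adaxial-scan confounders: optical blur and tape mottling (that exposure is
  taken through the plate and adhesive tape) and air-bubble rings in the
  tape glue that superficially resemble eggs.

Ground truth is exact by construction: object lists with centres, sizes and
boxes; per-side leaf-label and damage masks; per-leaf and per-plant tables in
physical units.  Areas of generated blobs are controlled to the pixel (blob
masks take exactly the top-k pixels of a shaped random field), so physical
areas are stable across render resolutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw as skdraw

from .scan_io import ABAXIAL, ADAXIAL, SIDES, ScanImage, ScanMeta, dpi_to_um_per_px
from .stats import TraitTable

__all__ = [
    "GenerationError",
    "PlantSpec",
    "RenderSettings",
    "TruthObject",
    "GroundTruth",
    "EcotypeDesign",
    "ExperimentResult",
    "default_plant_spec",
    "generate_plant",
    "generate_experiment",
]


class GenerationError(RuntimeError):
    """Requested symptom load cannot be placed on the specified leaves."""


# --------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class PlantSpec:
    """Complete description of one synthetic plant before rendering."""

    n_leaves: int
    leaf_lengths_mm: Sequence[float]  # index 0 = youngest (mounting order)
    eggs_per_leaf: Sequence[int]
    feces_per_leaf: Sequence[int]
    damage_fraction_per_leaf: Sequence[float]  # of blade area, per side
    p_adaxial_egg: float = 1.0 / 6.0
    p_adaxial_feces: float = 0.5
    damage_side_overlap: float = 0.6
    bubble_density: float = 0.5  # confounders per cm² on the adaxial scan
    trichome_density_gradient: float = 0.25  # oldest-leaf density / youngest
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        for name in ("leaf_lengths_mm", "eggs_per_leaf", "feces_per_leaf",
                     "damage_fraction_per_leaf"):
            if len(getattr(self, name)) != self.n_leaves:
                raise ValueError(f"{name} must have length n_leaves={self.n_leaves}")
        if min(self.leaf_lengths_mm) < 4.0:
            raise ValueError("leaf lengths must be >= 4 mm (smaller leaves are not mounted)")
        for name in ("p_adaxial_egg", "p_adaxial_feces", "damage_side_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(f < 0 or f > 0.5 for f in self.damage_fraction_per_leaf):
            raise ValueError("damage fractions must be in [0, 0.5]")
        if any(e < 0 for e in self.eggs_per_leaf) or any(f < 0 for f in self.feces_per_leaf):
            raise ValueError("symptom counts must be non-negative")
        if self.bubble_density < 0 or self.trichome_density_gradient < 0:
            raise ValueError("densities must be non-negative")


@dataclass(frozen=True)
class RenderSettings:
    """Appearance parameters of the renderer (µm sizes, colours, noise)."""

    dpi: float = 1200.0  # desk-test default; 8500 dpi crops are supported
    egg_diameter_um: tuple[float, float] = (100.0, 150.0)
    feces_diameter_um: tuple[float, float] = (100.0, 250.0)
    bubble_diameter_um: tuple[float, float] = (110.0, 240.0)
    noise_sigma: float = 3.0
    adaxial_blur_sigma_px: float = 0.6
    trichome_density_youngest: float = 2.0  # lines per mm² of blade
    background_rgb: tuple[int, int, int] = (233, 231, 226)
    leaf_rgb: tuple[int, int, int] = (75, 140, 65)
    leaf_rgb_adaxial: tuple[int, int, int] = (66, 132, 60)
    damage_rgb: tuple[int, int, int] = (195, 185, 95)
    feces_rgb: tuple[int, int, int] = (22, 20, 16)
    egg_tints: tuple[tuple[int, int, int], ...] = (
        (210, 212, 175),  # translucent (freshly laid; faint warm cast)
        (225, 210, 140),  # straw yellow
        (240, 180, 80),   # orange (oldest, opaque)
    )
    margin_mm: float = 4.0
    spacing_mm: float = 3.0  # clear spacing between leaves (protocol: a few mm)

    @property
    def um_per_px(self) -> float:
        return dpi_to_um_per_px(self.dpi)


DEFAULT_RENDER = RenderSettings()


def default_plant_spec(
    n_leaves: int = 10,
    seed: int = 0,
    *,
    mean_eggs: float = 40.0,
    mean_feces: float = 25.0,
    mean_damage_fraction: float = 0.06,
    p_adaxial_egg: float = 1.0 / 6.0,
    p_adaxial_feces: float = 0.5,
    dispersion: float = 5.0,
    n_young_protected: int = 2,
) -> PlantSpec:
    """Sample a realistic plant: symptom totals drawn from overdispersed
    counts and spread over leaves in proportion to blade area, with the
    youngest ``n_young_protected`` leaves free of eggs and damage (their
    dense trichome coat keeps females off them; feces still occur there).
    """
    rng = np.random.default_rng([int(seed), 91])
    lengths = np.linspace(4.5, 14.0, n_leaves) if n_leaves > 1 else np.array([9.0])
    areas = lengths**2  # blade area scales with length²
    protected = np.arange(n_leaves) < min(n_young_protected, max(n_leaves - 1, 0))
    w_sym = np.where(protected, 0.0, areas)
    if w_sym.sum() == 0:
        w_sym = areas
    w_sym = w_sym / w_sym.sum()
    w_all = areas / areas.sum()

    def negbin(mean: float) -> int:
        if mean <= 0:
            return 0
        p = dispersion / (dispersion + mean)
        return int(rng.negative_binomial(dispersion, p))

    eggs = rng.multinomial(negbin(mean_eggs), w_sym)
    feces = rng.multinomial(negbin(mean_feces), w_all)
    # two-level damage variance: leaves of one plant share that plant's
    # susceptibility (between-plant CV ~15%, inbred accessions in a
    # controlled chamber), with within-plant leaf-to-leaf scatter (CV ~20%)
    m = np.clip(mean_damage_fraction, 0.0, 0.45)
    plant_factor = rng.gamma(45.0, 1.0 / 45.0)
    leaf_jitter = rng.gamma(25.0, 1.0 / 25.0, size=n_leaves)
    dmg = m * plant_factor * leaf_jitter
    dmg = np.where(protected, 0.0, np.clip(dmg, 0.0, 0.5))
    return PlantSpec(
        n_leaves=n_leaves,
        leaf_lengths_mm=[float(x) for x in lengths],
        eggs_per_leaf=[int(x) for x in eggs],
        feces_per_leaf=[int(x) for x in feces],
        damage_fraction_per_leaf=[float(x) for x in dmg],
        p_adaxial_egg=p_adaxial_egg,
        p_adaxial_feces=p_adaxial_feces,
        seed=int(seed),
    )


# --------------------------------------------------------------------------
# ground truth containers


@dataclass
class TruthObject:
    klass: str  # "egg" | "feces" | "bubble"
    side: str
    leaf_index: int  # -1 for objects not on any leaf
    center: tuple[float, float]  # (row, col) in that side's image
    diameter_um: float
    box: tuple[int, int, int, int]  # half-open (r0, c0, r1, c1)
    area_mm2: float = 0.0
    tint: str = ""


@dataclass
class GroundTruth:
    """Exact truth emitted by the generator for one plant."""

    objects: list[TruthObject]
    leaf_labels: dict  # side -> int array, 0 = background, i+1 = leaf i
    damage_masks: dict  # side -> bool array (same frame as that side's image)
    per_leaf: pd.DataFrame
    merged_damage: pd.DataFrame  # leaf_index, merged_damage_area_mm2
    plant_totals: dict
    um_per_px: float

    def objects_of(self, klass: str, side: str | None = None,
                   leaf_index: int | None = None) -> list[TruthObject]:
        out = [o for o in self.objects if o.klass == klass]
        if side is not None:
            out = [o for o in out if o.side == side]
        if leaf_index is not None:
            out = [o for o in out if o.leaf_index == leaf_index]
        return out


# --------------------------------------------------------------------------
# low-level helpers


def _blend(canvas: np.ndarray, rr: np.ndarray, cc: np.ndarray,
           color: np.ndarray, alpha) -> None:
    a = np.asarray(alpha, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    canvas[rr, cc] = (1.0 - a) * canvas[rr, cc] + a * color


def _topk_blob(shape: tuple[int, int], center: tuple[float, float],
               k: int, rough_radius: float, rng: np.random.Generator,
               allowed: np.ndarray | None = None,
               irregularity: float = 0.5,
               attract: np.ndarray | None = None) -> np.ndarray:
    """Boolean blob of exactly ``k`` pixels around ``center`` (or hugging the
    ``attract`` field if given).  Pixels are ranked by a shaped random field
    and the top ``k`` taken, so blob area is exact while the outline stays
    irregular."""
    if k <= 0:
        return np.zeros(shape, dtype=bool)
    if attract is None:
        rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
        base = -np.hypot(rows - center[0], cols - center[1]) / max(rough_radius, 1.0)
    else:
        base = attract
    noise = ndi.gaussian_filter(rng.standard_normal(shape),
                                sigma=max(rough_radius / 3.0, 1.0))
    nstd = noise.std() or 1.0
    value = base + irregularity * noise / nstd
    if allowed is not None:
        value = np.where(allowed, value, -np.inf)
        if int(np.count_nonzero(allowed)) < k:
            raise GenerationError(
                f"only {int(np.count_nonzero(allowed))} px available for a {k}-px blob")
    flat = np.argpartition(value.ravel(), -k)[-k:]
    mask = np.zeros(shape, dtype=bool)
    mask.ravel()[flat] = True
    return mask


def _connected_blob(shape: tuple[int, int], center: tuple[float, float],
                    k: int, rough_radius: float, rng: np.random.Generator,
                    allowed: np.ndarray,
                    irregularity: float = 0.45) -> np.ndarray:
    """Connected blob of exactly ``k`` pixels grown greedily by field value.

    Starting at the allowed pixel nearest ``center``, repeatedly annexes the
    highest-valued pixel on the current boundary; guarantees connectivity
    (a single pellet never fragments) while the noise field keeps the
    outline irregular."""
    import heapq

    if k <= 0:
        return np.zeros(shape, dtype=bool)
    if int(np.count_nonzero(allowed)) < k:
        raise GenerationError(f"not enough room for a {k}-px connected blob")
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    # superlinear distance penalty keeps the pellet compact; the noise only
    # roughens its outline
    dist = np.hypot(rows - center[0], cols - center[1]) / max(rough_radius, 1.0)
    base = -(dist ** 1.5)
    noise = ndi.gaussian_filter(rng.standard_normal(shape),
                                sigma=max(rough_radius / 3.0, 1.0))
    value = base + irregularity * noise / (noise.std() or 1.0)
    rr_a, cc_a = np.nonzero(allowed)
    start = int(np.argmin((rr_a - center[0]) ** 2 + (cc_a - center[1]) ** 2))
    sr, sc = int(rr_a[start]), int(cc_a[start])
    mask = np.zeros(shape, dtype=bool)
    seen = np.zeros(shape, dtype=bool)
    heap = [(-value[sr, sc], sr, sc)]
    seen[sr, sc] = True
    taken = 0
    while heap and taken < k:
        _, r, c = heapq.heappop(heap)
        mask[r, c] = True
        taken += 1
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                nr, nc = r + dr, c + dc
                if (0 <= nr < shape[0] and 0 <= nc < shape[1]
                        and not seen[nr, nc] and allowed[nr, nc]):
                    seen[nr, nc] = True
                    heapq.heappush(heap, (-value[nr, nc], nr, nc))
    if taken < k:
        raise GenerationError(f"connected region exhausted at {taken}/{k} px")
    return mask


def _bbox_of(rr: np.ndarray, cc: np.ndarray) -> tuple[int, int, int, int]:
    return int(rr.min()), int(cc.min()), int(rr.max()) + 1, int(cc.max()) + 1


# --------------------------------------------------------------------------
# geometry


@dataclass
class _LeafGeom:
    index: int
    center_rc: tuple[float, float]  # blade centre in plate px
    blade_ab: tuple[float, float]  # semi-axes (row, col) px
    petiole_len: float
    petiole_halfwidth: float


def _layout(spec: PlantSpec, um_per_px: float, settings: RenderSettings,
            rng: np.random.Generator) -> tuple[tuple[int, int], list[_LeafGeom]]:
    """Two-row plate layout, youngest leaf first, top row then bottom row."""
    mm = 1000.0 / um_per_px  # px per mm
    n = spec.n_leaves
    n_top = math.ceil(n / 2)
    margin = settings.margin_mm * mm
    spacing = settings.spacing_mm * mm

    geoms: list[_LeafGeom] = []
    widths = []
    for L in spec.leaf_lengths_mm:
        blade_len = 0.72 * L * mm
        aspect = rng.uniform(0.62, 0.78)
        a = blade_len / 2.0
        b = a * aspect
        geoms.append(_LeafGeom(index=len(geoms), center_rc=(0.0, 0.0),
                               blade_ab=(a, b),
                               petiole_len=0.28 * L * mm,
                               petiole_halfwidth=max(0.15 * mm, 1.5)))
        widths.append(2 * b)

    rows = [list(range(n_top)), list(range(n_top, n))]
    plate_w = 0.0
    y0 = margin
    for row in rows:
        if not row:
            continue
        x = margin
        h = max(2 * geoms[i].blade_ab[0] + geoms[i].petiole_len for i in row)
        for i in row:
            g = geoms[i]
            g.center_rc = (y0 + g.blade_ab[0], x + g.blade_ab[1])
            x += widths[i] + spacing
        plate_w = max(plate_w, x - spacing + margin)
        y0 += h + spacing
    plate_h = y0 - spacing + margin
    return (int(math.ceil(plate_h)), int(math.ceil(plate_w))), geoms


# --------------------------------------------------------------------------
# object attribute sampling (shared by renderer and truth-only path)


def _sample_objects(spec: PlantSpec, settings: RenderSettings,
                    rng: np.random.Generator) -> list[dict]:
    objs: list[dict] = []
    tints = ("transparent", "straw", "orange")
    for i in range(spec.n_leaves):
        for _ in range(spec.eggs_per_leaf[i]):
            side = ADAXIAL if rng.random() < spec.p_adaxial_egg else ABAXIAL
            d = rng.uniform(*settings.egg_diameter_um)
            objs.append({"klass": "egg", "leaf": i, "side": side, "diameter_um": d,
                         "tint": tints[rng.integers(0, 3)],
                         "aspect": rng.uniform(0.78, 0.95),
                         "angle": rng.uniform(0, math.pi)})
        for _ in range(spec.feces_per_leaf[i]):
            side = ADAXIAL if rng.random() < spec.p_adaxial_feces else ABAXIAL
            d = rng.uniform(*settings.feces_diameter_um)
            objs.append({"klass": "feces", "leaf": i, "side": side, "diameter_um": d,
                         "aspect": rng.uniform(0.75, 1.0), "tint": ""})
    return objs


# --------------------------------------------------------------------------
# the renderer


def generate_plant(
    spec: PlantSpec,
    settings: RenderSettings = DEFAULT_RENDER,
    meta: ScanMeta | None = None,
) -> tuple[ScanImage, ScanImage, GroundTruth]:
    """Render the abaxial and adaxial scans of one plant plus ground truth.

    Deterministic: the same spec (including its seed) and settings yield
    bit-identical images and truth.  The adaxial image is the horizontal
    mirror of the plate with added blur, tape mottling and bubble rings.
    """
    um = settings.um_per_px
    px_area_mm2 = (um / 1000.0) ** 2
    mm = 1000.0 / um
    rng_obj = np.random.default_rng([spec.seed, 1])
    rng_rnd = np.random.default_rng([spec.seed, 2])

    shape, geoms = _layout(spec, um, settings, rng_rnd)
    objs = _sample_objects(spec, settings, rng_obj)

    canvases = {
        s: np.broadcast_to(np.asarray(settings.background_rgb, float),
                           shape + (3,)).copy()
        for s in SIDES
    }
    leaf_labels = np.zeros(shape, dtype=np.int16)
    damage = {s: np.zeros(shape, dtype=bool) for s in SIDES}

    leaves: list[dict] = []

    # --- leaves, damage, trichomes ----------------------------------------
    for g in geoms:
        a, b = g.blade_ab
        r0 = max(int(g.center_rc[0] - a) - 2, 0)
        r1 = min(int(g.center_rc[0] + a + g.petiole_len) + 3, shape[0])
        c0 = max(int(g.center_rc[1] - b) - 2, 0)
        c1 = min(int(g.center_rc[1] + b) + 3, shape[1])
        sl = np.s_[r0:r1, c0:c1]
        cshape = (r1 - r0, c1 - c0)
        lc = (g.center_rc[0] - r0, g.center_rc[1] - c0)

        blade = np.zeros(cshape, dtype=bool)
        rr, cc = skdraw.ellipse(lc[0], lc[1], a, b, shape=cshape)
        blade[rr, cc] = True
        full = blade.copy()
        pr0 = int(lc[0] + a * 0.8)
        pr1 = min(int(lc[0] + a + g.petiole_len), cshape[0])
        pc0 = max(int(lc[1] - g.petiole_halfwidth), 0)
        pc1 = min(int(lc[1] + g.petiole_halfwidth) + 1, cshape[1])
        full[pr0:pr1, pc0:pc1] = True
        leaf_labels[sl][full] = g.index + 1
        blade_px = int(np.count_nonzero(blade))

        # per-side damage sharing a common core
        frac = spec.damage_fraction_per_leaf[g.index]
        T = int(round(frac * blade_px))
        dmg_side = {s: np.zeros(cshape, dtype=bool) for s in SIDES}
        if T > 0:
            interior = ndi.binary_erosion(blade, iterations=3)
            rr_i, cc_i = np.nonzero(interior)
            if len(rr_i) == 0:
                raise GenerationError(f"leaf {g.index}: blade too small for damage")
            pick = rng_rnd.integers(0, len(rr_i))
            center = (float(rr_i[pick]), float(cc_i[pick]))
            rough_r = math.sqrt(T / math.pi)
            k_core = int(round(spec.damage_side_overlap * T))
            core = _topk_blob(cshape, center, k_core, rough_r, rng_rnd, allowed=blade)
            if k_core > 0:
                attract = -ndi.distance_transform_edt(~core) / max(rough_r, 1.0)
            else:
                rows_, cols_ = np.mgrid[0:cshape[0], 0:cshape[1]]
                attract = -np.hypot(rows_ - center[0], cols_ - center[1]) / max(rough_r, 1.0)
            for s in SIDES:
                extra_k = T - k_core
                if extra_k > 0:
                    extra = _topk_blob(cshape, center, extra_k, rough_r, rng_rnd,
                                       allowed=blade & ~core, irregularity=0.6,
                                       attract=attract)
                    dmg_side[s] = core | extra
                else:
                    dmg_side[s] = core.copy()
                damage[s][sl] |= dmg_side[s]

        # painting
        base = {ABAXIAL: np.asarray(settings.leaf_rgb, float),
                ADAXIAL: np.asarray(settings.leaf_rgb_adaxial, float)}
        jitter = rng_rnd.normal(0, 5, size=3)
        dens_young = settings.trichome_density_youngest
        dens_old = dens_young * spec.trichome_density_gradient
        t = g.index / max(spec.n_leaves - 1, 1)  # 0 = youngest
        density = dens_young + (dens_old - dens_young) * t
        n_trich = int(rng_rnd.poisson(density * blade_px * px_area_mm2))
        rr_b, cc_b = np.nonzero(blade)
        trich = [(int(rng_rnd.integers(0, len(rr_b))),
                  float(rng_rnd.uniform(0, 2 * math.pi)))
                 for _ in range(n_trich)] if len(rr_b) else []
        for s in SIDES:
            sub = canvases[s][sl]
            color = np.clip(base[s] + jitter, 0, 255)
            rr_f, cc_f = np.nonzero(full)
            _blend(sub, rr_f, cc_f, color, 1.0)
            pet = full & ~blade
            rr_p, cc_p = np.nonzero(pet)
            if len(rr_p):
                _blend(sub, rr_p, cc_p, np.clip(color * 1.06 + 3, 0, 255), 1.0)
            rr_d, cc_d = np.nonzero(dmg_side[s])
            if len(rr_d):
                dcol = np.clip(np.asarray(settings.damage_rgb, float) + jitter * 0.5, 0, 255)
                _blend(sub, rr_d, cc_d, dcol, 0.9)
            tl = 0.25 * mm
            for j, ang in trich:
                r1_ = int(np.clip(rr_b[j] + tl * math.sin(ang), 0, cshape[0] - 1))
                c1_ = int(np.clip(cc_b[j] + tl * math.cos(ang), 0, cshape[1] - 1))
                lr, lcc = skdraw.line(int(rr_b[j]), int(cc_b[j]), r1_, c1_)
                _blend(sub, lr, lcc, np.array([185.0, 192.0, 178.0]), 0.45)

        leaves.append({"geom": g, "sl": sl, "origin": (r0, c0), "blade": blade,
                       "dmg": dmg_side, "blade_px": blade_px,
                       "leaf_area_px": int(np.count_nonzero(full))})

    # --- eggs and feces ----------------------------------------------------
    truth_objects: list[TruthObject] = []
    placed: dict = {}  # (leaf, side) -> list of (row, col, r_px) in crop coords
    counts = {(i, s): {"egg_count": 0, "feces_count": 0, "feces_area_mm2": 0.0}
              for i in range(spec.n_leaves) for s in SIDES}
    max_r = max(settings.egg_diameter_um[1], settings.feces_diameter_um[1]) / um / 2.0
    for lf in leaves:
        lf["interior"] = ndi.binary_erosion(lf["blade"],
                                            iterations=int(math.ceil(max_r)) + 2)
        lf["int_px"] = np.nonzero(lf["interior"])

    for obj in objs:
        lf = leaves[obj["leaf"]]
        side = obj["side"]
        r_px = obj["diameter_um"] / um / 2.0
        rr_i, cc_i = lf["int_px"]
        if len(rr_i) == 0:
            raise GenerationError(
                f"leaf {obj['leaf']} is too small to host a {obj['klass']}")
        key = (obj["leaf"], side)
        placed.setdefault(key, [])
        pos = None
        for _ in range(300):
            j = int(rng_rnd.integers(0, len(rr_i)))
            r, c = float(rr_i[j]), float(cc_i[j])
            if obj["klass"] == "egg":
                # keep eggs off chlorotic tissue so their contrast is defined
                w = int(math.ceil(r_px)) + 1
                win = lf["dmg"][side][max(int(r) - w, 0):int(r) + w + 1,
                                      max(int(c) - w, 0):int(c) + w + 1]
                if win.any():
                    continue
            ok = all((r - pr) ** 2 + (c - pc) ** 2 >= (r_px + prad + 3.0) ** 2
                     for pr, pc, prad in placed[key])
            if ok:
                pos = (r, c)
                break
        if pos is None:
            raise GenerationError(
                f"leaf {obj['leaf']}: no room left for a {obj['klass']} "
                f"({obj['diameter_um']:.0f} µm) on the {side} side")
        placed[key].append((pos[0], pos[1], r_px))
        orr, occ = lf["origin"]
        sub = canvases[side][lf["sl"]]
        cshape = sub.shape[:2]

        if obj["klass"] == "egg":
            a = r_px / math.sqrt(obj["aspect"])
            b = r_px * math.sqrt(obj["aspect"])
            rr, cc = skdraw.ellipse(pos[0], pos[1], a, b,
                                    rotation=obj["angle"], shape=cshape)
            tint_idx = {"transparent": 0, "straw": 1, "orange": 2}[obj["tint"]]
            tint = np.asarray(settings.egg_tints[tint_idx], float)
            rho = np.hypot(rr - pos[0], cc - pos[1]) / max(r_px, 1.0)
            # chorion gloss: specular-bright centre falling off to the rim
            shade = (1.18 - 0.38 * np.clip(rho, 0, 1.3) ** 2)[:, None]
            alpha = 0.8 if obj["tint"] == "transparent" else 0.92
            sub[rr, cc] = (1 - alpha) * sub[rr, cc] + alpha * np.clip(tint * shade, 0, 255)
            counts[(obj["leaf"], side)]["egg_count"] += 1
            truth_objects.append(TruthObject(
                klass="egg", side=side, leaf_index=obj["leaf"],
                center=(pos[0] + orr, pos[1] + occ),
                diameter_um=obj["diameter_um"],
                box=_bbox_of(rr + orr, cc + occ),
                area_mm2=len(rr) * px_area_mm2, tint=obj["tint"]))
        else:
            a = r_px / math.sqrt(obj["aspect"])
            b = r_px * math.sqrt(obj["aspect"])
            k = max(int(round(math.pi * a * b)), 4)
            blob = _connected_blob(cshape, pos, k, r_px, rng_rnd,
                                   allowed=lf["blade"], irregularity=0.3)
            rr, cc = np.nonzero(blob)
            _blend(sub, rr, cc, np.asarray(settings.feces_rgb, float), 0.97)
            counts[(obj["leaf"], side)]["feces_count"] += 1
            counts[(obj["leaf"], side)]["feces_area_mm2"] += len(rr) * px_area_mm2
            truth_objects.append(TruthObject(
                klass="feces", side=side, leaf_index=obj["leaf"],
                center=(float(rr.mean()) + orr, float(cc.mean()) + occ),
                diameter_um=2.0 * math.sqrt(len(rr) / math.pi) * um,
                box=_bbox_of(rr + orr, cc + occ),
                area_mm2=len(rr) * px_area_mm2))

    # --- adaxial degradation: bubbles, mottling, blur ----------------------
    plate_area_cm2 = shape[0] * shape[1] * px_area_mm2 / 100.0
    n_bubbles = int(rng_rnd.poisson(spec.bubble_density * plate_area_cm2))
    for _ in range(n_bubbles):
        d = rng_rnd.uniform(*settings.bubble_diameter_um)
        R = d / um / 2.0
        cr = float(rng_rnd.uniform(R + 1, shape[0] - R - 1))
        cb = float(rng_rnd.uniform(R + 1, shape[1] - R - 1))
        rr, cc = skdraw.disk((cr, cb), R, shape=shape)
        rho = np.hypot(rr - cr, cc - cb) / max(R, 1.0)
        rim = rho >= 0.68
        _blend(canvases[ADAXIAL], rr[~rim], cc[~rim],
               np.array([206.0, 207.0, 209.0]), 0.85)
        _blend(canvases[ADAXIAL], rr[rim], cc[rim],
               np.array([229.0, 230.0, 232.0]), 0.95)
        leaf_here = int(leaf_labels[int(round(cr)), int(round(cb))]) - 1
        truth_objects.append(TruthObject(
            klass="bubble", side=ADAXIAL, leaf_index=leaf_here,
            center=(cr, cb), diameter_um=d, box=_bbox_of(rr, cc)))

    mottle = ndi.gaussian_filter(rng_rnd.standard_normal(shape), sigma=25.0)
    canvases[ADAXIAL] += (4.0 * mottle / (mottle.std() or 1.0))[:, :, None]
    if settings.adaxial_blur_sigma_px > 0:
        for c in range(3):
            canvases[ADAXIAL][:, :, c] = ndi.gaussian_filter(
                canvases[ADAXIAL][:, :, c], sigma=settings.adaxial_blur_sigma_px)

    for s in SIDES:
        canvases[s] += rng_rnd.normal(0.0, settings.noise_sigma, size=shape + (3,))
        np.clip(canvases[s], 0, 255, out=canvases[s])

    # merged (cross-side union) damage in the shared plate frame
    merged_rows = []
    for lf in leaves:
        union = lf["dmg"][ABAXIAL] | lf["dmg"][ADAXIAL]
        merged_rows.append({
            "leaf_index": lf["geom"].index,
            "merged_damage_area_mm2": float(np.count_nonzero(union) * px_area_mm2),
        })

    # --- mirror the adaxial frame (plate turned over) ----------------------
    W = shape[1]
    adaxial_img = np.flip(canvases[ADAXIAL], axis=1)
    leaf_labels_ad = np.flip(leaf_labels, axis=1).copy()
    damage_ad = np.flip(damage[ADAXIAL], axis=1).copy()
    for o in truth_objects:
        if o.side == ADAXIAL:
            br0, bc0, br1, bc1 = o.box
            o.box = (br0, W - bc1, br1, W - bc0)
            o.center = (o.center[0], W - 1 - o.center[1])

    per_leaf = []
    for lf in leaves:
        i = lf["geom"].index
        leaf_area = lf["leaf_area_px"] * px_area_mm2
        for s in SIDES:
            c = counts[(i, s)]
            per_leaf.append({
                "leaf_index": i, "side": s, "leaf_area_mm2": leaf_area,
                "damage_area_mm2": float(np.count_nonzero(lf["dmg"][s]) * px_area_mm2),
                "egg_count": c["egg_count"], "feces_count": c["feces_count"],
                "feces_area_mm2": c["feces_area_mm2"],
            })
    per_leaf = pd.DataFrame(per_leaf)
    merged_df = pd.DataFrame(merged_rows)
    totals = {
        "egg_count": int(per_leaf["egg_count"].sum()),
        "feces_count": int(per_leaf["feces_count"].sum()),
        "feces_area_mm2": float(per_leaf["feces_area_mm2"].sum()),
        "damage_area_mm2": float(merged_df["merged_damage_area_mm2"].sum()),
        "damage_area_by_side_mm2": float(per_leaf["damage_area_mm2"].sum()),
        "leaf_area_mm2": float(
            per_leaf.loc[per_leaf["side"] == ABAXIAL, "leaf_area_mm2"].sum()),
    }

    truth = GroundTruth(
        objects=truth_objects,
        leaf_labels={ABAXIAL: leaf_labels, ADAXIAL: leaf_labels_ad},
        damage_masks={ABAXIAL: damage[ABAXIAL], ADAXIAL: damage_ad},
        per_leaf=per_leaf, merged_damage=merged_df, plant_totals=totals,
        um_per_px=um,
    )

    def _meta_for(side: str) -> ScanMeta | None:
        if meta is None:
            return None
        return ScanMeta(side=side, ecotype_label=meta.ecotype_label,
                        ecotype_index=meta.ecotype_index, replicate=meta.replicate,
                        declared_leaf_count=meta.declared_leaf_count,
                        batch=meta.batch)

    scan_ab = ScanImage(canvases[ABAXIAL].round().astype(np.uint8), um,
                        ABAXIAL, _meta_for(ABAXIAL))
    scan_ad = ScanImage(np.ascontiguousarray(adaxial_img).round().astype(np.uint8),
                        um, ADAXIAL, _meta_for(ADAXIAL))
    return scan_ab, scan_ad, truth


# --------------------------------------------------------------------------
# experiment-level generation


@dataclass(frozen=True)
class EcotypeDesign:
    """Mean symptom levels and dispersion for one ecotype."""

    mean_eggs: float = 40.0
    mean_feces: float = 25.0
    mean_damage_fraction: float = 0.06
    dispersion: float = 5.0
    p_adaxial_egg: float = 1.0 / 6.0
    p_adaxial_feces: float = 0.5


@dataclass
class ExperimentResult:
    specs: list  # (ScanMeta template, PlantSpec) per plant
    table: TraitTable
    scans: list | None = None  # [(ScanImage, ScanImage, GroundTruth)] if rendered


def generate_experiment(
    design: dict,
    n_plants_per_ecotype: int = 6,
    reference_label: str = "Col-0",
    seed: int = 0,
    *,
    n_batches: int = 1,
    n_leaves: int = 8,
    n_females: int = 10,
    settings: RenderSettings = DEFAULT_RENDER,
    render: bool = False,
) -> ExperimentResult:
    """Sample a multi-ecotype infestation experiment with a reference ecotype.

    Per-plant symptom totals are drawn from negative-binomial distributions
    (damage fractions from a beta); the master truth table records the true
    per-plant values.  With ``render=True`` the plate scans are generated as
    well (slower); with ``render=False`` the truth table uses analytic blade
    areas.  Deterministic given ``seed``.
    """
    if reference_label not in design:
        raise ValueError(f"design must include the reference ecotype {reference_label!r}")
    if n_plants_per_ecotype < 2:
        raise ValueError("need at least 2 plants per ecotype for statistics")
    rng = np.random.default_rng([int(seed), 7])

    specs = []
    plant_rows = []
    leaf_rows = []
    scans = [] if render else None
    plant_id = 0
    labels = list(design)
    for batch_i in range(n_batches):
        batch = f"K{batch_i + 1}"
        for label in labels:
            des: EcotypeDesign = design[label]
            for rep in range(1, n_plants_per_ecotype + 1):
                plant_seed = int(rng.integers(0, 2**31 - 1))
                spec = default_plant_spec(
                    n_leaves=n_leaves, seed=plant_seed,
                    mean_eggs=des.mean_eggs, mean_feces=des.mean_feces,
                    mean_damage_fraction=des.mean_damage_fraction,
                    p_adaxial_egg=des.p_adaxial_egg,
                    p_adaxial_feces=des.p_adaxial_feces,
                    dispersion=des.dispersion,
                )
                meta = ScanMeta(side=ABAXIAL, ecotype_label=label,
                                ecotype_index=labels.index(label) + 1,
                                replicate=rep, declared_leaf_count=n_leaves,
                                batch=batch)
                specs.append((meta, spec))
                row, lrows = _truth_rows(spec, settings, n_females)
                row.update({"plant_id": plant_id, "ecotype": label,
                            "replicate": rep, "batch": batch})
                for lr in lrows:
                    lr.update({"plant_id": plant_id, "ecotype": label})
                plant_rows.append(row)
                leaf_rows.extend(lrows)
                if render:
                    scans.append(generate_plant(spec, settings, meta))
                plant_id += 1

    table = TraitTable(plants=pd.DataFrame(plant_rows),
                       leaves=pd.DataFrame(leaf_rows))
    return ExperimentResult(specs=specs, table=table, scans=scans)


def _truth_rows(spec: PlantSpec, settings: RenderSettings,
                n_females: int) -> tuple[dict, list[dict]]:
    """True per-plant and per-leaf trait values implied by a spec, without
    rendering.  Blade areas are analytic (mean-aspect ellipse); object sides
    and sizes replay the same random stream the renderer consumes."""
    objs = _sample_objects(spec, settings, np.random.default_rng([spec.seed, 1]))
    n = spec.n_leaves
    blade_mm2 = np.array([
        math.pi * (0.72 * L / 2.0) ** 2 * 0.70 for L in spec.leaf_lengths_mm
    ])
    egg_ab = np.zeros(n, dtype=int)
    egg_ad = np.zeros(n, dtype=int)
    fec_ab = np.zeros(n)
    fec_ad = np.zeros(n)
    fec_n = np.zeros(n, dtype=int)
    for o in objs:
        i = o["leaf"]
        if o["klass"] == "egg":
            (egg_ad if o["side"] == ADAXIAL else egg_ab)[i] += 1
        else:
            area = math.pi * (o["diameter_um"] / 2000.0) ** 2  # mm²
            if o["side"] == ADAXIAL:
                fec_ad[i] += area
            else:
                fec_ab[i] += area
            fec_n[i] += 1
    dmg_side = np.asarray(spec.damage_fraction_per_leaf) * blade_mm2  # per side
    ov = spec.damage_side_overlap
    dmg_merged = dmg_side * (2.0 - ov)  # |A ∪ B| with |A| = |B|, |A∩B| = ov·|A|
    total_eggs = int(egg_ab.sum() + egg_ad.sum())
    row = {
        "egg_count": total_eggs,
        "oviposition_rate": total_eggs / n_females,
        "feces_count": int(fec_n.sum()),
        "feces_area_mm2": float(fec_ab.sum() + fec_ad.sum()),
        "damage_area_mm2": float(dmg_merged.sum()),
        "egg_count_abaxial": int(egg_ab.sum()),
        "egg_count_adaxial": int(egg_ad.sum()),
        "feces_area_abaxial": float(fec_ab.sum()),
        "feces_area_adaxial": float(fec_ad.sum()),
    }
    lrows = [{
        "position_from_oldest": n - 1 - i,
        "egg_count": int(egg_ab[i] + egg_ad[i]),
        "feces_area_mm2": float(fec_ab[i] + fec_ad[i]),
        "damage_area_mm2": float(dmg_merged[i]),
    } for i in range(n)]
    return row, lrows
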