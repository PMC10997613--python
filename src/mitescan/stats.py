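"""Susceptibility statistics across plant genotypes.

Works on a tidy trait table with one row per plant (ecotype, replicate,
batch, whole-plant trait values, per-side totals) plus an optional long
per-leaf table for positional distributions.  Analyses mirror a standard
multi-genotype susceptibility screen:

* absolute trait values, and relative values normalised per experimental
  batch by the mean of the reference ecotype grown in that batch;
* one-way ANOVA followed by Tukey HSD pairwise comparisons, summarised as a
  compact letter display (CLD) — genotypes sharing a letter do not differ
  significantly;
* dynamic range: max/min ratio of ecotype means, a one-number summary of
  how much the screen separates genotypes;
* trait distribution over consecutive rosette leaves (indexed from the
  oldest leaf) and over the two leaf surfaces (adaxial fraction).

Group means are reported ± SE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "TraitTable",
    "CLDResult",
    "relative_values",
    "anova_cld",
    "letters_from_matrix",
    "dynamic_range",
    "leaf_distribution",
    "side_distribution",
]

PLANT_TRAITS = ("damage_area_mm2", "oviposition_rate", "feces_area_mm2", "egg_count")


@dataclass
class TraitTable:
    """Per-plant (wide) and per-leaf (long) trait measurements.

    ``plants`` columns: plant_id, ecotype, replicate, batch, the whole-plant
    traits in :data:`PLANT_TRAITS`, and per-side totals
    ``{egg_count,feces_area_mm2}_{abaxial,adaxial}``.
    ``leaves`` columns: plant_id, ecotype, position_from_oldest, and per-leaf
    trait values.
    """

    plants: pd.DataFrame
    leaves: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        req = {"plant_id", "ecotype"}
        missing = req - set(self.plants.columns)
        if missing:
            raise ValueError(f"plants table missing columns: {sorted(missing)}")
        num = self.plants.select_dtypes(include=[np.number])
        if (num < 0).any().any():
            raise ValueError("trait table contains negative values")

    def group_sizes(self) -> pd.Series:
        return self.plants.groupby("ecotype").size()


# --------------------------------------------------------------------------
# relative values

def relative_values(
    table: TraitTable,
    traits: tuple[str, ...] = PLANT_TRAITS,
    reference_label: str = "Col-0",
    n_reference: int = 6,
) -> pd.DataFrame:
    """Divide each plant's traits by its batch's mean reference-ecotype value.

    Every experimental batch must contain at least ``n_reference`` plants of
    the reference ecotype; scaling is strictly within-batch so that batches
    measured weeks apart remain comparable.
    """
    plants = table.plants
    if "batch" not in plants.columns:
        raise ValueError("plants table has no 'batch' column")
    out = plants.copy()
    for batch, grp in plants.groupby("batch"):
        ref = grp[grp["ecotype"] == reference_label]
        if len(ref) == 0:
            raise ValueError(f"batch {batch!r} contains no {reference_label!r} reference plants")
        if len(ref) < n_reference:
            warnings.warn(
                f"batch {batch!r} has only {len(ref)} reference plants "
                f"(expected >= {n_reference})",
                stacklevel=2,
            )
        for trait in traits:
            if trait not in plants.columns:
                continue
            mean_ref = ref[trait].mean()
            idx = grp.index
            if mean_ref == 0:
                warnings.warn(
                    f"batch {batch!r}: reference mean of {trait} is zero; "
                    "relative values set to NaN",
                    stacklevel=2,
                )
                out.loc[idx, trait] = np.nan
            else:
                out.loc[idx, trait] = plants.loc[idx, trait] / mean_ref
    return out


# --------------------------------------------------------------------------
# ANOVA + Tukey + compact letter display

@dataclass
class CLDResult:
    """Group means ± SE with compact letters and the underlying decisions."""

    summary: pd.DataFrame  # index: group; columns: n, mean, se, letters
    alpha: float
    anova_p: float
    #: symmetric boolean matrix, True where the pair differs significantly
    significant: pd.DataFrame = field(repr=False, default=None)
    tukey: pd.DataFrame | None = field(repr=False, default=None)

    @property
    def groups(self) -> list:
        return list(self.summary.index)

    def share_letter(self, a, b) -> bool:
        la = set(self.summary.loc[a, "letters"])
        lb = set(self.summary.loc[b, "letters"])
        return bool(la & lb)


def letters_from_matrix(
    groups: list,
    significant: np.ndarray,
    order: np.ndarray | None = None,
) -> dict:
    """Compact letters from a pairwise significance matrix (insert-and-absorb).

    Guarantees that two groups share a letter iff their pair is *not*
    significant, and absorbs redundant letters so the cover is minimal.
    ``order`` (e.g. by descending mean) controls letter naming only.
    """
    k = len(groups)
    significant = np.asarray(significant, dtype=bool)
    if significant.shape != (k, k):
        raise ValueError("significance matrix shape mismatch")
    if order is None:
        order = np.arange(k)

    letters: list[set] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not significant[i, j]:
                continue
            new_letters: list[set] = []
            for L in letters:
                if i in L and j in L:
                    new_letters.append(L - {i})
                    new_letters.append(L - {j})
                else:
                    new_letters.append(L)
            # absorb: drop any letter that is a subset of another
            new_letters.sort(key=len, reverse=True)
            kept: list[set] = []
            for L in new_letters:
                if not any(L <= K for K in kept):
                    kept.append(L)
            letters = kept

    # name letters a, b, c … by first appearance along the given group order
    pos_of = {int(g): p for p, g in enumerate(order)}

    def first_pos(L: set) -> int:
        return min((pos_of[gi] for gi in L), default=k)

    letters.sort(key=first_pos)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assignment: dict = {g: "" for g in groups}
    for li, L in enumerate(letters):
        name = alphabet[li] if li < len(alphabet) else f"l{li}"
        for gi in sorted(L, key=lambda x: pos_of[x]):
            assignment[groups[gi]] += name
    for g in groups:
        assignment[g] = "".join(sorted(assignment[g]))
    return assignment


def anova_cld(
    data: TraitTable | pd.DataFrame,
    trait: str,
    group_col: str = "ecotype",
    alpha: float = 0.05,
) -> CLDResult:
    """One-way ANOVA across groups; if significant, Tukey HSD + letters.

    When the global ANOVA does not reject, no pairwise comparison is
    declared significant and all groups share the single letter "a".
    """
    df = data.plants if isinstance(data, TraitTable) else data
    df = df[[group_col, trait]].dropna()
    groups = sorted(df[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups for ANOVA")
    samples = [df.loc[df[group_col] == g, trait].to_numpy(dtype=float) for g in groups]
    for g, s in zip(groups, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        anova_p = 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            anova_p = float(sps.f_oneway(*samples).pvalue)
        if np.isnan(anova_p):
            anova_p = 1.0

    k = len(groups)
    sig = np.zeros((k, k), dtype=bool)
    tukey_frame = None
    if anova_p <= alpha:
        res = pairwise_tukeyhsd(
            df[trait].to_numpy(dtype=float),
            df[group_col].to_numpy(),
            alpha=alpha,
        )
        tukey_frame = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
        pairs = [
            (a, b) for ai, a in enumerate(res.groupsunique) for b in res.groupsunique[ai + 1 :]
        ]
        for (a, b), rej in zip(pairs, res.reject):
            ia, ib = groups.index(a), groups.index(b)
            sig[ia, ib] = sig[ib, ia] = bool(rej)

    means = np.array([s.mean() for s in samples])
    ses = np.array([s.std(ddof=1) / np.sqrt(len(s)) for s in samples])
    order = np.argsort(-means, kind="stable")
    assignment = letters_from_matrix(groups, sig, order=order)
    summary = pd.DataFrame(
        {
            "n": [len(s) for s in samples],
            "mean": means,
            "se": ses,
            "letters": [assignment[g] for g in groups],
        },
        index=pd.Index(groups, name=group_col),
    )
    sig_df = pd.DataFrame(sig, index=groups, columns=groups)
    return CLDResult(summary=summary, alpha=alpha, anova_p=anova_p,
                     significant=sig_df, tukey=tukey_frame)


# --------------------------------------------------------------------------
# dynamic range

def dynamic_range(
    data: TraitTable | pd.DataFrame,
    trait: str,
    group_col: str = "ecotype",
) -> float:
    """Ratio of the largest to the smallest ecotype mean for a trait."""
    df = data.plants if isinstance(data, TraitTable) else data
    means = df.groupby(group_col)[trait].mean()
    if len(means) < 2:
        raise ValueError("need at least two ecotypes")
    lo, hi = float(means.min()), float(means.max())
    if lo == 0:
        warnings.warn(f"{trait}: smallest ecotype mean is zero; dynamic range is infinite",
                      stacklevel=2)
        return float("inf")
    return hi / lo


# --------------------------------------------------------------------------
# distributions over leaves and sides

def plot_cld_bars(cld: CLDResult, ax=None, ylabel: str = ""):
    """Bar chart of group means ± SE annotated with the compact letters."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.6 * len(cld.groups)), 3.2))
    s = cld.summary.sort_values("mean", ascending=False)
    x = np.arange(len(s))
    ax.bar(x, s["mean"], yerr=s["se"], capsize=3, color="#7fa86b",
           edgecolor="black", linewidth=0.5)
    for xi, (m, se, let) in enumerate(zip(s["mean"], s["se"], s["letters"])):
        ax.text(xi, m + (se if np.isfinite(se) else 0) + 0.02 * s["mean"].max(),
                let, ha="center", va="bottom", fontsize=9)
    ax.set_xticks(x, s.index, rotation=45, ha="right")
    ax.set_ylabel(ylabel)
    ax.figure.tight_layout()
    return ax


def leaf_distribution(
    table: TraitTable,
    trait: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mean ± SE of a trait per leaf position (0 = oldest leaf) with CLD.

    Plants with different leaf counts are aligned from the oldest leaf;
    positions a plant does not have are simply absent from that plant's
    rows and excluded from the means.
    """
    if table.leaves is None:
        raise ValueError("trait table has no per-leaf data")
    lv = table.leaves
    grp = lv.groupby("position_from_oldest")[trait]
    out = grp.agg(n="count", mean="mean").reset_index()
    out["se"] = grp.sem().to_numpy()
    single = out["n"] < 2
    if single.any():
        out.loc[single, "se"] = np.nan
        warnings.warn(
            "some leaf positions are represented by a single plant; SE undefined there",
            stacklevel=2,
        )
    # CLD across positions where replication allows it
    ok_pos = out.loc[out["n"] >= 2, "position_from_oldest"]
    out["letters"] = ""
    if len(ok_pos) >= 2:
        sub = lv[lv["position_from_oldest"].isin(ok_pos)]
        cld = anova_cld(sub, trait, group_col="position_from_oldest", alpha=alpha)
        mapping = cld.summary["letters"].to_dict()
        out["letters"] = out["position_from_oldest"].map(mapping).fillna("")
    return out


def side_distribution(
    table: TraitTable,
    trait: str = "egg_count",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, CLDResult | None]:
    """Adaxial fraction of a trait per plant, summarised per ecotype with CLD.

    The fraction is adaxial / (adaxial + abaxial) per plant; plants with a
    zero total carry no information about side preference and are excluded
    with a warning.
    """
    ab_col = f"{trait}_abaxial"
    ad_col = f"{trait}_adaxial"
    plants = table.plants
    for col in (ab_col, ad_col):
        if col not in plants.columns:
            raise ValueError(f"plants table has no column {col!r}")
    total = plants[ab_col] + plants[ad_col]
    keep = total > 0
    if (~keep).any():
        warnings.warn(
            f"{trait}: excluded {int((~keep).sum())} plant(s) with zero total",
            stacklevel=2,
        )
    df = plants[keep].copy()
    df["adaxial_fraction"] = df[ad_col] / (df[ab_col] + df[ad_col])
    grp = df.groupby("ecotype")["adaxial_fraction"]
    summary = grp.agg(n="count", mean="mean").reset_index()
    summary["se"] = grp.sem().to_numpy()
    cld = None
    counts = df.groupby("ecotype").size()
    if len(counts) >= 2 and (counts >= 2).all():
        cld = anova_cld(df, "adaxial_fraction", alpha=alpha)
        summary["letters"] = summary["ecotype"].map(cld.summary["letters"].to_dict())
    return summary, cld
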