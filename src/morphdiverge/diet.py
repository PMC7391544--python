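"""Diet-composition statistics.

Occurrence rates (F%) per prey item, wet-weight percentages (W%) per food
category, Schoener's proportional overlap index between the two morphs,
and per-category Kruskal-Wallis tests of the per-specimen compositions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import DIET_CATEGORIES

#: Conventional threshold above which diet overlap is considered
#: biologically significant.
OVERLAP_THRESHOLD = 0.6


def exclude_empty_guts(diet: pd.DataFrame) -> pd.DataFrame:
    """Drop specimens whose total prey wet weight is zero.

    Guts containing only gelatinous material (gastric juices etc.) carry
    no countable prey and are excluded before N_total is formed.
    """
    totals = diet.groupby("specimen_id")["wet_weight_g"].sum()
    keep = totals.index[totals > 0]
    return diet[diet["specimen_id"].isin(keep)].copy()


def occurrence_rate(diet: pd.DataFrame, morph: str | None = None) -> pd.Series:
    """F% per prey item: 100 * (guts containing the item) / (guts with food).

    Guts may contain several prey items, so the F% values can sum past 100.
    """
    d = diet if morph is None else diet[diet["morph"] == morph]
    d = exclude_empty_guts(d)
    n_total = d["specimen_id"].nunique()
    if n_total < 1:
        raise ValueError(
            f"no guts with food{'' if morph is None else f' for morph {morph!r}'}"
        )
    counts = (
        d[d["present"].astype(bool)]
        .groupby("prey_item")["specimen_id"]
        .nunique()
        .reindex(sorted(d["prey_item"].unique()), fill_value=0)
    )
    return 100.0 * counts / n_total


def weight_percentage(diet: pd.DataFrame, morph: str | None = None) -> pd.Series:
    """W% per category: 100 * W_c / W_total over the six categories."""
    d = diet if morph is None else diet[diet["morph"] == morph]
    d = exclude_empty_guts(d)
    w_total = d["wet_weight_g"].sum()
    if w_total <= 0:
        raise ValueError("total prey wet weight is zero; W% undefined")
    by_cat = (
        d.groupby("category")["wet_weight_g"].sum().reindex(DIET_CATEGORIES, fill_value=0.0)
    )
    return 100.0 * by_cat / w_total


@dataclass
class DietComposition:
    """Per-morph composition summary (F% by item, W% by category)."""

    morph: str
    n_total: int
    w_total: float
    f_pct: pd.Series
    w_pct: pd.Series


def diet_composition(diet: pd.DataFrame, morph: str) -> DietComposition:
    d = exclude_empty_guts(diet[diet["morph"] == morph])
    if d["specimen_id"].nunique() < 1:
        raise ValueError(f"no guts with food for morph {morph!r}")
    return DietComposition(
        morph=morph,
        n_total=int(d["specimen_id"].nunique()),
        w_total=float(d["wet_weight_g"].sum()),
        f_pct=occurrence_rate(diet, morph),
        w_pct=weight_percentage(diet, morph),
    )


@dataclass
class OverlapResult:
    c_xy: float
    significant: bool  # exceeds the 0.6 biological-overlap convention
    p_x: np.ndarray
    p_y: np.ndarray


def schoener_overlap(p_x, p_y) -> OverlapResult:
    """Schoener's proportional overlap C_xy = 1 - 0.5 * sum |P_xc - P_yc|.

    Inputs are the six category proportions of each morph and must each
    sum to 1 (no silent renormalization). Symmetric, bounded in [0, 1],
    equal to 1 exactly when the compositions coincide. The literature also
    calls this statistic D_xy; one statistic underlies both symbols.
    """
    p_x = np.asarray(p_x, dtype=float)
    p_y = np.asarray(p_y, dtype=float)
    if p_x.shape != p_y.shape:
        raise ValueError("composition vectors differ in length")
    for name, v in (("x", p_x), ("y", p_y)):
        if np.any(v < -1e-12):
            raise ValueError(f"composition {name} has negative entries")
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"composition {name} sums to {v.sum():.8f}, not 1; "
                "pass proportions, not percentages"
            )
    c = 1.0 - 0.5 * float(np.sum(np.abs(p_x - p_y)))
    c = float(np.clip(c, 0.0, 1.0))
    return OverlapResult(
        c_xy=c, significant=c > OVERLAP_THRESHOLD, p_x=p_x, p_y=p_y
    )


def per_specimen_weight_pct(diet: pd.DataFrame) -> pd.DataFrame:
    """Per-specimen W% composition (rows: specimens, cols: six categories)."""
    d = exclude_empty_guts(diet)
    wide = (
        d.pivot_table(
            index=["specimen_id", "morph"],
            columns="category",
            values="wet_weight_g",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=DIET_CATEGORIES, fill_value=0.0)
    )
    return 100.0 * wide.div(wide.sum(axis=1), axis=0)


def overlap_from_table(diet: pd.DataFrame, basis: str = "pooled") -> OverlapResult:
    """Compute Schoener's overlap between the two morphs from a diet table.

    ``basis="pooled"`` (default) uses pooled wet-weight shares per morph —
    the W%-based definition; ``basis="mean"`` averages the per-specimen
    compositions first.
    """
    morphs = sorted(diet["morph"].unique())
    if len(morphs) != 2:
        raise ValueError(f"overlap needs exactly 2 morphs, found {morphs}")
    if basis == "pooled":
        p_x = weight_percentage(diet, morphs[0]).to_numpy() / 100.0
        p_y = weight_percentage(diet, morphs[1]).to_numpy() / 100.0
    elif basis == "mean":
        per = per_specimen_weight_pct(diet)
        grouped = per.groupby(level="morph").mean() / 100.0
        p_x = grouped.loc[morphs[0]].to_numpy()
        p_y = grouped.loc[morphs[1]].to_numpy()
    else:
        raise ValueError("basis must be 'pooled' or 'mean'")
    return schoener_overlap(p_x, p_y)


def category_tests(diet: pd.DataFrame) -> pd.DataFrame:
    """Kruskal-Wallis test of per-specimen W% between morphs, per category.

    The between-morph test is defined on the per-specimen compositions
    (each gut contributes one W% value per category); the statistic uses
    the standard tie correction. Categories absent from every specimen are
    flagged undefined; all-tied values give statistic 0.
    """
    per = per_specimen_weight_pct(diet)
    morphs = sorted(per.index.get_level_values("morph").unique())
    if len(morphs) != 2:
        raise ValueError(f"tests need exactly 2 morphs, found {morphs}")
    rows = []
    for cat in DIET_CATEGORIES:
        a = per.loc[per.index.get_level_values("morph") == morphs[0], cat].to_numpy()
        b = per.loc[per.index.get_level_values("morph") == morphs[1], cat].to_numpy()
        if np.all(np.concatenate([a, b]) == 0):
            rows.append(
                {"category": cat, "chi2": np.nan, "p": np.nan, "undefined": True}
            )
            continue
        try:
            with np.errstate(invalid="ignore"):
                h, p = stats.kruskal(a, b)
        except ValueError:  # all values identical: no ranks to compare
            h, p = 0.0, 1.0
        if not np.isfinite(h) and np.ptp(np.concatenate([a, b])) == 0:
            h, p = 0.0, 1.0  # every value tied: zero statistic by convention
        rows.append(
            {"category": cat, "chi2": float(h), "p": float(p), "undefined": False}
        )
    return pd.DataFrame(rows)
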