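"""CSV readers and validators for the trait, diet and growth tables.

All tables are comma-delimited UTF-8 with a header row. Validation errors
report the offending row (1-based, counting the header as row 1) so field
sheets can be fixed quickly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import DIET_CATEGORIES, MORPHS, TRAIT_NAMES, SchemaError

TRAIT_REQUIRED = ("specimen_id", "SL_mm") + TRAIT_NAMES
TRAIT_OPTIONAL = (
    "morph",
    "sex",
    "TL_mm",
    "W_g",
    "gill_raker_count",
    "gill_raker_length_mm",
    "tooth_rows",
    "parasite",
    "horny_edge_width_cm",
)

DIET_REQUIRED = ("specimen_id", "morph", "prey_item", "wet_weight_g")
GROWTH_REQUIRED = (
    "specimen_id",
    "morph",
    "sex",
    "age",
    "Lc_mm",
    "Oc_mm",
    "ring_index",
    "Oi_mm",
)


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing required columns: {missing}")


def _row(df: pd.DataFrame, idx) -> int:
    # +2: header is row 1 and pandas indices are 0-based
    return int(idx) + 2


def read_trait_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_trait_table(df)


def validate_trait_table(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, TRAIT_REQUIRED, "trait")
    df = df.copy()
    for col in ("SL_mm",) + TRAIT_NAMES:
        df[col] = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[df[col].isna()]
        if len(bad):
            raise SchemaError(
                f"trait column {col!r}: non-numeric value at row {_row(df, bad[0])}"
            )
    bad = df.index[df["SL_mm"] <= 0]
    if len(bad):
        raise SchemaError(f"SL_mm must be > 0 (row {_row(df, bad[0])})")
    # Ratio traits are strictly positive; UpperL1 (upper/lower jaw length)
    # routinely exceeds 1 and is not bounded above.
    for col in TRAIT_NAMES:
        bad = df.index[df[col] <= 0]
        if len(bad):
            raise SchemaError(f"ratio trait {col!r} must be > 0 (row {_row(df, bad[0])})")
    if "tooth_rows" in df.columns:
        bad = df.index[~df["tooth_rows"].isin([1, 2])]
        if len(bad):
            raise SchemaError(
                f"tooth_rows must be 1 or 2 (row {_row(df, bad[0])})"
            )
    if "morph" in df.columns:
        bad = df.index[~df["morph"].isin(MORPHS + ("unknown",))]
        if len(bad):
            raise SchemaError(
                f"unknown morph label {df.loc[bad[0], 'morph']!r} "
                f"(row {_row(df, bad[0])})"
            )
    return df


def read_diet_table(
    path: str | Path, category_map: dict[str, str] | None = None
) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_diet_table(df, category_map=category_map)


def validate_diet_table(
    df: pd.DataFrame, category_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Validate a long-format gut-content table.

    Each row is (specimen, prey_item, wet weight). Every prey item must map
    to exactly one of the six categories, either through a ``category``
    column or the supplied ``category_map``.
    """
    _require_columns(df, DIET_REQUIRED, "diet")
    df = df.copy()
    df["wet_weight_g"] = pd.to_numeric(df["wet_weight_g"], errors="coerce")
    bad = df.index[df["wet_weight_g"].isna()]
    if len(bad):
        raise SchemaError(f"non-numeric wet_weight_g at row {_row(df, bad[0])}")
    bad = df.index[df["wet_weight_g"] < 0]
    if len(bad):
        raise SchemaError(f"wet_weight_g must be >= 0 (row {_row(df, bad[0])})")
    if "category" not in df.columns:
        if category_map is None:
            unknown = sorted(df["prey_item"].unique())
            raise SchemaError(
                "diet table has no 'category' column and no category_map was "
                f"given; prey items needing a category: {unknown}"
            )
        unknown = sorted(set(df["prey_item"]) - set(category_map))
        if unknown:
            raise SchemaError(f"prey items with no category mapping: {unknown}")
        df["category"] = df["prey_item"].map(category_map)
    else:
        # an item must not be mapped to two different categories
        n_cats = df.groupby("prey_item")["category"].nunique()
        multi = sorted(n_cats.index[n_cats > 1])
        if multi:
            raise SchemaError(
                f"prey items mapped to more than one category: {multi}"
            )
    bad_cat = sorted(set(df["category"]) - set(DIET_CATEGORIES))
    if bad_cat:
        raise SchemaError(
            f"unknown diet categories {bad_cat}; expected one of {list(DIET_CATEGORIES)}"
        )
    bad = df.index[~df["morph"].isin(MORPHS)]
    if len(bad):
        raise SchemaError(
            f"unknown morph label {df.loc[bad[0], 'morph']!r} (row {_row(df, bad[0])})"
        )
    if "present" not in df.columns:
        df["present"] = df["wet_weight_g"] > 0
    return df


def read_growth_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_growth_table(df)


def validate_growth_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format otolith table (one row per annual ring).

    Enforced invariants: Lc > 0, 0 < Oi <= Oc, ring radii strictly
    increasing with ring index within each specimen, and ring indices
    running 1..age_at_capture.
    """
    _require_columns(df, GROWTH_REQUIRED, "growth")
    df = df.copy()
    for col in ("age", "Lc_mm", "Oc_mm", "ring_index", "Oi_mm"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[df[col].isna()]
        if len(bad):
            raise SchemaError(
                f"growth column {col!r}: non-numeric value at row {_row(df, bad[0])}"
            )
    for col, bound in (("Lc_mm", 0.0), ("Oc_mm", 0.0), ("Oi_mm", 0.0)):
        bad = df.index[df[col] <= bound]
        if len(bad):
            raise SchemaError(f"{col} must be > {bound} (row {_row(df, bad[0])})")
    bad = df.index[df["Oi_mm"] > df["Oc_mm"] * (1 + 1e-12)]
    if len(bad):
        i = bad[0]
        raise SchemaError(
            f"ring radius Oi_mm={df.loc[i, 'Oi_mm']} exceeds capture radius "
            f"Oc_mm={df.loc[i, 'Oc_mm']} for specimen "
            f"{df.loc[i, 'specimen_id']!r} (row {_row(df, i)})"
        )
    bad = df.index[df["age"] < 1]
    if len(bad):
        raise SchemaError(f"age must be >= 1 (row {_row(df, bad[0])})")
    for sid, grp in df.groupby("specimen_id", sort=False):
        grp = grp.sort_values("ring_index")
        rings = grp["ring_index"].to_numpy()
        age = int(grp["age"].iloc[0])
        if not np.array_equal(rings, np.arange(1, age + 1)):
            raise SchemaError(
                f"specimen {sid!r}: ring indices {rings.tolist()} do not run "
                f"1..{age} (age at capture)"
            )
        radii = grp["Oi_mm"].to_numpy()
        if np.any(np.diff(radii) <= 0):
            raise SchemaError(
                f"specimen {sid!r}: ring radii must be strictly increasing, "
                f"got {radii.tolist()}"
            )
    return df
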