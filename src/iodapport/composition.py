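"""Food-composition database construction from sample-level iodine measurements.

Raw laboratory measurements of iodine concentration in foods, salt and water are
right-skewed and left-censored at the analytical limit of detection (LOD).
This module applies the conventional half-LOD substitution to censored records
and summarises concentrations per food item or tissue group as
median (Q1, Q3) with min, max, n and the number of censored observations.

Units are never converted here: solids are mg kg⁻¹ dry weight (salt included),
water is μg L⁻¹.  Unit handling belongs to the supply and intake modules.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default limit of detection for solid matrices, mg kg⁻¹ dry weight.
LOD_SOLID = 0.01
#: Default limit of detection for liquid matrices (water), μg L⁻¹.
LOD_LIQUID = 0.25

#: Required columns of a measurements table.
MEASUREMENT_COLUMNS = [
    "sample_id",
    "item",
    "group",
    "basis",
    "value",
    "below_lod",
]

#: Columns of a composition-database table.
COMPOSITION_COLUMNS = [
    "key",
    "n",
    "median",
    "q1",
    "q3",
    "min",
    "max",
    "mean",
    "n_below_lod",
]

VALID_BASES = ("DW", "FW", "liquid")


def quartiles(values: Sequence[float] | np.ndarray) -> tuple[float, float, float]:
    """Return ``(q1, median, q3)`` of *values*.

    Order statistics are computed by linear interpolation between adjacent
    observations (the common "type 7" rule), the same convention used
    throughout the package for median (Q1, Q3) reporting.

    Raises
    ------
    ValueError
        If *values* is empty or contains NaN.
    """
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float)
    if arr.size == 0:
        raise ValueError("quartiles of an empty sequence are undefined")
    if np.isnan(arr).any():
        raise ValueError("quartiles: input contains NaN")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    return float(q1), float(med), float(q3)


def _row_lods(df: pd.DataFrame, lod: float | None,
              lod_solid: float, lod_liquid: float) -> pd.Series:
    if lod is not None:
        if lod <= 0:
            raise ValueError("lod must be positive")
        return pd.Series(float(lod), index=df.index)
    if lod_solid <= 0 or lod_liquid <= 0:
        raise ValueError("LODs must be positive")
    is_liquid = df["basis"].astype(str).str.lower().eq("liquid")
    return pd.Series(np.where(is_liquid, lod_liquid, lod_solid), index=df.index)


def substitute_below_lod(
    measurements: pd.DataFrame,
    lod: float | None = None,
    *,
    lod_solid: float = LOD_SOLID,
    lod_liquid: float = LOD_LIQUID,
) -> pd.DataFrame:
    """Replace censored values by half the limit of detection.

    A record is censored when its ``below_lod`` flag is set, or when its value
    is strictly below the applicable LOD (input files may carry "<x" strings
    that upstream parsing converts to a flag, but plain numbers below the LOD
    are treated identically).  Censored records get ``value = LOD / 2`` and
    ``below_lod = True``; everything else is returned unchanged, in the input
    order.  The operation is idempotent.

    Parameters
    ----------
    measurements
        Table with at least ``sample_id``, ``basis``, ``value``, ``below_lod``.
    lod
        Single LOD applied to every record.  If None (default), ``lod_solid``
        applies to DW/FW records and ``lod_liquid`` to liquid records.
    """
    _require_columns(measurements, ["sample_id", "basis", "value", "below_lod"],
                     "measurements")
    df = measurements.copy()
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    df["below_lod"] = df["below_lod"].fillna(False).astype(bool)

    negative = df["value"] < 0
    if negative.any():
        bad = ", ".join(map(str, df.loc[negative, "sample_id"].tolist()))
        raise ValueError(f"negative iodine concentration for sample(s): {bad}")

    missing_unflagged = df["value"].isna() & ~df["below_lod"]
    if missing_unflagged.any():
        bad = ", ".join(map(str, df.loc[missing_unflagged, "sample_id"].tolist()))
        raise ValueError(
            f"missing value without below-LOD flag for sample(s): {bad}")

    lods = _row_lods(df, lod, lod_solid, lod_liquid)
    censored = df["below_lod"] | (df["value"] < lods)
    df.loc[censored, "value"] = lods[censored] / 2.0
    df.loc[censored, "below_lod"] = True
    n_sub = int(censored.sum())
    if n_sub:
        logger.info("substituted half-LOD for %d of %d records", n_sub, len(df))
    return df


def summarize(measurements: pd.DataFrame, by: str = "group") -> pd.DataFrame:
    """Summarise substituted measurements per item or per tissue group.

    Returns one row per key with ``n, median, q1, q3, min, max, mean,
    n_below_lod``.  Mixing measurement bases (e.g. DW and liquid) within one
    key is a hard error because the statistics would mix units.

    Call :func:`substitute_below_lod` first; remaining NaN values are refused.
    """
    if by not in ("item", "group"):
        raise ValueError("by must be 'item' or 'group'")
    _require_columns(measurements, ["sample_id", by, "basis", "value", "below_lod"],
                     "measurements")
    if len(measurements) == 0:
        raise ValueError("cannot summarise an empty measurements table")
    if measurements["value"].isna().any():
        raise ValueError(
            "measurements contain missing values; run substitute_below_lod first")

    rows = []
    for key, sub in measurements.groupby(by, sort=True):
        bases = set(sub["basis"].astype(str))
        if len(bases) > 1:
            raise ValueError(
                f"mixed measurement bases {sorted(bases)} within key {key!r}")
        values = sub["value"].to_numpy(dtype=float)
        q1, med, q3 = quartiles(values)
        rows.append({
            "key": key,
            "n": int(len(values)),
            "median": med,
            "q1": q1,
            "q3": q3,
            "min": float(values.min()),
            "max": float(values.max()),
            "mean": float(values.mean()),
            "n_below_lod": int(sub["below_lod"].astype(bool).sum()),
        })
    return pd.DataFrame(rows, columns=COMPOSITION_COLUMNS)


def build_composition(
    measurements: pd.DataFrame,
    *,
    lod_solid: float = LOD_SOLID,
    lod_liquid: float = LOD_LIQUID,
) -> pd.DataFrame:
    """Half-LOD substitution followed by item-level and group-level summaries.

    Item- and group-level entries are concatenated into one composition
    database (keys are assumed not to collide between the two levels; a
    duplicate key keeps the item-level entry).
    """
    sub = substitute_below_lod(measurements, lod_solid=lod_solid,
                               lod_liquid=lod_liquid)
    by_item = summarize(sub, by="item")
    by_group = summarize(sub, by="group")
    db = pd.concat([by_item, by_group], ignore_index=True)
    db = db.drop_duplicates(subset="key", keep="first").reset_index(drop=True)
    return db


def _require_columns(df: pd.DataFrame, cols: Iterable[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table is missing column(s): {missing}")
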