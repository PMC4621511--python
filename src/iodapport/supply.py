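"""Per-capita dietary iodine supply from food-balance-sheet style tables.

Each supply item (g capita⁻¹ d⁻¹ fresh weight) is matched to a composition
entry — directly via its ``composition_key`` or through a food-group fallback —
and its iodine contribution is ``supply × dw_fraction × concentration``
(g × mg kg⁻¹ = μg).  Contributions are aggregated per item, per food group and
nationally, with integer-rounded percentage shares of the total.

The dry-matter fraction ``dw_fraction`` converts the fresh-weight supply mass
to the dry-weight basis of the composition data; the default 1.0 means the
supply is already on the composition basis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

SUPPLY_COLUMNS = ["item", "food_group", "supply_fw", "dw_fraction",
                  "composition_key"]

FOOD_GROUPS = ["Cereals", "Animal products", "Roots and tubers",
               "Fruits and vegetables", "Pulses and beans", "Other"]


@dataclass
class SupplyResult:
    """Aggregated iodine supply: per item, per food group, total and shares."""

    per_item: pd.Series          # μg capita⁻¹ d⁻¹, indexed by item
    per_group: pd.Series         # μg capita⁻¹ d⁻¹, indexed by food group
    total: float                 # μg capita⁻¹ d⁻¹
    shares: dict[str, int]       # integer % of total, per food group
    shares_exact: pd.Series = field(repr=False, default=None)
    unmatched: list[str] = field(default_factory=list)


def item_supply(supply_fw: float, dw_fraction: float, conc_dw: float) -> float:
    """Iodine supplied by one item, μg capita⁻¹ d⁻¹.

    ``supply_fw`` g d⁻¹ fresh weight × ``dw_fraction`` × ``conc_dw`` mg kg⁻¹
    dry weight.  1 g × 1 mg kg⁻¹ = 1 μg, so no further unit factor is needed.
    """
    if supply_fw < 0 or conc_dw < 0:
        raise ValueError("supply and concentration must be non-negative")
    if not (0 < dw_fraction <= 1):
        raise ValueError(f"dw_fraction must be in (0, 1], got {dw_fraction}")
    return supply_fw * dw_fraction * conc_dw


def match_composition(
    items: pd.DataFrame,
    db: pd.DataFrame,
    fallback: Mapping[str, str] | None = None,
    *,
    strict: bool = False,
    statistic: str = "median",
) -> tuple[pd.DataFrame, list[str]]:
    """Pair each supply item with one composition entry.

    Resolution order: the item's ``composition_key`` looked up in ``db``,
    then ``fallback[food_group]`` looked up in ``db``.  Unresolved items are
    excluded from totals and reported (returned and logged); with
    ``strict=True`` they raise instead.

    Returns the matched table with ``conc_dw`` (the chosen composition
    statistic, median by default) and ``matched_key`` columns, plus the list
    of unmatched item names.
    """
    for col in SUPPLY_COLUMNS:
        if col not in items.columns:
            raise ValueError(f"supply table is missing column {col!r}")
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    fallback = dict(fallback or {})
    lookup = db.set_index("key")[statistic].to_dict()

    matched_rows, unmatched = [], []
    for row in items.itertuples(index=False):
        key = row.composition_key
        if key in lookup:
            resolved = key
        else:
            group_key = fallback.get(row.food_group)
            resolved = group_key if group_key in lookup else None
        if resolved is None:
            unmatched.append(row.item)
            continue
        d = row._asdict()
        d["matched_key"] = resolved
        d["conc_dw"] = float(lookup[resolved])
        matched_rows.append(d)

    if unmatched:
        msg = f"{len(unmatched)} unmatched supply item(s): {', '.join(unmatched)}"
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    matched = pd.DataFrame(matched_rows,
                           columns=SUPPLY_COLUMNS + ["matched_key", "conc_dw"])
    return matched, unmatched


def group_shares(per_group: Mapping[str, float] | pd.Series,
                 total: float | None = None) -> dict[str, int]:
    """Integer-rounded percentage share of each food group in the total.

    ``total`` defaults to the sum of the group supplies; passing it explicitly
    allows shares relative to a total that includes a remainder.
    """
    series = pd.Series(dict(per_group), dtype=float)
    tot = float(series.sum()) if total is None else float(total)
    if tot <= 0:
        raise ValueError("total supply must be positive to compute shares")
    return {g: int(round(100.0 * v / tot)) for g, v in series.items()}


def aggregate(matched: pd.DataFrame) -> SupplyResult:
    """Aggregate matched items into per-item/per-group supplies and shares."""
    if len(matched) == 0:
        raise ValueError("no matched items to aggregate")
    contrib = matched.apply(
        lambda r: item_supply(r["supply_fw"], r["dw_fraction"], r["conc_dw"]),
        axis=1,
    )
    per_item = pd.Series(contrib.values, index=matched["item"].values,
                         name="ug_capita_day")
    per_group = (pd.Series(contrib.values, index=matched["food_group"].values)
                 .groupby(level=0).sum().sort_values(ascending=False))
    total = float(per_item.sum())
    shares_exact = 100.0 * per_group / total
    return SupplyResult(
        per_item=per_item,
        per_group=per_group,
        total=total,
        shares=group_shares(per_group, total),
        shares_exact=shares_exact,
    )


def compute_supply(
    items: pd.DataFrame,
    db: pd.DataFrame,
    fallback: Mapping[str, str] | None = None,
    *,
    strict: bool = False,
    statistic: str = "median",
) -> SupplyResult:
    """Match then aggregate; convenience wrapper for the full supply stage."""
    matched, unmatched = match_composition(items, db, fallback, strict=strict,
                                           statistic=statistic)
    result = aggregate(matched)
    result.unmatched = unmatched
    return result
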