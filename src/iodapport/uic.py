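"""Urinary iodine concentration (UIC): individual and population status.

UIC (μg L⁻¹) in a casual urine sample is the WHO biomarker of recent iodine
intake.  Spot samples are optionally corrected for urine dilution by dividing
by creatinine (g L⁻¹), giving μg g⁻¹ creatinine; corrected values are
classified against the same numeric cut-offs as uncorrected ones.

Categories (left-closed, right-open; the published band edges overlap, so the
package fixes <100 / 100–<200 / 200–<300 / ≥300):

* deficient        < 100
* sufficient       100 – <200
* moderate_excess  200 – <300
* severe_excess    ≥ 300

A population is called iodine-inadequate when its median UIC is below
100 μg L⁻¹.  Group medians are considered interpretable for n > 30; WHO
recommends ≥ 300 casual samples per population, so smaller cohorts are
flagged/warned rather than refused.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from dataclasses import dataclass, field

from .composition import quartiles

logger = logging.getLogger(__name__)

CATEGORIES = ["deficient", "sufficient", "moderate_excess", "severe_excess"]
#: Upper bounds (exclusive) of the first three categories, μg L⁻¹.
CATEGORY_BOUNDS = [100.0, 200.0, 300.0]

URINE_COLUMNS = ["subject_id", "site", "uic", "creatinine"]


@dataclass
class UICSummary:
    """Population UIC summary: median (Q1, Q3), category mix, adequacy call."""

    n: int
    median: float
    q1: float
    q3: float
    proportions: dict[str, int]               # category -> integer %
    population_call: str                      # inadequate | not_inadequate
    small_sample_flag: bool                   # n < 30
    proportions_exact: dict[str, float] = field(default_factory=dict, repr=False)


def creatinine_adjust(uic, creatinine):
    """Creatinine-corrected UIC, μg g⁻¹ creatinine (element-wise division)."""
    uic_arr = np.asarray(uic, dtype=float)
    creat_arr = np.asarray(creatinine, dtype=float)
    if np.any(np.isnan(creat_arr)) or np.any(creat_arr <= 0):
        raise ValueError("creatinine must be present and positive for correction")
    out = uic_arr / creat_arr
    return float(out) if out.ndim == 0 else out


def classify_uic(value: float) -> str:
    """Category of a single UIC value (μg L⁻¹ or μg g⁻¹ creatinine)."""
    if value < 0 or np.isnan(value):
        raise ValueError(f"UIC must be a non-negative number, got {value}")
    for bound, cat in zip(CATEGORY_BOUNDS, CATEGORIES):
        if value < bound:
            return cat
    return CATEGORIES[-1]


def classify_series(values) -> pd.Series:
    """Vectorised :func:`classify_uic` preserving the category order."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0) or np.any(np.isnan(arr)):
        raise ValueError("UIC values must be non-negative numbers")
    idx = np.searchsorted(CATEGORY_BOUNDS, arr, side="right")
    return pd.Series(pd.Categorical.from_codes(idx, categories=CATEGORIES,
                                               ordered=True))


def summarize_cohort(records: pd.DataFrame, mode: str = "uncorrected") -> UICSummary:
    """Summarise one cohort of urine records.

    ``mode='corrected'`` divides UIC by creatinine first and requires
    creatinine on every record.  Percentages are reported both exact and
    rounded to integers; the exact ones always sum to 100.
    """
    if mode not in ("corrected", "uncorrected"):
        raise ValueError("mode must be 'corrected' or 'uncorrected'")
    for col in ("uic",) + (("creatinine",) if mode == "corrected" else ()):
        if col not in records.columns:
            raise ValueError(f"urine table is missing column {col!r}")
    if len(records) == 0:
        raise ValueError("cannot summarise an empty cohort")

    values = records["uic"].to_numpy(dtype=float)
    if np.any(np.isnan(values)) or np.any(values < 0):
        raise ValueError("UIC values must be non-negative numbers")
    if mode == "corrected":
        values = creatinine_adjust(values, records["creatinine"].to_numpy())

    n = len(values)
    q1, med, q3 = quartiles(values)
    cats = classify_series(values)
    counts = cats.value_counts().reindex(CATEGORIES, fill_value=0)
    exact = {c: 100.0 * counts[c] / n for c in CATEGORIES}
    rounded = {c: int(round(p)) for c, p in exact.items()}

    if n < 300:
        logger.warning(
            "cohort n=%d is below the recommended >=300 casual urine samples", n)
    return UICSummary(
        n=n,
        median=med, q1=q1, q3=q3,
        proportions=rounded,
        proportions_exact=exact,
        population_call="inadequate" if med < 100.0 else "not_inadequate",
        small_sample_flag=n < 30,
    )


def summarize_by_site(records: pd.DataFrame,
                      modes: tuple[str, ...] = ("corrected", "uncorrected")
                      ) -> pd.DataFrame:
    """Per-site and combined summaries, corrected and uncorrected.

    Output rows mirror the usual survey-table layout: one row per
    (site, mode), plus a pooled "Combined" row per mode.
    """
    if "site" not in records.columns:
        raise ValueError("urine table is missing column 'site'")
    rows = []
    sites = sorted(records["site"].astype(str).unique())
    for mode in modes:
        for site in sites + ["Combined"]:
            sub = records if site == "Combined" else records[
                records["site"].astype(str) == site]
            s = summarize_cohort(sub, mode=mode)
            row = {"site": site, "mode": mode, "n": s.n,
                   "median": round(s.median, 1), "q1": round(s.q1, 1),
                   "q3": round(s.q3, 1), "population_call": s.population_call}
            row.update({c: s.proportions[c] for c in CATEGORIES})
            rows.append(row)
    return pd.DataFrame(rows)


def pool_proportions(site_proportions: dict[str, dict[str, float]],
                     site_ns: dict[str, int]) -> dict[str, float]:
    """Pool per-site category percentages into combined percentages.

    The pooled percentage is the site-size-weighted mean; with equal site
    sizes it reduces to the plain arithmetic mean of the site percentages.
    """
    if set(site_proportions) != set(site_ns) or not site_ns:
        raise ValueError("site_proportions and site_ns must cover the same sites")
    total_n = sum(site_ns.values())
    if total_n <= 0:
        raise ValueError("site sizes must be positive")
    pooled: dict[str, float] = {}
    categories = next(iter(site_proportions.values())).keys()
    for cat in categories:
        pooled[cat] = sum(site_proportions[s][cat] * site_ns[s]
                          for s in site_ns) / total_n
    return pooled
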