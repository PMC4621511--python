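"""Soil classification and soil–plant iodine relationship statistics.

FAO soil classes are grouped into calcareous (Calcaric/Eutric), non-calcareous
(all other classes) and unassigned (Leptosols, which cannot be classified on
this basis).  Soils are also partitioned into pH × organic-matter quadrants
relative to the dataset medians, since soil pH and organic matter (as % loss on
ignition) are the main controls on iodine retention.

Correlations are reported in the signed-R² convention used in the soil-trace-
element literature: sign(r) × r², so a strong negative relationship prints as
e.g. −0.27.  Group comparisons use one-way ANOVA on log10-transformed
concentrations (concentration data are right-skewed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .composition import quartiles

logger = logging.getLogger(__name__)

SOIL_COLUMNS = ["soil_id", "ph", "om", "total_i", "water_ext_i", "fao_class"]

CALC_GROUPS = ["calcareous", "non_calcareous", "unassigned"]
QUADRANTS = ["highpH_highOM", "highpH_lowOM", "lowpH_highOM", "lowpH_lowOM"]


def classify_fao(fao_class: str) -> str:
    """Calcareous grouping of one FAO soil class.

    Case-insensitive prefix match: Calcaric*/Eutric* are calcareous,
    Leptosol* unassigned, anything else non-calcareous.
    """
    if not fao_class or not str(fao_class).strip():
        raise ValueError("empty FAO soil class")
    name = str(fao_class).strip().lower()
    if name.startswith(("calcaric", "eutric")):
        return "calcareous"
    if name.startswith("leptosol"):
        return "unassigned"
    return "non_calcareous"


def classify_soils(soils: pd.DataFrame) -> pd.DataFrame:
    """Add the derived ``calc_group`` column."""
    if "fao_class" not in soils.columns:
        raise ValueError("soils table is missing column 'fao_class'")
    out = soils.copy()
    out["calc_group"] = out["fao_class"].map(classify_fao)
    return out


def quadrant_groups(soils: pd.DataFrame) -> pd.DataFrame:
    """Assign each soil to a pH × OM quadrant relative to the dataset medians.

    "High" means strictly above the median (ties go low).  Medians are
    recomputed from the data passed in, never hard-coded.
    """
    for col in ("ph", "om"):
        if col not in soils.columns:
            raise ValueError(f"soils table is missing column {col!r}")
    sub = soils.dropna(subset=["ph", "om"])
    if len(sub) < 2:
        raise ValueError("quadrant grouping needs at least 2 soils with pH and OM")
    ph_med = float(sub["ph"].median())
    om_med = float(sub["om"].median())
    out = soils.copy()
    high_ph = out["ph"] > ph_med
    high_om = out["om"] > om_med
    labels = np.where(high_ph,
                      np.where(high_om, "highpH_highOM", "highpH_lowOM"),
                      np.where(high_om, "lowpH_highOM", "lowpH_lowOM"))
    out["quadrant"] = labels
    out.loc[out["ph"].isna() | out["om"].isna(), "quadrant"] = pd.NA
    return out


def water_extractable_pct(total_i: float, water_ext_i: float) -> float:
    """Water-extractable (mobile) iodine as % of total soil iodine."""
    if total_i <= 0:
        raise ValueError("total_i must be positive")
    if water_ext_i < 0:
        raise ValueError("water_ext_i must be non-negative")
    return 100.0 * water_ext_i / total_i


def signed_r2(x, y, log10_x: bool = False, log10_y: bool = False) -> float:
    """sign(r) × r² of the (optionally log10-transformed) vectors.

    This reproduces the signed-R² reporting convention (a negative value
    denotes a negative correlation); use :func:`correlation_report` when the
    plain Pearson r and n are wanted alongside.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 pairs")
    if log10_x:
        if np.any(xa <= 0):
            raise ValueError("log10 transform requires positive x values")
        xa = np.log10(xa)
    if log10_y:
        if np.any(ya <= 0):
            raise ValueError("log10 transform requires positive y values")
        ya = np.log10(ya)
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(xa, ya)[0, 1])
    return float(np.sign(r) * r * r)


def correlation_report(x, y, log10_x: bool = False, log10_y: bool = False,
                       label: str = "") -> dict:
    """Pearson r, signed R² and n for one variable pair."""
    xa = np.asarray(x, dtype=float)
    s = signed_r2(xa, y, log10_x=log10_x, log10_y=log10_y)
    r = float(np.sign(s) * np.sqrt(abs(s)))
    return {"label": label, "n": int(xa.size), "r": r, "signed_r2": s}


@dataclass
class AnovaResult:
    f: float
    p: float
    group_geomeans: dict[str, float]   # back-transformed means on log10 scale
    n: int


def soil_type_anova(concentrations, groups) -> AnovaResult:
    """One-way fixed-effects ANOVA on log10-transformed concentrations.

    Returns the F statistic, p value and per-group geometric means.  The F
    statistic is invariant to multiplying all concentrations by a positive
    constant, because that only shifts every log by the same amount.
    """
    conc = np.asarray(concentrations, dtype=float)
    grp = np.asarray(groups)
    if conc.shape != grp.shape:
        raise ValueError("concentrations and groups must have equal length")
    bad = ~(conc > 0)
    if bad.any():
        idx = np.flatnonzero(bad)[:5].tolist()
        raise ValueError(
            f"non-positive concentration(s) at position(s) {idx}; "
            "log10 transform requires positive values")
    logs = np.log10(conc)
    samples, geomeans = [], {}
    for g in pd.unique(grp):
        vals = logs[grp == g]
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        samples.append(vals)
        geomeans[g] = float(10.0 ** vals.mean())
    if len(samples) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    f, p = stats.f_oneway(*samples)
    return AnovaResult(f=float(f), p=float(p), group_geomeans=geomeans,
                       n=int(conc.size))


def summarize_soils(soils: pd.DataFrame, by: str = "calc_group",
                    value: str = "total_i") -> pd.DataFrame:
    """n, median (Q1, Q3) of a soil variable per calcareous group or quadrant."""
    if by not in soils.columns:
        raise ValueError(f"soils table is missing column {by!r}")
    rows = []
    for key, sub in soils.dropna(subset=[by, value]).groupby(by, sort=True):
        vals = sub[value].to_numpy(dtype=float)
        if len(vals) == 0:
            continue
        q1, med, q3 = quartiles(vals)
        rows.append({by: key, "n": len(vals), "median": med, "q1": q1, "q3": q3})
    return pd.DataFrame(rows)


def soil_correlation_table(soils: pd.DataFrame) -> pd.DataFrame:
    """Standard correlation report: total/water-extractable iodine vs pH and OM.

    Each correlation uses the rows where both variables are present; n is
    recorded alongside every coefficient because subsets differ.
    """
    pairs = [
        ("total_i_vs_ph", "ph", "total_i", False, True),
        ("total_i_vs_om", "om", "total_i", True, True),
        ("water_ext_i_vs_ph", "ph", "water_ext_i", False, True),
        ("water_ext_i_vs_om", "om", "water_ext_i", True, True),
    ]
    rows = []
    for label, xcol, ycol, lx, ly in pairs:
        sub = soils.dropna(subset=[xcol, ycol])
        if len(sub) < 3:
            logger.warning("correlation %s skipped: only %d pairs", label, len(sub))
            continue
        try:
            rows.append(correlation_report(sub[xcol], sub[ycol],
                                           log10_x=lx, log10_y=ly, label=label))
        except ValueError as exc:
            logger.warning("correlation %s skipped: %s", label, exc)
    return pd.DataFrame(rows, columns=["label", "n", "r", "signed_r2"])
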