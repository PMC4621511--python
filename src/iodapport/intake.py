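"""Scenario model of total daily iodine intake and its adequacy.

Total intake is the sum of three sources:

* food        — μg d⁻¹, typically the national per-capita supply from foods;
* iodised salt — salt mass (g d⁻¹) × iodine concentration (mg kg⁻¹) × (1 − cooking loss);
* drinking water — volume (L d⁻¹) × concentration (μg L⁻¹).

The total is classified against population dietary reference values: the
Estimated Average Requirement (EAR), the Recommended Nutrient Intake (RNI) and
the Tolerable Upper Limit (TUL).  Defaults: EAR 64/107/143 and RNI 120/150/200
μg d⁻¹ for children, adults and pregnant women; adult TUL 600 μg d⁻¹ (EU) or
1,100 μg d⁻¹ (USA), selectable by region.

Salt is "adequately iodised" at ≥ 15 mg kg⁻¹ (WHO convention; the boundary is
treated as inclusive).  ``required_iodisation`` inverts the salt term to give
the concentration needed to keep salt-derived intake fixed under a
salt-reduction scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

#: Salt iodine concentration defining "adequately iodised", mg kg⁻¹.
ADEQUATE_SALT_IODINE = 15.0

ADEQUACY_LEVELS = ["below_EAR", "EAR_to_RNI", "adequate", "above_TUL"]

_EAR = {"child": 64.0, "adult": 107.0, "pregnant": 143.0}
_RNI = {"child": 120.0, "adult": 150.0, "pregnant": 200.0}
_TUL = {"EU": 600.0, "USA": 1100.0}


@dataclass(frozen=True)
class Thresholds:
    """EAR/RNI/TUL reference values, μg d⁻¹, for one demographic group."""

    demographic: str
    ear: float
    rni: float
    tul: float

    def __post_init__(self) -> None:
        if not (self.ear < self.rni <= self.tul):
            raise ValueError(
                f"thresholds must satisfy EAR < RNI <= TUL, got "
                f"{self.ear}, {self.rni}, {self.tul}")


def thresholds(demographic: str = "adult", region: str = "EU") -> Thresholds:
    """Reference values for a demographic group and TUL region."""
    if demographic not in _EAR:
        raise ValueError(f"unknown demographic {demographic!r}")
    if region not in _TUL:
        raise ValueError(f"unknown TUL region {region!r}")
    return Thresholds(demographic, _EAR[demographic], _RNI[demographic],
                      _TUL[region])


@dataclass
class IntakeScenario:
    """One intake scenario: food, iodised salt and drinking water."""

    food_ug: float = 0.0       # μg d⁻¹ from foods other than salt
    salt_g: float = 0.0        # g d⁻¹ salt consumed
    salt_conc: float = 0.0     # mg kg⁻¹ iodine in salt
    cooking_loss: float = 0.0  # fraction of salt iodine lost, [0, 1]
    water_l: float = 0.0       # L d⁻¹ drinking water
    water_conc: float = 0.0    # μg L⁻¹ iodine in water
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("food_ug", "salt_g", "salt_conc", "water_l", "water_conc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 <= self.cooking_loss <= 1):
            raise ValueError("cooking_loss must be in [0, 1]")


@dataclass
class IntakeResult:
    contributions: dict[str, float]   # source -> μg d⁻¹
    total: float                      # μg d⁻¹
    fraction_from_salt: float         # % of total
    adequacy: str                     # one of ADEQUACY_LEVELS
    total_rounded_10: float = field(default=0.0)  # headline, nearest 10 μg


def salt_contribution(salt_g: float, salt_conc: float,
                      cooking_loss: float = 0.0) -> float:
    """Iodine from iodised salt, μg d⁻¹ (g × mg kg⁻¹ = μg)."""
    if salt_g < 0 or salt_conc < 0:
        raise ValueError("salt mass and concentration must be non-negative")
    if not (0 <= cooking_loss <= 1):
        raise ValueError("cooking_loss must be in [0, 1]")
    return salt_g * salt_conc * (1.0 - cooking_loss)


def water_contribution(water_l: float, water_conc: float) -> float:
    """Iodine from drinking water, μg d⁻¹ (L × μg L⁻¹ = μg)."""
    if water_l < 0 or water_conc < 0:
        raise ValueError("water volume and concentration must be non-negative")
    return water_l * water_conc


def salt_adequately_iodised(conc: float,
                            threshold: float = ADEQUATE_SALT_IODINE) -> bool:
    """True when the salt iodine concentration meets the iodisation standard."""
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    return conc >= threshold


def required_iodisation(target_salt_ug: float, salt_g: float,
                        cooking_loss: float = 0.0) -> float:
    """Salt iodine concentration (mg kg⁻¹) delivering ``target_salt_ug``.

    Inverse of :func:`salt_contribution`; halving salt consumption doubles the
    required concentration for the same salt-derived intake.
    """
    if salt_g <= 0:
        raise ValueError("salt_g must be positive")
    if not (0 <= cooking_loss < 1):
        raise ValueError("cooking_loss must be in [0, 1)")
    if target_salt_ug < 0:
        raise ValueError("target must be non-negative")
    return target_salt_ug / (salt_g * (1.0 - cooking_loss))


def classify_adequacy(total: float, limits: Thresholds) -> str:
    """Classify a total intake against EAR/RNI/TUL (monotone in the total)."""
    if total < limits.ear:
        return "below_EAR"
    if total < limits.rni:
        return "EAR_to_RNI"
    if total <= limits.tul:
        return "adequate"
    return "above_TUL"


def total_intake(scenario: IntakeScenario, limits: Thresholds) -> IntakeResult:
    """Sum the three sources and classify the total."""
    salt = salt_contribution(scenario.salt_g, scenario.salt_conc,
                             scenario.cooking_loss)
    water = water_contribution(scenario.water_l, scenario.water_conc)
    contributions = {
        "food": round(scenario.food_ug, 1),
        "salt": round(salt, 1),
        "water": round(water, 1),
    }
    total = scenario.food_ug + salt + water
    frac_salt = 100.0 * salt / total if total > 0 else 0.0
    return IntakeResult(
        contributions=contributions,
        total=total,
        fraction_from_salt=frac_salt,
        adequacy=classify_adequacy(total, limits),
        total_rounded_10=float(10 * round(total / 10.0)),
    )


def run_scenarios(scenarios: Iterable[IntakeScenario],
                  limits: Thresholds) -> pd.DataFrame:
    """Evaluate a batch of scenarios; one output row per scenario."""
    rows = []
    for i, sc in enumerate(scenarios):
        res = total_intake(sc, limits)
        rows.append({
            "scenario": sc.label or f"scenario_{i}",
            "food_ug": sc.food_ug,
            "salt_g": sc.salt_g,
            "salt_conc": sc.salt_conc,
            "cooking_loss": sc.cooking_loss,
            "water_l": sc.water_l,
            "water_conc": sc.water_conc,
            "salt_ug": res.contributions["salt"],
            "water_ug": res.contributions["water"],
            "total_ug": round(res.total, 1),
            "total_rounded_10": res.total_rounded_10,
            "fraction_from_salt_pct": round(res.fraction_from_salt, 1),
            "adequacy": res.adequacy,
        })
    if not rows:
        raise ValueError("no scenarios supplied")
    return pd.DataFrame(rows)


def scenario_grid(food_ug: float, salt_g_values: Iterable[float],
                  salt_conc_values: Iterable[float],
                  water_conc_values: Iterable[float],
                  water_l: float = 2.0,
                  cooking_loss: float = 0.0) -> list[IntakeScenario]:
    """Cartesian grid of salt mass × salt concentration × water concentration."""
    grid = []
    for sg in salt_g_values:
        for sc in salt_conc_values:
            for wc in water_conc_values:
                grid.append(IntakeScenario(
                    food_ug=food_ug, salt_g=sg, salt_conc=sc,
                    cooking_loss=cooking_loss, water_l=water_l, water_conc=wc,
                    label=f"salt{sg:g}g_conc{sc:g}_water{wc:g}"))
    return grid
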