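"""Seeded synthetic datasets with the statistical structure the analysis assumes.

All concentration variables are log-normal (right-skewed, strictly positive —
the same assumption behind the log10 ANOVA in the soils module).  Defaults are
calibrated to the medians and quartiles of the Malawi survey data the package
is designed around: e.g. leafy vegetables median 0.155 mg kg⁻¹ DW with the
geometric SD solved from the printed (0.087, 0.250) quartiles via
``sigma = ln(Q3/Q1) / (2 × 0.6745)``.

Generated tables:

* food/fish/salt/water sample measurements, with values below the LOD emitted
  as censored records (flag set, value blank) so the pipeline's half-LOD
  substitution is exercised end to end;
* soils with pH, organic matter, total and water-extractable iodine and an FAO
  class consistent with pH (calcareous classes skew to pH > 6.5);
* a two-site urine cohort (59 + 59 by default) with independent creatinine;
* an FBS-style supply table of 92 items resolvable against the generated
  composition database.

Every generator takes a sub-stream of one global seed keyed by a fixed index,
so adding a generator never perturbs the others, and each returns its ground
truth (the true generating parameters) for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

#: Fixed sub-stream index per generator (stable across versions).
_STREAMS = {"food": 0, "soil": 1, "urine": 2, "fbs": 3}

#: z-score of the upper quartile of a standard normal.
_Z75 = norm.ppf(0.75)  # 0.6745


def sigma_from_quartiles(q1: float, q3: float) -> float:
    """Log-SD of a log-normal solved from its quartile ratio."""
    if not (0 < q1 <= q3):
        raise ValueError("need 0 < q1 <= q3")
    return float(np.log(q3 / q1) / (2.0 * _Z75))


@dataclass(frozen=True)
class FoodGroupSpec:
    """Log-normal concentration model for one sampled item."""

    item: str
    group: str      # tissue/food group: leaves|grain|root|fish|salt|water...
    basis: str      # DW or liquid
    median: float   # mg kg⁻¹ DW (μg L⁻¹ for water)
    sigma_ln: float # log-scale SD (ln of the geometric SD)
    n: int


def _default_food_groups() -> tuple[FoodGroupSpec, ...]:
    return (
        # Maize: median at the solid LOD; geometric SD set to an order of
        # magnitude consistent with the printed grain range (<0.005-0.165).
        FoodGroupSpec("maize grain", "grain", "DW", 0.01, 1.0, 82),
        FoodGroupSpec("cassava root", "root", "DW", 0.008, 1.0, 27),
        FoodGroupSpec("leafy vegetables", "leaves", "DW", 0.155,
                      sigma_from_quartiles(0.087, 0.250), 151),
        FoodGroupSpec("fish", "fish", "DW", 0.51,
                      sigma_from_quartiles(0.37, 0.87), 12),
        FoodGroupSpec("beans", "seeds", "DW", 0.01, 1.0, 20),
        FoodGroupSpec("fruit", "fruit", "DW", 0.02, 1.0, 20),
        FoodGroupSpec("salt", "salt", "DW", 53.1,
                      sigma_from_quartiles(20.8, 107.1), 5),
        FoodGroupSpec("water", "water", "liquid", 12.6,
                      sigma_from_quartiles(1.9, 20.9), 19),
    )


@dataclass(frozen=True)
class SoilModel:
    """pH, OM and iodine model for synthetic soils.

    ``log10(total_i)`` is linear in standardised log-OM and pH plus noise;
    the default loadings give signed R² of +0.57 with OM and −0.27 with pH
    in expectation, with the marginal median/quartiles of total iodine
    matching 2.06 (1.18, 3.35) mg kg⁻¹.
    """

    n: int = 92
    ph_min: float = 4.8
    ph_max: float = 8.5
    om_median: float = 2.8        # % LOI
    om_sigma_ln: float = 0.73
    total_i_median: float = 2.06  # mg kg⁻¹
    total_i_sigma_log10: float = sigma_from_quartiles(1.18, 3.35) / np.log(10)
    loading_om: float = np.sqrt(0.57)    # correlation with log OM
    loading_ph: float = -np.sqrt(0.27)   # correlation with pH
    # water-extractable fraction ~ Beta(a, b); median ~1.3% of total iodine
    wext_beta_a: float = 2.0
    wext_beta_b: float = 126.9
    n_water_ext: int = 58         # soils with a water-extraction measurement
    p_leptosol: float = 0.05


@dataclass(frozen=True)
class UrineSiteSpec:
    """Log-normal corrected-UIC model for one survey site."""

    site: str
    n: int
    median_corrected: float  # μg g⁻¹ creatinine
    sigma_ln: float


def _default_urine_sites() -> tuple[UrineSiteSpec, ...]:
    # Per-site parameters solved from the per-site corrected category mix.
    return (
        UrineSiteSpec("Zombwe", 59, 181.0, 0.674),
        UrineSiteSpec("Mikalango", 59, 214.0, 0.464),
    )


#: Target iodine supply per FBS food group, μg capita⁻¹ d⁻¹ (survey values;
#: the 0.1 "Other" remainder closes the gap between the 7.7 group sum and the
#: 7.8 national total).
_FBS_GROUP_IODINE_UG = {
    "Cereals": 3.1, "Animal products": 2.6, "Roots and tubers": 1.1,
    "Fruits and vegetables": 0.6, "Pulses and beans": 0.3, "Other": 0.1,
}

#: Composition median feeding each group under the default food specs.
_GROUP_DEFAULT_MEDIAN = {
    "Cereals": 0.01, "Animal products": 0.51, "Roots and tubers": 0.008,
    "Fruits and vegetables": 0.155, "Pulses and beans": 0.01, "Other": 0.02,
}

_FBS_GROUP_MASS = {g: ug / _GROUP_DEFAULT_MEDIAN[g]
                   for g, ug in _FBS_GROUP_IODINE_UG.items()}
_FBS_DEFAULT_TOTAL = float(sum(_FBS_GROUP_MASS.values()))
_FBS_DEFAULT_SHARES = tuple(
    (g, m / _FBS_DEFAULT_TOTAL) for g, m in _FBS_GROUP_MASS.items())


@dataclass(frozen=True)
class GeneratorConfig:
    """One seed + calibrated distribution parameters for every dataset."""

    seed: int = 0
    lod_solid: float = 0.01    # mg kg⁻¹
    lod_liquid: float = 0.25   # μg L⁻¹
    food_groups: tuple[FoodGroupSpec, ...] = field(
        default_factory=_default_food_groups)
    soil: SoilModel = field(default_factory=SoilModel)
    urine_sites: tuple[UrineSiteSpec, ...] = field(
        default_factory=_default_urine_sites)
    creatinine_median: float = 1.1   # g L⁻¹
    creatinine_sigma_ln: float = 0.5
    fbs_n_items: int = 92
    fbs_total_fw: float = _FBS_DEFAULT_TOTAL
    # supply-mass share per food group, on the composition (dry-weight) basis;
    # calibrated so each group's iodine supply matches the survey's printed
    # group supplies (3.1/2.6/1.1/0.6/0.3/0.1 μg capita⁻¹ d⁻¹, total 7.8)
    fbs_group_mass_shares: tuple[tuple[str, float], ...] = _FBS_DEFAULT_SHARES


def _rng(config: GeneratorConfig, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed, spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


def gen_food_samples(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Sample-level measurements table plus ground truth.

    Values below the applicable LOD are emitted censored: ``below_lod`` set
    and ``value`` blank, so downstream half-LOD substitution is mandatory.
    """
    rng = _rng(config, "food")
    rows, truth = [], {}
    for spec in config.food_groups:
        lod = config.lod_liquid if spec.basis == "liquid" else config.lod_solid
        draws = np.exp(rng.normal(np.log(spec.median), spec.sigma_ln, spec.n))
        censored = draws < lod
        for i, (v, c) in enumerate(zip(draws, censored)):
            rows.append({
                "sample_id": f"{spec.group}_{i:03d}",
                "item": spec.item,
                "group": spec.group,
                "basis": spec.basis,
                "value": np.nan if c else round(float(v), 6),
                "below_lod": bool(c),
                "soil_id": "",
                "site": "",
            })
        truth[spec.item] = {
            "median": spec.median, "sigma_ln": spec.sigma_ln, "n": spec.n,
            "lod": lod,
            "expected_censored_fraction": float(
                norm.cdf(np.log(lod / spec.median) / spec.sigma_ln)),
        }
    df = pd.DataFrame(rows)
    return df, {"food": truth}


def gen_soil_samples(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Soils table (pH, OM, total/water-extractable iodine, FAO class)."""
    rng = _rng(config, "soil")
    m = config.soil
    n = m.n
    ph = rng.uniform(m.ph_min, m.ph_max, n)
    z_om = rng.standard_normal(n)
    om = m.om_median * np.exp(m.om_sigma_ln * z_om)

    ph_sd = (m.ph_max - m.ph_min) / np.sqrt(12.0)
    z_ph = (ph - (m.ph_min + m.ph_max) / 2.0) / ph_sd
    resid_var = 1.0 - m.loading_om ** 2 - m.loading_ph ** 2
    if resid_var < 0:
        raise ValueError("soil loadings imply correlation above 1")
    z = (m.loading_om * z_om + m.loading_ph * z_ph
         + np.sqrt(resid_var) * rng.standard_normal(n))
    total_i = m.total_i_median * 10.0 ** (m.total_i_sigma_log10 * z)

    frac = rng.beta(m.wext_beta_a, m.wext_beta_b, n)
    water_ext = np.minimum(frac, 1.0) * total_i
    has_wext = np.zeros(n, dtype=bool)
    has_wext[rng.choice(n, size=min(m.n_water_ext, n), replace=False)] = True

    calcareous_classes = ["Eutric Fluvisol", "Calcaric Regosol", "Eutric Vertisol"]
    noncalc_classes = ["Ferralsol", "Lixisol", "Acrisol", "Cambisol"]
    fao = []
    for p in ph:
        if rng.random() < m.p_leptosol:
            fao.append("Leptosol")
        elif p > 6.5:
            pool = calcareous_classes if rng.random() < 0.85 else noncalc_classes
            fao.append(pool[rng.integers(len(pool))])
        else:
            pool = noncalc_classes if rng.random() < 0.85 else calcareous_classes
            fao.append(pool[rng.integers(len(pool))])

    df = pd.DataFrame({
        "soil_id": [f"soil_{i:03d}" for i in range(n)],
        "ph": np.round(ph, 2),
        "om": np.round(om, 2),
        "total_i": np.round(total_i, 4),
        "water_ext_i": np.where(has_wext, np.round(water_ext, 5), np.nan),
        "fao_class": fao,
    })
    truth = {"soil": {
        "n": n,
        "total_i_median": m.total_i_median,
        "signed_r2_om": float(np.sign(m.loading_om) * m.loading_om ** 2),
        "signed_r2_ph": float(np.sign(m.loading_ph) * m.loading_ph ** 2),
        "water_ext_fraction_median_pct": 100.0 * _beta_median(
            m.wext_beta_a, m.wext_beta_b),
    }}
    return df, truth


def _beta_median(a: float, b: float) -> float:
    from scipy.stats import beta as beta_dist
    return float(beta_dist.median(a, b))


def gen_urine_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Two-site urine cohort: corrected UIC log-normal per site, independent
    creatinine; the uncorrected UIC is their product."""
    if not config.urine_sites:
        raise ValueError("at least one urine site is required")
    rng = _rng(config, "urine")
    rows = []
    truth_sites = {}
    bounds = np.array([100.0, 200.0, 300.0])
    for site in config.urine_sites:
        corrected = np.exp(rng.normal(np.log(site.median_corrected),
                                      site.sigma_ln, site.n))
        creat = np.exp(rng.normal(np.log(config.creatinine_median),
                                  config.creatinine_sigma_ln, site.n))
        uic = corrected * creat
        for i in range(site.n):
            rows.append({
                "subject_id": f"{site.site[:3].upper()}_{i:03d}",
                "site": site.site,
                "uic": round(float(uic[i]), 2),
                "creatinine": round(float(creat[i]), 3),
            })
        z = (np.log(bounds) - np.log(site.median_corrected)) / site.sigma_ln
        cdf = norm.cdf(z)
        truth_sites[site.site] = {
            "n": site.n,
            "median_corrected": site.median_corrected,
            "sigma_ln": site.sigma_ln,
            "proportions_corrected_pct": {
                "deficient": 100.0 * cdf[0],
                "sufficient": 100.0 * (cdf[1] - cdf[0]),
                "moderate_excess": 100.0 * (cdf[2] - cdf[1]),
                "severe_excess": 100.0 * (1.0 - cdf[2]),
            },
        }
    total_n = sum(s.n for s in config.urine_sites)
    pooled = {
        cat: sum(truth_sites[s.site]["proportions_corrected_pct"][cat] * s.n
                 for s in config.urine_sites) / total_n
        for cat in ("deficient", "sufficient", "moderate_excess", "severe_excess")
    }
    truth = {"urine": {"sites": truth_sites,
                       "pooled_proportions_corrected_pct": pooled}}
    return pd.DataFrame(rows), truth


#: Which generated composition key serves each FBS food group.
_GROUP_COMPOSITION_KEY = {
    "Cereals": "maize grain",
    "Roots and tubers": "cassava root",
    "Fruits and vegetables": "leafy vegetables",
    "Animal products": "fish",
    "Pulses and beans": "beans",
    "Other": "fruit",
}


def gen_fbs_table(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """FBS-style per-capita supply table resolvable against the generated
    composition database."""
    if config.fbs_n_items < 1:
        raise ValueError("fbs_n_items must be >= 1")
    rng = _rng(config, "fbs")
    groups = [g for g, _ in config.fbs_group_mass_shares]
    shares = np.array([s for _, s in config.fbs_group_mass_shares], dtype=float)
    shares = shares / shares.sum()
    # spread items over groups roughly proportionally, at least one per group
    counts = np.maximum(1, np.round(shares * config.fbs_n_items).astype(int))
    while counts.sum() > config.fbs_n_items:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < config.fbs_n_items:
        counts[np.argmax(shares)] += 1

    rows = []
    for g, share, count in zip(groups, shares, counts):
        group_mass = config.fbs_total_fw * share
        weights = rng.dirichlet(np.ones(count))
        for j, w in enumerate(weights):
            rows.append({
                "item": f"{g.lower().replace(' ', '_')}_{j:02d}",
                "food_group": g,
                "supply_fw": round(float(group_mass * w), 3),
                "dw_fraction": 1.0,
                "composition_key": _GROUP_COMPOSITION_KEY.get(g, g),
            })
    df = pd.DataFrame(rows)
    truth = {"fbs": {"n_items": int(len(df)),
                     "total_fw": float(df["supply_fw"].sum()),
                     "group_mass_shares": dict(zip(groups, shares.tolist()))}}
    return df, truth


def generate_dataset(config: GeneratorConfig, outdir: str | Path) -> dict:
    """Write the complete demo dataset (CSVs + ground-truth JSON) to *outdir*.

    Returns the merged ground truth.  Deterministic: identical config + seed
    give byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth: dict = {"seed": config.seed}
    food, t = gen_food_samples(config)
    truth.update(t)
    food.to_csv(outdir / "measurements.csv", index=False)
    soil, t = gen_soil_samples(config)
    truth.update(t)
    soil.to_csv(outdir / "soils.csv", index=False)
    urine, t = gen_urine_cohort(config)
    truth.update(t)
    urine.to_csv(outdir / "urine.csv", index=False)
    fbs, t = gen_fbs_table(config)
    truth.update(t)
    fbs.to_csv(outdir / "fbs.csv", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
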