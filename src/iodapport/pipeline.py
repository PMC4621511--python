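"""End-to-end orchestration: composition → supply → intake → UIC → soils.

Each stage is a pure function of its declared inputs; the pipeline only wires
them together, writes the per-stage CSVs and a plain-text report, and logs
every exclusion (unmatched supply items, censoring substitutions, small
cohorts) so reported n values are auditable.  Stages whose input files are
absent are skipped and marked as such in the report; output files are fully
deterministic for fixed inputs and configuration (no timestamps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import composition, intake, io, soils, supply, uic

logger = logging.getLogger(__name__)

#: Default FBS food-group → composition-key fallback used by the demo dataset.
DEFAULT_FALLBACK = {
    "Cereals": "grain",
    "Roots and tubers": "root",
    "Fruits and vegetables": "leaves",
    "Animal products": "fish",
    "Pulses and beans": "seeds",
    "Other": "fruit",
}


@dataclass
class RunConfig:
    """Inputs, reference values and scenario settings for one pipeline run."""

    measurements: str | None = None
    soils: str | None = None
    fbs: str | None = None
    urine: str | None = None
    outdir: str = "results"
    seed: int = 0
    lod_solid: float = composition.LOD_SOLID
    lod_liquid: float = composition.LOD_LIQUID
    demographic: str = "adult"
    tul_region: str = "EU"
    salt_g: float = 5.0          # g d⁻¹, typical adult consumption
    water_l: float = 2.0         # L d⁻¹, assumed adult water intake
    cooking_loss: float = 0.0
    strict: bool = False
    fallback: dict = field(default_factory=lambda: dict(DEFAULT_FALLBACK))
    # optional scenario grid: lists of salt_g, salt_conc, water_conc
    scenario_salt_g: list = field(default_factory=list)
    scenario_salt_conc: list = field(default_factory=list)
    scenario_water_conc: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def validate_inputs(paths: Mapping[str, str]) -> list[dict]:
    """Schema-check every provided input file; defects are returned, not raised."""
    defects = []
    for kind, path in paths.items():
        if path:
            defects.extend(io.validate_file(path, kind))
    return defects


def run_all(config: RunConfig) -> dict:
    """Execute all stages available from the configured inputs.

    Returns a dict of stage outputs and writes CSVs plus ``report.txt`` to
    ``config.outdir``.  Raises on missing files that were explicitly
    configured and on stage validation errors (with the stage named).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("measurements", "soils", "fbs", "urine"):
        path = getattr(config, name)
        if path and not Path(path).exists():
            raise FileNotFoundError(f"configured {name} input not found: {path}")

    outputs: dict = {}
    report: list[str] = ["Iodine source apportionment — run report", ""]

    comp_db = None
    if config.measurements:
        comp_db = _stage("composition", _run_composition, config, outputs,
                         report, outdir)
    else:
        report.append("[composition] skipped: no measurements input")

    if config.fbs and comp_db is not None:
        _stage("supply", _run_supply, config, outputs, report, outdir)
    else:
        report.append("[supply] skipped: needs measurements and fbs inputs")

    if comp_db is not None:
        _stage("intake", _run_intake, config, outputs, report, outdir)
    else:
        report.append("[intake] skipped: needs composition (measurements input)")

    if config.urine:
        _stage("uic", _run_uic, config, outputs, report, outdir)
    else:
        report.append("[uic] skipped: no urine input")

    if config.soils:
        _stage("soils", _run_soils, config, outputs, report, outdir)
    else:
        report.append("[soils] skipped: no soils input")

    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    outputs["report"] = str(outdir / "report.txt")
    return outputs


def _stage(name, fn, config, outputs, report, outdir):
    try:
        result = fn(config, outputs, report, outdir)
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    outputs[name] = result
    return result


def _run_composition(config, outputs, report, outdir):
    measurements = io.read_measurements(config.measurements)
    substituted = composition.substitute_below_lod(
        measurements, lod_solid=config.lod_solid, lod_liquid=config.lod_liquid)
    db = composition.build_composition(measurements,
                                       lod_solid=config.lod_solid,
                                       lod_liquid=config.lod_liquid)
    db.to_csv(outdir / "composition.csv", index=False)
    n_cens = int(substituted["below_lod"].sum())
    report += [f"[composition] {len(measurements)} measurements, "
               f"{n_cens} below LOD substituted at half-LOD, "
               f"{len(db)} composition entries", ""]
    outputs["substituted"] = substituted
    return db


def _run_supply(config, outputs, report, outdir):
    items = io.read_fbs(config.fbs)
    result = supply.compute_supply(items, outputs["composition"],
                                   config.fallback, strict=config.strict)
    per_item = result.per_item.rename_axis("item").reset_index()
    per_item.to_csv(outdir / "supply_items.csv", index=False)
    groups = pd.DataFrame({
        "food_group": result.per_group.index,
        "ug_capita_day": result.per_group.values,
        "share_pct": [result.shares[g] for g in result.per_group.index],
    })
    groups.to_csv(outdir / "supply_groups.csv", index=False)
    report += [f"[supply] {len(items)} FBS items, "
               f"{len(result.unmatched)} unmatched"
               + (f" ({', '.join(result.unmatched)})" if result.unmatched else ""),
               f"  national supply from foods: {result.total:.1f} ug/capita/day",
               "  group shares (%): "
               + ", ".join(f"{g}={s}" for g, s in result.shares.items()), ""]
    return result


def _median_of(db: pd.DataFrame, key: str) -> float | None:
    hit = db.loc[db["key"] == key, "median"]
    return float(hit.iloc[0]) if len(hit) else None


def _run_intake(config, outputs, report, outdir):
    db = outputs["composition"]
    food_ug = outputs["supply"].total if "supply" in outputs else 0.0
    salt_conc = _median_of(db, "salt") or 0.0
    water_conc = _median_of(db, "water") or 0.0
    limits = intake.thresholds(config.demographic, config.tul_region)

    scenarios = [intake.IntakeScenario(
        food_ug=food_ug, salt_g=config.salt_g, salt_conc=salt_conc,
        cooking_loss=config.cooking_loss, water_l=config.water_l,
        water_conc=water_conc, label="baseline")]
    if config.scenario_salt_g:
        scenarios += intake.scenario_grid(
            food_ug, config.scenario_salt_g,
            config.scenario_salt_conc or [salt_conc],
            config.scenario_water_conc or [water_conc],
            water_l=config.water_l, cooking_loss=config.cooking_loss)
    table = intake.run_scenarios(scenarios, limits)
    table.to_csv(outdir / "intake_scenarios.csv", index=False)
    head = table.iloc[0]
    report += [f"[intake] {len(table)} scenario(s); baseline total "
               f"{head['total_ug']:.1f} ug/day (~{head['total_rounded_10']:.0f}), "
               f"adequacy: {head['adequacy']}, "
               f"{head['fraction_from_salt_pct']:.1f}% from salt", ""]
    return table


def _run_uic(config, outputs, report, outdir):
    urine = io.read_urine(config.urine)
    modes = ("corrected", "uncorrected") if urine["creatinine"].notna().all() \
        else ("uncorrected",)
    table = uic.summarize_by_site(urine, modes=modes)
    table.to_csv(outdir / "uic_summary.csv", index=False)
    combined = table[(table["site"] == "Combined")].iloc[0]
    report += [f"[uic] {len(urine)} volunteers across "
               f"{urine['site'].nunique()} site(s); combined {combined['mode']} "
               f"median {combined['median']:.1f} (Q1 {combined['q1']:.1f}, "
               f"Q3 {combined['q3']:.1f}); population: "
               f"{combined['population_call']}", ""]
    return table


def _run_soils(config, outputs, report, outdir):
    soil_df = io.read_soils(config.soils)
    soil_df = soils.classify_soils(soil_df)
    soil_df = soils.quadrant_groups(soil_df)
    by_calc = soils.summarize_soils(soil_df, by="calc_group")
    by_quad = soils.summarize_soils(soil_df, by="quadrant")
    corr = soils.soil_correlation_table(soil_df)
    by_calc.to_csv(outdir / "soils_by_calc_group.csv", index=False)
    by_quad.to_csv(outdir / "soils_by_quadrant.csv", index=False)
    corr.to_csv(outdir / "soils_correlations.csv", index=False)
    wext = soil_df.dropna(subset=["water_ext_i"])
    report.append(f"[soils] {len(soil_df)} soils; calc groups: "
                  + ", ".join(f"{r.calc_group}(n={r.n})"
                              for r in by_calc.itertuples()))
    if len(wext):
        pcts = [soils.water_extractable_pct(t, w)
                for t, w in zip(wext["total_i"], wext["water_ext_i"])]
        q1, med, q3 = composition.quartiles(pcts)
        report.append(f"  water-extractable fraction: median {med:.1f}% "
                      f"({q1:.1f}, {q3:.1f}; n={len(pcts)})")
    report.append("")
    return {"by_calc_group": by_calc, "by_quadrant": by_quad,
            "correlations": corr, "soils": soil_df}
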