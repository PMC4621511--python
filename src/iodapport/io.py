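"""CSV reading, censoring-string parsing and schema validation.

CSV is the sole tabular interchange format (UTF-8, header row, "." decimal).
Concentration columns may carry "<x" strings meaning "below the limit of
detection x"; these are parsed into a numeric value with the ``below_lod``
flag set.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import MEASUREMENT_COLUMNS
from .soils import SOIL_COLUMNS
from .supply import SUPPLY_COLUMNS
from .uic import URINE_COLUMNS

_LT = re.compile(r"^\s*<\s*([0-9.eE+-]+)\s*$")

#: Required columns per known input-file kind.
SCHEMAS = {
    "measurements": MEASUREMENT_COLUMNS,
    "soils": SOIL_COLUMNS,
    "fbs": SUPPLY_COLUMNS,
    "urine": URINE_COLUMNS,
}

_NUMERIC = {
    "measurements": ["value"],
    "soils": ["ph", "om", "total_i", "water_ext_i"],
    "fbs": ["supply_fw", "dw_fraction"],
    "urine": ["uic", "creatinine"],
}


def parse_censored_column(raw: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Split a concentration column into (numeric values, below-LOD flags).

    "<x" entries return value x with the flag set (the half-LOD substitution
    happens later, in the composition stage); blanks return NaN, flag False.
    """
    values = np.full(len(raw), np.nan)
    flags = np.zeros(len(raw), dtype=bool)
    for i, entry in enumerate(raw.astype(object)):
        if entry is None or (isinstance(entry, float) and np.isnan(entry)):
            continue
        text = str(entry).strip()
        if not text:
            continue
        m = _LT.match(text)
        if m:
            values[i] = float(m.group(1))
            flags[i] = True
        else:
            values[i] = float(text)  # may raise ValueError for garbage
    return (pd.Series(values, index=raw.index),
            pd.Series(flags, index=raw.index))


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a sample-measurements CSV, handling "<x" censoring strings."""
    df = pd.read_csv(path, dtype={"value": str})
    _check_columns(df, "measurements", path)
    values, lt_flags = parse_censored_column(df["value"])
    df["value"] = values
    if "below_lod" in df.columns:
        explicit = df["below_lod"].map(
            lambda x: _parse_bool(x) is True).astype(bool)
    else:
        explicit = pd.Series(False, index=df.index)
    df["below_lod"] = explicit | lt_flags
    return df


def read_soils(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, "soils", path)
    return df


def read_fbs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, "fbs", path)
    return df


def read_urine(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, "urine", path)
    return df


def _parse_bool(x):
    if isinstance(x, bool):
        return x
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return np.nan
    return str(x).strip().lower() in ("true", "1", "yes", "t")


def _check_columns(df: pd.DataFrame, kind: str, path) -> None:
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing} for {kind} file")


def validate_file(path: str | Path, kind: str) -> list[dict]:
    """Schema-check one CSV without mutating it.

    Returns a machine-readable defect list: each defect names the file, the
    column and (where applicable) the 1-based data row.  Defects are data,
    not exceptions; an unreadable file yields a single defect.
    """
    path = Path(path)
    defects: list[dict] = []
    if kind not in SCHEMAS:
        raise ValueError(f"unknown file kind {kind!r}")
    if not path.exists():
        return [{"file": str(path), "row": None, "column": None,
                 "message": "file does not exist"}]
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # malformed CSV
        return [{"file": str(path), "row": None, "column": None,
                 "message": f"unreadable CSV: {exc}"}]
    for col in SCHEMAS[kind]:
        if col not in df.columns:
            defects.append({"file": str(path), "row": None, "column": col,
                            "message": "missing required column"})
    for col in _NUMERIC[kind]:
        if col not in df.columns:
            continue
        censorable = kind == "measurements" and col == "value"
        for i, entry in enumerate(df[col]):
            if entry is None or (isinstance(entry, float) and np.isnan(entry)):
                continue
            text = str(entry).strip()
            if not text or text.lower() == "nan":
                continue
            if censorable and _LT.match(text):
                continue
            try:
                value = float(text)
            except ValueError:
                defects.append({"file": str(path), "row": i + 1, "column": col,
                                "message": f"non-numeric value {text!r}"})
                continue
            if col in ("value", "uic", "total_i", "water_ext_i", "supply_fw",
                       "om") and value < 0:
                defects.append({"file": str(path), "row": i + 1, "column": col,
                                "message": f"negative value {value}"})
    return defects
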