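"""Cohort CSV reading/writing and the study inclusion filters.

The on-disk dialect is a UTF-8 CSV with a header row and one patient per
row; see ``docs/data_dictionary.md`` for the column meanings. Missing cells
stay missing (empty string on disk, ``None``/``NaN`` in memory). Column
renames are supplied through a schema mapping (YAML/JSON file or dict of
``canonical_name: actual_name``); unmapped extra columns are carried
through untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Optional, Union

import pandas as pd
import yaml
from pydantic import ValidationError

from .records import (
    SGA_ITEM_NAMES,
    OutcomePanel,
    PatientRecord,
    SGAItems,
)

Source = Union[str, Path, IO[str]]

CATEGORICAL_COLUMNS = ("sex", "marital_status", "education", "admission_reason")
INT_COLUMNS = ("nrs2002_total",)
FLOAT_COLUMNS = (
    "age",
    "height_cm",
    "weight_kg",
    "bmi_kg_m2",
    "weight_loss_pct_6mo",
    "weight_loss_pct_beyond_6mo",
    "calf_circumference_cm",
    "grip_strength_kg",
    "mid_arm_circumference_cm",
    "albumin_g_L",
    "hemoglobin_g_L",
    "lymphocytes_1e9_L",
    "total_protein_g_L",
    "prealbumin_g_L",
    "triglyceride_mmol_L",
    "cholesterol_mmol_L",
)
BOOL_COLUMNS = (
    "unintentional_weight_loss",
    "intake_reduced_gt50pct_1wk",
    "intake_reduced_gt2wk",
    "chronic_gi_disease",
    "inflammatory_condition",
)
SGA_COLUMNS = tuple(f"sga_{name}" for name in SGA_ITEM_NAMES)
OUTCOME_BOOL_COLUMNS = (
    "total_complication",
    "infectious_complication",
    "noninfectious_complication",
    "icu_admission",
    "mortality",
)
OUTCOME_FLOAT_COLUMNS = ("icu_days", "los_days", "expenses_usd")

#: Full canonical column order of the cohort CSV dialect.
CANONICAL_COLUMNS = (
    ("patient_id",)
    + ("age",)
    + CATEGORICAL_COLUMNS
    + INT_COLUMNS
    + tuple(c for c in FLOAT_COLUMNS if c != "age")
    + BOOL_COLUMNS
    + SGA_COLUMNS
    + OUTCOME_BOOL_COLUMNS
    + OUTCOME_FLOAT_COLUMNS
)

MANDATORY_COLUMNS = ("patient_id", "age", "sex")

_TRUE = {"1", "true", "yes", "t"}
_FALSE = {"0", "false", "no", "f"}


class CohortIOError(Exception):
    """Unreadable/unwritable stream or unmapped mandatory column."""


class CellParseError(CohortIOError):
    """An unparseable cell; message names the row and column."""


def load_schema(path: Union[str, Path]) -> dict[str, str]:
    """Load a canonical→actual column-name mapping from YAML or JSON."""
    text = Path(path).read_text(encoding="utf-8")
    mapping = (
        json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    )
    if not isinstance(mapping, dict):
        raise CohortIOError(f"schema file {path} must contain a mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def _parse_bool(raw: str, row: int, column: str) -> bool:
    low = raw.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise CellParseError(f"row {row}, column {column!r}: cannot parse boolean {raw!r}")


def _parse_float(raw: str, row: int, column: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise CellParseError(
            f"row {row}, column {column!r}: cannot parse number {raw!r}"
        ) from None


def _row_to_record(row: dict[str, str], idx: int) -> PatientRecord:
    data: dict = {}
    present = {k: v for k, v in row.items() if v is not None and str(v).strip() != ""}

    for col in ("patient_id",) + CATEGORICAL_COLUMNS:
        if col in present:
            data[col] = str(present[col]).strip()
    for col in FLOAT_COLUMNS:
        if col in present:
            data[col] = _parse_float(str(present[col]), idx, col)
    for col in INT_COLUMNS:
        if col in present:
            value = _parse_float(str(present[col]), idx, col)
            data[col] = int(round(value))
    for col in BOOL_COLUMNS:
        if col in present:
            data[col] = _parse_bool(str(present[col]), idx, col)

    sga = {}
    for name, col in zip(SGA_ITEM_NAMES, SGA_COLUMNS):
        if col in present:
            sga[name] = str(present[col]).strip()
    if sga:
        if len(sga) != len(SGA_ITEM_NAMES):
            missing = [c for c in SGA_COLUMNS if c not in present]
            raise CellParseError(
                f"row {idx}: partial bedside-assessment items; missing {missing}"
            )
        try:
            data["sga_items"] = SGAItems(**sga)
        except ValidationError as exc:
            bad = "; ".join(str(e["loc"][0]) for e in exc.errors())
            raise CellParseError(
                f"row {idx}: invalid A/B/C rating for item(s): {bad}"
            ) from exc

    outcome = {}
    for col in OUTCOME_BOOL_COLUMNS:
        if col in present:
            outcome[col] = _parse_bool(str(present[col]), idx, col)
    for col in OUTCOME_FLOAT_COLUMNS:
        if col in present:
            outcome[col] = _parse_float(str(present[col]), idx, col)
    if outcome:
        try:
            data["outcomes"] = OutcomePanel(**outcome)
        except ValidationError as exc:
            raise CellParseError(f"row {idx}: inconsistent outcome panel: {exc}") from exc

    known = set(CANONICAL_COLUMNS)
    data["extras"] = {
        k: str(v) for k, v in present.items() if k not in known
    }
    try:
        return PatientRecord(**data)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise CellParseError(
            f"row {idx}, column {loc!r}: {first['msg']}"
        ) from exc


def read_cohort(
    source: Source, schema: Optional[Union[dict[str, str], str, Path]] = None
) -> list[PatientRecord]:
    """Read a cohort CSV into validated :class:`PatientRecord` objects.

    Row order is preserved; missing cells become ``None``. ``schema`` maps
    canonical column names to the names actually present in the file.
    """
    if isinstance(schema, (str, Path)):
        schema = load_schema(schema)
    try:
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CohortIOError(f"cannot read cohort table: {exc}") from exc
    if schema:
        reverse = {actual: canonical for canonical, actual in schema.items()}
        df = df.rename(columns=reverse)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise CohortIOError(f"mandatory column {col!r} missing and unmapped")
    rows = df.to_dict(orient="records")
    return [_row_to_record(row, idx) for idx, row in enumerate(rows)]


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Flatten records into the canonical cohort DataFrame."""
    rows = []
    extra_cols: list[str] = []
    for rec in records:
        row: dict = {}
        for col in CANONICAL_COLUMNS:
            if col.startswith("sga_"):
                name = col[len("sga_"):]
                row[col] = (
                    getattr(rec.sga_items, name) if rec.sga_items is not None else None
                )
            elif col in OUTCOME_BOOL_COLUMNS + OUTCOME_FLOAT_COLUMNS:
                row[col] = (
                    getattr(rec.outcomes, col) if rec.outcomes is not None else None
                )
            else:
                row[col] = getattr(rec, col)
        for key, value in rec.extras.items():
            row[key] = value
            if key not in extra_cols:
                extra_cols.append(key)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS) + extra_cols)


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    """Parse a canonical cohort DataFrame into validated records."""
    def cell(v) -> str:
        if v is None or (isinstance(v, float) and pd.isna(v)):
            return ""
        if isinstance(v, bool):
            return "1" if v else "0"
        return str(v)

    return [
        _row_to_record({k: cell(v) for k, v in row.items()}, idx)
        for idx, row in enumerate(df.to_dict(orient="records"))
    ]


def write_cohort(records: Iterable[PatientRecord], sink: Source) -> int:
    """Write records as a canonical cohort CSV; returns the row count.

    Round-trip contract: ``read_cohort(write_cohort(x))`` reproduces every
    field, with missing values staying missing.
    """
    records = list(records)
    df = records_to_frame(records)
    out = df.copy()
    for col in BOOL_COLUMNS + OUTCOME_BOOL_COLUMNS:
        out[col] = out[col].map(lambda v: "" if v is None or pd.isna(v) else str(int(v)))
    try:
        out.to_csv(sink, index=False, na_rep="")
    except OSError as exc:
        raise CohortIOError(f"cannot write cohort table: {exc}") from exc
    return len(records)


@dataclass(frozen=True)
class Exclusion:
    """One excluded record and the first inclusion rule it violated."""

    patient_id: str
    reason: str  # "age" | "los" | "anthropometrics"


def apply_study_filters(
    records: Iterable[PatientRecord],
    min_age: float = 65.0,
    los_window: tuple[float, float] = (7.0, 30.0),
) -> tuple[list[PatientRecord], list[Exclusion]]:
    """Apply the cohort inclusion rules; returns (kept, exclusion log).

    Keeps patients aged >= ``min_age`` whose length of stay — when known —
    lies inside ``los_window`` days and whose weight and height are both
    recorded. Filtering is idempotent.
    """
    kept: list[PatientRecord] = []
    excluded: list[Exclusion] = []
    lo, hi = los_window
    for rec in records:
        if rec.age < min_age:
            excluded.append(Exclusion(rec.patient_id, "age"))
            continue
        los = rec.outcomes.los_days if rec.outcomes is not None else None
        if los is not None and not (lo <= los <= hi):
            excluded.append(Exclusion(rec.patient_id, "los"))
            continue
        if rec.weight_kg is None or rec.height_cm is None:
            excluded.append(Exclusion(rec.patient_id, "anthropometrics"))
            continue
        kept.append(rec)
    return kept, excluded
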