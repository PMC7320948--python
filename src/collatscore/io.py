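"""Cohort, vasculature and config file I/O.

All artifacts are plain text: the cohort is a one-row-per-patient CSV, the
grading sheets a long-format CSV (patient_id, vessel, side, grade plus the
two pial counts), provenance a JSON sidecar, and generator configs JSON or
YAML.  Write→read round-trips reproduce tables exactly, including missing
values.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import grading
from .cohort import CohortTable, GeneratorConfig

__all__ = [
    "COHORT_COLUMNS",
    "SchemaError",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_vasculature_csv",
    "read_vasculature_csv",
    "write_provenance",
    "read_provenance",
    "load_generator_config",
    "save_generator_config",
]


class SchemaError(ValueError):
    """Malformed cohort or vasculature file."""


_STRING_COLS = ("patient_id", "excluded", "treatment", "territory")
_INT_COLS = (
    "tia",
    "male",
    "atherosclerosis",
    "smoking",
    "glucose",
    "infection",
    "statin",
    "onset_known",
    "whole_brain_score",
    "pial_only_score",
    "pial_cortical_count",
    "pial_cerebellar_count",
)
_FLOAT_COLS = (
    "age",
    "fiv_ml",
    "nihss_admission",
    "nihss_discharge",
    "mrs_admission",
    "mrs_discharge",
)

#: cohort CSV column dictionary, in file order
COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "excluded",
    "tia",
    "age",
    "male",
    "atherosclerosis",
    "smoking",
    "glucose",
    "infection",
    "statin",
    "treatment",
    "territory",
    "onset_known",
    "whole_brain_score",
    "pial_only_score",
    "pial_cortical_count",
    "pial_cerebellar_count",
    "fiv_ml",
    "nihss_admission",
    "nihss_discharge",
    "mrs_admission",
    "mrs_discharge",
)

_VASC_COLUMNS = (
    "patient_id",
    "vessel",
    "side",
    "grade",
    "pial_cortical_count",
    "pial_cerebellar_count",
)


def write_cohort_csv(cohort: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    df = cohort.table.loc[:, list(COHORT_COLUMNS)]
    df.to_csv(path, index=False)
    return path


def _coerce_numeric(df: pd.DataFrame, col: str, kind: str) -> pd.Series:
    raw = df[col]
    coerced = pd.to_numeric(raw, errors="coerce")
    bad = coerced.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(bad.idxmax()) + 2  # header line + 1-based
        raise SchemaError(
            f"non-numeric value {raw[bad.idxmax()]!r} in numeric column "
            f"{col!r} (file line {row})"
        )
    if kind == "int":
        if coerced.notna().all():
            return coerced.astype(int)
    return coerced.astype(float)


def read_cohort_csv(
    path: str | Path, vasculature_path: str | Path | None = None
) -> CohortTable:
    """Read a cohort CSV (and optionally its companion grading sheets).

    Raises :class:`SchemaError` naming missing/unexpected columns, or the
    offending line for a non-numeric value in a numeric column.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={c: "string" for c in _STRING_COLS})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    unexpected = [c for c in df.columns if c not in COHORT_COLUMNS]
    if missing or unexpected:
        raise SchemaError(
            f"cohort CSV schema mismatch: missing {missing}, unexpected {unexpected}"
        )
    for col in _INT_COLS:
        df[col] = _coerce_numeric(df, col, "int")
    for col in _FLOAT_COLS:
        df[col] = _coerce_numeric(df, col, "float")
    for col in _STRING_COLS:
        df[col] = df[col].astype(object).where(df[col].notna(), np.nan)
    df = df.loc[:, list(COHORT_COLUMNS)]
    grades = None
    if vasculature_path is not None:
        grades = _grades_matrix(
            read_vasculature_csv(vasculature_path), df["patient_id"]
        )
    return CohortTable(df, grades)


def write_vasculature_csv(cohort: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    cohort.vasculature_frame().to_csv(path, index=False)
    return path


def read_vasculature_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _VASC_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"vasculature CSV missing column(s): {missing}")
    return df


def _grades_matrix(vasc: pd.DataFrame, patient_ids: pd.Series) -> np.ndarray:
    """Pivot a long-format grading sheet into the (n, 34) slot matrix."""
    key = vasc.set_index(["patient_id", "vessel", "side"])["grade"]
    n = len(patient_ids)
    out = np.zeros((n, len(grading.SLOTS)), dtype=int)
    for i, pid in enumerate(patient_ids):
        for j, (v, s) in enumerate(grading.SLOTS):
            try:
                out[i, j] = int(key.loc[(pid, v.value, s.value)])
            except KeyError as exc:
                raise SchemaError(
                    f"vasculature CSV missing slot {v.value}/{s.value} for "
                    f"patient {pid!r}"
                ) from exc
    return out


def sheet_to_frame(
    patient_id: str, vasc: grading.PatientVasculature
) -> pd.DataFrame:
    """One patient's grading sheet in the long CSV layout."""
    rows = [
        {
            "patient_id": patient_id,
            "vessel": g.vessel.value,
            "side": g.side.value,
            "grade": g.grade,
            "pial_cortical_count": vasc.pial.cortical_count,
            "pial_cerebellar_count": vasc.pial.cerebellar_count,
        }
        for g in vasc.grades
    ]
    return pd.DataFrame(rows)


def frame_to_sheets(vasc: pd.DataFrame) -> dict[str, grading.PatientVasculature]:
    """Parse a long-format vasculature frame into grading sheets by patient."""
    sheets: dict[str, grading.PatientVasculature] = {}
    for pid, grp in vasc.groupby("patient_id", sort=False):
        grades = {
            (grading.Vessel(r.vessel), grading.Side(r.side)): int(r.grade)
            for r in grp.itertuples()
        }
        pial = grading.PialCounts(
            int(grp["pial_cortical_count"].iloc[0]),
            int(grp["pial_cerebellar_count"].iloc[0]),
        )
        sheets[str(pid)] = grading.PatientVasculature.from_mapping(grades, pial)
    return sheets


def write_provenance(cohort: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(cohort.provenance, sort_keys=True, indent=2) + "\n")
    return path


def read_provenance(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def load_generator_config(path: str | Path) -> GeneratorConfig:
    """Load a generator config from JSON or YAML (by file extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return GeneratorConfig.model_validate(data)


def save_generator_config(config: GeneratorConfig, path: str | Path) -> Path:
    path = Path(path)
    data = config.model_dump()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")
    return path
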