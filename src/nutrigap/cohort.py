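"""Subject records, the clinical panel, and the cohort CSV format.

A cohort is a flat CSV with one row per subject: demographics, the ten
energy/macronutrient intake variables, and the eleven-outcome clinical
panel. Energy is stored in MJ/day internally; readers can declare a kcal
column and have it converted on entry.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

SEXES = ("female", "male")

#: Order of the ten intake variables; this is also the order of the gap
#: (delta) vector used as the regression design throughout the package.
INTAKE_VARS = (
    "energy",    # MJ/day
    "carb",      # %EI
    "sugars",    # %EI
    "fat",       # %EI
    "sfa",       # %EI
    "ufa",       # %EI
    "pufa",      # %EI
    "protein",   # g/day
    "fibre",     # g/day
    "alcohol",   # servings/day
)

#: The clinical outcome panel, in reporting order.
OUTCOME_VARS = (
    "bmi",         # kg/m^2
    "wc",          # cm
    "tg",          # mg/dL
    "total_chol",  # mg/dL
    "hdl_c",       # mg/dL
    "ldl_c",       # mg/dL
    "glucose",     # mg/dL
    "insulin",     # uIU/mL
    "hba1c",       # %
    "sbp",         # mmHg
    "dbp",         # mmHg
)

KCAL_PER_MJ = 1000.0 / 4.184  # 1 MJ = 239.0 kcal


def kcal_to_mj(kcal: float) -> float:
    """Convert kcal/day to MJ/day (x 4.184/1000)."""
    return kcal * 4.184 / 1000.0


class CohortValidationError(ValueError):
    """Raised when one or more subject rows fail validation."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "cohort validation failed:\n" + "\n".join(self.problems)
        )


@dataclass(frozen=True)
class ClinicalPanel:
    """The eleven metabolic-syndrome-related clinical outcomes."""

    bmi: float
    wc: float
    tg: float
    total_chol: float
    hdl_c: float
    ldl_c: float
    glucose: float
    insulin: float
    hba1c: float
    sbp: float
    dbp: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def is_complete(self) -> bool:
        return all(math.isfinite(v) for v in self.as_dict().values())


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: demographics, daily intakes, clinical panel.

    Intake units follow the study convention: energy MJ/day; carbohydrate,
    sugars, total fat, SFA, UFA and PUFA as percent of energy intake (%EI);
    protein and fibre g/day; alcohol servings/day. ``clinical`` is None for
    subjects whose panel is incomplete (they are excluded before analysis,
    never imputed).
    """

    id: str
    sex: str
    age: float
    weight: float   # kg
    height: float   # cm
    centre: str
    energy: float
    carb: float
    sugars: float
    fat: float
    sfa: float
    ufa: float
    pufa: float
    protein: float
    fibre: float
    alcohol: float
    clinical: ClinicalPanel | None = None

    def intake(self, nutrient: str) -> float:
        if nutrient not in INTAKE_VARS:
            raise KeyError(f"unknown intake variable {nutrient!r}")
        return getattr(self, nutrient)

    def validation_problems(self, centres: Iterable[str] | None = None) -> list[str]:
        """Return human-readable problems; empty list means valid."""
        out: list[str] = []
        if self.sex not in SEXES:
            out.append(
                f"subject {self.id}: sex {self.sex!r} not in {SEXES}"
            )
        if centres is not None and self.centre not in set(centres):
            out.append(
                f"subject {self.id}: centre {self.centre!r} not in {sorted(set(centres))}"
            )
        if not (18.0 <= self.age <= 80.0):
            out.append(f"subject {self.id}: age {self.age} outside [18, 80]")
        if not self.weight > 0:
            out.append(f"subject {self.id}: non-positive weight {self.weight}")
        if not self.height > 0:
            out.append(f"subject {self.id}: non-positive height {self.height}")
        for var in INTAKE_VARS:
            v = self.intake(var)
            if not math.isfinite(v):
                out.append(f"subject {self.id}: non-finite intake {var}")
            elif v < 0:
                out.append(f"subject {self.id}: negative intake {var} = {v}")
            elif var in PCT_EI_VARS and v > 100:
                out.append(f"subject {self.id}: {var} = {v} %EI exceeds 100")
        return out


PCT_EI_VARS = ("carb", "sugars", "fat", "sfa", "ufa", "pufa")

#: Column order of the cohort CSV.
CSV_COLUMNS = (
    ("id", "sex", "age", "weight", "height", "centre")
    + INTAKE_VARS
    + OUTCOME_VARS
)


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Flatten records into the cohort table (one row per subject)."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "id": r.id, "sex": r.sex, "age": r.age, "weight": r.weight,
            "height": r.height, "centre": r.centre,
        }
        for var in INTAKE_VARS:
            row[var] = r.intake(var)
        panel = r.clinical.as_dict() if r.clinical is not None else {}
        for var in OUTCOME_VARS:
            row[var] = panel.get(var, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[SubjectRecord]:
    records = []
    for _, row in df.iterrows():
        panel_vals = {k: float(row[k]) for k in OUTCOME_VARS}
        clinical: ClinicalPanel | None = ClinicalPanel(**panel_vals)
        if not clinical.is_complete():
            clinical = None
        records.append(
            SubjectRecord(
                id=str(row["id"]),
                sex=str(row["sex"]),
                age=float(row["age"]),
                weight=float(row["weight"]),
                height=float(row["height"]),
                centre=str(row["centre"]),
                clinical=clinical,
                **{v: float(row[v]) for v in INTAKE_VARS},
            )
        )
    return records


def write_cohort_csv(df_or_records, path: str | Path) -> None:
    """Write a cohort table to CSV with a stable numeric format.

    Accepts either the flat DataFrame or a sequence of SubjectRecord.
    The fixed '%.10g' float format makes repeated writes of the same
    cohort byte-identical.
    """
    if not isinstance(df_or_records, pd.DataFrame):
        df_or_records = records_to_frame(df_or_records)
    df = df_or_records.reindex(columns=list(CSV_COLUMNS))
    df.to_csv(path, index=False, float_format="%.10g")


def read_cohort_csv(
    path: str | Path,
    energy_unit: str = "MJ",
    centres: Iterable[str] | None = None,
    validate: bool = True,
) -> list[SubjectRecord]:
    """Read and validate a cohort CSV.

    ``energy_unit`` declares the unit of the energy column ("MJ" or
    "kcal"); kcal values are converted to MJ/day on entry so the
    misreporting screen's EI:BMR ratio is unit-consistent by construction.
    Row-level problems are collected and raised together.
    """
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise OSError(f"cannot read cohort file {path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(
            [f"{path}: missing mandatory columns: {', '.join(missing)}"]
        )
    if energy_unit not in ("MJ", "kcal"):
        raise ValueError(f"energy_unit must be 'MJ' or 'kcal', got {energy_unit!r}")

    problems: list[str] = []
    numeric_cols = [c for c in CSV_COLUMNS if c not in ("id", "sex", "centre")]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for i in bad:
            problems.append(
                f"line {i + 2}: non-numeric value {df.loc[i, col]!r} in column {col}"
            )
        df[col] = coerced
    if problems:
        raise CohortValidationError(problems)

    if energy_unit == "kcal":
        df["energy"] = df["energy"].map(kcal_to_mj)

    records = frame_to_records(df)
    if validate:
        for i, rec in enumerate(records):
            for p in rec.validation_problems(centres=centres):
                problems.append(f"line {i + 2}: {p}")
        if problems:
            raise CohortValidationError(problems)
    return records
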