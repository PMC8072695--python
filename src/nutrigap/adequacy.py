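"""Dietary reference values and intake-gap (delta) computation.

Adequacy of each of the ten energy/macronutrient intakes is encoded as a
per-nutrient, per-sex reference entry carrying either a two-sided adequate
range (midpoint rule: the recommendation is the range mean) or a one-sided
limit (limit rule: the recommendation is the limit itself). A subject's
gap vector holds the ten signed differences

    delta = current intake - recommended intake

in native units (MJ/day, %EI, g/day, servings/day); cross-unit
comparability is deferred to the standard-scaling step of the regression.

Default values follow the EFSA dietary reference values and WHO/FAO
guidelines for adults:

* energy: adequate 6.8-10.1 MJ/day (women), 8.3-12.6 MJ/day (men) - the
  sex-level aggregates spanned by PAL 1.4-1.8; midpoint rule
* total carbohydrates: 45-60 %EI, midpoint rule
* sugars: < 10 %EI, limit rule
* dietary fibre: >= 25 g/day, limit rule
* protein: between the average requirement (AR, 0.66 g/kg/day) and the
  population reference intake (PRI, 0.83 g/kg/day); midpoint 0.745
  g/kg/day scaled by the subject's actual body weight
* total fat: 20-35 %EI, midpoint rule
* SFA: < 10 %EI, limit rule
* total UFA (MUFA + PUFA): 15-20 %EI, midpoint rule
* PUFA: 6-11 %EI, midpoint rule
* alcohol: up to 1 serving/day (women) / 2 servings/day (men), limit rule
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import INTAKE_VARS, SEXES, SubjectRecord

MIDPOINT = "midpoint"
LIMIT = "limit"


class ReferenceLookupError(KeyError):
    pass


class MissingIntakeError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceEntry:
    """Adequacy reference for one nutrient (optionally sex-specific).

    For ``rule == "midpoint"`` both bounds must be present and the
    recommendation is their mean; for ``rule == "limit"`` exactly one bound
    is present and is itself the recommendation. ``per_kg`` marks g/kg/day
    entries (protein) whose recommendation scales with body weight.
    """

    nutrient: str
    sex: str          # 'female', 'male' or 'any'
    rule: str         # 'midpoint' | 'limit'
    lower: float | None = None
    upper: float | None = None
    units: str = ""
    per_kg: bool = False

    def __post_init__(self):
        if self.rule not in (MIDPOINT, LIMIT):
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.rule == MIDPOINT and (self.lower is None or self.upper is None):
            raise ValueError(f"{self.nutrient}: midpoint rule needs both bounds")
        if self.rule == LIMIT and (self.lower is None) == (self.upper is None):
            raise ValueError(f"{self.nutrient}: limit rule needs exactly one bound")
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValueError(f"{self.nutrient}: lower {self.lower} > upper {self.upper}")

    @property
    def bounds(self) -> tuple[float | None, float | None]:
        return (self.lower, self.upper)

    @property
    def limit(self) -> float:
        if self.rule != LIMIT:
            raise ValueError(f"{self.nutrient}: not a limit-rule entry")
        return self.lower if self.lower is not None else self.upper  # type: ignore

    def recommendation_per_unit(self) -> float:
        """Recommendation before any body-weight scaling."""
        if self.rule == MIDPOINT:
            return (self.lower + self.upper) / 2.0  # type: ignore
        return self.limit


@dataclass
class ReferenceTable:
    """Lookup of ReferenceEntry by (nutrient, sex), with 'any' fallback."""

    entries: list[ReferenceEntry] = field(default_factory=list)

    def entry(self, nutrient: str, sex: str = "any") -> ReferenceEntry:
        by_key = {(e.nutrient, e.sex): e for e in self.entries}
        e = by_key.get((nutrient, sex)) or by_key.get((nutrient, "any"))
        if e is None:
            raise ReferenceLookupError(
                f"no reference entry for nutrient {nutrient!r}, sex {sex!r}"
            )
        return e

    def to_yaml(self, path: str | Path) -> None:
        payload = [
            {
                "nutrient": e.nutrient, "sex": e.sex, "rule": e.rule,
                "lower": e.lower, "upper": e.upper, "units": e.units,
                "per_kg": e.per_kg,
            }
            for e in self.entries
        ]
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReferenceTable":
        payload = yaml.safe_load(Path(path).read_text())
        return cls([ReferenceEntry(**row) for row in payload])


def default_reference_table() -> ReferenceTable:
    """The built-in adult EFSA / WHO-FAO reference table (module docstring)."""
    e = ReferenceEntry
    return ReferenceTable([
        e("energy", "female", MIDPOINT, 6.8, 10.1, "MJ/day"),
        e("energy", "male", MIDPOINT, 8.3, 12.6, "MJ/day"),
        e("carb", "any", MIDPOINT, 45.0, 60.0, "%EI"),
        e("sugars", "any", LIMIT, upper=10.0, units="%EI"),
        e("fat", "any", MIDPOINT, 20.0, 35.0, "%EI"),
        e("sfa", "any", LIMIT, upper=10.0, units="%EI"),
        e("ufa", "any", MIDPOINT, 15.0, 20.0, "%EI"),
        e("pufa", "any", MIDPOINT, 6.0, 11.0, "%EI"),
        e("protein", "any", MIDPOINT, 0.66, 0.83, "g/kg/day", per_kg=True),
        e("fibre", "any", LIMIT, lower=25.0, units="g/day"),
        e("alcohol", "female", LIMIT, upper=1.0, units="servings/day"),
        e("alcohol", "male", LIMIT, upper=2.0, units="servings/day"),
    ])


def recommended_value(
    table: ReferenceTable, nutrient: str, subject: SubjectRecord
) -> float:
    """Recommended intake for this subject, in the nutrient's native unit.

    Midpoint-rule nutrients return the range mean, limit-rule nutrients the
    limit; per-kg entries (protein) are scaled by the subject's weight.
    """
    e = table.entry(nutrient, subject.sex)
    base = e.recommendation_per_unit()
    if e.per_kg:
        return base * subject.weight
    return base


def compute_gaps(subject: SubjectRecord, table: ReferenceTable) -> np.ndarray:
    """The subject's ten signed intake deltas, in INTAKE_VARS order.

    delta = current intake - recommended intake; no imputation - a missing
    (non-finite) intake raises MissingIntakeError naming subject and field.
    """
    gaps = np.empty(len(INTAKE_VARS))
    for i, nutrient in enumerate(INTAKE_VARS):
        current = subject.intake(nutrient)
        if not np.isfinite(current):
            raise MissingIntakeError(
                f"subject {subject.id}: missing intake value for {nutrient!r}"
            )
        gaps[i] = current - recommended_value(table, nutrient, subject)
    return gaps


def gap_table(records, table: ReferenceTable | None = None):
    """Gap vectors for a cohort as a DataFrame (rows follow input order).

    Columns are ``d_<nutrient>`` in INTAKE_VARS order, indexed by subject id.
    """
    import pandas as pd

    if table is None:
        table = default_reference_table()
    data = {f"d_{v}": [] for v in INTAKE_VARS}
    ids = []
    for rec in records:
        g = compute_gaps(rec, table)
        for v, val in zip(INTAKE_VARS, g):
            data[f"d_{v}"].append(val)
        ids.append(rec.id)
    return pd.DataFrame(data, index=pd.Index(ids, name="id"))


def check_table_complete(table: ReferenceTable) -> None:
    """Assert a recommendation resolves for every (nutrient, sex) pair."""
    for nutrient in INTAKE_VARS:
        for sex in SEXES:
            table.entry(nutrient, sex)
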