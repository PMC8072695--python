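"""Goldberg energy-misreporting screen (Black modification).

Implausible energy reporters are flagged by the ratio of reported energy
intake to estimated basal metabolic rate (EI:BMR). BMR comes from the
sex- and age-specific Oxford (Henry 2005) linear equations, shipped as an
editable YAML coefficient table. The published cutoffs applied here are

    underreporter  : EI:BMR < 0.901
    overreporter   : EI:BMR > 2.841
    plausible      : otherwise (boundary values are plausible - the
                     inequalities are strict, which differs from
                     implementations that use <=)

The cutoffs already embed the assumed moderately-active PAL of 1.6 and the
Goldberg confidence-interval arithmetic, so PAL is recorded in the report
metadata but never enters the computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .cohort import SubjectRecord

UNDER_CUTOFF = 0.901
OVER_CUTOFF = 2.841
ASSUMED_PAL = 1.6

UNDERREPORTER = "underreporter"
PLAUSIBLE = "plausible"
OVERREPORTER = "overreporter"


class BMRConfigError(ValueError):
    pass


@dataclass(frozen=True)
class BMRBand:
    sex: str
    age_min: float
    age_max: float
    intercept: float      # MJ/day
    weight_coef: float    # MJ/day per kg
    height_coef: float = 0.0  # MJ/day per m, optional height-aware form

    def covers(self, sex: str, age: float) -> bool:
        return sex == self.sex and self.age_min <= age < self.age_max


@dataclass
class BMRModel:
    """Piecewise-linear BMR in weight (and optionally height), MJ/day."""

    bands: list[BMRBand]

    def band_for(self, sex: str, age: float) -> BMRBand:
        for b in self.bands:
            if b.covers(sex, age):
                return b
        # closed upper edge of the oldest band per sex
        top = [b for b in self.bands if b.sex == sex]
        if top:
            oldest = max(top, key=lambda b: b.age_max)
            if age == oldest.age_max:
                return oldest
        raise BMRConfigError(
            f"no BMR age band covers sex={sex!r}, age={age}"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BMRModel":
        payload = yaml.safe_load(Path(path).read_text())
        return cls([BMRBand(**row) for row in payload])


def default_bmr_model() -> BMRModel:
    """The packaged weight-only Oxford/Henry coefficient table."""
    ref = resources.files("nutrigap.data") / "bmr_oxford_weight.yaml"
    payload = yaml.safe_load(ref.read_text())
    return BMRModel([BMRBand(**row) for row in payload])


def basal_metabolic_rate(subject: SubjectRecord, model: BMRModel | None = None) -> float:
    """Estimated BMR in MJ/day for the subject under the given model."""
    if model is None:
        model = default_bmr_model()
    if subject.weight <= 0:
        raise ValueError(f"subject {subject.id}: non-positive weight")
    band = model.band_for(subject.sex, subject.age)
    bmr = (
        band.intercept
        + band.weight_coef * subject.weight
        + band.height_coef * subject.height / 100.0
    )
    if bmr <= 0:
        raise ValueError(
            f"subject {subject.id}: non-positive BMR {bmr:.3f} MJ/day"
        )
    return bmr


@dataclass(frozen=True)
class MisreportLabel:
    ratio: float      # EI:BMR, dimensionless
    category: str     # underreporter | plausible | overreporter


def classify_ratio(ratio: float) -> str:
    if ratio < UNDER_CUTOFF:
        return UNDERREPORTER
    if ratio > OVER_CUTOFF:
        return OVERREPORTER
    return PLAUSIBLE


def classify_reporting(
    subject: SubjectRecord, model: BMRModel | None = None
) -> MisreportLabel:
    """EI:BMR ratio and its under/plausible/over category."""
    ratio = subject.energy / basal_metabolic_rate(subject, model)
    return MisreportLabel(ratio=ratio, category=classify_ratio(ratio))


def screen_cohort(
    records: Sequence[SubjectRecord], model: BMRModel | None = None
) -> tuple[list[SubjectRecord], list[SubjectRecord], dict]:
    """Partition a cohort into plausible reporters and misreporters.

    Returns (retained, flagged, report); retained and flagged are disjoint
    and their union is the input. The report carries the per-subject table
    (id, sex, ratio, category) and counts by sex and category.
    """
    if model is None:
        model = default_bmr_model()
    retained: list[SubjectRecord] = []
    flagged: list[SubjectRecord] = []
    rows = []
    for rec in records:
        try:
            label = classify_reporting(rec, model)
        except (ValueError, BMRConfigError) as exc:
            raise type(exc)(f"screening subject {rec.id}: {exc}") from exc
        rows.append(
            {"id": rec.id, "sex": rec.sex, "ratio": label.ratio,
             "category": label.category}
        )
        (retained if label.category == PLAUSIBLE else flagged).append(rec)
    table = pd.DataFrame(rows, columns=["id", "sex", "ratio", "category"])
    counts = {
        sex: {
            cat: int(((table["sex"] == sex) & (table["category"] == cat)).sum())
            for cat in (UNDERREPORTER, PLAUSIBLE, OVERREPORTER)
        }
        for sex in sorted(table["sex"].unique())
    } if len(table) else {}
    report = {
        "table": table,
        "counts": counts,
        "n_input": len(records),
        "n_retained": len(retained),
        "n_flagged": len(flagged),
        "cutoffs": {"under": UNDER_CUTOFF, "over": OVER_CUTOFF},
        "assumed_pal": ASSUMED_PAL,
    }
    return retained, flagged, report
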