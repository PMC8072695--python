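"""Clinical panel classification and the gender-stratified cohort summary.

Two services live here:

* normal/abnormal coding of each clinical outcome against a configurable
  normal-range table (1 = within range, bounds inclusive; 2 = outside);
* a descriptive cohort summary - per-sex medians and interquartile ranges
  for every outcome, with a between-sex comparison that uses Student's
  t-test when the D'Agostino-Pearson test accepts normality in both sex
  groups (alpha = 0.05) and the Mann-Whitney U test otherwise.

Quartiles use linear interpolation (numpy default); the IQR endpoints
depend on that convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import OUTCOME_VARS, SubjectRecord

log = logging.getLogger(__name__)

NORMAL = 1
ABNORMAL = 2

NORMALITY_ALPHA = 0.05


class RangeConfigError(ValueError):
    pass


@dataclass
class NormalRangeTable:
    """Per-(outcome, sex) normal bounds; sex key 'any' applies to both."""

    ranges: dict  # outcome -> sex -> {"lower": float|None, "upper": float|None}

    def bounds(self, outcome: str, sex: str) -> tuple[float, float]:
        per_sex = self.ranges.get(outcome)
        if per_sex is None:
            raise RangeConfigError(f"no normal range configured for {outcome!r}")
        entry = per_sex.get(sex, per_sex.get("any"))
        if entry is None:
            raise RangeConfigError(
                f"no normal range for outcome {outcome!r}, sex {sex!r}"
            )
        lower = entry.get("lower")
        upper = entry.get("upper")
        if lower is None and upper is None:
            raise RangeConfigError(f"{outcome!r}: range entry has no bounds")
        return (
            -np.inf if lower is None else float(lower),
            np.inf if upper is None else float(upper),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NormalRangeTable":
        return cls(yaml.safe_load(Path(path).read_text()))


def default_normal_ranges() -> NormalRangeTable:
    ref = resources.files("nutrigap.data") / "normal_ranges.yaml"
    return NormalRangeTable(yaml.safe_load(ref.read_text()))


def classify_panel(
    panel, sex: str, ranges: NormalRangeTable | None = None
) -> dict[str, int]:
    """Code each outcome 1 (normal, within bounds inclusive) or 2."""
    if ranges is None:
        ranges = default_normal_ranges()
    values = panel.as_dict()
    out = {}
    for outcome in OUTCOME_VARS:
        lo, hi = ranges.bounds(outcome, sex)
        out[outcome] = NORMAL if lo <= values[outcome] <= hi else ABNORMAL
    return out


def _median_iqr(values: np.ndarray) -> tuple[float, float, float]:
    q25, med, q75 = np.percentile(values, [25, 50, 75])
    return float(med), float(q25), float(q75)


def _normal_in_both(a: np.ndarray, b: np.ndarray) -> tuple[bool, str | None]:
    """D'Agostino-Pearson in each group; both must pass at alpha=0.05."""
    for grp, name in ((a, "female"), (b, "male")):
        if np.ptp(grp) == 0:
            return False, f"{name} group constant; normality test inapplicable"
        if len(grp) < 8:
            return False, f"{name} group too small for D'Agostino-Pearson"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = stats.normaltest(grp)
        if p < NORMALITY_ALPHA:
            return False, None
    return True, None


def summarise_cohort(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Gender-stratified descriptive summary of the clinical panel.

    One row per outcome: median and IQR per sex, the test used for the
    between-sex comparison ('t' or 'mannwhitney') and its two-sided p.
    Requires >= 3 subjects per sex with complete panels.
    """
    groups = {}
    for sex in ("female", "male"):
        vals = [r for r in records if r.sex == sex and r.clinical is not None]
        if len(vals) < 3:
            raise ValueError(f"need >= 3 {sex} subjects with complete panels")
        groups[sex] = pd.DataFrame([r.clinical.as_dict() for r in vals])

    rows = []
    for outcome in OUTCOME_VARS:
        f = groups["female"][outcome].to_numpy(float)
        m = groups["male"][outcome].to_numpy(float)
        f_med, f_lo, f_hi = _median_iqr(f)
        m_med, m_lo, m_hi = _median_iqr(m)
        is_normal, note = _normal_in_both(f, m)
        if note:
            log.info("%s: %s; falling back to Mann-Whitney", outcome, note)
        if is_normal:
            test = "t"
            _, p = stats.ttest_ind(f, m)
        else:
            test = "mannwhitney"
            _, p = stats.mannwhitneyu(f, m, alternative="two-sided")
        rows.append({
            "outcome": outcome,
            "female_median": f_med, "female_q25": f_lo, "female_q75": f_hi,
            "male_median": m_med, "male_q25": m_lo, "male_q75": m_hi,
            "test": test, "p_value": float(p),
        })
    return pd.DataFrame(rows)
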