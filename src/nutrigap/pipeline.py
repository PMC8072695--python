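"""End-to-end pipeline: read -> exclude incomplete -> screen -> gaps ->
summary -> ridge CV -> correlation maps, with a reproducible manifest.

Stage-count bookkeeping mirrors a cohort flow of the form
assessed -> complete (clinical panel present) -> retained (screen passed):
assessed = complete + excluded_missing and complete = retained + flagged,
and both identities are asserted on every run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adequacy import ReferenceTable, default_reference_table, gap_table
from .clinical import NormalRangeTable, default_normal_ranges, summarise_cohort
from .cohort import SubjectRecord, read_cohort_csv
from .correlations import correlation_map
from .ridge import (
    DEFAULT_ALPHA_GRID,
    coefficient_table,
    fit_all_outcomes,
    r2_table,
)
from .screen import BMRModel, default_bmr_model, screen_cohort

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    cohort_csv: str = ""
    output_dir: str = "pipeline_out"
    reference_yaml: str | None = None
    bmr_yaml: str | None = None
    ranges_yaml: str | None = None
    energy_unit: str = "MJ"          # unit of the cohort's energy column
    seed: int = 0
    alpha_grid: Sequence[float] = field(
        default_factory=lambda: list(DEFAULT_ALPHA_GRID)
    )
    k_folds: int = 5
    run_screen: bool = True
    run_summary: bool = True
    run_ridge: bool = True
    run_maps: bool = True

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def load_tables(self) -> tuple[ReferenceTable, BMRModel, NormalRangeTable]:
        ref = (ReferenceTable.from_yaml(self.reference_yaml)
               if self.reference_yaml else default_reference_table())
        bmr = (BMRModel.from_yaml(self.bmr_yaml)
               if self.bmr_yaml else default_bmr_model())
        ranges = (NormalRangeTable.from_yaml(self.ranges_yaml)
                  if self.ranges_yaml else default_normal_ranges())
        return ref, bmr, ranges


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(
        dataclasses.asdict(config), sort_keys=True, default=str
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; write outputs and manifest to output_dir.

    Returns the manifest dict (also written as manifest.json).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref_table, bmr_model, ranges = config.load_tables()

    records = read_cohort_csv(
        config.cohort_csv, energy_unit=config.energy_unit
    )
    n_assessed = len(records)

    complete = [r for r in records if r.clinical is not None]
    excluded = [r for r in records if r.clinical is None]
    for r in excluded:
        log.debug("excluded (missing clinical data): subject %s", r.id)
    n_complete = len(complete)

    if config.run_screen:
        retained, flagged, screen_report = screen_cohort(complete, bmr_model)
        screen_report["table"].to_csv(
            out / "screening_report.csv", index=False, float_format="%.10g"
        )
        (out / "screening_summary.json").write_text(json.dumps(
            {k: v for k, v in screen_report.items() if k != "table"},
            indent=1,
        ))
    else:
        retained, flagged = complete, []
        screen_report = {"counts": {}, "n_flagged": 0}

    assert n_assessed == n_complete + len(excluded)
    assert n_complete == len(retained) + len(flagged)

    gaps = gap_table(retained, ref_table)
    gaps.to_csv(out / "gap_table.csv", float_format="%.10g")

    if config.run_summary:
        summary = summarise_cohort(retained)
        summary.to_csv(out / "cohort_summary.csv", index=False,
                       float_format="%.10g")

    if config.run_ridge:
        results = fit_all_outcomes(
            retained, ref_table, alpha_grid=config.alpha_grid,
            k=config.k_folds, seed=config.seed,
        )
        r2_table(results).to_csv(out / "r2_table.csv", index=False,
                                 float_format="%.10g")
        coefficient_table(results).to_csv(
            out / "coefficients.csv", index=False, float_format="%.10g"
        )

    if config.run_maps:
        for sex in ("female", "male"):
            if any(r.sex == sex for r in retained):
                cm = correlation_map(retained, sex, ref_table)
                cm.to_csv(out / f"correlation_map_{sex}.csv")

    n_retained = len(retained)
    n_f = sum(r.sex == "female" for r in retained)
    n_m = sum(r.sex == "male" for r in retained)
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "nutrigap": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "counts": {
            "assessed": n_assessed,
            "excluded_missing_clinical": len(excluded),
            "complete": n_complete,
            "flagged_misreporters": len(flagged),
            "retained": n_retained,
            "retained_female": n_f,
            "retained_male": n_m,
            "retained_female_pct": round(100.0 * n_f / n_retained, 1)
            if n_retained else float("nan"),
            "retained_male_pct": round(100.0 * n_m / n_retained, 1)
            if n_retained else float("nan"),
        },
        "flagged_by_sex": screen_report.get("counts", {}),
        "stages_run": {
            "screen": config.run_screen, "summary": config.run_summary,
            "ridge": config.run_ridge, "maps": config.run_maps,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
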