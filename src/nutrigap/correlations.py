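"""Spearman rank-correlation maps between intake gaps and clinical outcomes.

The map is a 10 x 11 matrix (rows = intake deltas, columns = clinical
outcomes) per gender, suitable for heatmap rendering. Spearman's rho is
the Pearson correlation of mid-ranks (ties get the average of the ranks
they span); a constant vector has no rank ordering, so its cells are NaN
- an explicit not-a-value marker, never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .adequacy import ReferenceTable, default_reference_table, gap_table
from .cohort import OUTCOME_VARS, SubjectRecord


def spearman_rho(a: Sequence[float], b: Sequence[float]) -> float:
    """Spearman rank correlation with mid-rank tie handling.

    Returns NaN when either vector is constant (rho undefined).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if len(a) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


@dataclass
class CorrelationMap:
    """Gap x outcome Spearman matrix for one gender."""

    rho: pd.DataFrame       # index = gap names, columns = outcomes
    gender: str
    n: int

    def to_csv(self, path: str | Path) -> None:
        self.rho.to_csv(path, float_format="%.10g")

    def undefined_cells(self) -> list[tuple[str, str]]:
        mask = self.rho.isna()
        return [
            (i, c) for i in self.rho.index for c in self.rho.columns
            if mask.loc[i, c]
        ]


def correlation_map(
    records: Sequence[SubjectRecord],
    gender: str,
    table: ReferenceTable | None = None,
) -> CorrelationMap:
    """Spearman map over one gender's retained subjects."""
    if table is None:
        table = default_reference_table()
    group = [r for r in records if r.sex == gender and r.clinical is not None]
    if len(group) < 3:
        raise ValueError(f"need >= 3 {gender} records, have {len(group)}")
    gaps = gap_table(group, table)
    outcomes = pd.DataFrame(
        [r.clinical.as_dict() for r in group], columns=list(OUTCOME_VARS)
    )
    rho = pd.DataFrame(
        index=gaps.columns, columns=outcomes.columns, dtype=float
    )
    for g in gaps.columns:
        for o in outcomes.columns:
            rho.loc[g, o] = spearman_rho(
                gaps[g].to_numpy(), outcomes[o].to_numpy()
            )
    return CorrelationMap(rho=rho, gender=gender, n=len(group))


def render_heatmap(cmap: CorrelationMap, path: str | Path) -> None:
    """Optional PNG/SVG rendering; the CSV matrix is the contract."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7.5, 6))
    im = ax.imshow(
        cmap.rho.to_numpy(float), vmin=-1, vmax=1, cmap="RdBu_r", aspect="auto"
    )
    ax.set_xticks(range(len(cmap.rho.columns)), cmap.rho.columns,
                  rotation=45, ha="right")
    ax.set_yticks(range(len(cmap.rho.index)), cmap.rho.index)
    ax.set_title(f"Spearman rho, intake gaps vs clinical panel ({cmap.gender}, n={cmap.n})")
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
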