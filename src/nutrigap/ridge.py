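"""Closed-form ridge regression with centre-stratified cross-validation.

The model minimises

    sum_i (y_i - b0 - sum_j b_j x_ij)^2  +  alpha * sum_j b_j^2

over the ten intake-gap predictors, separately per clinical outcome and
per gender. Predictors are standardised (mean 0, sd 1) and the outcome
centred on the training data only, which leaves the intercept b0
unpenalised and equal to the training mean of y; the coefficients then
solve the normal equations (X'X + alpha I) b = X'y in closed form.

The penalty alpha is tuned by k-fold cross-validation whose folds
preserve the proportion of subjects from each recruiting centre, so
country-of-origin dietary habits cannot act as a train/test confounder.
The headline per-fold score is the squared Pearson correlation between
held-out predictions and observations ("Pearson coefficient of
determination"); the 1 - SSE/SST form is computed alongside, and the two
differ on test folds. Fold-level scores are averaged arithmetically and
ties on alpha are broken towards more shrinkage (the largest alpha).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .adequacy import ReferenceTable, default_reference_table, gap_table
from .cohort import INTAKE_VARS, OUTCOME_VARS, SubjectRecord

log = logging.getLogger(__name__)

#: 13 log-spaced penalties from 1e-3 (near-OLS) to 1e3 (heavy shrinkage).
DEFAULT_ALPHA_GRID = tuple(np.logspace(-3.0, 3.0, 13))


class ZeroVarianceError(ValueError):
    pass


class SingularSystemError(np.linalg.LinAlgError):
    pass


@dataclass(frozen=True)
class Scaler:
    """Column means/sds of training X and mean of training y."""

    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    column_names: tuple[str, ...] = ()

    def apply(self, X: np.ndarray, y: np.ndarray | None = None):
        Xs = (np.asarray(X, float) - self.x_mean) / self.x_sd
        if y is None:
            return Xs
        return Xs, np.asarray(y, float) - self.y_mean


def standard_scale_fit(
    X: np.ndarray, y: np.ndarray, column_names: Sequence[str] = ()
) -> Scaler:
    """Fit a standard scaler on training data only (no leakage)."""
    X = np.asarray(X, float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd; any positive scale works identically
    degenerate = sd <= 1e-12 * (1.0 + np.abs(mean))
    if np.any(degenerate):
        names = list(column_names) or [f"x{j}" for j in range(X.shape[1])]
        bad = [names[j] for j in np.flatnonzero(degenerate)]
        raise ZeroVarianceError(
            f"zero-variance column(s) cannot be standardised: {', '.join(bad)}"
        )
    return Scaler(mean, sd, float(np.mean(y)), tuple(column_names))


def ridge_solve(Xs: np.ndarray, ys: np.ndarray, alpha: float) -> np.ndarray:
    """Penalised coefficients on standardised data: (X'X + aI)^-1 X'y."""
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    Xs = np.asarray(Xs, float)
    ys = np.asarray(ys, float)
    p = Xs.shape[1]
    A = Xs.T @ Xs + alpha * np.eye(p)
    if alpha == 0 and np.linalg.matrix_rank(Xs) < p:
        raise SingularSystemError(
            "design is rank-deficient at alpha=0 (collinear columns); "
            "use alpha > 0"
        )
    return np.linalg.solve(A, Xs.T @ ys)


@dataclass(frozen=True)
class RidgeFit:
    """A fitted ridge model: penalty, intercept, standardised-scale betas."""

    alpha: float
    beta0: float              # training mean of y (unpenalised intercept)
    beta: np.ndarray          # per-sd-of-x coefficients
    scaler: Scaler

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.beta0 + self.scaler.apply(X) @ self.beta

    @property
    def column_names(self) -> tuple[str, ...]:
        return self.scaler.column_names

    def ranking(self) -> list[str]:
        """Variables ordered by decreasing |beta| (standardised scale)."""
        names = self.column_names or tuple(
            f"x{j}" for j in range(len(self.beta))
        )
        order = np.argsort(-np.abs(self.beta), kind="stable")
        return [names[j] for j in order]


def fit_ridge(
    X: np.ndarray, y: np.ndarray, alpha: float,
    column_names: Sequence[str] = (),
) -> RidgeFit:
    """Standardise on (X, y) then solve; the one-stop full-data fit."""
    scaler = standard_scale_fit(X, y, column_names)
    Xs, ys = scaler.apply(X, y)
    beta = ridge_solve(Xs, ys, alpha)
    return RidgeFit(alpha=float(alpha), beta0=scaler.y_mean, beta=beta,
                    scaler=scaler)


def stratified_folds(
    centre_labels: Sequence[str], k: int = 5, seed=0
) -> np.ndarray:
    """Assign subjects to k CV folds preserving centre proportions.

    Within each centre the (shuffled) subjects are dealt round-robin, with
    the deal position carried across centres so overall fold sizes also
    balance; per-centre fold counts differ by at most one. Deterministic
    for a given seed.
    """
    labels = np.asarray(centre_labels)
    n = len(labels)
    if k > n:
        raise ValueError(f"k={k} folds exceed n={n} subjects")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    cursor = 0
    for centre in sorted(pd.unique(labels)):
        idx = np.flatnonzero(labels == centre)
        idx = rng.permutation(idx)
        for i, subject in enumerate(idx):
            folds[subject] = (cursor + i) % k
        cursor += len(idx)
    return folds


def _pearson_r2(pred: np.ndarray, obs: np.ndarray) -> float:
    """Squared Pearson correlation; 0 when the prediction is constant."""
    if np.std(pred) == 0 or np.std(obs) == 0:
        return 0.0
    return float(np.corrcoef(pred, obs)[0, 1] ** 2)


def _cod_r2(pred: np.ndarray, obs: np.ndarray) -> float:
    """1 - SSE/SST on the held-out fold; can be negative, never clipped."""
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        return float("nan")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / sst


@dataclass
class DesignMatrix:
    """One outcome's regression problem: gaps, outcome, centre labels."""

    X: np.ndarray
    y: np.ndarray
    centre_labels: np.ndarray
    column_names: tuple[str, ...]
    outcome_name: str = ""

    def __post_init__(self):
        self.X = np.asarray(self.X, float)
        self.y = np.asarray(self.y, float)
        self.centre_labels = np.asarray(self.centre_labels)
        n = self.X.shape[0]
        if not (len(self.y) == len(self.centre_labels) == n):
            raise ValueError("X, y and centre_labels are not aligned")
        if not (np.isfinite(self.X).all() and np.isfinite(self.y).all()):
            raise ValueError(
                f"design for {self.outcome_name or 'outcome'} has missing entries"
            )


@dataclass
class CVReport:
    """Cross-validation result for one outcome (one gender)."""

    outcome_name: str
    alpha_grid: tuple[float, ...]
    folds: np.ndarray                    # fold id per subject
    mean_r2_by_alpha: np.ndarray         # mean Pearson R^2 per grid alpha
    alpha_selected: float
    fold_r2: np.ndarray                  # per-fold Pearson R^2 at alpha_selected
    fold_r2_cod: np.ndarray              # per-fold 1 - SSE/SST at alpha_selected
    fit: RidgeFit                        # full-data refit at alpha_selected
    sex: str = ""
    fold_test_indices: list = field(default_factory=list)

    @property
    def r2_mean(self) -> float:
        return float(np.mean(self.fold_r2))

    @property
    def r2_cod_mean(self) -> float:
        return float(np.mean(self.fold_r2_cod))

    @property
    def coefficient_ranking(self) -> list[str]:
        return self.fit.ranking()


def cross_validate(
    dm: DesignMatrix,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    k: int = 5,
    seed=0,
    folds: np.ndarray | None = None,
) -> CVReport:
    """Tune alpha by centre-stratified k-fold CV and refit on all data.

    Each fold's scaler and coefficients are fitted on its training split
    only. The selected alpha maximises the fold-averaged squared Pearson
    correlation between held-out predictions and observations; ties go to
    the largest alpha.
    """
    alphas = np.asarray(sorted(alpha_grid), float)
    if alphas.size == 0 or np.any(alphas < 0):
        raise ValueError("alpha_grid must be non-empty with alphas >= 0")
    if folds is None:
        folds = stratified_folds(dm.centre_labels, k=k, seed=seed)
    folds = np.asarray(folds)
    fold_ids = np.unique(folds)
    test_indices = [np.flatnonzero(folds == f) for f in fold_ids]
    for f, idx in zip(fold_ids, test_indices):
        if len(idx) < 3:
            raise ValueError(
                f"fold {f} has {len(idx)} test subjects; R^2 undefined (< 3)"
            )

    r2 = np.empty((len(alphas), len(fold_ids)))
    r2_cod = np.empty_like(r2)
    for j, idx in enumerate(test_indices):
        train = np.setdiff1d(np.arange(len(dm.y)), idx)
        scaler = standard_scale_fit(dm.X[train], dm.y[train], dm.column_names)
        Xs_tr, ys_tr = scaler.apply(dm.X[train], dm.y[train])
        Xs_te = scaler.apply(dm.X[idx])
        G = Xs_tr.T @ Xs_tr
        Xty = Xs_tr.T @ ys_tr
        for i, a in enumerate(alphas):
            beta = np.linalg.solve(G + a * np.eye(G.shape[0]), Xty)
            pred = scaler.y_mean + Xs_te @ beta
            r2[i, j] = _pearson_r2(pred, dm.y[idx])
            r2_cod[i, j] = _cod_r2(pred, dm.y[idx])

    mean_by_alpha = r2.mean(axis=1)
    best = np.max(mean_by_alpha)
    # largest alpha among ties (alphas ascending)
    i_sel = int(np.flatnonzero(mean_by_alpha >= best - 1e-12)[-1])
    alpha_sel = float(alphas[i_sel])
    final = fit_ridge(dm.X, dm.y, alpha_sel, dm.column_names)
    return CVReport(
        outcome_name=dm.outcome_name,
        alpha_grid=tuple(alphas),
        folds=folds,
        mean_r2_by_alpha=mean_by_alpha,
        alpha_selected=alpha_sel,
        fold_r2=r2[i_sel],
        fold_r2_cod=r2_cod[i_sel],
        fit=final,
        fold_test_indices=test_indices,
    )


def design_matrices(
    records: Sequence[SubjectRecord],
    table: ReferenceTable | None = None,
) -> dict[str, DesignMatrix]:
    """Build the per-outcome design (gap features) for one record set."""
    if table is None:
        table = default_reference_table()
    gaps = gap_table(records, table)
    X = gaps.to_numpy(float)
    centres = np.array([r.centre for r in records])
    out = {}
    for outcome in OUTCOME_VARS:
        y = np.array([getattr(r.clinical, outcome) for r in records], float)
        out[outcome] = DesignMatrix(
            X=X, y=y, centre_labels=centres,
            column_names=tuple(gaps.columns), outcome_name=outcome,
        )
    return out


def fit_all_outcomes(
    records: Sequence[SubjectRecord],
    table: ReferenceTable | None = None,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    k: int = 5,
    seed: int = 0,
) -> dict[str, dict[str, CVReport]]:
    """Per-gender, per-outcome cross-validated ridge fits (11 x 2 models).

    Records must already be screened (misreporters removed) and have
    complete clinical panels. Within a gender the same stratified fold
    assignment is reused for every outcome (one draw per gender per seed).
    """
    results: dict[str, dict[str, CVReport]] = {}
    for gi, sex in enumerate(("female", "male")):
        group = [r for r in records if r.sex == sex]
        if not group:
            continue
        p = len(INTAKE_VARS)
        if len(group) < 6 * p:
            log.warning(
                "%s group has n=%d < %d subjects; fits proceed but are unstable",
                sex, len(group), 6 * p,
            )
        dms = design_matrices(group, table)
        folds = stratified_folds(
            [r.centre for r in group], k=k, seed=(seed, gi)
        )
        results[sex] = {}
        for outcome, dm in dms.items():
            rep = cross_validate(dm, alpha_grid, k=k, folds=folds)
            rep.sex = sex
            results[sex][outcome] = rep
    return results


def r2_table(results: Mapping[str, Mapping[str, CVReport]]) -> pd.DataFrame:
    """Fold-averaged R^2 per outcome x gender (the headline table)."""
    rows = []
    for outcome in OUTCOME_VARS:
        row = {"outcome": outcome}
        for sex in ("female", "male"):
            rep = results.get(sex, {}).get(outcome)
            if rep is not None:
                row[f"{sex}_r2"] = rep.r2_mean
                row[f"{sex}_r2_cod"] = rep.r2_cod_mean
                row[f"{sex}_alpha"] = rep.alpha_selected
        rows.append(row)
    return pd.DataFrame(rows)


def coefficient_table(results: Mapping[str, Mapping[str, CVReport]]) -> pd.DataFrame:
    """Standardised-scale coefficients with |beta| ranks, long format."""
    rows = []
    for sex, per_outcome in results.items():
        for outcome, rep in per_outcome.items():
            order = np.argsort(-np.abs(rep.fit.beta), kind="stable")
            rank_of = {int(j): r + 1 for r, j in enumerate(order)}
            for j, name in enumerate(rep.fit.column_names):
                rows.append({
                    "outcome": outcome, "sex": sex, "variable": name,
                    "beta_standardised": float(rep.fit.beta[j]),
                    "abs_beta_rank": rank_of[j],
                    "alpha_selected": rep.alpha_selected,
                })
    return pd.DataFrame(rows)


def lasso_solve(
    Xs: np.ndarray, ys: np.ndarray, alpha: float,
    max_iter: int = 10_000, tol: float = 1e-10,
) -> np.ndarray:
    """L1-penalised baseline via coordinate descent (optional, not headline).

    Minimises ||ys - Xs b||^2 + alpha * sum |b_j| on standardised data.
    """
    Xs = np.asarray(Xs, float)
    ys = np.asarray(ys, float)
    n, p = Xs.shape
    beta = np.zeros(p)
    col_ss = (Xs ** 2).sum(axis=0)
    resid = ys.copy()
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            old = beta[j]
            rho = Xs[:, j] @ resid + col_ss[j] * old
            new = np.sign(rho) * max(abs(rho) - alpha / 2.0, 0.0) / col_ss[j]
            if new != old:
                resid += Xs[:, j] * (old - new)
                beta[j] = new
                delta = max(delta, abs(new - old))
        if delta < tol:
            break
    return beta
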