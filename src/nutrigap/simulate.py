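"""Synthetic cohort generator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage (screen, gap engine, summary, ridge CV, maps) is
testable without the unavailable trial data:

* two genders x four recruiting centres, centre proportions held within
  one subject of target;
* gap-first generation: the ten intake deltas are drawn from a
  multivariate normal whose covariance embeds a strongly correlated "fat
  block" (total fat / SFA / UFA / PUFA pairwise r = 0.7; all other pairs
  r = 0.1) - the multicollinearity that motivates ridge penalisation -
  and raw intakes are reconstructed as gap + recommended value, so the
  planted regression coefficients act on exactly the features the model
  sees;
* each clinical outcome is linear in the gaps with per-sex planted
  coefficients plus Gaussian noise. Default intercepts, spreads and
  noise levels are tied to the modelled study population's per-sex medians,
  IQR-implied scales, and target fold-averaged R^2 via
  R^2 = var(x.beta) / (var(x.beta) + sigma^2);
* a configurable fraction of subjects (scalar, or per-sex mapping) have
  reported energy rescaled to an EI:BMR ratio well below 0.901 or above
  2.841, so the misreporting screen has a knowable answer key;
* a single global seed governs everything; each subject consumes an
  independent counter-derived stream, so enlarging the cohort never
  reshuffles earlier subjects.

Reconstructed raw intakes are floored at zero (a Gaussian tail can dip
below a small recommendation, alcohol especially) and the subject's gap
recomputed, keeping features and stored outcomes exactly consistent.
Body weight is solved self-consistently: BMI is a modelled outcome,
weight = BMI x height^2 feeds the protein recommendation, which feeds
the protein gap, which feeds BMI - a contraction iterated to a fixed
point.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import screen as screen_mod
from .adequacy import ReferenceTable, default_reference_table
from .cohort import (
    INTAKE_VARS,
    OUTCOME_VARS,
    ClinicalPanel,
    SubjectRecord,
    records_to_frame,
    write_cohort_csv,
)

DEFAULT_CENTRES = {
    "bologna": 0.25, "clermont": 0.25, "karlsruhe": 0.25, "leeds": 0.25,
}

#: Per-gap standard deviations, native units (MJ/day, %EI, g/day, serv/day).
DEFAULT_GAP_SD = np.array(
    [1.3, 7.0, 4.0, 6.0, 3.0, 4.0, 2.0, 20.0, 7.0, 0.25]
)

#: Mean gaps of an at-risk cohort: energy surplus, fat/SFA/sugar excess,
#: UFA/PUFA and fibre shortfall, modest protein surplus, alcohol below limit.
DEFAULT_GAP_MEAN = np.array(
    [1.0, -5.0, 3.0, 5.0, 3.0, -2.0, -2.0, 10.0, -7.0, -0.5]
)

_FAT_BLOCK = ("fat", "sfa", "ufa", "pufa")


def default_gap_correlation() -> np.ndarray:
    """r = 0.7 within the fat block, r = 0.1 everywhere else."""
    p = len(INTAKE_VARS)
    R = np.full((p, p), 0.1)
    for a in _FAT_BLOCK:
        for b in _FAT_BLOCK:
            R[INTAKE_VARS.index(a), INTAKE_VARS.index(b)] = 0.7
    np.fill_diagonal(R, 1.0)
    return R


def default_gap_cov() -> np.ndarray:
    D = np.diag(DEFAULT_GAP_SD)
    return D @ default_gap_correlation() @ D


# Per-sex cohort anchors for the modelled at-risk population:
# outcome -> (median, q25, q75, target fold-averaged R^2).
_OUTCOME_ANCHORS = {
    "female": {
        "bmi": (31.6, 27.5, 35.5, 0.43),
        "wc": (100.5, 93.0, 111.0, 0.39),
        "tg": (160.5, 125.1, 192.6, 0.46),
        "total_chol": (232.6, 201.4, 254.2, 0.35),
        "hdl_c": (48.2, 41.7, 56.6, 0.44),
        "ldl_c": (164.5, 138.0, 180.7, 0.42),
        "glucose": (96.1, 87.4, 100.8, 0.33),
        "insulin": (12.4, 7.9, 18.4, 0.26),
        "hba1c": (5.6, 5.3, 5.8, 0.27),
        "sbp": (130.0, 120.0, 145.0, 0.36),
        "dbp": (81.0, 76.0, 89.0, 0.27),
    },
    "male": {
        "bmi": (29.0, 26.1, 33.0, 0.78),
        "wc": (104.5, 99.0, 113.5, 0.79),
        "tg": (188.9, 153.1, 239.1, 0.22),
        "total_chol": (202.7, 188.6, 230.1, 0.25),
        "hdl_c": (39.2, 35.2, 42.6, 0.34),
        "ldl_c": (136.0, 112.2, 154.8, 0.22),
        "glucose": (97.0, 89.2, 102.6, 0.44),
        "insulin": (12.9, 9.7, 18.5, 0.49),
        "hba1c": (5.3, 5.1, 5.6, 0.52),
        "sbp": (130.0, 125.0, 141.5, 0.52),
        "dbp": (85.0, 80.0, 91.0, 0.40),
    },
}

# Standardised-space coefficient directions (INTAKE_VARS order). A diffuse
# pattern stands in where no single nutrient dominates the narrative.
_DIFFUSE = [0.3, 0.2, 0.2, 0.3, 0.3, -0.2, -0.3, -0.3, -0.3, 0.1]
_DIRECTIONS = {
    "female": {
        "bmi": [0.6, 0.1, 0.1, 0.2, 0.4, -0.1, -0.1, -0.1, -0.2, 0.1],
        "wc": _DIFFUSE,
        "tg": [0.3, 0.1, 0.2, 0.1, 0.2, -0.1, -0.6, -0.1, -0.6, 0.1],
        "total_chol": _DIFFUSE,
        "hdl_c": [-0.5, -0.5, -0.2, -0.2, -0.5, 0.1, 0.2, 0.1, 0.2, -0.1],
        "ldl_c": [0.2, 0.55, 0.1, 0.55, 0.3, -0.1, -0.5, -0.1, -0.2, 0.1],
        "glucose": _DIFFUSE,
        "insulin": _DIFFUSE,
        "hba1c": _DIFFUSE,
        "sbp": _DIFFUSE,
        "dbp": _DIFFUSE,
    },
    "male": {
        "bmi": [0.65, 0.05, 0.05, 0.35, 0.35, -0.05, -0.1, -0.35, -0.1, 0.05],
        "wc": [0.4, 0.05, 0.05, 0.2, 0.6, -0.05, -0.1, -0.4, -0.1, 0.05],
        "tg": _DIFFUSE,
        "total_chol": _DIFFUSE,
        "hdl_c": _DIFFUSE,
        "ldl_c": _DIFFUSE,
        "glucose": [0.2, 0.1, 0.1, 0.5, 0.5, -0.1, -0.2, -0.1, -0.2, 0.1],
        "insulin": _DIFFUSE,
        "hba1c": _DIFFUSE,
        "sbp": [0.2, 0.1, 0.1, 0.55, 0.3, -0.1, -0.55, -0.1, -0.1, 0.1],
        "dbp": _DIFFUSE,
    },
}

# Per-sex misreporter rates observed in the modelled cohort (17/94, 41/121).
DEFAULT_MISREPORTER_FRACTION = {"female": 17 / 94, "male": 41 / 121}

_HEIGHT = {"female": (162.0, 6.0), "male": (175.0, 7.0)}

# Injected EI:BMR targets, kept >= ~0.05 beyond the screen cutoffs.
_UNDER_RATIO_RANGE = (0.55, 0.85)
_OVER_RATIO_RANGE = (2.95, 3.40)


class GeneratorConfigError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


def calibrate_noise(beta: np.ndarray, gap_cov: np.ndarray, r2: float) -> float:
    """Noise sd giving target R^2 = var(x.b) / (var(x.b) + sigma^2)."""
    if not 0 < r2 < 1:
        raise ValueError("target R^2 must be in (0, 1)")
    signal_var = float(beta @ gap_cov @ beta)
    return float(np.sqrt(signal_var * (1 - r2) / r2))


def beta_from_pattern(
    pattern: Sequence[float],
    r2: float,
    sigma_y: float,
    gap_sd: np.ndarray = DEFAULT_GAP_SD,
    corr: np.ndarray | None = None,
) -> np.ndarray:
    """Native-unit coefficients from a standardised direction pattern.

    Scaled so the linear predictor's sd is sigma_y * sqrt(r2); combined
    with noise sd sigma_y * sqrt(1 - r2) the outcome has total sd sigma_y
    and population R^2 = r2.
    """
    if corr is None:
        corr = default_gap_correlation()
    d = np.asarray(pattern, float)
    scale = np.sqrt(r2) * sigma_y / np.sqrt(d @ corr @ d)
    return scale * d / np.asarray(gap_sd, float)


@dataclass
class GeneratorConfig:
    """Everything the generator needs, with study-condition defaults."""

    # defaults are the complete (pre-screen) cohort; with the default
    # per-sex misreporter rates the screen retains 77 women and 80 men
    n_female: int = 94
    n_male: int = 121
    centres: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CENTRES)
    )
    seed: int = 0
    gap_mean: np.ndarray = field(
        default_factory=lambda: DEFAULT_GAP_MEAN.copy()
    )
    gap_cov: np.ndarray = field(default_factory=default_gap_cov)
    true_beta: dict = field(default_factory=dict)   # sex -> outcome -> (10,)
    intercept: dict = field(default_factory=dict)   # sex -> outcome -> float
    noise_sd: dict = field(default_factory=dict)    # sex -> outcome -> float
    misreporter_fraction: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISREPORTER_FRACTION)
    )
    under_over_split: float = 0.8   # fraction of injected misreporters under

    def __post_init__(self):
        self.gap_mean = np.asarray(self.gap_mean, float)
        self.gap_cov = np.asarray(self.gap_cov, float)
        self._check_cov()
        if not self.true_beta:
            self._fill_default_signal()
        self.validate()

    def _check_cov(self):
        p = len(INTAKE_VARS)
        if self.gap_mean.shape != (p,) or self.gap_cov.shape != (p, p):
            raise GeneratorConfigError("gap_mean/gap_cov have wrong shape")
        if not np.allclose(self.gap_cov, self.gap_cov.T):
            raise GeneratorConfigError("gap_cov must be symmetric")
        if np.min(np.linalg.eigvalsh(self.gap_cov)) < -1e-8:
            raise GeneratorConfigError(
                "gap_cov must be positive semi-definite"
            )

    def _fill_default_signal(self):
        corr = default_gap_correlation()
        sds = np.sqrt(np.diag(self.gap_cov))
        for sex in ("female", "male"):
            self.true_beta[sex] = {}
            self.intercept[sex] = {}
            self.noise_sd[sex] = {}
            for outcome in OUTCOME_VARS:
                med, q25, q75, r2 = _OUTCOME_ANCHORS[sex][outcome]
                sigma_y = (q75 - q25) / 1.349  # normal-equivalent scale
                beta = beta_from_pattern(
                    _DIRECTIONS[sex][outcome], r2, sigma_y, sds, corr
                )
                self.true_beta[sex][outcome] = beta
                self.intercept[sex][outcome] = float(
                    med - self.gap_mean @ beta
                )
                self.noise_sd[sex][outcome] = float(
                    sigma_y * np.sqrt(1 - r2)
                )

    def misreporter_fraction_for(self, sex: str) -> float:
        if isinstance(self.misreporter_fraction, Mapping):
            return float(self.misreporter_fraction[sex])
        return float(self.misreporter_fraction)

    def validate(self):
        self._check_cov()
        if self.n_female < 10 or self.n_male < 10:
            raise GeneratorConfigError("n_female and n_male must be >= 10")
        if abs(sum(self.centres.values()) - 1.0) > 1e-9:
            raise GeneratorConfigError("centre proportions must sum to 1")
        if not 0.0 <= self.under_over_split <= 1.0:
            raise GeneratorConfigError("under_over_split must be in [0, 1]")
        for sex in ("female", "male"):
            f = self.misreporter_fraction_for(sex)
            if not 0.0 <= f <= 1.0:
                raise GeneratorConfigError(
                    "misreporter_fraction must be in [0, 1]"
                )
        for sex in ("female", "male"):
            for outcome in OUTCOME_VARS:
                if self.noise_sd[sex][outcome] < 0:
                    raise GeneratorConfigError("noise_sd must be >= 0")

    def copy(self) -> "GeneratorConfig":
        return copy.deepcopy(self)


@dataclass
class SyntheticCohort:
    records: list[SubjectRecord]
    truth: GeneratorConfig
    misreporter_ids: set[str]
    gaps: pd.DataFrame          # final per-subject gap vectors (answer key)

    def frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def allocate_centres(n: int, centres: Mapping[str, float]) -> list[str]:
    """Deterministic quota allocation; every prefix stays near-proportional."""
    labels = sorted(centres)
    assigned = {c: 0 for c in labels}
    out = []
    for i in range(n):
        # centre with the largest unmet quota after i+1 subjects
        c = max(labels, key=lambda c: (centres[c] * (i + 1) - assigned[c], c))
        assigned[c] += 1
        out.append(c)
    return out


def _matrix_sqrt(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(cov)
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def generate_cohort(
    config: GeneratorConfig,
    table: ReferenceTable | None = None,
    bmr_model: screen_mod.BMRModel | None = None,
) -> SyntheticCohort:
    """Draw a full synthetic cohort; reproducible given config.seed."""
    if table is None:
        table = default_reference_table()
    if bmr_model is None:
        bmr_model = screen_mod.default_bmr_model()
    L = _matrix_sqrt(config.gap_cov)
    n_total = config.n_female + config.n_male
    centre_seq = allocate_centres(n_total, config.centres)

    sexes = ["female"] * config.n_female + ["male"] * config.n_male
    records: list[SubjectRecord] = []
    gap_rows = []
    p = len(INTAKE_VARS)
    i_prot = INTAKE_VARS.index("protein")
    i_bmi = OUTCOME_VARS.index("bmi")

    for i, sex in enumerate(sexes):
        rng = np.random.default_rng([config.seed, i])
        age = float(rng.integers(23, 78))
        h_mean, h_sd = _HEIGHT[sex]
        height = float(rng.normal(h_mean, h_sd))
        gap = config.gap_mean + L @ rng.standard_normal(p)
        noise = rng.standard_normal(len(OUTCOME_VARS))

        beta = config.true_beta[sex]
        b0 = config.intercept[sex]
        sd = config.noise_sd[sex]
        betas = np.array([beta[o] for o in OUTCOME_VARS])
        eps = np.array([sd[o] * noise[j] for j, o in enumerate(OUTCOME_VARS)])
        b0v = np.array([b0[o] for o in OUTCOME_VARS])

        # recommendations that do not depend on weight
        rec = np.array([
            table.entry(v, sex).recommendation_per_unit()
            if not table.entry(v, sex).per_kg else np.nan
            for v in INTAKE_VARS
        ])
        prot_per_kg = table.entry("protein", sex).recommendation_per_unit()

        # floor weight-independent raw intakes at zero, keep gaps consistent
        g = gap.copy()
        for j, v in enumerate(INTAKE_VARS):
            if j != i_prot:
                g[j] = max(gap[j] + rec[j], 0.0) - rec[j]

        # weight <-> protein-gap fixed point: BMI is a modelled outcome,
        # weight = BMI * height^2 feeds the protein recommendation, which
        # feeds the protein gap, which feeds BMI. The map is a contraction
        # (|beta_protein| * 0.745 * height^2 << 1), so iterate.
        hm2 = (height / 100.0) ** 2
        weight = (b0v[i_bmi] + betas[i_bmi] @ g + eps[i_bmi]) * hm2
        raw_prot = 0.0
        for _ in range(100):
            rec_prot = prot_per_kg * weight
            raw_prot = max(gap[i_prot] + rec_prot, 0.0)
            g[i_prot] = raw_prot - rec_prot
            bmi = b0v[i_bmi] + betas[i_bmi] @ g + eps[i_bmi]
            w_new = bmi * hm2
            if abs(w_new - weight) < 1e-12 * max(1.0, abs(weight)):
                weight = w_new
                break
            weight = w_new
        else:
            raise GenerationError(
                f"subject index {i}: weight fixed point did not converge"
            )
        if weight <= 0:
            raise GenerationError(
                f"subject index {i} ({sex}): non-positive body weight "
                f"{weight:.2f} kg from modelled BMI"
            )

        y = b0v + betas @ g + eps
        panel = ClinicalPanel(**{o: float(y[j]) for j, o in enumerate(OUTCOME_VARS)})
        raw = g + rec
        raw[i_prot] = raw_prot
        intakes = {v: float(raw[j]) for j, v in enumerate(INTAKE_VARS)}
        gap = g
        sid = f"{'F' if sex == 'female' else 'M'}{i:04d}"
        records.append(SubjectRecord(
            id=sid, sex=sex, age=age, weight=float(weight),
            height=float(height), centre=centre_seq[i], clinical=panel,
            **intakes,
        ))
        gap_rows.append(gap)

    records, misreporter_ids = _inject_misreporters(records, config, bmr_model)
    # energy gap of rescaled subjects changes with their reported energy
    gaps = pd.DataFrame(
        gap_rows, columns=[f"d_{v}" for v in INTAKE_VARS],
        index=pd.Index([r.id for r in records], name="id"),
    )
    i_energy = INTAKE_VARS.index("energy")
    for j, r in enumerate(records):
        if r.id in misreporter_ids:
            rec_e = table.entry("energy", r.sex).recommendation_per_unit()
            gaps.iloc[j, i_energy] = r.energy - rec_e
    return SyntheticCohort(
        records=records, truth=config, misreporter_ids=misreporter_ids,
        gaps=gaps,
    )


def _inject_misreporters(
    records: list[SubjectRecord],
    config: GeneratorConfig,
    bmr_model: screen_mod.BMRModel,
) -> tuple[list[SubjectRecord], set[str]]:
    """Rescale reported energy only; %EI composition is left untouched."""
    misreporter_ids: set[str] = set()
    out = list(records)
    for si, sex in enumerate(("female", "male")):
        idx = [i for i, r in enumerate(records) if r.sex == sex]
        k = int(round(config.misreporter_fraction_for(sex) * len(idx)))
        if k == 0:
            continue
        sel_rng = np.random.default_rng([config.seed, 2_000_000 + si])
        chosen = [idx[j] for j in sel_rng.permutation(len(idx))[:k]]
        n_under = int(round(config.under_over_split * k))
        for rank, i in enumerate(chosen):
            rec = records[i]
            if rec.weight <= 0:
                raise GenerationError(
                    f"subject {rec.id}: cannot rescale energy "
                    f"(non-positive weight {rec.weight})"
                )
            bmr = screen_mod.basal_metabolic_rate(rec, bmr_model)
            rng = np.random.default_rng([config.seed, 1_000_000 + i])
            lo, hi = (_UNDER_RATIO_RANGE if rank < n_under
                      else _OVER_RATIO_RANGE)
            target_ratio = float(rng.uniform(lo, hi))
            out[i] = dataclasses.replace(rec, energy=target_ratio * bmr)
            misreporter_ids.add(rec.id)
    return out, misreporter_ids


def write_cohort(
    cohort: SyntheticCohort, path: str | Path,
    truth_path: str | Path | None = None,
) -> None:
    """Write the cohort CSV (pipeline input schema) and optional truth JSON."""
    write_cohort_csv(cohort.records, path)
    if truth_path is not None:
        cfg = cohort.truth
        payload = {
            "seed": cfg.seed,
            "n_female": cfg.n_female,
            "n_male": cfg.n_male,
            "misreporter_ids": sorted(cohort.misreporter_ids),
            "true_beta": {
                sex: {o: list(map(float, b)) for o, b in per.items()}
                for sex, per in cfg.true_beta.items()
            },
            "intercept": cfg.intercept,
            "noise_sd": cfg.noise_sd,
            "gap_mean": list(map(float, cfg.gap_mean)),
            "gap_sd": list(map(float, np.sqrt(np.diag(cfg.gap_cov)))),
        }
        Path(truth_path).write_text(json.dumps(payload, indent=1))


def blank_clinical(
    frame: pd.DataFrame, n_female: int, n_male: int, seed: int
) -> pd.DataFrame:
    """Blank the clinical panel of randomly chosen subjects, per sex.

    Models participants with dietary data but missing clinical work-up;
    the pipeline excludes them before screening.
    """
    out = frame.copy()
    rng = np.random.default_rng([seed, 3_000_000])
    for sex, n_blank in (("female", n_female), ("male", n_male)):
        rows = out.index[out["sex"] == sex].to_numpy()
        if n_blank > len(rows):
            raise ValueError(f"cannot blank {n_blank} of {len(rows)} {sex} rows")
        take = rng.permutation(len(rows))[:n_blank]
        out.loc[rows[take], list(OUTCOME_VARS)] = np.nan
    return out
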