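# Methods

## The analysis chain

The package estimates how far each subject's diet sits from reference
values and how those deviations predict eleven cardiometabolic outcomes.
Its stages, and the assumptions each makes, are:

**Misreporting screen.** Reported energy intake (EI, MJ/day) is divided by
basal metabolic rate (BMR) predicted from the sex- and age-banded Oxford
(Henry 2005) weight-only equations, shipped as an editable YAML table
(`nutrigap/data/bmr_oxford_weight.yaml`; bands 18–30, 30–60, 60–80 years,
half-open, the oldest band closed at 80). A height-aware table with a
`height_coef` column (per metre) is accepted in the same format. Subjects
with EI:BMR < 0.901 are labelled under-reporters and > 2.841
over-reporters; the inequalities are **strict**, so the boundary values are
plausible — other implementations use ≤, which flips boundary cases. The
cutoffs already fold in a physical activity level of 1.6 and the Goldberg
confidence-bound arithmetic; PAL is therefore recorded in report metadata
but never used in computation, and deriving bounds from first principles
(within-subject CVs, sample size) is out of scope.

**Intake gaps.** Each of ten dietary variables is compared with an adult
reference entry: a two-sided adequate range whose **midpoint** is the
recommendation (energy: 6.8–10.1 MJ/day women, 8.3–12.6 men; carbohydrate
45–60 %EI; fat 20–35 %EI; UFA 15–20 %EI; PUFA 6–11 %EI; protein AR–PRI),
or a one-sided **limit** that is itself the recommendation (sugars
< 10 %EI, SFA < 10 %EI, fibre ≥ 25 g/day, alcohol ≤ 1 serving/day women /
2 men). Protein uses the EFSA adult per-kilogram values AR = 0.66 and
PRI = 0.83 g/kg/day (midpoint 0.745) scaled by the subject's **actual**
body weight; whether reference or actual weight should anchor the
recommendation is genuinely open, and actual weight is the default
(overridable via a custom table). The gap is current − recommended, in
native units; a value inside an adequate range still has a non-zero gap
(distance from the range mean, not a violation flag). No imputation:
missing intakes raise. Energy recommendations use the sex-level aggregate
ranges rather than per-age tables; an age-resolved `ReferenceTable` can be
supplied. The optional grams-to-servings alcohol converter assumes 12 g
ethanol per serving.

**Ridge regression (the core).** Per gender and outcome, with the ten gaps
as predictors: predictors are standardised and the outcome centred on the
*training split only* (leak-free; the intercept equals the training mean
of y and is unpenalised), then β = (XᵀX + αI)⁻¹Xᵀy in closed form. α is
tuned on a 13-point log grid from 1e−3 to 1e3 (spanning near-OLS to heavy
shrinkage for standardised predictors) by 5-fold cross-validation whose
folds preserve recruiting-centre proportions: within each centre subjects
are shuffled and dealt round-robin, the deal position carried across
centres, so per-centre and total fold sizes both differ by at most one.
The same fold draw is reused for all outcomes within a gender. Ties on
the selected α go to the **largest** α (more shrinkage — stability under
the fat-block collinearity is the point of the penalty). The headline
per-fold score is the squared Pearson correlation between held-out
predictions and observations, averaged arithmetically over folds; the
1 − SSE/SST form is computed alongside (the two differ on test folds, and
the latter can be negative — it is reported as computed, never clipped).
A single CV loop both selects α and reports the fold-averaged R²; a
nested scheme would remove the mild selection optimism, and the null-level
checks in the test suite quantify that optimism (≈ 0.04–0.08 at n = 160,
p = 10) rather than hide it. Coefficient magnitude |β| on the
standardised scale ranks the dietary variables per outcome; coefficient
signs are not interpreted and no standard errors are produced. A
coordinate-descent LASSO is available behind the same interface as an
optional baseline, excluded from headline outputs.

**Descriptives.** Medians and IQRs per sex (linear-interpolation
quartiles — IQR endpoints depend on this convention); the between-sex test
is Student's t if the D'Agostino–Pearson test accepts normality in *both*
sex groups at α = 0.05 (one test per variable across the comparison),
otherwise Mann–Whitney U; constant or too-small groups fall through to
Mann–Whitney with a logged note. Clinical values are coded normal (1)
/ abnormal (2) against a YAML range table defaulting to the harmonised
metabolic-syndrome criteria (WC ≥ 94/80 cm M/F, TG ≥ 150 mg/dL,
HDL-C < 40/50, SBP ≥ 130, DBP ≥ 85, glucose ≥ 100) plus conventional
bounds (BMI 25 kg/m², total cholesterol 200, LDL-C 130 mg/dL, insulin
25 µIU/mL, HbA1c 5.7 %); bounds are inclusive on the normal side, so a
value exactly at a threshold codes normal. Spearman maps use mid-rank tie
handling; a constant vector yields NaN, never a silent zero; no
significance stars or multiplicity correction are attached (descriptive
use; a t-approximation p-value is available behind a flag).

## The synthetic cohort generator

The generator produces cohorts with the structure the analysis assumes
and a known answer key, and its defaults *are* the modelled study
conditions:

* 94 women + 121 men with complete panels across four centres at equal
  proportions (quota allocation keeps any prefix within one subject of
  target); ages uniform on 23–77; heights N(162, 6) / N(175, 7) cm.
* **Gap-first generation**: the ten deltas are multivariate normal. Mean
  gaps describe an at-risk cohort (energy +1.0 MJ/day, fat +5 %EI,
  SFA +3 %EI, sugars +3 %EI, fibre −7 g/day, PUFA/UFA −2 %EI, protein
  +10 g/day, alcohol −0.5 servings/day); SDs are (1.3 MJ, 7, 4, 6, 3, 4,
  2 %EI, 20 g, 7 g, 0.25 servings); correlations are 0.7 within the
  fat/SFA/UFA/PUFA block and 0.1 elsewhere — the multicollinearity that
  motivates ridge. Raw intakes are reconstructed as gap + recommendation
  and floored at zero with the gap recomputed; under these scales the
  floor touches ≲ 2 % of draws in the worst component (alcohol) and
  ≲ 0.1 % elsewhere, so large-sample gap moments match their targets at
  the 4·sd/√n level used in the tests. One consequence of the small
  alcohol spread is that only ~2 % of subjects exceed the alcohol limit,
  below the 6.5 %/16.5 % seen in comparable cohorts.
* **Planted outcomes**: y = β₀ + x·β + ε per outcome and sex, with
  per-sex coefficient directions following the qualitative pattern the
  analysis is meant to surface (e.g. male BMI dominated by the energy
  gap with fat/SFA excess and a protein deficit contribution), scaled so
  each outcome's total SD matches the IQR-implied spread of the modelled
  cohort and noise calibrated by R² = var(xβ)/(var(xβ)+σ²) to per-sex
  target R² (e.g. BMI 0.43 women / 0.78 men). Intercepts reproduce the
  per-sex medians. Body weight is solved self-consistently (BMI is an
  outcome; weight = BMI·height² feeds the protein recommendation, a
  contraction iterated to a fixed point), so BMI, weight and height are
  mutually consistent and the stored outcomes are exact linear functions
  of the gap features the downstream model computes.
* **Misreporters**: a per-sex fraction (defaults 17/94 women, 41/121 men,
  so the screen retains 77 + 80) has reported energy rescaled to an
  EI:BMR target drawn from 0.55–0.85 (under, 80 % of injections) or
  2.95–3.40 (over) — at least 0.05 beyond the cutoffs, so screen recovery
  is exact; only energy is rescaled, %EI composition is left untouched to
  isolate the screen's decision variable. Under the default plausible-
  ratio distribution, naturally extreme ratios among non-injected
  subjects are (empirically) absent at cohort scale.
* **Reproducibility**: one global seed; each subject consumes a
  counter-derived `default_rng([seed, i])` stream, so enlarging a cohort
  never reshuffles existing subjects, and repeated writes are
  byte-identical (fixed `%.10g` CSV format).

What the generator does **not** emulate — and hence what green tests do
not establish about real data: outcomes are exactly linear in the gaps
with homoscedastic Gaussian noise (real insulin/TG are right-skewed; at
the modelled insulin spread the Gaussian tail produces occasional
non-positive values, which the reader deliberately tolerates); intakes
have no reporting error beyond the injected energy rescaling; centres
differ only in label, not in dietary distributions; and there is no
longitudinal or food-level structure. Passing tests demonstrate the
estimator and bookkeeping are correct under the stated generative law,
not that real diets satisfy it.

## Numerical choices and degenerate inputs

* Standardisation uses population SDs; columns with SD ≤ 1e−12·(1+|mean|)
  raise a named zero-variance error.
* At α = 0 a rank-deficient design raises with advice to use α > 0;
  otherwise the symmetric system is solved directly (p = 10, no
  conditioning concerns at these scales).
* A constant held-out prediction has undefined Pearson correlation; its
  fold score is defined as 0.
* CV folds with fewer than 3 test subjects raise (R² undefined).
* Energy declared in kcal is converted on entry (×4.184/1000) so the
  EI:BMR ratio is unit-consistent by construction. Gap tables are
  exported in native units; unit choice is immaterial to the regression
  after standardisation but does affect exported deltas.
* Gender groups smaller than 6·p log a warning and proceed.

## Problem sizes

The test suite and the acceptance script run on generated cohorts of
40–500 subjects (one 50,000-subject draw for distributional fidelity),
100-seed replication for recovery checks and 200-seed for null
calibration; these sizes give stable pass/fail behaviour for every
property while keeping a full run to a few minutes on one CPU.
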