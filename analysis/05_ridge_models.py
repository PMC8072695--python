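"""Cross-validated ridge models per clinical outcome and gender.

Fits the closed-form ridge regression of each of the eleven outcomes on
the ten intake gaps, separately per gender, tuning the penalty by
centre-stratified 5-fold cross-validation. Writes the fold-averaged R^2
table (Pearson convention, with the 1 - SSE/SST form alongside) and the
standardised coefficient rankings, then prints the outcomes whose
prediction clears the conventional R^2 > 0.4 bar.
"""

from pathlib import Path

from nutrigap.cohort import read_cohort_csv
from nutrigap.ridge import coefficient_table, fit_all_outcomes, r2_table
from nutrigap.screen import screen_cohort

SEED = 2021
RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main():
    records = [r for r in read_cohort_csv(SCRATCH / "cohort.csv")
               if r.clinical is not None]
    retained, _, _ = screen_cohort(records)
    results = fit_all_outcomes(retained, seed=SEED)
    table = r2_table(results)
    table.to_csv(RESULTS / "r2_table.csv", index=False, float_format="%.10g")
    coefficient_table(results).to_csv(
        RESULTS / "coefficients.csv", index=False, float_format="%.10g")
    print(table.round(3).to_string(index=False))
    for sex in ("female", "male"):
        good = table.loc[table[f"{sex}_r2"] > 0.4, "outcome"].tolist()
        print(f"\n{sex}: outcomes with fold-averaged R^2 > 0.4: {good}")
        for outcome in good:
            top = results[sex][outcome].coefficient_ranking[:3]
            print(f"  {outcome}: strongest |beta| -> {', '.join(top)}")


if __name__ == "__main__":
    main()
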