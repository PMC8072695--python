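"""Gender-stratified cohort description.

Medians and interquartile ranges of the eleven clinical outcomes per sex,
with the between-sex comparison chosen by the D'Agostino-Pearson
normality gate (Student's t when both sex groups look normal, otherwise
Mann-Whitney U). Also reports the abnormality rate of each outcome
against the default normal ranges.
"""

from pathlib import Path

import pandas as pd

from nutrigap.clinical import classify_panel, summarise_cohort
from nutrigap.cohort import OUTCOME_VARS, read_cohort_csv
from nutrigap.screen import screen_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main():
    records = [r for r in read_cohort_csv(SCRATCH / "cohort.csv")
               if r.clinical is not None]
    retained, _, _ = screen_cohort(records)
    summary = summarise_cohort(retained)
    summary.to_csv(RESULTS / "cohort_summary.csv", index=False,
                   float_format="%.10g")
    print(summary.round(3).to_string(index=False))

    codes = pd.DataFrame([classify_panel(r.clinical, r.sex)
                          for r in retained])
    abnormal_pct = (codes == 2).mean().mul(100).round(1)
    abnormal_pct.to_csv(RESULTS / "abnormal_pct.csv",
                        header=["abnormal_pct"])
    print("\nabnormal (%) by outcome:")
    print(abnormal_pct.reindex(list(OUTCOME_VARS)).to_string())


if __name__ == "__main__":
    main()
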