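"""Spearman correlation maps between intake gaps and clinical outcomes.

One 10 x 11 matrix per gender over the retained subjects, written as CSV
(the contract) and rendered as PNG heatmaps; prints the strongest
gap-outcome association per gender.
"""

from pathlib import Path

from nutrigap.cohort import read_cohort_csv
from nutrigap.correlations import correlation_map, render_heatmap
from nutrigap.screen import screen_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
FIGURES = SCRATCH / "figures"


def main():
    records = [r for r in read_cohort_csv(SCRATCH / "cohort.csv")
               if r.clinical is not None]
    retained, _, _ = screen_cohort(records)
    FIGURES.mkdir(parents=True, exist_ok=True)
    for sex in ("female", "male"):
        cm = correlation_map(retained, sex)
        cm.to_csv(RESULTS / f"correlation_map_{sex}.csv")
        render_heatmap(cm, FIGURES / f"correlation_map_{sex}.png")
        flat = cm.rho.abs().stack()
        gap, outcome = flat.idxmax()
        print(f"{sex} (n={cm.n}): strongest association "
              f"{gap} vs {outcome}, rho = {cm.rho.loc[gap, outcome]:+.2f}")


if __name__ == "__main__":
    main()
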