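"""Aggregate per-hospital quarterly KPIs and first-vs-last comparisons.

Groups scored episodes into calendar quarters by admission date, computes
in-band proportions, complication proportions and median/IQR outcomes per
hospital-quarter (plus pooled ALL rows), and tests each hospital's first
vs last audited quarter with an uncorrected Pearson chi-square.  Writes
results/kpis.csv and results/comparisons.csv.
"""

from pathlib import Path

from dkaudit.io import cohort_paths, read_cohort
from dkaudit.pipeline import (
    comparisons_frame,
    first_last_comparisons,
    kpis_frame,
    quarterly_kpis,
    score_cohort,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    episodes, codes = read_cohort(*cohort_paths(RESULTS / "cohort"))
    scored = score_cohort(episodes, codes)
    kpis = quarterly_kpis(scored)
    kpis_frame(kpis).to_csv(RESULTS / "kpis.csv", index=False, lineterminator="\n")
    comparisons = first_last_comparisons(kpis)
    comparisons_frame(comparisons).to_csv(
        RESULTS / "comparisons.csv", index=False, lineterminator="\n")

    print(f"wrote {len(kpis)} hospital-quarter KPI rows and "
          f"{len(comparisons)} first-vs-last comparisons")
    significant = [c for c in comparisons if c.p_value < 0.05 and c.reliable]
    for c in significant:
        direction = "up" if c.last_proportion > c.first_proportion else "down"
        print(f"  {c.hospital_code}/{c.indicator}: "
              f"{100 * c.first_proportion:.0f}% -> {100 * c.last_proportion:.0f}% "
              f"({direction}, chi2={c.chi_square_statistic:.2f}, p={c.p_value:.3g})")


if __name__ == "__main__":
    main()
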