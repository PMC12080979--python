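"""Render the anonymised per-hospital feedback reports.

Each hospital receives a markdown document with its own trailing-four-
quarter trends (adherence bands, complications, outcomes) next to the
pooled performance of all participating hospitals, plus its first-vs-last
chi-square table.  Writes results/reports/<hospital>.md.
"""

from pathlib import Path

from dkaudit.io import cohort_paths, read_cohort
from dkaudit.pipeline import (
    first_last_comparisons,
    quarterly_kpis,
    score_cohort,
    write_reports,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    episodes, codes = read_cohort(*cohort_paths(RESULTS / "cohort"))
    scored = score_cohort(episodes, codes)
    kpis = quarterly_kpis(scored)
    comparisons = first_last_comparisons(kpis)
    paths = write_reports(kpis, comparisons, RESULTS / "reports")
    print(f"wrote {len(paths)} feedback reports to {RESULTS / 'reports'}")


if __name__ == "__main__":
    main()
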