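"""Ascertain and score the cohort generated by 01_simulate_cohort.py.

Screens episodes (DKA discharge codes merged with the FRIII-treated list),
confirms the diagnosis against the composite criterion, detects resolution,
and computes per-episode adherence scores, complication flags and outcomes.
Writes windows.csv, adherence.csv, complications.csv and outcomes.csv under
results/scored/ and prints the cohort demographic summary.
"""

from pathlib import Path

from dkaudit.complications import summarize_cohort
from dkaudit.io import cohort_paths, read_cohort
from dkaudit.pipeline import score_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    episodes, codes = read_cohort(*cohort_paths(RESULTS / "cohort"))
    scored = score_cohort(episodes, codes)
    scored.write(RESULTS / "scored")

    s = summarize_cohort(scored.episodes)
    resolved = sum(w.resolved for w in scored.windows)
    print(f"ascertained {len(scored.episodes)} DKA episodes "
          f"({len(scored.excluded)} screened out); {resolved} resolved in-record")
    print(f"median age {s.age_median:.1f} y (IQR {s.age_q1:.1f}-{s.age_q3:.1f}); "
          f"women:men ratio {s.ratio_women_to_men} "
          f"({s.n_women} women, {s.n_men} men)")


if __name__ == "__main__":
    main()
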