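"""End-to-end orchestration: screen, ascertain, score, aggregate, report.

This is the layer the command-line tool and the analysis drivers call.
It strings the library stages together and exposes the audit's tabular
products as DataFrames matching the documented CSV layouts:

* ``windows.csv`` — episode_code, diagnosis_time, resolution_time,
  resolved, dka_duration_h
* ``adherence.csv`` — the four indicator percentages (one decimal) and
  band flags
* ``complications.csv`` / ``outcomes.csv`` — flags and outcome metrics
* ``kpis.csv`` — per-hospital per-quarter aggregates plus pooled rows
  (hospital code ``ALL``)
* ``comparisons.csv`` — first-vs-last-quarter chi-square results
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .adherence import INDICATORS, AdherenceResult, score_episode
from .ascertain import (
    DkaWindow,
    build_window,
    dka_duration_hours,
    frii_treated_codes,
    screen_candidates,
)
from .complications import (
    COMPLICATIONS,
    ComplicationFlags,
    OutcomeRecord,
    detect_complications,
    length_of_stay_days,
)
from .feedback import (
    POOLED_LABEL,
    FirstLastComparison,
    QuarterKPI,
    aggregate_quarter,
    first_last_comparison,
    quarter_of,
    render_feedback,
)
from .io import DEFAULT_CONFIG, AppConfig
from .model import DischargeCode, Episode

log = logging.getLogger(__name__)

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M"


@dataclass
class ScoredCohort:
    """Per-episode products of the scoring stage, for ascertained episodes."""

    episodes: List[Episode]
    windows: List[DkaWindow]
    adherence: List[AdherenceResult]
    flags: List[ComplicationFlags]
    outcomes: List[OutcomeRecord]
    excluded: List[str] = field(default_factory=list)  # screened but not confirmed

    def _meta(self) -> Dict[str, Tuple[str, str]]:
        return {ep.episode_code: (ep.hospital_code, quarter_of(ep.admission))
                for ep in self.episodes}

    def windows_frame(self) -> pd.DataFrame:
        rows = []
        for w in self.windows:
            rows.append({
                "episode_code": w.episode_code,
                "diagnosis_time": w.diagnosis_time.strftime(TIMESTAMP_FORMAT),
                "resolution_time": w.resolution_time.strftime(TIMESTAMP_FORMAT)
                if w.resolved else "",
                "resolved": w.resolved,
                "dka_duration_h": dka_duration_hours(w),
            })
        return pd.DataFrame(rows, columns=[
            "episode_code", "diagnosis_time", "resolution_time",
            "resolved", "dka_duration_h"])

    def adherence_frame(self, decimals: Optional[int] = None) -> pd.DataFrame:
        def rnd(v):
            if v is None:
                return None
            return round(v, decimals) if decimals is not None else v
        rows = [{
            "episode_code": r.episode_code,
            **{f"{ind}_pct": rnd(r.pct(ind)) for ind in INDICATORS},
            **{f"{ind}_in_band": r.in_band(ind) for ind in INDICATORS},
        } for r in self.adherence]
        return pd.DataFrame(rows, columns=["episode_code"]
                            + [f"{i}_pct" for i in INDICATORS]
                            + [f"{i}_in_band" for i in INDICATORS])

    def complications_frame(self) -> pd.DataFrame:
        rows = [{
            "episode_code": f.episode_code,
            **{c: f.get(c) for c in COMPLICATIONS},
        } for f in self.flags]
        return pd.DataFrame(rows, columns=["episode_code", *COMPLICATIONS])

    def outcomes_frame(self) -> pd.DataFrame:
        rows = [{
            "episode_code": o.episode_code,
            "dka_duration_h": o.dka_duration_h,
            "length_of_stay_d": o.length_of_stay_d,
        } for o in self.outcomes]
        return pd.DataFrame(rows, columns=["episode_code", "dka_duration_h",
                                           "length_of_stay_d"])

    def write(self, directory) -> dict:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        frames = {
            "windows": self.windows_frame(),
            "adherence": self.adherence_frame(decimals=1),
            "complications": self.complications_frame(),
            "outcomes": self.outcomes_frame(),
        }
        paths = {}
        for name, frame in frames.items():
            path = directory / f"{name}.csv"
            frame.to_csv(path, index=False, lineterminator="\n")
            paths[name] = path
        return paths


def score_cohort(episodes: Sequence[Episode], codes: Sequence[DischargeCode],
                 config: AppConfig = DEFAULT_CONFIG) -> ScoredCohort:
    """Screen, confirm, and score a cohort.

    Episodes enter the case set when screened in (DKA discharge code or
    FRIII-treated) *and* the diagnosis detector confirms the composite
    criterion (the deterministic stand-in for manual case confirmation,
    overridable per episode via ``confirmed``).
    """
    candidates = screen_candidates(codes, frii_treated_codes(episodes))
    kept: List[Episode] = []
    windows: List[DkaWindow] = []
    excluded: List[str] = []
    for ep in episodes:
        if ep.episode_code not in candidates:
            excluded.append(ep.episode_code)
            continue
        window = build_window(
            ep, config.thresholds, config.lookback_hours,
            config.resolution_pair_minutes, config.resolution_tolerance_minutes,
            config.resolution_stamp)
        if window is None:
            excluded.append(ep.episode_code)
            continue
        kept.append(ep)
        windows.append(window)
    adherence = [score_episode(ep, w, config.thresholds, config.schedule, config.accrual)
                 for ep, w in zip(kept, windows)]
    flags = [detect_complications(ep, w, config.thresholds)
             for ep, w in zip(kept, windows)]
    outcomes = [OutcomeRecord(ep.episode_code,
                              length_of_stay_d=length_of_stay_days(ep),
                              dka_duration_h=dka_duration_hours(w))
                for ep, w in zip(kept, windows)]
    if excluded:
        log.info("%d of %d episodes screened out or unconfirmed",
                 len(excluded), len(episodes))
    return ScoredCohort(kept, windows, adherence, flags, outcomes, excluded)


def quarterly_kpis(scored: ScoredCohort) -> List[QuarterKPI]:
    """KPIs per hospital-quarter, plus pooled rows (hospital ``ALL``)."""
    meta = scored._meta()
    groups: Dict[Tuple[str, str], List[int]] = {}
    for i, ep in enumerate(scored.episodes):
        hospital, quarter = meta[ep.episode_code]
        groups.setdefault((hospital, quarter), []).append(i)
        groups.setdefault((POOLED_LABEL, quarter), []).append(i)
    kpis = []
    for (hospital, quarter) in sorted(groups):
        idx = groups[(hospital, quarter)]
        kpis.append(aggregate_quarter(
            [scored.adherence[i] for i in idx],
            [scored.flags[i] for i in idx],
            [scored.outcomes[i] for i in idx],
            hospital, quarter))
    return kpis


def kpis_frame(kpis: Sequence[QuarterKPI]) -> pd.DataFrame:
    rows = []
    for k in kpis:
        rows.append({
            "hospital_code": k.hospital_code,
            "quarter": k.quarter,
            "n_episodes": k.n_episodes,
            **{f"{i}_in_band_n": k.in_band_n[i] for i in INDICATORS},
            **{f"{i}_eligible_n": k.eligible_n[i] for i in INDICATORS},
            **{f"{i}_in_band_prop": k.in_band_prop[i] for i in INDICATORS},
            "hypo_prop": k.complication_prop["hypoglycaemia"],
            "hypok_prop": k.complication_prop["hypokalaemia"],
            "hyperk_prop": k.complication_prop["hyperkalaemia"],
            "duration_median": k.duration_median,
            "duration_q1": k.duration_q1,
            "duration_q3": k.duration_q3,
            "los_median": k.los_median,
            "los_q1": k.los_q1,
            "los_q3": k.los_q3,
        })
    return pd.DataFrame(rows)


def kpis_from_frame(frame: pd.DataFrame) -> List[QuarterKPI]:
    """Rebuild KPI records from a ``kpis.csv`` table (inverse of
    :func:`kpis_frame` up to float representation)."""
    def opt(v):
        return None if pd.isna(v) else float(v)

    def opt_int(v):
        return None if pd.isna(v) else int(v)

    kpis = []
    for rec in frame.to_dict("records"):
        kpis.append(QuarterKPI(
            hospital_code=str(rec["hospital_code"]),
            quarter=str(rec["quarter"]),
            n_episodes=int(rec["n_episodes"]),
            in_band_n={i: opt_int(rec[f"{i}_in_band_n"]) for i in INDICATORS},
            eligible_n={i: int(rec[f"{i}_eligible_n"]) for i in INDICATORS},
            in_band_prop={i: opt(rec[f"{i}_in_band_prop"]) for i in INDICATORS},
            complication_prop={
                "hypoglycaemia": opt(rec["hypo_prop"]),
                "hypokalaemia": opt(rec["hypok_prop"]),
                "hyperkalaemia": opt(rec["hyperk_prop"]),
            },
            duration_median=opt(rec["duration_median"]),
            duration_q1=opt(rec["duration_q1"]),
            duration_q3=opt(rec["duration_q3"]),
            los_median=opt(rec["los_median"]),
            los_q1=opt(rec["los_q1"]),
            los_q3=opt(rec["los_q3"]),
        ))
    return kpis


def first_last_comparisons(kpis: Sequence[QuarterKPI],
                           correction: bool = False) -> List[FirstLastComparison]:
    """All per-hospital, per-indicator first-vs-last comparisons that are
    computable (skipping hospitals with fewer than two audited quarters)."""
    out = []
    hospitals = sorted({k.hospital_code for k in kpis if k.hospital_code != POOLED_LABEL})
    for hospital in hospitals:
        own = [k for k in kpis if k.hospital_code == hospital]
        for ind in INDICATORS:
            comp = first_last_comparison(own, ind, correction)
            if comp is not None:
                out.append(comp)
    return out


def comparisons_frame(comparisons: Sequence[FirstLastComparison]) -> pd.DataFrame:
    rows = [{
        "hospital_code": c.hospital_code,
        "indicator": c.indicator,
        "first_q": c.first_quarter,
        "last_q": c.last_quarter,
        "first_prop": c.first_proportion,
        "last_prop": c.last_proportion,
        "chi2": c.chi_square_statistic,
        "p": c.p_value,
        "reliable": c.reliable,
    } for c in comparisons]
    return pd.DataFrame(rows, columns=["hospital_code", "indicator", "first_q",
                                       "last_q", "first_prop", "last_prop",
                                       "chi2", "p", "reliable"])


def write_reports(kpis: Sequence[QuarterKPI],
                  comparisons: Sequence[FirstLastComparison],
                  directory) -> dict:
    """Render one markdown feedback report per hospital."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pooled = [k for k in kpis if k.hospital_code == POOLED_LABEL]
    hospitals = sorted({k.hospital_code for k in kpis if k.hospital_code != POOLED_LABEL})
    paths = {}
    for hospital in hospitals:
        text = render_feedback(hospital, kpis, pooled, comparisons)
        path = directory / f"{hospital}.md"
        path.write_text(text)
        paths[hospital] = path
    return paths
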