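"""Quarterly KPI aggregation, first-vs-last-quarter tests and feedback reports.

Episodes are grouped into calendar quarters (Q1 = Jan-Mar) by admission
date, per hospital.  Each hospital-quarter yields a KPI record: episode
count, the proportion of episodes within the 80-120 % adherence band for
each of the four indicators, complication proportions, and median/IQR of
DKA duration and length of stay.  Episodes whose score for an indicator is
absent (e.g. unresolved DKA) drop out of that indicator's denominator only.

Change over the audit is tested per hospital and indicator with an
uncorrected Pearson chi-square on the 2x2 table [in-band, not in-band] x
[first quarter, last quarter], 1 degree of freedom; the first quarter is
the earliest with data for that hospital (robust to staggered onboarding).
Results with any expected cell below 1 are flagged unreliable but still
returned.

Feedback reports are deterministic markdown: each hospital sees its own
trailing-four-quarter trends next to the pooled, anonymised performance of
all participating hospitals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .adherence import INDICATORS, AdherenceResult
from .complications import (
    COMPLICATIONS,
    ComplicationFlags,
    OutcomeRecord,
    complication_proportion,
    quantiles,
)
from .model import DomainError

POOLED_LABEL = "ALL"


def quarter_of(timestamp: datetime) -> str:
    """Calendar-quarter label "YYYY-Qn" (Q1 = Jan-Mar)."""
    return f"{timestamp.year}-Q{(timestamp.month - 1) // 3 + 1}"


@dataclass(frozen=True)
class QuarterKPI:
    """Per-hospital, per-quarter aggregate of the audit measures."""

    hospital_code: str
    quarter: str
    n_episodes: int
    in_band_n: Dict[str, Optional[int]] = field(default_factory=dict)
    eligible_n: Dict[str, int] = field(default_factory=dict)
    in_band_prop: Dict[str, Optional[float]] = field(default_factory=dict)
    complication_prop: Dict[str, Optional[float]] = field(default_factory=dict)
    duration_median: Optional[float] = None
    duration_q1: Optional[float] = None
    duration_q3: Optional[float] = None
    los_median: Optional[float] = None
    los_q1: Optional[float] = None
    los_q3: Optional[float] = None


@dataclass(frozen=True)
class FirstLastComparison:
    """Chi-square comparison of one indicator between a hospital's first
    and last audited quarters."""

    hospital_code: str
    indicator: str
    first_quarter: str
    last_quarter: str
    first_proportion: float
    last_proportion: float
    chi_square_statistic: float
    p_value: float
    reliable: bool = True


def aggregate_quarter(adherence: Sequence[AdherenceResult],
                      flags: Sequence[ComplicationFlags],
                      outcomes: Sequence[OutcomeRecord],
                      hospital: str, quarter: str) -> QuarterKPI:
    """Aggregate one hospital-quarter's per-episode results into a KPI."""
    n = len(outcomes)
    in_band_n: Dict[str, Optional[int]] = {}
    eligible_n: Dict[str, int] = {}
    in_band_prop: Dict[str, Optional[float]] = {}
    for ind in INDICATORS:
        scored = [r.in_band(ind) for r in adherence if r.pct(ind) is not None]
        eligible_n[ind] = len(scored)
        if scored:
            in_band_n[ind] = int(sum(scored))
            in_band_prop[ind] = in_band_n[ind] / len(scored)
        else:
            in_band_n[ind] = None
            in_band_prop[ind] = None
    comp = {c: complication_proportion(flags, c) for c in COMPLICATIONS}
    durations = [o.dka_duration_h for o in outcomes if o.dka_duration_h is not None]
    stays = [o.length_of_stay_d for o in outcomes]
    dq1, dmed, dq3 = quantiles(durations)
    lq1, lmed, lq3 = quantiles(stays)
    return QuarterKPI(
        hospital_code=hospital, quarter=quarter, n_episodes=n,
        in_band_n=in_band_n, eligible_n=eligible_n, in_band_prop=in_band_prop,
        complication_prop=comp,
        duration_median=dmed, duration_q1=dq1, duration_q3=dq3,
        los_median=lmed, los_q1=lq1, los_q3=lq3,
    )


def pearson_chi2_2x2(table, correction: bool = False) -> Tuple[float, float, float]:
    """Pearson chi-square on a 2x2 table: ``(statistic, p, min_expected)``.

    Statistic is sum (O-E)^2 / E with 1 df; ``correction`` applies Yates'
    continuity correction.  A table with a zero marginal carries no
    association information: statistic 0, p 1, min_expected 0.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise DomainError("expected a non-negative 2x2 table")
    n = obs.sum()
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if n == 0 or (rows == 0).any() or (cols == 0).any():
        return 0.0, 1.0, 0.0
    expected = np.outer(rows, cols) / n
    diff = np.abs(obs - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff ** 2 / expected).sum())
    p = float(chi2_dist.sf(statistic, df=1))
    return statistic, p, float(expected.min())


def first_last_comparison(kpis: Sequence[QuarterKPI], indicator: str,
                          correction: bool = False) -> Optional[FirstLastComparison]:
    """Compare an indicator between a hospital's first and last quarters.

    ``kpis`` must all belong to one hospital.  The first quarter is the
    earliest with >= 1 episode, the last the latest.  Returns ``None`` when
    fewer than two quarters have data or the indicator was never assessable
    in one of them.
    """
    if indicator not in INDICATORS:
        raise DomainError(f"unknown indicator {indicator!r}")
    hospitals = {k.hospital_code for k in kpis}
    if len(hospitals) > 1:
        raise DomainError(f"KPIs span multiple hospitals: {sorted(hospitals)}")
    with_data = sorted((k for k in kpis if k.n_episodes > 0), key=lambda k: k.quarter)
    if len(with_data) < 2:
        return None
    first, last = with_data[0], with_data[-1]
    if not first.eligible_n.get(indicator) or not last.eligible_n.get(indicator):
        return None
    a = first.in_band_n[indicator]
    b = first.eligible_n[indicator] - a
    c = last.in_band_n[indicator]
    d = last.eligible_n[indicator] - c
    statistic, p, min_expected = pearson_chi2_2x2([[a, b], [c, d]], correction)
    return FirstLastComparison(
        hospital_code=first.hospital_code, indicator=indicator,
        first_quarter=first.quarter, last_quarter=last.quarter,
        first_proportion=first.in_band_prop[indicator],
        last_proportion=last.in_band_prop[indicator],
        chi_square_statistic=statistic, p_value=p,
        reliable=min_expected >= 1.0,
    )


# --- report rendering ------------------------------------------------------

_INDICATOR_TITLES = {
    "frii": "FRIII rate",
    "fluid": "Fluid volume",
    "glucose": "Glucose monitoring",
    "ketone": "Ketone monitoring",
}
_COMPLICATION_TITLES = {
    "hypoglycaemia": "Hypoglycaemia",
    "hypokalaemia": "Hypokalaemia",
    "hyperkalaemia": "Hyperkalaemia",
}


def _fmt_prop(p: Optional[float]) -> str:
    return "--" if p is None else f"{100 * p:.1f}%"


def _fmt_stat(v: Optional[float]) -> str:
    return "--" if v is None else f"{v:.1f}"


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def _fmt_median_iqr(med, q1, q3) -> str:
    if med is None:
        return "--"
    return f"{med:.1f} ({q1:.1f}-{q3:.1f})"


def _table(header: List[str], rows: List[List[str]]) -> str:
    lines = ["| " + " | ".join(header) + " |",
             "| " + " | ".join("---" for _ in header) + " |"]
    lines += ["| " + " | ".join(row) + " |" for row in rows]
    return "\n".join(lines)


def _kpi_tables(kpis: Sequence[QuarterKPI]) -> str:
    quarters = [k.quarter for k in kpis]
    by_q = {k.quarter: k for k in kpis}
    head = ["indicator"] + quarters
    adh_rows = []
    for ind in INDICATORS:
        adh_rows.append([_INDICATOR_TITLES[ind]] + [
            f"{_fmt_prop(by_q[q].in_band_prop[ind])}"
            f" ({by_q[q].in_band_n[ind] if by_q[q].in_band_n[ind] is not None else '-'}"
            f"/{by_q[q].eligible_n[ind]})"
            for q in quarters])
    comp_rows = [[_COMPLICATION_TITLES[c]] +
                 [_fmt_prop(by_q[q].complication_prop[c]) for q in quarters]
                 for c in COMPLICATIONS]
    out_rows = [
        ["DKA duration (h), median (IQR)"] +
        [_fmt_median_iqr(by_q[q].duration_median, by_q[q].duration_q1, by_q[q].duration_q3)
         for q in quarters],
        ["Length of stay (d), median (IQR)"] +
        [_fmt_median_iqr(by_q[q].los_median, by_q[q].los_q1, by_q[q].los_q3)
         for q in quarters],
    ]
    n_row = _table(["quarter"] + quarters,
                   [["episodes"] + [str(by_q[q].n_episodes) for q in quarters]])
    return "\n\n".join([
        "### Episodes\n\n" + n_row,
        "### Adherence within 80-120% of recommendation\n\n" + _table(head, adh_rows),
        "### Complications (proportion of episodes)\n\n"
        + _table(["complication"] + quarters, comp_rows),
        "### Outcomes\n\n" + _table(["outcome"] + quarters, out_rows),
    ])


def render_feedback(hospital: str,
                    kpis: Sequence[QuarterKPI],
                    peer: Sequence[QuarterKPI],
                    comparisons: Sequence[FirstLastComparison] = ()) -> str:
    """Render one hospital's feedback report as markdown.

    ``kpis`` are the hospital's own quarterly KPIs (the trailing four
    quarters are shown), ``peer`` the pooled series across all hospitals
    (anonymised comparator), ``comparisons`` the hospital's first-vs-last
    chi-square results (section omitted when empty).
    """
    own = sorted((k for k in kpis if k.hospital_code == hospital),
                 key=lambda k: k.quarter)
    if not own:
        raise DomainError(f"no KPIs available for hospital {hospital!r}")
    own = own[-4:]
    pooled = sorted(peer, key=lambda k: k.quarter)[-4:]
    parts = [
        f"# DKA care feedback -- hospital {hospital}",
        f"Quarters shown: {own[0].quarter} to {own[-1].quarter}."
        " Peer figures pool all participating hospitals without naming them.",
        f"## Hospital {hospital}",
        _kpi_tables(own),
        "## All participating hospitals (pooled)",
        _kpi_tables(pooled),
    ]
    comps = [c for c in comparisons if c.hospital_code == hospital]
    if comps:
        rows = [[
            _INDICATOR_TITLES[c.indicator], c.first_quarter, c.last_quarter,
            _fmt_prop(c.first_proportion), _fmt_prop(c.last_proportion),
            f"{c.chi_square_statistic:.2f}", _fmt_p(c.p_value),
            "" if c.reliable else "low expected counts",
        ] for c in comps]
        parts += [
            "## First vs last quarter",
            _table(["indicator", "first", "last", "first %", "last %",
                    "chi-square", "p", "note"], rows),
        ]
    return "\n\n".join(parts) + "\n"
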