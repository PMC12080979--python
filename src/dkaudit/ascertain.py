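"""DKA case ascertainment: screening, diagnosis, resolution, duration.

Screening merges two imperfect sources — episodes discharged with a DKA
ICD-10 code and episodes treated with a fixed-rate intravenous insulin
infusion (FRIII) — because either list alone misses cases (an episode may
be miscoded, or coded but never escalated to FRIII).

Diagnosis follows the national (JBDS-IP) composite criterion evaluated at
a time point using the most recent reading of each analyte:

    (glucose > 11 mmol/L  OR  known diabetes)
    AND (blood ketones > 3 mmol/L  OR  urine ketones >= ++)
    AND (pH < 7.30  OR  bicarbonate < 15 mmol/L)

Readings older than ``lookback_hours`` (default 6 h) are considered stale
and ignored, so a day-old panel cannot validate a diagnosis.  If no ketone
datum or no acid-base datum is available at the evaluation time the result
is *indeterminate* (``None``), distinct from ``False``.

Resolution requires pH > 7.30 or bicarbonate > 18 mmol/L together with
blood ketones < 0.6 mmol/L sustained over two consecutive hours,
operationalised as two readings 60 +/- 15 minutes apart at both of which
the composite condition holds; the resolution is stamped at the second
reading of the earliest qualifying pair (the moment sustainment is
confirmed).  Urine ketones never substitute at resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Optional, Set

from .model import Analyte, DischargeCode, DKA_ICD10_CODES, Episode, Thresholds

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DkaWindow:
    """The confirmed DKA interval of one episode."""

    episode_code: str
    diagnosis_time: datetime
    resolution_time: Optional[datetime] = None

    def __post_init__(self) -> None:
        if self.resolution_time is not None and self.resolution_time < self.diagnosis_time:
            raise ValueError("resolution_time precedes diagnosis_time")

    @property
    def resolved(self) -> bool:
        return self.resolution_time is not None


def screen_candidates(codes: Iterable[DischargeCode],
                      frii_treated: Iterable[str]) -> Set[str]:
    """Episode codes carrying a DKA ICD-10 code, union those treated with FRIII."""
    coded = {c.episode_code for c in codes if c.icd10 in DKA_ICD10_CODES}
    return coded | set(frii_treated)


def frii_treated_codes(episodes: Iterable[Episode]) -> Set[str]:
    """Episodes with at least one FRIII prescription (the treated list)."""
    return {
        ep.episode_code
        for ep in episodes
        if any(rx.kind.value == "frii" for rx in ep.prescriptions)
    }


def latest_value(episode: Episode, analyte: Analyte, at: datetime,
                 lookback_hours: float = 6.0) -> Optional[float]:
    """Most recent reading of ``analyte`` at or before ``at``, within the
    staleness window; ``None`` if there is none."""
    horizon = at - timedelta(hours=lookback_hours)
    best = None
    for obs in episode.observations:  # sorted ascending; keep the last hit
        if obs.timestamp > at:
            break
        if obs.analyte is analyte and obs.timestamp >= horizon:
            best = obs.value
    return best


def meets_dka_criteria(episode: Episode, at: datetime,
                       thresholds: Thresholds = Thresholds(),
                       lookback_hours: float = 6.0) -> Optional[bool]:
    """Evaluate the composite diagnosis criterion at time ``at``.

    Returns ``True``/``False``, or ``None`` (indeterminate) when the ketone
    arm or the acid-base arm has no usable reading.  A definite failure of
    any arm short-circuits to ``False`` even if another arm is indeterminate.
    """
    glucose = latest_value(episode, Analyte.GLUCOSE, at, lookback_hours)
    ketones = latest_value(episode, Analyte.KETONES, at, lookback_hours)
    ph = latest_value(episode, Analyte.PH, at, lookback_hours)
    bicarb = latest_value(episode, Analyte.BICARBONATE, at, lookback_hours)

    if episode.has_diabetes_history:
        glucose_arm: Optional[bool] = True
    elif glucose is not None:
        glucose_arm = glucose > thresholds.dka_glucose
    else:
        glucose_arm = None

    if ketones is not None:
        ketone_arm: Optional[bool] = ketones > thresholds.dka_ketones or episode.urine_ketones_high
    elif episode.urine_ketones_high:
        ketone_arm = True
    else:
        ketone_arm = None

    if ph is None and bicarb is None:
        acid_arm: Optional[bool] = None
    else:
        acid_arm = (ph is not None and ph < thresholds.dka_ph) or (
            bicarb is not None and bicarb < thresholds.dka_bicarbonate)

    arms = (glucose_arm, ketone_arm, acid_arm)
    if any(a is False for a in arms):
        return False
    if any(a is None for a in arms):
        return None
    return True


def detect_diagnosis(episode: Episode,
                     thresholds: Thresholds = Thresholds(),
                     lookback_hours: float = 6.0) -> Optional[datetime]:
    """Earliest observation timestamp at which the diagnosis criterion holds.

    An explicit ``confirmed=False`` adjudication vetoes the episode.
    Returns ``None`` when the criterion is never met or there are no
    observations.
    """
    if episode.confirmed is False:
        return None
    if not episode.observations:
        log.warning("episode %s has no observations; cannot ascertain DKA",
                    episode.episode_code)
        return None
    seen = set()
    for obs in episode.observations:
        t = obs.timestamp
        if t in seen:
            continue
        seen.add(t)
        if meets_dka_criteria(episode, t, thresholds, lookback_hours) is True:
            return t
    return None


def _resolution_ok(episode: Episode, at: datetime, thresholds: Thresholds,
                   lookback_hours: float) -> bool:
    """The resolution condition at one time point (indeterminate counts as
    not met: resolution must be demonstrated, not assumed)."""
    ketones = latest_value(episode, Analyte.KETONES, at, lookback_hours)
    if ketones is None or ketones >= thresholds.res_ketones:
        return False
    ph = latest_value(episode, Analyte.PH, at, lookback_hours)
    bicarb = latest_value(episode, Analyte.BICARBONATE, at, lookback_hours)
    if ph is None and bicarb is None:
        return False
    return (ph is not None and ph > thresholds.res_ph) or (
        bicarb is not None and bicarb > thresholds.res_bicarbonate)


def detect_resolution(episode: Episode, diagnosis_time: datetime,
                      thresholds: Thresholds = Thresholds(),
                      lookback_hours: float = 6.0,
                      pair_minutes: float = 60.0,
                      tolerance_minutes: float = 15.0,
                      stamp: str = "second") -> Optional[datetime]:
    """Earliest sustained normalisation after ``diagnosis_time``.

    Scans reading timestamps strictly after diagnosis (and not after
    discharge) for the earliest pair spaced ``pair_minutes`` +/-
    ``tolerance_minutes`` apart at both of which the resolution condition
    holds, and returns the second (or first, per ``stamp``) timestamp of
    that pair; ``None`` if no pair qualifies.
    """
    times = sorted({
        o.timestamp for o in episode.observations
        if diagnosis_time < o.timestamp <= episode.discharge
    })
    if not times:
        log.warning("episode %s: no observations after diagnosis at %s",
                    episode.episode_code, diagnosis_time)
        return None
    ok = [_resolution_ok(episode, t, thresholds, lookback_hours) for t in times]
    lo = timedelta(minutes=pair_minutes - tolerance_minutes)
    hi = timedelta(minutes=pair_minutes + tolerance_minutes)
    for j, t2 in enumerate(times):
        if not ok[j]:
            continue
        for i in range(j):
            if ok[i] and lo <= t2 - times[i] <= hi:
                return times[i] if stamp == "first" else t2
    return None


def dka_duration_hours(window: DkaWindow) -> Optional[float]:
    """Diagnosis-to-resolution interval in fractional hours; ``None`` if
    the episode never resolved."""
    if not window.resolved:
        return None
    return (window.resolution_time - window.diagnosis_time).total_seconds() / 3600.0


def build_window(episode: Episode,
                 thresholds: Thresholds = Thresholds(),
                 lookback_hours: float = 6.0,
                 pair_minutes: float = 60.0,
                 tolerance_minutes: float = 15.0,
                 stamp: str = "second") -> Optional[DkaWindow]:
    """Ascertain one episode end-to-end: diagnosis then resolution."""
    diagnosis = detect_diagnosis(episode, thresholds, lookback_hours)
    if diagnosis is None:
        return None
    resolution = detect_resolution(
        episode, diagnosis, thresholds, lookback_hours,
        pair_minutes, tolerance_minutes, stamp)
    return DkaWindow(episode.episode_code, diagnosis, resolution)
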