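"""Guideline-adherence scoring for the four key performance indicators.

Each DKA episode receives a percentage score against the national
(JBDS-IP) recommendation for:

* **FRIII** — fixed-rate intravenous insulin at 0.1 units/kg/h:
  ``(rate / (weight / 10)) x 100``, so a 70 kg patient prescribed
  7.0 units/h scores 100 %.
* **Fluids** — administered volume against the guideline replacement
  schedule evaluated at the episode's DKA duration (e.g. 4 L are
  recommended for a 5 h episode, so 3 L score 75 %).
* **Glucose / ketone monitoring** — hourly monitoring is the standard, so
  ``(number of readings / DKA duration in hours) x 100``.

An episode is *in band* for an indicator when its score lies within
80-120 % inclusive.  Scores below 100 % mean under-treatment relative to
the recommendation, above 100 % over-treatment; neither is truncated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import datetime
from typing import Optional

from .ascertain import DkaWindow, dka_duration_hours
from .model import (
    Analyte,
    ConfigError,
    DomainError,
    Episode,
    PrescriptionKind,
    Thresholds,
)

log = logging.getLogger(__name__)

INDICATORS = ("frii", "fluid", "glucose", "ketone")


@dataclass(frozen=True)
class FluidSchedule:
    """The guideline fluid-replacement schedule.

    An initial bolus (500 mL repeated until systolic BP > 90 mmHg; counted
    here as 1000 mL total, the calibration that reproduces the guideline's
    4 L at 5 h anchor), then a fixed sequence of bags each delivered over a
    stated interval, then a continuation bag repeated until resolution.
    Cumulative recommended volume is evaluated by
    :func:`recommended_fluid_volume`.
    """

    bolus_ml: float = 1000.0
    bags: tuple = ((1000.0, 1.0), (1000.0, 2.0), (1000.0, 2.0),
                   (1000.0, 4.0), (1000.0, 4.0), (1000.0, 6.0))
    continuation: tuple = (1000.0, 6.0)

    def __post_init__(self) -> None:
        if self.bolus_ml <= 0:
            raise ConfigError("bolus volume must be positive")
        for vol, hours in tuple(self.bags) + (tuple(self.continuation),):
            if vol <= 0 or hours <= 0:
                raise ConfigError("bag volumes and durations must be positive")

    def boundaries(self, horizon_h: float):
        """Yield ``(completion_time_h, bag_volume_ml)`` for every bag whose
        interval starts before ``horizon_h`` (finite bags then continuation)."""
        t = 0.0
        for vol, hours in self.bags:
            t += hours
            yield t, vol
            if t > horizon_h:
                return
        vol, hours = self.continuation
        while t <= horizon_h:
            t += hours
            yield t, vol


DEFAULT_SCHEDULE = FluidSchedule()


@dataclass(frozen=True)
class AdherenceResult:
    """Per-episode adherence scores (percent) and band flags.

    A ``None`` score means the indicator was not assessable: no FRIII
    prescription or, for the duration-dependent indicators, an unresolved
    DKA window.
    """

    episode_code: str
    frii_pct: Optional[float] = None
    fluid_pct: Optional[float] = None
    glucose_pct: Optional[float] = None
    ketone_pct: Optional[float] = None
    frii_in_band: Optional[bool] = None
    fluid_in_band: Optional[bool] = None
    glucose_in_band: Optional[bool] = None
    ketone_in_band: Optional[bool] = None

    def pct(self, indicator: str) -> Optional[float]:
        return getattr(self, f"{indicator}_pct")

    def in_band(self, indicator: str) -> Optional[bool]:
        return getattr(self, f"{indicator}_in_band")


def frii_adherence(rate_units_per_h: float, weight_kg: float) -> float:
    """FRIII adherence percent: ``(rate / (weight / 10)) x 100``.

    100 % iff the prescribed rate equals 0.1 units/kg/h.
    """
    if not (math.isfinite(weight_kg) and weight_kg > 0):
        raise DomainError(f"weight must be positive, got {weight_kg}")
    if not (math.isfinite(rate_units_per_h) and rate_units_per_h >= 0):
        raise DomainError(f"rate must be non-negative, got {rate_units_per_h}")
    return rate_units_per_h / (weight_kg / 10.0) * 100.0


def recommended_fluid_volume(duration_h: float,
                             schedule: FluidSchedule = DEFAULT_SCHEDULE,
                             accrual: str = "whole_bag") -> float:
    """Guideline fluid volume (litres) for a DKA episode of ``duration_h``.

    ``whole_bag`` (default) credits each bag in full once its interval has
    completed, giving the step function 1 L (bolus) -> 2 L at 1 h -> 3 L at
    3 h -> 4 L at 5 h -> 5 L at 9 h -> 6 L at 13 h -> 7 L at 19 h, then one
    further litre per continuation interval.  ``pro_rata`` accrues each
    bag linearly over its interval instead.
    """
    if not (math.isfinite(duration_h) and duration_h >= 0):
        raise DomainError(f"duration must be non-negative, got {duration_h}")
    if accrual not in ("whole_bag", "pro_rata"):
        raise ConfigError(f"unknown accrual mode {accrual!r}")
    volume_ml = schedule.bolus_ml
    prev_end = 0.0
    for end, bag_ml in schedule.boundaries(duration_h):
        if accrual == "whole_bag":
            if end <= duration_h:
                volume_ml += bag_ml
        else:
            if prev_end >= duration_h:
                break
            covered = min(duration_h, end) - prev_end
            volume_ml += bag_ml * covered / (end - prev_end)
        prev_end = end
    return volume_ml / 1000.0


def fluid_adherence(administered_l: float, duration_h: float,
                    schedule: FluidSchedule = DEFAULT_SCHEDULE,
                    accrual: str = "whole_bag") -> float:
    """Fluid adherence percent: administered over recommended volume."""
    if not (math.isfinite(administered_l) and administered_l >= 0):
        raise DomainError(f"administered volume must be non-negative, got {administered_l}")
    recommended = recommended_fluid_volume(duration_h, schedule, accrual)
    if recommended <= 0:
        raise DomainError("recommended volume is zero")  # impossible with a positive bolus
    return administered_l / recommended * 100.0


def monitoring_adherence(n_readings: int, duration_h: float) -> Optional[float]:
    """Monitoring adherence percent: readings per hour of DKA, x 100.

    Undefined (``None``, logged) for a zero-length DKA window.
    """
    if n_readings < 0:
        raise DomainError(f"negative reading count {n_readings}")
    if not (math.isfinite(duration_h) and duration_h >= 0):
        raise DomainError(f"duration must be non-negative, got {duration_h}")
    if duration_h == 0:
        log.warning("monitoring adherence undefined for zero DKA duration")
        return None
    return n_readings / duration_h * 100.0


def within_band(pct: float, thresholds: Thresholds = Thresholds()) -> bool:
    """Band membership: 80 % <= pct <= 120 %, both bounds inclusive,
    evaluated at full precision."""
    if pct < 0:
        raise DomainError(f"negative percentage {pct}")
    return thresholds.band_low <= pct <= thresholds.band_high


def _count_readings(episode: Episode, analyte: Analyte,
                    start: datetime, end: datetime) -> int:
    # duplicate charting at the same minute counts once per analyte
    return len({
        o.timestamp for o in episode.observations
        if o.analyte is analyte and start <= o.timestamp <= end
    })


def score_episode(episode: Episode, window: Optional[DkaWindow],
                  thresholds: Thresholds = Thresholds(),
                  schedule: FluidSchedule = DEFAULT_SCHEDULE,
                  accrual: str = "whole_bag") -> AdherenceResult:
    """Assemble the four indicator scores and band flags for one episode.

    FRIII is scored from the first FRIII prescription by start time (the
    single-rate guideline formula; later rate changes are not scored).
    The duration-dependent indicators — fluids and glucose/ketone
    monitoring — require a resolved DKA window: fluid volumes administered
    within [diagnosis, resolution] are summed, and monitoring counts use
    the same closed interval so the diagnosis-time panel counts.
    """
    frii_pct = None
    frii_rx = sorted(
        (rx for rx in episode.prescriptions if rx.kind is PrescriptionKind.FRIII),
        key=lambda rx: rx.start)
    if frii_rx:
        frii_pct = frii_adherence(frii_rx[0].rate_units_per_h, episode.weight_kg)
    else:
        log.warning("episode %s has no FRIII prescription; FRIII score absent",
                    episode.episode_code)

    fluid_pct = glucose_pct = ketone_pct = None
    if window is not None and window.resolved:
        duration = dka_duration_hours(window)
        if duration and duration > 0:
            start, end = window.diagnosis_time, window.resolution_time
            administered_l = sum(
                rx.volume_ml for rx in episode.prescriptions
                if rx.kind is PrescriptionKind.FLUID and start <= rx.start <= end
            ) / 1000.0
            fluid_pct = fluid_adherence(administered_l, duration, schedule, accrual)
            glucose_pct = monitoring_adherence(
                _count_readings(episode, Analyte.GLUCOSE, start, end), duration)
            ketone_pct = monitoring_adherence(
                _count_readings(episode, Analyte.KETONES, start, end), duration)

    def band(pct):
        return None if pct is None else within_band(pct, thresholds)

    return AdherenceResult(
        episode_code=episode.episode_code,
        frii_pct=frii_pct, fluid_pct=fluid_pct,
        glucose_pct=glucose_pct, ketone_pct=ketone_pct,
        frii_in_band=band(frii_pct), fluid_in_band=band(fluid_pct),
        glucose_in_band=band(glucose_pct), ketone_in_band=band(ketone_pct),
    )
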