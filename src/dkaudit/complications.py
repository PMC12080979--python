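"""Treatment complications and outcome metrics.

Complications are flagged at episode level over the DKA window (diagnosis
to resolution, or to discharge when the episode never resolved):
hypoglycaemia is any glucose strictly below 4 mmol/L; hypokalaemia and
hyperkalaemia are potassium readings below 3.5 or above 5.5 mmol/L, and
both may be flagged on one episode (excursions at different times).
Outcomes are the DKA duration in hours and the admission-to-discharge
length of stay in days.

Cohort quantiles use the SPSS HAVERAGE convention (Hyndman-Fan type 6,
linear interpolation at position (n+1)p), the default of the statistics
package conventionally used for this kind of audit; the convention is
configurable via ``QUANTILE_METHOD``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, List, Optional, Sequence

import numpy as np

from .ascertain import DkaWindow
from .model import Analyte, DomainError, Episode, Sex, Thresholds

log = logging.getLogger(__name__)

#: numpy quantile method; "weibull" is Hyndman-Fan type 6 (SPSS HAVERAGE).
QUANTILE_METHOD = "weibull"

COMPLICATIONS = ("hypoglycaemia", "hypokalaemia", "hyperkalaemia")


class PotassiumBand(str, Enum):
    HYPO = "hypo"
    NORMO = "normo"
    HYPER = "hyper"


@dataclass(frozen=True)
class ComplicationFlags:
    episode_code: str
    hypoglycaemia: bool
    hypokalaemia: bool
    hyperkalaemia: bool

    def get(self, which: str) -> bool:
        if which not in COMPLICATIONS:
            raise DomainError(f"unknown complication {which!r}")
        return getattr(self, which)


@dataclass(frozen=True)
class OutcomeRecord:
    episode_code: str
    length_of_stay_d: float
    dka_duration_h: Optional[float] = None

    def __post_init__(self) -> None:
        if self.length_of_stay_d < 0:
            raise DomainError("negative length of stay")
        if self.dka_duration_h is not None and self.dka_duration_h < 0:
            raise DomainError("negative DKA duration")


def _window_bounds(episode: Episode, window: DkaWindow):
    end = window.resolution_time if window.resolved else episode.discharge
    return window.diagnosis_time, end


def detect_hypoglycaemia(episode: Episode, window: DkaWindow,
                         thresholds: Thresholds = Thresholds()) -> bool:
    """Any glucose reading strictly below the hypoglycaemia threshold inside
    the DKA window (closed interval)."""
    start, end = _window_bounds(episode, window)
    readings = [o.value for o in episode.observations
                if o.analyte is Analyte.GLUCOSE and start <= o.timestamp <= end]
    if not readings:
        log.warning("episode %s: no glucose readings within the DKA window",
                    episode.episode_code)
        return False
    return any(v < thresholds.hypoglycaemia for v in readings)


def classify_potassium(value_mmol_l: float,
                       thresholds: Thresholds = Thresholds()) -> PotassiumBand:
    """Partition a potassium value: hypo (< 3.5), normo (3.5-5.5 inclusive)
    or hyper (> 5.5 mmol/L)."""
    if value_mmol_l <= 0:
        raise DomainError(f"non-positive potassium {value_mmol_l}")
    if value_mmol_l < thresholds.hypokalaemia:
        return PotassiumBand.HYPO
    if value_mmol_l > thresholds.hyperkalaemia:
        return PotassiumBand.HYPER
    return PotassiumBand.NORMO


def detect_complications(episode: Episode, window: DkaWindow,
                         thresholds: Thresholds = Thresholds()) -> ComplicationFlags:
    """Episode-level complication flags over the DKA window."""
    start, end = _window_bounds(episode, window)
    potassium = [o.value for o in episode.observations
                 if o.analyte is Analyte.POTASSIUM and start <= o.timestamp <= end]
    bands = {classify_potassium(v, thresholds) for v in potassium}
    return ComplicationFlags(
        episode_code=episode.episode_code,
        hypoglycaemia=detect_hypoglycaemia(episode, window, thresholds),
        hypokalaemia=PotassiumBand.HYPO in bands,
        hyperkalaemia=PotassiumBand.HYPER in bands,
    )


def complication_proportion(flags: Sequence[ComplicationFlags],
                            which: str) -> Optional[float]:
    """Episodes flagged with ``which`` over total episodes; ``None`` (not
    zero) for an empty list."""
    if not flags:
        return None
    return sum(f.get(which) for f in flags) / len(flags)


def length_of_stay_days(episode: Episode) -> float:
    """Admission-to-discharge interval in fractional days."""
    return (episode.discharge - episode.admission).total_seconds() / 86400.0


def quantiles(values: Sequence[float], qs=(0.25, 0.5, 0.75)) -> tuple:
    """Quantiles under the package-wide convention (see module docstring)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return tuple(None for _ in qs)
    return tuple(float(v) for v in np.quantile(arr, qs, method=QUANTILE_METHOD))


@dataclass(frozen=True)
class CohortSummary:
    n: int
    age_median: float
    age_q1: float
    age_q3: float
    n_women: int
    n_men: int
    ratio_women_to_men: str  # "1: r" with r = men / women to 2 d.p.


def summarize_cohort(episodes: Sequence[Episode]) -> Optional[CohortSummary]:
    """Cohort demographics: n, median age with IQR, sex counts, and the
    women-to-men ratio reported as "1: r"."""
    if not episodes:
        return None
    ages = [ep.age_years for ep in episodes]
    q1, med, q3 = quantiles(ages)
    n_women = sum(ep.sex is Sex.FEMALE for ep in episodes)
    n_men = len(episodes) - n_women
    ratio = sex_ratio_label(n_women, n_men)
    return CohortSummary(
        n=len(episodes), age_median=med, age_q1=q1, age_q3=q3,
        n_women=n_women, n_men=n_men, ratio_women_to_men=ratio,
    )


def sex_ratio_label(n_women: int, n_men: int) -> str:
    """Women-to-men ratio string "1: r", r = men / women to 2 d.p."""
    if n_women <= 0:
        raise DomainError("ratio undefined without women in the cohort")
    return f"1: {n_men / n_women:.2f}"
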