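"""Synthetic multi-hospital DKA cohort generator with a ground-truth table.

The real audit registry is not public, so every pipeline stage is
exercised against simulated cohorts whose structure is controlled and
recorded: per-episode adherence factors, complication flags and DKA
durations are sampled first (the *truth table*), then episode records —
timestamped lab panels, an FRIII prescription, fluid volumes, an ICD-10
discharge code — are constructed so that the scoring pipeline, run blind,
should recover exactly what was injected.

Construction guarantees, by design rather than by chance:

* the diagnosis panel satisfies the composite DKA criterion at admission;
* lab trajectories cross the resolution condition precisely at the
  intended hour, with the final two panels exactly 60 minutes apart so the
  two-consecutive-readings rule always fires (other panels are jittered);
* the FRIII rate is ``weight/10 x factor`` and the administered fluid
  volume is ``recommended(duration) x factor``, so recovered percentages
  equal the sampled factors;
* monitoring counts are chosen so each episode's realised adherence falls
  on the intended side of the 80-120 % band (infeasible draws — e.g.
  under-monitoring a 2 h episode that must still carry the readings
  resolution needs — are flipped to the opposite out-of-band side, or the
  realised label is recorded, keeping the truth table exact);
* complication excursions (glucose < 4, potassium < 3.5 or > 5.5 mmol/L)
  are injected into in-window readings.

In-band labels, complication flags and miscoding are assigned by *quota*
by default: exactly ``round(p * n)`` episodes drawn by a seeded
permutation, so configured proportions are realised exactly in every
cohort and parameter-recovery checks are sharp; per-episode ``bernoulli``
sampling is available.  Lognormal distributions are parameterised by
(median, IQR) via quantile matching.  Identical seed and config give
identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .adherence import DEFAULT_SCHEDULE, INDICATORS, FluidSchedule, \
    fluid_adherence, frii_adherence, monitoring_adherence, \
    recommended_fluid_volume, within_band
from .complications import COMPLICATIONS
from .model import (
    Analyte,
    ConfigError,
    DiabetesType,
    DischargeCode,
    Episode,
    Observation,
    Prescription,
    Sex,
    Thresholds,
)

_Z75 = 0.6744897501960817  # standard normal 75th percentile


def _lognormal_params(median: float, iqr: Tuple[float, float]) -> Tuple[float, float]:
    q1, q3 = iqr
    if not (0 < q1 < median < q3):
        raise ConfigError(f"inconsistent median/IQR: median={median}, IQR=({q1}, {q3})")
    return math.log(median), math.log(q3 / q1) / (2 * _Z75)


def parse_quarter(label: str) -> Tuple[int, int]:
    year, q = label.split("-Q")
    return int(year), int(q)


def quarter_start(label: str) -> datetime:
    year, q = parse_quarter(label)
    return datetime(year, 3 * (q - 1) + 1, 1)


def next_quarter(label: str) -> str:
    year, q = parse_quarter(label)
    return f"{year + 1}-Q1" if q == 4 else f"{year}-Q{q + 1}"


def quarter_range(first: str, last: str) -> List[str]:
    out, q = [], first
    while True:
        out.append(q)
        if q == last:
            return out
        q = next_quarter(q)
        if len(out) > 400:
            raise ConfigError(f"quarter range {first}..{last} is not increasing")


@dataclass(frozen=True)
class HospitalPlan:
    """One simulated hospital: single-letter code, onboarding quarter and
    mean episodes per active quarter (Poisson mean, or an exact count)."""

    code: str
    onboard_quarter: str
    episodes_per_quarter: float
    poisson: bool = True


#: Default layout: 11 hospitals onboarded over three years (3 in the first
#: year, 2 in the second, 6 in the third); per-quarter means reproduce the
#: per-hospital totals of a ~2000-episode, 3-year audit.
DEFAULT_HOSPITALS: Tuple[HospitalPlan, ...] = (
    HospitalPlan("A", "2020-Q1", 516 / 12),
    HospitalPlan("B", "2020-Q1", 218 / 12),
    HospitalPlan("C", "2020-Q1", 142 / 12),
    HospitalPlan("D", "2021-Q1", 163 / 8),
    HospitalPlan("E", "2021-Q1", 133 / 8),
    HospitalPlan("F", "2022-Q1", 226 / 4),
    HospitalPlan("G", "2022-Q1", 33 / 4),
    HospitalPlan("H", "2022-Q1", 106 / 4),
    HospitalPlan("I", "2022-Q1", 187 / 4),
    HospitalPlan("J", "2022-Q1", 122 / 4),
    HospitalPlan("K", "2022-Q1", 133 / 4),
)


def _default_in_band() -> Dict[str, float]:
    # mid-scale values for a cohort in which fluid and monitoring adherence
    # are the weak indicators and FRIII dosing is largely protocolised
    return {"frii": 0.80, "fluid": 0.40, "glucose": 0.40, "ketone": 0.55}


def _default_complications() -> Dict[str, float]:
    return {"hypoglycaemia": 0.10, "hypokalaemia": 0.30, "hyperkalaemia": 0.15}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    ``target_in_band`` gives, per indicator, the probability that an
    episode is scored within 80-120 % of the recommendation;
    ``off_band_spread`` scales how far off-band episodes deviate (factors
    are drawn at least 0.25 away from 1.0, i.e. clear of the band edge).
    Durations, stays, weights and ages are lognormal, parameterised by
    printed-scale medians and IQRs.
    """

    seed: int = 0
    hospitals: Tuple[HospitalPlan, ...] = DEFAULT_HOSPITALS
    study_end_quarter: str = "2022-Q4"
    weight_median_kg: float = 75.0
    weight_iqr: Tuple[float, float] = (63.0, 89.0)
    age_median: float = 45.0
    age_iqr: Tuple[float, float] = (29.0, 61.0)
    sex_ratio_men_per_woman: float = 1.29
    t1dm_fraction: float = 0.70
    t2dm_fraction: float = 0.25
    diabetes_history_fraction: float = 0.85
    target_in_band: Dict[str, float] = field(default_factory=_default_in_band)
    off_band_spread: float = 0.5
    band_sampling: str = "quota"  # or "bernoulli"
    complication_rates: Dict[str, float] = field(default_factory=_default_complications)
    duration_median_h: float = 15.0
    duration_iqr: Tuple[float, float] = (8.0, 25.0)
    los_median_d: float = 3.2
    los_iqr: Tuple[float, float] = (1.8, 6.0)
    reading_jitter_min: int = 5
    miscoded_fraction: float = 0.05
    schedule: FluidSchedule = DEFAULT_SCHEDULE
    max_duration_h: int = 96

    def __post_init__(self) -> None:
        for name, p in {**self.target_in_band, **self.complication_rates,
                        "miscoded_fraction": self.miscoded_fraction}.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {name}={p} outside [0, 1]")
        if set(self.target_in_band) != set(INDICATORS):
            raise ConfigError(f"target_in_band must cover exactly {INDICATORS}")
        if set(self.complication_rates) != set(COMPLICATIONS):
            raise ConfigError(f"complication_rates must cover exactly {COMPLICATIONS}")
        if self.band_sampling not in ("quota", "bernoulli"):
            raise ConfigError(f"unknown band_sampling {self.band_sampling!r}")
        if not 0 <= self.reading_jitter_min <= 14:
            raise ConfigError("reading_jitter_min must lie in [0, 14] minutes "
                              "(larger jitter breaks the hourly-panel construction)")
        if self.duration_median_h < 2.5:
            raise ConfigError("duration_median_h below 2.5 h cannot support the "
                              "two-consecutive-readings resolution rule")
        if self.off_band_spread <= 0:
            raise ConfigError("off_band_spread must be positive")
        _lognormal_params(self.duration_median_h, self.duration_iqr)
        _lognormal_params(self.los_median_d, self.los_iqr)
        _lognormal_params(self.weight_median_kg, self.weight_iqr)
        _lognormal_params(self.age_median, self.age_iqr)


def _quota_bool(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    out = np.zeros(n, dtype=bool)
    k = int(round(p * n))
    if k:
        out[rng.permutation(n)[:k]] = True
    return out


def _draw_labels(rng, n: int, p: float, mode: str) -> np.ndarray:
    if mode == "quota":
        return _quota_bool(rng, n, p)
    return rng.random(n) < p


def _sample_lognormal(rng, median, iqr, size=None):
    mu, sigma = _lognormal_params(median, iqr)
    return np.exp(rng.normal(mu, sigma, size=size))


def _off_band_factor(rng, spread: float) -> float:
    """A factor outside [0.8, 1.2] with a 0.05 margin from the band edge."""
    magnitude = rng.uniform(0.25, 0.25 + spread)
    if rng.random() < 0.5:
        return max(0.05, 1.0 - magnitude)
    return 1.0 + magnitude


@dataclass
class _EpisodeTruth:
    episode_code: str
    hospital_code: str
    quarter: str
    factors: Dict[str, float]
    pcts: Dict[str, Optional[float]]
    in_band: Dict[str, bool]
    complications: Dict[str, bool]
    duration_h: float
    intended_duration_h: int
    los_d: float
    miscoded: bool


def _choose_monitoring_counts(rng, factor: float, in_band_target: bool,
                              k_star: int, n_min: int, n_max: int,
                              duration_h: float) -> int:
    """Reading count whose realised adherence lands on the intended side of
    the band; flips side or accepts the realised label when infeasible."""
    if in_band_target:
        target = k_star  # exactly hourly over the realised window
    else:
        target = int(round(factor * k_star))
    n = min(max(target, n_min), n_max)

    def realised(n_):
        return n_ / duration_h * 100.0

    if in_band_target:
        # nudge toward 100% if jitter pushed the count out of band
        for _ in range(3):
            if within_band(realised(n)):
                return n
            n = n + 1 if realised(n) < 100.0 else n - 1
            n = min(max(n, n_min), n_max)
        return n
    # intended off-band: push away from 100% while feasible
    direction = -1 if factor < 1.0 else 1
    while within_band(realised(n)):
        nxt = n + direction
        if not n_min <= nxt <= n_max:
            direction = -direction  # flip to the opposite side
            nxt = n + direction
            if not n_min <= nxt <= n_max:
                break
        n = nxt
    return n


def _pick_subset(rng, pool: Sequence[int], k: int) -> List[int]:
    if k <= 0:
        return []
    if k >= len(pool):
        return list(pool)
    return sorted(rng.choice(np.asarray(pool), size=k, replace=False).tolist())


def _make_episode(rng: np.random.Generator, config: SimConfig, code: str,
                  hospital: str, quarter: str,
                  band_target: Dict[str, bool], comp_target: Dict[str, bool],
                  miscoded: bool) -> Tuple[Episode, DischargeCode, _EpisodeTruth]:
    thresholds = Thresholds()
    # demographics
    sex = Sex.MALE if rng.random() < config.sex_ratio_men_per_woman / (
        1 + config.sex_ratio_men_per_woman) else Sex.FEMALE
    age = int(np.clip(round(_sample_lognormal(rng, config.age_median, config.age_iqr)), 16, 97))
    weight = float(np.clip(round(_sample_lognormal(
        rng, config.weight_median_kg, config.weight_iqr), 1), 40.0, 180.0))
    u = rng.random()
    if u < config.t1dm_fraction:
        dm_type = DiabetesType.T1DM
    elif u < config.t1dm_fraction + config.t2dm_fraction:
        dm_type = DiabetesType.T2DM
    else:
        dm_type = DiabetesType.UNKNOWN
    has_history = bool(rng.random() < config.diabetes_history_fraction)

    # timing: admission somewhere in the quarter, diagnosis panel at admission
    q_start = quarter_start(quarter)
    q_minutes = int((quarter_start(next_quarter(quarter)) - q_start).total_seconds() // 60)
    admission = q_start + timedelta(minutes=int(rng.integers(0, q_minutes - 1)))
    t0 = admission

    duration_sample = float(_sample_lognormal(rng, config.duration_median_h, config.duration_iqr))
    k_star = int(np.clip(round(duration_sample), 2, config.max_duration_h))

    # hourly panels with jitter; the final spacing is exactly 60 min so the
    # two-consecutive-readings resolution rule always fires at panel k_star
    j = config.reading_jitter_min
    jitter = rng.integers(-j, j + 1, size=k_star + 1) if j else np.zeros(k_star + 1, int)
    jitter[0] = 0
    jitter[k_star] = jitter[k_star - 1]
    panel_times = [t0 + timedelta(minutes=60 * k + int(jitter[k])) for k in range(k_star + 1)]
    duration_h = (panel_times[k_star] - t0).total_seconds() / 3600.0

    # biochemistry trajectories: acidotic and ketotic at panel 0, resolution
    # condition holding only at the final two panels
    denom = max(k_star - 1, 1)
    ketone_vals, ph_vals, bicarb_vals, glucose_vals = [], [], [], []
    for k in range(k_star + 1):
        frac = min(k / denom, 1.0)
        if k >= k_star - 1:
            ketone_vals.append(0.4 if k == k_star - 1 else 0.3)
            ph_vals.append(7.35 if k == k_star - 1 else 7.38)
            bicarb_vals.append(19.0 if k == k_star - 1 else 20.0)
        else:
            ketone_vals.append(round(5.0 - (5.0 - 0.8) * frac, 2))
            ph_vals.append(round(7.05 + 0.20 * frac, 2))
            bicarb_vals.append(round(10.0 + 4.0 * frac, 1))
        glucose_vals.append(round(max(22.0 - 16.0 * frac, 5.5), 1))

    # adherence factors and monitoring layouts
    factors = {}
    for ind in INDICATORS:
        factors[ind] = 1.0 if band_target[ind] else _off_band_factor(rng, config.off_band_spread)

    slots = k_star + 1  # panels 0..k_star

    # glucose readings: panel 0 kept unless under-monitoring demands fewer
    g_extras_pool = list(range(0, k_star))  # half-hour slots after panel k
    n_g = _choose_monitoring_counts(
        rng, factors["glucose"], band_target["glucose"], k_star,
        n_min=0 if has_history else 1, n_max=slots + len(g_extras_pool), duration_h=duration_h)
    glucose_panels: List[int] = []
    glucose_extras: List[int] = []
    if n_g > 0:
        base = min(n_g, slots)
        glucose_panels = [0] + _pick_subset(rng, range(1, k_star + 1), base - 1)
        glucose_extras = _pick_subset(rng, g_extras_pool, n_g - base)
    if 0 not in glucose_panels:
        has_history = True  # diagnosis then rests on documented diabetes

    # ketone readings: resolution needs panels k_star-1 and k_star; the
    # diagnosis-time reading can be replaced by a urine dipstick of ++
    urine_ketones_high = False
    k_extras_pool = list(range(1, k_star))  # half-hour slots; value chosen per slot
    n_k = _choose_monitoring_counts(
        rng, factors["ketone"], band_target["ketone"], k_star,
        n_min=2, n_max=slots + len(k_extras_pool), duration_h=duration_h)
    required = [k_star - 1, k_star]
    if n_k <= 2:
        ketone_panels = list(required)
        urine_ketones_high = True
    else:
        base = min(n_k, slots)
        optional = _pick_subset(rng, range(1, k_star - 1), base - 3) if base >= 3 else []
        ketone_panels = sorted({0, *optional, *required}) if base >= 3 else list(required)
        if 0 not in ketone_panels:
            urine_ketones_high = True
    ketone_extras = _pick_subset(rng, k_extras_pool, n_k - len(ketone_panels))

    observations: List[Observation] = []

    def obs(ts, analyte, value):
        observations.append(Observation(code, ts, analyte, value))

    for k in range(k_star + 1):
        ts = panel_times[k]
        obs(ts, Analyte.PH, ph_vals[k])
        obs(ts, Analyte.BICARBONATE, bicarb_vals[k])
        obs(ts, Analyte.POTASSIUM, 4.2)
        if k in glucose_panels:
            obs(ts, Analyte.GLUCOSE, glucose_vals[k])
        if k in ketone_panels:
            obs(ts, Analyte.KETONES, ketone_vals[k])
    for k in glucose_extras:
        obs(panel_times[k] + timedelta(minutes=30), Analyte.GLUCOSE,
            round(max(glucose_vals[k] - 0.3, 5.0), 1))
    for k in ketone_extras:
        # half-hour extras: still ketotic before the final hour, clearing after
        value = 0.45 if k >= k_star - 1 else max(ketone_vals[k] - 0.1, 0.8)
        obs(panel_times[k] + timedelta(minutes=30), Analyte.KETONES, round(value, 2))

    # complication injection into in-window readings
    glucose_times = sorted({o.timestamp for o in observations if o.analyte is Analyte.GLUCOSE})
    if comp_target["hypoglycaemia"]:
        candidates = [t for t in glucose_times if t > t0]
        if candidates:
            hypo_ts = candidates[int(rng.integers(0, len(candidates)))]
            observations = [
                o if not (o.analyte is Analyte.GLUCOSE and o.timestamp == hypo_ts)
                else Observation(code, o.timestamp, Analyte.GLUCOSE, 3.2)
                for o in observations
            ]
        else:  # no post-diagnosis glucose reading scheduled: add one
            observations.append(Observation(
                code, t0 + timedelta(minutes=30), Analyte.GLUCOSE, 3.2))
    potassium_slots = list(range(1, k_star + 1))
    k_hypo_slot = k_hyper_slot = None
    if comp_target["hypokalaemia"]:
        k_hypo_slot = potassium_slots[int(rng.integers(0, len(potassium_slots)))]
    if comp_target["hyperkalaemia"]:
        remaining = [s for s in potassium_slots if s != k_hypo_slot]
        k_hyper_slot = remaining[int(rng.integers(0, len(remaining)))]
    if k_hypo_slot is not None or k_hyper_slot is not None:
        def fix_k(o):
            if o.analyte is not Analyte.POTASSIUM:
                return o
            slot = round((o.timestamp - t0).total_seconds() / 3600)
            if slot == k_hypo_slot:
                return Observation(code, o.timestamp, Analyte.POTASSIUM, 3.0)
            if slot == k_hyper_slot:
                return Observation(code, o.timestamp, Analyte.POTASSIUM, 5.8)
            return o
        observations = [fix_k(o) for o in observations]

    # prescriptions: FRIII at weight/10 x factor; fluids sized against the
    # schedule at the realised duration
    frii_rate = (weight / 10.0) * factors["frii"]
    recommended_l = recommended_fluid_volume(duration_h, config.schedule)
    administered_l = recommended_l * factors["fluid"]
    prescriptions = [
        Prescription(code, "frii", start=t0, rate_units_per_h=frii_rate),
    ]
    if administered_l > 0:
        prescriptions.append(
            Prescription(code, "fluid", start=t0, volume_ml=administered_l * 1000.0))

    los_sample = float(_sample_lognormal(rng, config.los_median_d, config.los_iqr))
    los_d = max(los_sample, duration_h / 24.0 + 0.25)
    discharge = t0 + timedelta(minutes=int(round(los_d * 1440)))
    los_d = (discharge - t0).total_seconds() / 86400.0

    episode = Episode(
        episode_code=code, hospital_code=hospital, age_years=age, sex=sex,
        diabetes_type=dm_type, has_diabetes_history=has_history,
        weight_kg=weight, admission=admission, discharge=discharge,
        observations=observations, prescriptions=prescriptions,
        urine_ketones_high=urine_ketones_high,
    )

    if miscoded:
        icd10 = "K59.0"  # non-DKA code: episode is reachable only via the FRIII list
    else:
        icd10 = {"t1dm": "E10.1", "t2dm": "E11.1", "unknown": "E14.1"}[dm_type.value]
    discharge_code = DischargeCode(code, icd10)

    n_glucose = len({o.timestamp for o in episode.observations
                     if o.analyte is Analyte.GLUCOSE and t0 <= o.timestamp <= panel_times[k_star]})
    n_ketone = len({o.timestamp for o in episode.observations
                    if o.analyte is Analyte.KETONES and t0 <= o.timestamp <= panel_times[k_star]})
    pcts = {
        "frii": frii_adherence(frii_rate, weight),
        "fluid": fluid_adherence(administered_l, duration_h, config.schedule),
        "glucose": monitoring_adherence(n_glucose, duration_h),
        "ketone": monitoring_adherence(n_ketone, duration_h),
    }
    truth = _EpisodeTruth(
        episode_code=code, hospital_code=hospital, quarter=quarter,
        factors=factors, pcts=pcts,
        in_band={ind: within_band(pcts[ind], thresholds) for ind in INDICATORS},
        complications=dict(comp_target),
        duration_h=duration_h, intended_duration_h=k_star,
        los_d=los_d, miscoded=miscoded,
    )
    return episode, discharge_code, truth


def generate_cohort(config: SimConfig = SimConfig()):
    """Generate a cohort: ``(episodes, discharge_codes, truth_table)``.

    The truth table is a DataFrame with one row per episode recording the
    sampled adherence factors, the realised per-indicator percentages and
    band labels, injected complication flags, realised DKA duration and
    length of stay, and whether the discharge code was deliberately
    miscoded (exercising the FRIII screening path).
    """
    rng = np.random.default_rng(config.seed)
    slots: List[Tuple[str, str]] = []
    for plan in config.hospitals:
        for quarter in quarter_range(plan.onboard_quarter, config.study_end_quarter):
            n = int(rng.poisson(plan.episodes_per_quarter)) if plan.poisson \
                else int(round(plan.episodes_per_quarter))
            slots.extend((plan.code, quarter) for _ in range(n))
    n_total = len(slots)

    band_labels = {ind: _draw_labels(rng, n_total, config.target_in_band[ind],
                                     config.band_sampling) for ind in INDICATORS}
    comp_labels = {c: _draw_labels(rng, n_total, config.complication_rates[c],
                                   config.band_sampling) for c in COMPLICATIONS}
    miscoded = _draw_labels(rng, n_total, config.miscoded_fraction, config.band_sampling)

    episodes, codes, truths = [], [], []
    for i, (hospital, quarter) in enumerate(slots):
        code = f"{hospital}{i:05d}"
        ep, dc, truth = _make_episode(
            rng, config, code, hospital, quarter,
            band_target={ind: bool(band_labels[ind][i]) for ind in INDICATORS},
            comp_target={c: bool(comp_labels[c][i]) for c in COMPLICATIONS},
            miscoded=bool(miscoded[i]),
        )
        episodes.append(ep)
        codes.append(dc)
        truths.append(truth)

    truth_df = pd.DataFrame([{
        "episode_code": t.episode_code,
        "hospital_code": t.hospital_code,
        "quarter": t.quarter,
        **{f"{ind}_factor": t.factors[ind] for ind in INDICATORS},
        **{f"{ind}_pct": t.pcts[ind] for ind in INDICATORS},
        **{f"{ind}_in_band": t.in_band[ind] for ind in INDICATORS},
        **{c: t.complications[c] for c in COMPLICATIONS},
        "duration_h": t.duration_h,
        "intended_duration_h": t.intended_duration_h,
        "los_d": t.los_d,
        "miscoded": t.miscoded,
    } for t in truths])
    return episodes, codes, truth_df


def truth_compare(truth: pd.DataFrame, scored) -> dict:
    """Compare a truth table against pipeline outputs (a ScoredCohort).

    Reports, per indicator: configured (truth) vs recovered in-band
    proportions, label mismatches and the largest absolute percentage-point
    discrepancy; per complication: configured vs recovered proportions and
    flag mismatches; and the largest DKA-duration discrepancy in hours.
    Raises on mismatched episode sets.
    """
    adh = scored.adherence_frame().set_index("episode_code")
    comp = scored.complications_frame().set_index("episode_code")
    win = scored.windows_frame().set_index("episode_code")
    t = truth.set_index("episode_code")
    if set(t.index) != set(adh.index):
        raise ValueError("truth table and pipeline outputs cover different episodes")
    adh, comp, win = adh.loc[t.index], comp.loc[t.index], win.loc[t.index]

    report: dict = {"indicators": {}, "complications": {}}
    worst = 0.0
    for ind in INDICATORS:
        rec = adh[f"{ind}_pct"].astype(float)
        diff = (rec - t[f"{ind}_pct"].astype(float)).abs()
        mismatches = int((adh[f"{ind}_in_band"].astype(bool) !=
                          t[f"{ind}_in_band"].astype(bool)).sum())
        entry = {
            "configured": float(t[f"{ind}_in_band"].mean()),
            "recovered": float(adh[f"{ind}_in_band"].astype(bool).mean()),
            "label_mismatches": mismatches,
            "max_abs_pct_diff": float(diff.max()),
        }
        report["indicators"][ind] = entry
        worst = max(worst, entry["max_abs_pct_diff"],
                    abs(entry["configured"] - entry["recovered"]) * 100)
    for c in COMPLICATIONS:
        mism = int((comp[c].astype(bool) != t[c].astype(bool)).sum())
        report["complications"][c] = {
            "configured": float(t[c].mean()),
            "recovered": float(comp[c].astype(bool).mean()),
            "flag_mismatches": mism,
        }
        worst = max(worst, float(mism))
    dur_diff = (win["dka_duration_h"].astype(float) - t["duration_h"]).abs()
    report["duration"] = {
        "max_abs_diff_h": float(dur_diff.max()),
        "configured_median_h": float(t["duration_h"].median()),
        "recovered_median_h": float(win["dka_duration_h"].astype(float).median()),
    }
    worst = max(worst, report["duration"]["max_abs_diff_h"])
    report["max_abs_discrepancy"] = worst
    return report


def load_sim_config(path, seed: Optional[int] = None) -> SimConfig:
    """Load a SimConfig from YAML; ``seed`` overrides the file's seed."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "hospitals" in raw:
        raw["hospitals"] = tuple(HospitalPlan(**h) for h in raw["hospitals"])
    if "schedule" in raw:
        s = raw["schedule"]
        raw["schedule"] = FluidSchedule(
            bolus_ml=float(s.get("bolus_ml", DEFAULT_SCHEDULE.bolus_ml)),
            bags=tuple((float(v), float(h)) for v, h in s.get("bags", DEFAULT_SCHEDULE.bags)),
            continuation=tuple(s.get("continuation", DEFAULT_SCHEDULE.continuation)),
        )
    for key in ("weight_iqr", "age_iqr", "duration_iqr", "los_iqr"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if seed is not None:
        raw["seed"] = int(seed)
    return SimConfig(**raw)
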