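"""Flat-file cohort readers/writers and YAML configuration.

The registry is exchanged as four CSV tables:

* ``episodes.csv`` — one row per admission (demographics, weight, stay).
* ``observations.csv`` — timestamped analyte readings.
* ``prescriptions.csv`` — FRIII rates and fluid volumes.
* ``discharge_codes.csv`` — ICD-10 discharge diagnoses (screening input;
  codes may reference episodes outside the supplied cohort, e.g. a
  hospital-wide coding extract).

Validation is total: a missing column raises :class:`SchemaError`, a bad
cell raises :class:`RowValidationError` carrying the file, row number and
column, and an observation or prescription referencing an unknown episode
raises :class:`OrphanRecordError`.  Writing then reading a valid cohort is
the identity on every field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from .adherence import DEFAULT_SCHEDULE, FluidSchedule
from .model import (
    CohortValidationError,
    ConfigError,
    DischargeCode,
    Episode,
    Observation,
    OrphanRecordError,
    Prescription,
    RowValidationError,
    SchemaError,
    Thresholds,
)

log = logging.getLogger(__name__)

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M"

EPISODE_COLUMNS = [
    "episode_code", "hospital_code", "age_years", "sex", "diabetes_type",
    "has_diabetes_history", "weight_kg", "admission", "discharge",
]
OPTIONAL_EPISODE_COLUMNS = ["urine_ketones_high", "confirmed"]
OBSERVATION_COLUMNS = ["episode_code", "timestamp", "analyte", "value"]
PRESCRIPTION_COLUMNS = ["episode_code", "kind", "rate_units_per_h", "volume_ml", "start"]
CODE_COLUMNS = ["episode_code", "icd10"]

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def _parse_timestamp(source, row: int, column: str, raw: str) -> datetime:
    for fmt in (TIMESTAMP_FORMAT, "%Y-%m-%dT%H:%M:%S"):
        try:
            return datetime.strptime(raw, fmt)
        except ValueError:
            continue
    raise RowValidationError(source, row, column, f"unparseable timestamp {raw!r}")


def _parse_float(source, row: int, column: str, raw: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise RowValidationError(source, row, column, f"non-numeric value {raw!r}") from None


def _parse_bool(source, row: int, column: str, raw: str) -> bool:
    low = raw.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise RowValidationError(source, row, column, f"non-boolean value {raw!r}")


def read_cohort(episodes_path, observations_path, prescriptions_path, codes_path):
    """Read the four cohort tables and return ``(episodes, discharge_codes)``.

    Observations and prescriptions are attached to their episode;
    observations are sorted ascending by timestamp (stable, so same-minute
    readings keep file order).  Row counts are conserved.
    """
    ep_df = _read_table(episodes_path, EPISODE_COLUMNS)
    raw_episodes: dict[str, dict] = {}
    order: list[str] = []
    for i, rec in enumerate(ep_df.to_dict("records")):
        row = i + 2  # header is line 1
        code = rec["episode_code"]
        if not code:
            raise RowValidationError(episodes_path, row, "episode_code", "empty code")
        if code in raw_episodes:
            raise RowValidationError(episodes_path, row, "episode_code", f"duplicate code {code!r}")
        kwargs = dict(
            episode_code=code,
            hospital_code=rec["hospital_code"],
            age_years=int(_parse_float(episodes_path, row, "age_years", rec["age_years"])),
            sex=rec["sex"],
            diabetes_type=rec["diabetes_type"],
            has_diabetes_history=_parse_bool(
                episodes_path, row, "has_diabetes_history", rec["has_diabetes_history"]),
            weight_kg=_parse_float(episodes_path, row, "weight_kg", rec["weight_kg"]),
            admission=_parse_timestamp(episodes_path, row, "admission", rec["admission"]),
            discharge=_parse_timestamp(episodes_path, row, "discharge", rec["discharge"]),
            observations=[],
            prescriptions=[],
        )
        if rec.get("urine_ketones_high", ""):
            kwargs["urine_ketones_high"] = _parse_bool(
                episodes_path, row, "urine_ketones_high", rec["urine_ketones_high"])
        if rec.get("confirmed", ""):
            kwargs["confirmed"] = _parse_bool(episodes_path, row, "confirmed", rec["confirmed"])
        try:
            # validate scalar fields early for a row-addressed diagnostic
            Episode(**{**kwargs, "observations": [], "prescriptions": []})
        except ValueError as exc:
            raise RowValidationError(episodes_path, row, "episode", str(exc)) from None
        raw_episodes[code] = kwargs
        order.append(code)

    obs_df = _read_table(observations_path, OBSERVATION_COLUMNS)
    for i, rec in enumerate(obs_df.to_dict("records")):
        row = i + 2
        code = rec["episode_code"]
        if code not in raw_episodes:
            raise OrphanRecordError(
                f"{observations_path}, row {row}: observation references unknown episode {code!r}")
        try:
            obs = Observation(
                episode_code=code,
                timestamp=_parse_timestamp(observations_path, row, "timestamp", rec["timestamp"]),
                analyte=rec["analyte"],
                value=_parse_float(observations_path, row, "value", rec["value"]),
            )
        except ValueError as exc:
            if isinstance(exc, RowValidationError):
                raise
            raise RowValidationError(observations_path, row, "value", str(exc)) from None
        raw_episodes[code]["observations"].append(obs)

    rx_df = _read_table(prescriptions_path, PRESCRIPTION_COLUMNS)
    for i, rec in enumerate(rx_df.to_dict("records")):
        row = i + 2
        code = rec["episode_code"]
        if code not in raw_episodes:
            raise OrphanRecordError(
                f"{prescriptions_path}, row {row}: prescription references unknown episode {code!r}")
        rate = rec["rate_units_per_h"]
        vol = rec["volume_ml"]
        try:
            rx = Prescription(
                episode_code=code,
                kind=rec["kind"],
                start=_parse_timestamp(prescriptions_path, row, "start", rec["start"]),
                rate_units_per_h=_parse_float(prescriptions_path, row, "rate_units_per_h", rate)
                if rate else None,
                volume_ml=_parse_float(prescriptions_path, row, "volume_ml", vol) if vol else None,
            )
        except ValueError as exc:
            if isinstance(exc, RowValidationError):
                raise
            raise RowValidationError(prescriptions_path, row, "kind", str(exc)) from None
        raw_episodes[code]["prescriptions"].append(rx)

    code_df = _read_table(codes_path, CODE_COLUMNS)
    codes = []
    for i, rec in enumerate(code_df.to_dict("records")):
        row = i + 2
        try:
            codes.append(DischargeCode(episode_code=rec["episode_code"], icd10=rec["icd10"]))
        except ValueError as exc:
            raise RowValidationError(codes_path, row, "icd10", str(exc)) from None

    episodes = [Episode(**raw_episodes[code]) for code in order]
    return episodes, codes


def _fmt_ts(ts: datetime) -> str:
    return ts.strftime(TIMESTAMP_FORMAT)


def _fmt_num(v: Optional[float]) -> str:
    if v is None:
        return ""
    return repr(float(v))


def _fmt_bool(v: Optional[bool]) -> str:
    if v is None:
        return ""
    return "true" if v else "false"


def write_cohort(episodes: Sequence[Episode], directory,
                 codes: Iterable[DischargeCode] = ()) -> dict:
    """Write the four cohort CSVs under ``directory``; returns name->path.

    Inverse of :func:`read_cohort` on valid cohorts: numeric cells are
    written with ``repr`` so doubles round-trip exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    ep_rows, obs_rows, rx_rows = [], [], []
    for ep in episodes:
        ep_rows.append({
            "episode_code": ep.episode_code,
            "hospital_code": ep.hospital_code,
            "age_years": ep.age_years,
            "sex": ep.sex.value,
            "diabetes_type": ep.diabetes_type.value,
            "has_diabetes_history": _fmt_bool(ep.has_diabetes_history),
            "weight_kg": _fmt_num(ep.weight_kg),
            "admission": _fmt_ts(ep.admission),
            "discharge": _fmt_ts(ep.discharge),
            "urine_ketones_high": _fmt_bool(ep.urine_ketones_high),
            "confirmed": _fmt_bool(ep.confirmed),
        })
        for o in ep.observations:
            obs_rows.append({
                "episode_code": o.episode_code,
                "timestamp": _fmt_ts(o.timestamp),
                "analyte": o.analyte.value,
                "value": _fmt_num(o.value),
            })
        for rx in ep.prescriptions:
            rx_rows.append({
                "episode_code": rx.episode_code,
                "kind": rx.kind.value,
                "rate_units_per_h": _fmt_num(rx.rate_units_per_h),
                "volume_ml": _fmt_num(rx.volume_ml),
                "start": _fmt_ts(rx.start),
            })
    code_rows = [{"episode_code": c.episode_code, "icd10": c.icd10} for c in codes]

    paths = {}
    for name, rows, cols in (
        ("episodes", ep_rows, EPISODE_COLUMNS + OPTIONAL_EPISODE_COLUMNS),
        ("observations", obs_rows, OBSERVATION_COLUMNS),
        ("prescriptions", rx_rows, PRESCRIPTION_COLUMNS),
        ("discharge_codes", code_rows, CODE_COLUMNS),
    ):
        path = directory / f"{name}.csv"
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False, lineterminator="\n")
        paths[name] = path
    return paths


def cohort_paths(directory) -> tuple:
    """The four canonical file paths inside a cohort directory."""
    d = Path(directory)
    return (d / "episodes.csv", d / "observations.csv",
            d / "prescriptions.csv", d / "discharge_codes.csv")


@dataclass(frozen=True)
class AppConfig:
    """Pipeline configuration: thresholds, fluid schedule and detector knobs.

    ``lookback_hours`` bounds how stale a reading may be when criteria are
    evaluated at a time point; ``resolution_pair_minutes`` +/-
    ``resolution_tolerance_minutes`` define what counts as two consecutive
    hourly readings; ``resolution_stamp`` picks which reading of the
    qualifying pair timestamps the resolution.
    """

    thresholds: Thresholds = Thresholds()
    schedule: FluidSchedule = DEFAULT_SCHEDULE
    accrual: str = "whole_bag"
    lookback_hours: float = 6.0
    resolution_pair_minutes: float = 60.0
    resolution_tolerance_minutes: float = 15.0
    resolution_stamp: str = "second"
    yates_correction: bool = False

    def __post_init__(self) -> None:
        if self.accrual not in ("whole_bag", "pro_rata"):
            raise ConfigError(f"unknown accrual mode {self.accrual!r}")
        if self.resolution_stamp not in ("first", "second"):
            raise ConfigError(f"unknown resolution_stamp {self.resolution_stamp!r}")
        if self.lookback_hours <= 0:
            raise ConfigError("lookback_hours must be positive")


DEFAULT_CONFIG = AppConfig()


def load_config(path) -> AppConfig:
    """Load an :class:`AppConfig` from YAML, falling back to defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    thresholds = Thresholds(**raw.get("thresholds", {}))
    sched_raw = raw.get("fluid_schedule", {})
    schedule = FluidSchedule(
        bolus_ml=float(sched_raw.get("bolus_ml", DEFAULT_SCHEDULE.bolus_ml)),
        bags=tuple((float(v), float(h)) for v, h in sched_raw.get("bags", DEFAULT_SCHEDULE.bags)),
        continuation=tuple(sched_raw.get("continuation", DEFAULT_SCHEDULE.continuation)),
    )
    asc = raw.get("ascertainment", {})
    analysis = raw.get("analysis", {})
    return AppConfig(
        thresholds=thresholds,
        schedule=schedule,
        accrual=sched_raw.get("accrual", "whole_bag"),
        lookback_hours=float(asc.get("lookback_hours", 6.0)),
        resolution_pair_minutes=float(asc.get("pair_minutes", 60.0)),
        resolution_tolerance_minutes=float(asc.get("pair_tolerance_minutes", 15.0)),
        resolution_stamp=asc.get("resolution_stamp", "second"),
        yates_correction=bool(analysis.get("yates_correction", False)),
    )
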