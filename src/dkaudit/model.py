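"""Domain model for DKA audit episodes.

An *episode* is one hospital admission treated for diabetic ketoacidosis
(DKA): demographics, the weight used for insulin dosing, admission and
discharge times, and the timestamped laboratory observations and
prescriptions recorded during the stay.  All downstream stages (case
ascertainment, adherence scoring, complication detection, quarterly
aggregation) operate on these types only.

Units follow UK inpatient convention: glucose, ketones, bicarbonate and
potassium in mmol/L; pH dimensionless; systolic blood pressure in mmHg;
insulin infusion rates in units/h; fluid volumes in mL; weight in kg.
Timestamps are timezone-naive local times at minute resolution.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from typing import Optional


class Analyte(str, Enum):
    """Kind of measured quantity carried by an :class:`Observation`."""

    GLUCOSE = "glucose"
    KETONES = "ketones"
    PH = "ph"
    BICARBONATE = "bicarbonate"
    POTASSIUM = "potassium"
    SBP = "sbp"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class DiabetesType(str, Enum):
    T1DM = "t1dm"
    T2DM = "t2dm"
    UNKNOWN = "unknown"


class PrescriptionKind(str, Enum):
    FRIII = "frii"
    FLUID = "fluid"


class CohortValidationError(ValueError):
    """Base class for cohort file/record validation failures."""


class SchemaError(CohortValidationError):
    """A required column is missing from an input table."""


class RowValidationError(CohortValidationError):
    """A single row failed validation; carries source, row number and column."""

    def __init__(self, source: str, row: int, column: str, message: str):
        self.source = str(source)
        self.row = row
        self.column = column
        super().__init__(f"{source}, row {row}, column '{column}': {message}")


class OrphanRecordError(CohortValidationError):
    """A record references an episode code absent from the episodes table."""


class DomainError(ValueError):
    """An argument lies outside the domain of an operation."""


class ConfigError(ValueError):
    """A configuration is internally inconsistent or infeasible."""


#: Plausible range for blood pH; values outside it are charting errors.
PH_RANGE = (6.5, 8.0)

ICD10_PATTERN = re.compile(r"^[A-Z]\d{2}(\.\d)?$")

#: ICD-10 discharge codes used to screen for DKA: diabetes (E10-E14) with
#: coma (.0) or with ketoacidosis (.1).
DKA_ICD10_CODES = frozenset(f"E1{i}.{j}" for i in range(5) for j in (0, 1))


@dataclass(frozen=True)
class Observation:
    """One timestamped measurement of a single analyte."""

    episode_code: str
    timestamp: datetime
    analyte: Analyte
    value: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "analyte", Analyte(self.analyte))
        object.__setattr__(self, "value", float(self.value))
        if not math.isfinite(self.value):
            raise DomainError(f"non-finite value for {self.analyte.value}")
        if self.analyte is Analyte.PH:
            lo, hi = PH_RANGE
            if not lo <= self.value <= hi:
                raise DomainError(f"pH {self.value} outside plausible range [{lo}, {hi}]")
        elif self.value < 0:
            raise DomainError(f"negative value {self.value} for {self.analyte.value}")


@dataclass(frozen=True)
class Prescription:
    """An insulin-infusion (FRIII) rate or a fluid volume with its start time.

    Exactly one of ``rate_units_per_h`` (for ``frii`` records) and
    ``volume_ml`` (for ``fluid`` records) is populated.
    """

    episode_code: str
    kind: PrescriptionKind
    start: datetime
    rate_units_per_h: Optional[float] = None
    volume_ml: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", PrescriptionKind(self.kind))
        if self.kind is PrescriptionKind.FRIII:
            if self.rate_units_per_h is None or self.volume_ml is not None:
                raise DomainError("frii prescription carries a rate and no volume")
            object.__setattr__(self, "rate_units_per_h", float(self.rate_units_per_h))
            if not math.isfinite(self.rate_units_per_h) or self.rate_units_per_h < 0:
                raise DomainError(f"invalid FRIII rate {self.rate_units_per_h}")
        else:
            if self.volume_ml is None or self.rate_units_per_h is not None:
                raise DomainError("fluid prescription carries a volume and no rate")
            object.__setattr__(self, "volume_ml", float(self.volume_ml))
            if not math.isfinite(self.volume_ml) or self.volume_ml < 0:
                raise DomainError(f"invalid fluid volume {self.volume_ml}")


@dataclass
class Episode:
    """One DKA admission with its attached observations and prescriptions.

    ``urine_ketones_high`` records a urine dipstick of ++ or more, which may
    substitute for the blood-ketone arm of the diagnosis (never of
    resolution).  ``confirmed`` reproduces manual case adjudication: ``False``
    vetoes the episode from the DKA case set, ``None``/``True`` defer to the
    automatic detector.
    """

    episode_code: str
    hospital_code: str
    age_years: int
    sex: Sex
    diabetes_type: DiabetesType
    has_diabetes_history: bool
    weight_kg: float
    admission: datetime
    discharge: datetime
    observations: list = field(default_factory=list)
    prescriptions: list = field(default_factory=list)
    urine_ketones_high: bool = False
    confirmed: Optional[bool] = None

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        self.diabetes_type = DiabetesType(self.diabetes_type)
        self.age_years = int(self.age_years)
        self.weight_kg = float(self.weight_kg)
        if self.age_years < 16:
            raise DomainError(f"age {self.age_years} below the >=16 inclusion criterion")
        if not math.isfinite(self.weight_kg) or self.weight_kg <= 0:
            raise DomainError(f"non-positive weight {self.weight_kg}")
        if self.discharge < self.admission:
            raise DomainError("discharge precedes admission")
        # stable sort: ties at the same minute keep file order
        self.observations = sorted(self.observations, key=lambda o: o.timestamp)

    def observations_of(self, analyte: Analyte) -> list:
        a = Analyte(analyte)
        return [o for o in self.observations if o.analyte is a]


@dataclass(frozen=True)
class DischargeCode:
    """An ICD-10 discharge-diagnosis code attached to an episode."""

    episode_code: str
    icd10: str

    def __post_init__(self) -> None:
        if not ICD10_PATTERN.match(self.icd10):
            raise DomainError(f"malformed ICD-10 code {self.icd10!r}")


@dataclass(frozen=True)
class Thresholds:
    """Biochemical thresholds of the national (JBDS-IP) DKA guideline.

    ``dka_*`` define diagnosis (glucose > 11 mmol/L or known diabetes, AND
    ketones > 3 mmol/L, AND pH < 7.30 or bicarbonate < 15 mmol/L);
    ``res_*`` define resolution (pH > 7.30 or bicarbonate > 18 mmol/L, with
    ketones < 0.6 mmol/L, sustained over two consecutive hours);
    complication cut-offs and the 80-120 % adherence band complete the set.
    """

    dka_glucose: float = 11.0
    dka_ketones: float = 3.0
    dka_ph: float = 7.30
    dka_bicarbonate: float = 15.0
    res_ph: float = 7.30
    res_bicarbonate: float = 18.0
    res_ketones: float = 0.6
    hypoglycaemia: float = 4.0
    hypokalaemia: float = 3.5
    hyperkalaemia: float = 5.5
    frii_rate_per_kg: float = 0.1
    band_low: float = 80.0
    band_high: float = 120.0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ConfigError(f"threshold {name} must be a positive number, got {v!r}")
        if self.band_low >= self.band_high:
            raise ConfigError("band_low must be below band_high")


DEFAULT_THRESHOLDS = Thresholds()
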