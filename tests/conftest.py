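"""Shared fixtures: episode builders and reference synthetic cohorts."""

from __future__ import annotations

from datetime import datetime, timedelta

import pytest
from hypothesis import HealthCheck, settings

from dkaudit.model import Episode, Observation, Prescription
from dkaudit.pipeline import score_cohort
from dkaudit.simulate import HospitalPlan, SimConfig, generate_cohort

settings.register_profile(
    "det", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("det")

T0 = datetime(2022, 3, 10, 10, 0)


def build_episode(readings=(), *, code="ep1", hospital="A", age=40, sex="female",
                  diabetes_type="t1dm", history=False, weight=70.0,
                  admission=T0, discharge_hours=72.0, prescriptions=(),
                  urine_ketones_high=False, confirmed=None) -> Episode:
    """Episode from compact readings: (minutes_after_admission, analyte, value)."""
    obs = [Observation(code, admission + timedelta(minutes=m), analyte, value)
           for m, analyte, value in readings]
    return Episode(
        episode_code=code, hospital_code=hospital, age_years=age, sex=sex,
        diabetes_type=diabetes_type, has_diabetes_history=history,
        weight_kg=weight, admission=admission,
        discharge=admission + timedelta(hours=discharge_hours),
        observations=obs, prescriptions=list(prescriptions),
        urine_ketones_high=urine_ketones_high, confirmed=confirmed,
    )


@pytest.fixture
def episode_builder():
    return build_episode


def rx_frii(code, rate, start):
    return Prescription(code, "frii", start=start, rate_units_per_h=rate)


def rx_fluid(code, volume_ml, start):
    return Prescription(code, "fluid", start=start, volume_ml=volume_ml)


#: Conditions for the parameter-recovery check: a 500-episode cohort with
#: configured in-band proportions {0.2, 0.6, 0.9} and complication rates
#: {0.05, 0.2}, spread over two hospitals and five quarters.
RECOVERY_CONFIG = SimConfig(
    seed=0,
    hospitals=(
        HospitalPlan("A", "2021-Q4", 50, poisson=False),
        HospitalPlan("B", "2021-Q4", 50, poisson=False),
    ),
    study_end_quarter="2022-Q4",
    target_in_band={"frii": 0.9, "fluid": 0.6, "glucose": 0.2, "ketone": 0.6},
    complication_rates={"hypoglycaemia": 0.05, "hypokalaemia": 0.2,
                        "hyperkalaemia": 0.05},
)


@pytest.fixture(scope="session")
def recovery_cohort():
    episodes, codes, truth = generate_cohort(RECOVERY_CONFIG)
    return episodes, codes, truth


@pytest.fixture(scope="session")
def recovery_scored(recovery_cohort):
    episodes, codes, _ = recovery_cohort
    return score_cohort(episodes, codes)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact two-hospital cohort for structural tests."""
    config = SimConfig(
        seed=7,
        hospitals=(
            HospitalPlan("A", "2022-Q1", 12, poisson=False),
            HospitalPlan("B", "2022-Q2", 9, poisson=False),
        ),
        study_end_quarter="2022-Q4",
    )
    return generate_cohort(config)
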