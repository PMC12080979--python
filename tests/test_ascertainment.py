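"""Screening, diagnosis/resolution detection, and duration arithmetic.

The detectors are checked against independent brute-force oracles that
re-derive the composite criteria by filtering the raw reading lists at
every candidate time point (and every candidate pair, for resolution).
"""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dkaudit.ascertain import (
    DkaWindow,
    detect_diagnosis,
    detect_resolution,
    dka_duration_hours,
    meets_dka_criteria,
    screen_candidates,
)
from dkaudit.model import DischargeCode, Episode, Observation, Thresholds

from conftest import T0, build_episode

H = timedelta(hours=1)


# --- independent oracles ---------------------------------------------------

def oracle_latest(episode, analyte, at, lookback_h):
    hits = [o.value for o in episode.observations
            if o.analyte.value == analyte
            and o.timestamp <= at
            and (at - o.timestamp) <= timedelta(hours=lookback_h)
            and o.timestamp == max(
                p.timestamp for p in episode.observations
                if p.analyte.value == analyte and p.timestamp <= at
                and (at - p.timestamp) <= timedelta(hours=lookback_h))]
    return hits[-1] if hits else None


def oracle_meets(episode, at, thr, lookback_h):
    g = oracle_latest(episode, "glucose", at, lookback_h)
    k = oracle_latest(episode, "ketones", at, lookback_h)
    ph = oracle_latest(episode, "ph", at, lookback_h)
    bic = oracle_latest(episode, "bicarbonate", at, lookback_h)
    glucose_arm = True if episode.has_diabetes_history else (
        None if g is None else g > thr.dka_glucose)
    if k is not None:
        ketone_arm = (k > thr.dka_ketones) or episode.urine_ketones_high
    else:
        ketone_arm = True if episode.urine_ketones_high else None
    if ph is None and bic is None:
        acid_arm = None
    else:
        acid_arm = ((ph is not None and ph < thr.dka_ph)
                    or (bic is not None and bic < thr.dka_bicarbonate))
    arms = [glucose_arm, ketone_arm, acid_arm]
    if False in arms:
        return False
    if None in arms:
        return None
    return True


def oracle_diagnosis(episode, thr, lookback_h=6.0):
    for t in sorted({o.timestamp for o in episode.observations}):
        if oracle_meets(episode, t, thr, lookback_h) is True:
            return t
    return None


def oracle_resolution_ok(episode, at, thr, lookback_h):
    k = oracle_latest(episode, "ketones", at, lookback_h)
    ph = oracle_latest(episode, "ph", at, lookback_h)
    bic = oracle_latest(episode, "bicarbonate", at, lookback_h)
    if k is None or (ph is None and bic is None):
        return False
    return (k < thr.res_ketones) and (
        (ph is not None and ph > thr.res_ph)
        or (bic is not None and bic > thr.res_bicarbonate))


def oracle_resolution(episode, diagnosis, thr, lookback_h=6.0):
    times = sorted({o.timestamp for o in episode.observations
                    if diagnosis < o.timestamp <= episode.discharge})
    best = None
    for i, t1 in enumerate(times):
        for t2 in times[i + 1:]:
            gap = t2 - t1
            if (timedelta(minutes=45) <= gap <= timedelta(minutes=75)
                    and oracle_resolution_ok(episode, t1, thr, lookback_h)
                    and oracle_resolution_ok(episode, t2, thr, lookback_h)):
                if best is None or t2 < best:
                    best = t2
    return best


# --- screening -------------------------------------------------------------

def test_screen_union_and_dedup():
    codes = [DischargeCode("ep1", "E10.1")]
    assert screen_candidates(codes, {"ep2"}) == {"ep1", "ep2"}
    assert screen_candidates(codes, {"ep1"}) == {"ep1"}


def test_screen_excludes_non_dka_codes():
    assert screen_candidates([DischargeCode("ep3", "I21.0")], set()) == set()
    assert screen_candidates([], set()) == set()


# --- criteria at a time point ----------------------------------------------

@pytest.mark.parametrize("readings,history,expected", [
    # glucose, ketones and acidosis all present and positive
    ([(0, "glucose", 12.0), (0, "ketones", 3.5), (0, "ph", 7.25)], False, True),
    # glucose arm fails without documented diabetes
    ([(0, "glucose", 10.0), (0, "ketones", 4.0), (0, "ph", 7.2)], False, False),
    # diabetes history substitutes for hyperglycaemia; bicarbonate arm carries
    ([(0, "glucose", 9.0), (0, "ketones", 3.2), (0, "bicarbonate", 14.0),
      (0, "ph", 7.35)], True, True),
])
def test_dka_criteria_worked_cases(readings, history, expected):
    ep = build_episode(readings, history=history)
    assert meets_dka_criteria(ep, T0) is expected


def test_missing_ketone_reading_is_indeterminate_not_false():
    ep = build_episode([(0, "glucose", 15.0), (0, "ph", 7.1)])
    assert meets_dka_criteria(ep, T0) is None
    # but a definite failure elsewhere short-circuits to False
    ep2 = build_episode([(0, "glucose", 15.0), (0, "ph", 7.4),
                         (0, "bicarbonate", 20.0)])
    assert meets_dka_criteria(ep2, T0) is False


def test_stale_readings_ignored():
    """A reading older than the lookback window cannot support a diagnosis."""
    ep = build_episode([(0, "glucose", 20.0), (0, "ketones", 5.0), (0, "ph", 7.1)])
    later = T0 + timedelta(hours=7)
    assert meets_dka_criteria(ep, later) is None
    assert meets_dka_criteria(ep, later, lookback_hours=8.0) is True


# --- diagnosis and resolution ----------------------------------------------

def test_diagnosis_at_third_reading_matches_linear_scan():
    ep = build_episode([
        (0, "glucose", 10.0), (0, "ketones", 2.0), (0, "ph", 7.35),
        (60, "glucose", 13.0), (60, "ketones", 2.5), (60, "ph", 7.32),
        (120, "glucose", 15.0), (120, "ketones", 3.5), (120, "ph", 7.25),
    ])
    expected = T0 + 2 * H
    assert detect_diagnosis(ep) == expected == oracle_diagnosis(ep, Thresholds())


def test_diagnosis_at_first_reading_and_never():
    sick = build_episode([(0, "glucose", 15.0), (0, "ketones", 4.0), (0, "ph", 7.1)])
    assert detect_diagnosis(sick) == T0
    well = build_episode([(0, "glucose", 8.0), (0, "ketones", 0.5), (0, "ph", 7.4)])
    assert detect_diagnosis(well) is None
    assert detect_diagnosis(build_episode([])) is None


def test_manual_adjudication_veto():
    sick = build_episode([(0, "glucose", 15.0), (0, "ketones", 4.0), (0, "ph", 7.1)],
                         confirmed=False)
    assert detect_diagnosis(sick) is None


def test_resolution_on_qualifying_pair():
    """Qualifying readings at 14:00 and 15:00 resolve at 15:00."""
    ep = build_episode([
        (0, "glucose", 18.0), (0, "ketones", 5.0), (0, "ph", 7.1),
        (240, "ketones", 0.4), (240, "ph", 7.35),   # 14:00
        (300, "ketones", 0.3), (300, "ph", 7.38),   # 15:00
    ])
    diag = detect_diagnosis(ep)
    assert diag == T0
    assert detect_resolution(ep, diag) == T0 + 5 * H
    assert detect_resolution(ep, diag, stamp="first") == T0 + 4 * H


def test_resolution_after_relapse_matches_pair_scan():
    """A single qualifying reading followed by a ketone relapse does not
    resolve; the detector keeps scanning for the next sustained pair."""
    ep = build_episode([
        (0, "glucose", 18.0), (0, "ketones", 5.0), (0, "ph", 7.1),
        (60, "ketones", 0.4), (60, "ph", 7.35),
        (120, "ketones", 1.2), (120, "ph", 7.35),   # relapse
        (180, "ketones", 0.5), (180, "ph", 7.36),
        (240, "ketones", 0.4), (240, "ph", 7.38),
    ])
    diag = detect_diagnosis(ep)
    got = detect_resolution(ep, diag)
    assert got == T0 + 4 * H
    assert got == oracle_resolution(ep, diag, Thresholds())


def test_resolution_absent_when_biochemistry_never_normalises():
    ep = build_episode([
        (0, "glucose", 18.0), (0, "ketones", 5.0), (0, "ph", 7.1),
        (60, "ketones", 2.0), (60, "ph", 7.2),
        (120, "ketones", 1.5), (120, "ph", 7.25),
    ])
    assert detect_resolution(ep, T0) is None


@pytest.mark.parametrize("start,end,hours", [
    (datetime(2022, 5, 2, 10, 0), datetime(2022, 5, 2, 15, 0), 5.0),
    (datetime(2022, 5, 2, 22, 30), datetime(2022, 5, 3, 8, 18), 9.8),
    (datetime(2022, 5, 2, 10, 0), datetime(2022, 5, 2, 10, 0), 0.0),
])
def test_duration_arithmetic(start, end, hours):
    window = DkaWindow("x", start, end)
    assert dka_duration_hours(window) == pytest.approx(hours)


def test_duration_absent_when_unresolved():
    assert dka_duration_hours(DkaWindow("x", T0)) is None


# --- randomised oracle equivalence and invariants --------------------------

def random_episode(rng) -> Episode:
    n = int(rng.integers(3, 50))
    readings = []
    for _ in range(n):
        minute = int(rng.integers(0, 48 * 60))
        kind = rng.choice(["glucose", "ketones", "ph", "bicarbonate", "potassium"])
        value = {
            "glucose": lambda: round(float(rng.uniform(2.0, 28.0)), 1),
            "ketones": lambda: round(float(rng.uniform(0.0, 7.0)), 2),
            "ph": lambda: round(float(rng.uniform(6.9, 7.6)), 2),
            "bicarbonate": lambda: round(float(rng.uniform(5.0, 30.0)), 1),
            "potassium": lambda: round(float(rng.uniform(2.5, 6.5)), 1),
        }[kind]()
        readings.append((minute, kind, value))
    return build_episode(
        readings, history=bool(rng.random() < 0.4),
        urine_ketones_high=bool(rng.random() < 0.2), discharge_hours=48.0)


def random_thresholds(rng) -> Thresholds:
    return Thresholds(
        dka_glucose=float(rng.uniform(9, 14)),
        dka_ketones=float(rng.uniform(2, 4)),
        dka_ph=float(rng.uniform(7.2, 7.35)),
        dka_bicarbonate=float(rng.uniform(12, 18)),
        res_ph=float(rng.uniform(7.25, 7.4)),
        res_bicarbonate=float(rng.uniform(16, 20)),
        res_ketones=float(rng.uniform(0.4, 1.0)),
    )


def test_detectors_match_brute_force_on_random_episodes():
    rng = np.random.default_rng(42)
    checked_resolutions = 0
    for _ in range(300):
        ep = random_episode(rng)
        thr = random_thresholds(rng)
        diag = detect_diagnosis(ep, thr)
        assert diag == oracle_diagnosis(ep, thr)
        if diag is not None:
            got = detect_resolution(ep, diag, thr)
            assert got == oracle_resolution(ep, diag, thr)
            checked_resolutions += got is not None
    assert checked_resolutions > 5  # the sweep exercises the resolution path


def test_tightening_resolution_ketones_never_resolves_earlier():
    rng = np.random.default_rng(3)
    for _ in range(100):
        ep = random_episode(rng)
        diag = detect_diagnosis(ep)
        if diag is None:
            continue
        loose = detect_resolution(ep, diag, Thresholds(res_ketones=0.8))
        tight = detect_resolution(ep, diag, Thresholds(res_ketones=0.5))
        if tight is not None:
            assert loose is not None and tight >= loose


@given(st.integers(-10_000, 10_000))
def test_duration_invariant_under_time_translation(shift_minutes):
    base = DkaWindow("x", T0, T0 + timedelta(hours=9, minutes=48))
    delta = timedelta(minutes=shift_minutes)
    shifted = DkaWindow("x", base.diagnosis_time + delta,
                        base.resolution_time + delta)
    assert dka_duration_hours(shifted) == dka_duration_hours(base)


def test_detection_translation_invariance():
    """Shifting every timestamp shifts diagnosis and resolution equally."""
    rng = np.random.default_rng(9)
    for _ in range(20):
        ep = random_episode(rng)
        delta = timedelta(minutes=int(rng.integers(-5000, 5000)))
        shifted = build_episode(
            [], history=ep.has_diabetes_history,
            urine_ketones_high=ep.urine_ketones_high,
            admission=ep.admission + delta, discharge_hours=48.0)
        shifted.observations = sorted(
            [Observation(ep.episode_code, o.timestamp + delta, o.analyte, o.value)
             for o in ep.observations], key=lambda o: o.timestamp)
        diag, diag_s = detect_diagnosis(ep), detect_diagnosis(shifted)
        if diag is None:
            assert diag_s is None
            continue
        assert diag_s == diag + delta
        res = detect_resolution(ep, diag)
        res_s = detect_resolution(shifted, diag_s)
        assert (res is None and res_s is None) or res_s == res + delta
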