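"""Quarterly aggregation, chi-square comparisons and report rendering."""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from dkaudit.adherence import AdherenceResult, INDICATORS
from dkaudit.complications import ComplicationFlags, OutcomeRecord
from dkaudit.feedback import (
    POOLED_LABEL,
    aggregate_quarter,
    first_last_comparison,
    pearson_chi2_2x2,
    quarter_of,
    render_feedback,
)
from dkaudit.pipeline import (
    first_last_comparisons,
    quarterly_kpis,
    score_cohort,
    write_reports,
)


@pytest.mark.parametrize("ts,label", [
    (datetime(2020, 2, 15), "2020-Q1"),
    (datetime(2022, 12, 31, 23, 59), "2022-Q4"),
    (datetime(2021, 4, 1), "2021-Q2"),
    (datetime(2021, 3, 31, 23, 59), "2021-Q1"),
])
def test_quarter_assignment(ts, label):
    assert quarter_of(ts) == label


def adherence_fixture(n, n_in_band):
    out = []
    for i in range(n):
        pct = 100.0 if i < n_in_band else 150.0
        out.append(AdherenceResult(
            episode_code=f"e{i}",
            **{f"{ind}_pct": pct for ind in INDICATORS},
            **{f"{ind}_in_band": pct == 100.0 for ind in INDICATORS}))
    return out


def flags_fixture(n):
    return [ComplicationFlags(f"e{i}", False, False, False) for i in range(n)]


def outcomes_fixture(durations, stays=None):
    stays = stays or [3.0] * len(durations)
    return [OutcomeRecord(f"e{i}", length_of_stay_d=s, dka_duration_h=d)
            for i, (d, s) in enumerate(zip(durations, stays))]


def test_aggregate_in_band_proportion():
    kpi = aggregate_quarter(adherence_fixture(10, 6), flags_fixture(10),
                            outcomes_fixture([10.0] * 10), "A", "2022-Q1")
    assert kpi.n_episodes == 10
    assert kpi.in_band_prop["fluid"] == pytest.approx(0.6)
    assert kpi.in_band_n["fluid"] == 6 and kpi.eligible_n["fluid"] == 10


def test_aggregate_median_iqr():
    kpi = aggregate_quarter(adherence_fixture(5, 5), flags_fixture(5),
                            outcomes_fixture([4.0, 6.0, 8.0, 10.0, 12.0]),
                            "A", "2022-Q1")
    assert kpi.duration_median == pytest.approx(8.0)
    assert (kpi.duration_q1, kpi.duration_q3) == (pytest.approx(5.0), pytest.approx(11.0))


def test_aggregate_zero_episodes():
    kpi = aggregate_quarter([], [], [], "A", "2022-Q1")
    assert kpi.n_episodes == 0
    assert kpi.duration_median is None
    assert all(v is None for v in kpi.in_band_prop.values())
    assert all(v is None for v in kpi.complication_prop.values())


def test_absent_scores_excluded_from_denominator_only():
    adh = adherence_fixture(4, 2) + [AdherenceResult(episode_code="e9")]
    kpi = aggregate_quarter(adh, flags_fixture(5), outcomes_fixture([5.0] * 5),
                            "A", "2022-Q1")
    assert kpi.n_episodes == 5
    assert kpi.eligible_n["fluid"] == 4
    assert kpi.in_band_prop["fluid"] == pytest.approx(0.5)


# --- Pearson chi-square ----------------------------------------------------

def closed_form(table):
    (a, b), (c, d) = table
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


@pytest.mark.parametrize("table,expected", [
    ([[10, 20], [20, 10]], 6.667),
    ([[0, 10], [10, 0]], 20.0),
    ([[15, 15], [15, 15]], 0.0),
])
def test_chi_square_worked_tables(table, expected):
    stat, p, _ = pearson_chi2_2x2(table)
    assert round(stat, 3) == expected
    assert 0.0 <= p <= 1.0


def test_chi_square_matches_closed_form_and_scipy():
    rng = np.random.default_rng(5)
    checked = 0
    while checked < 200:
        table = rng.integers(0, 40, size=(2, 2))
        if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
            continue
        stat, p, _ = pearson_chi2_2x2(table)
        assert stat == pytest.approx(closed_form(table), abs=1e-9)
        ref_stat, ref_p, _, _ = chi2_contingency(table, correction=False)
        assert stat == pytest.approx(ref_stat, abs=1e-9)
        assert p == pytest.approx(ref_p, abs=1e-12)
        checked += 1


def test_chi_square_symmetric_in_quarter_order():
    rng = np.random.default_rng(8)
    for _ in range(50):
        table = rng.integers(1, 30, size=(2, 2))
        stat1, _, _ = pearson_chi2_2x2(table)
        stat2, _, _ = pearson_chi2_2x2(table[::-1])
        assert stat1 == pytest.approx(stat2, abs=1e-12)


def test_chi_square_zero_margin_is_flagged_degenerate():
    stat, p, min_exp = pearson_chi2_2x2([[0, 0], [5, 7]])
    assert (stat, p, min_exp) == (0.0, 1.0, 0.0)


def kpi_for(hospital, quarter, in_n, out_n):
    return aggregate_quarter(
        adherence_fixture(in_n + out_n, in_n),
        flags_fixture(in_n + out_n),
        outcomes_fixture([8.0] * (in_n + out_n)), hospital, quarter)


def test_first_last_comparison_uses_earliest_and_latest_quarters():
    kpis = [kpi_for("A", "2022-Q3", 5, 5), kpi_for("A", "2021-Q2", 10, 20),
            kpi_for("A", "2022-Q1", 7, 3)]
    comp = first_last_comparison(kpis, "fluid")
    assert (comp.first_quarter, comp.last_quarter) == ("2021-Q2", "2022-Q3")
    assert comp.first_proportion == pytest.approx(1 / 3)
    assert comp.last_proportion == pytest.approx(0.5)
    expected, _, _ = pearson_chi2_2x2([[10, 20], [5, 5]])
    assert comp.chi_square_statistic == pytest.approx(expected)


def test_first_last_comparison_low_expected_flagged_unreliable():
    kpis = [kpi_for("A", "2022-Q1", 1, 0), kpi_for("A", "2022-Q4", 0, 1)]
    comp = first_last_comparison(kpis, "frii")
    assert comp is not None and not comp.reliable


def test_first_last_comparison_single_quarter_none():
    assert first_last_comparison([kpi_for("A", "2022-Q1", 5, 5)], "frii") is None


# --- pipeline-level aggregation and reports --------------------------------

@pytest.fixture(scope="module")
def small_scored(small_cohort):
    episodes, codes, _ = small_cohort
    return score_cohort(episodes, codes)


@pytest.fixture(scope="module")
def small_kpis(small_scored):
    return quarterly_kpis(small_scored)


def test_pooled_counts_conserved(small_kpis):
    """Per quarter, pooled episode and in-band counts equal the sums over
    hospitals."""
    pooled = {k.quarter: k for k in small_kpis if k.hospital_code == POOLED_LABEL}
    per_hosp = [k for k in small_kpis if k.hospital_code != POOLED_LABEL]
    for quarter, pool in pooled.items():
        own = [k for k in per_hosp if k.quarter == quarter]
        assert pool.n_episodes == sum(k.n_episodes for k in own)
        for ind in INDICATORS:
            assert pool.in_band_n[ind] == sum(k.in_band_n[ind] or 0 for k in own)
            assert pool.eligible_n[ind] == sum(k.eligible_n[ind] for k in own)


def test_pooled_proportion_is_weighted_mean(small_kpis):
    pooled = {k.quarter: k for k in small_kpis if k.hospital_code == POOLED_LABEL}
    per_hosp = [k for k in small_kpis if k.hospital_code != POOLED_LABEL]
    for quarter, pool in pooled.items():
        own = [k for k in per_hosp if k.quarter == quarter]
        for ind in INDICATORS:
            weights = [k.eligible_n[ind] for k in own if k.in_band_prop[ind] is not None]
            props = [k.in_band_prop[ind] for k in own if k.in_band_prop[ind] is not None]
            if not weights:
                continue
            weighted = float(np.average(props, weights=weights))
            assert pool.in_band_prop[ind] == pytest.approx(weighted)


def test_reports_one_per_hospital_with_pooled_table(small_kpis, tmp_path):
    comparisons = first_last_comparisons(small_kpis)
    paths = write_reports(small_kpis, comparisons, tmp_path)
    assert sorted(paths) == ["A", "B"]
    text = paths["A"].read_text()
    assert "# DKA care feedback -- hospital A" in text
    assert "## All participating hospitals (pooled)" in text
    assert "## First vs last quarter" in text
    assert "hospital B" not in text  # peers stay anonymous


def test_report_single_quarter_hospital_has_no_comparison_section():
    kpis = [kpi_for("A", "2022-Q1", 5, 5)]
    text = render_feedback("A", kpis, kpis, comparisons=[])
    assert "First vs last quarter" not in text


def test_report_rendering_deterministic(small_kpis):
    comparisons = first_last_comparisons(small_kpis)
    pooled = [k for k in small_kpis if k.hospital_code == POOLED_LABEL]
    a = render_feedback("A", small_kpis, pooled, comparisons)
    b = render_feedback("A", small_kpis, pooled, comparisons)
    assert a == b
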