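"""Temporal merge: windows, nearest-report priority, debut resolution."""

import datetime

import numpy as np
import pandas as pd
import pytest

from afdebut.overlap import (OverlapConfig, merge, missingness,
                             recurrence_candidates, resolve_debut)
from afdebut.types import PatientVector, ReportVector

from oracles import oracle_nearest_candidate

DEBUT = datetime.date(2019, 6, 1)


def rv(rid, days_from_debut, values, patient="P1", onset=False, prior=False):
    return ReportVector(
        report_id=rid, patient_id=patient,
        report_date=DEBUT + datetime.timedelta(days=days_from_debut),
        values=values, af_new_onset=onset, af_prior_history=prior)


def config(**class_map):
    return OverlapConfig(variable_class_map=class_map or
                         {"creatinine": "lab", "lvef": "echo", "diabetes": "history"})


def test_lab_outside_180_day_lookback_is_missing():
    pv = merge([rv("a", -210, {"creatinine": 1.2})], DEBUT, config())
    assert "creatinine" not in pv.values
    assert pv.missing_count == 3


def test_closest_report_wins():
    pv = merge([rv("a", -30, {"creatinine": 1.0}), rv("b", -10, {"creatinine": 2.0})],
               DEBUT, config())
    assert pv.values["creatinine"] == 2.0
    assert pv.source["creatinine"].report_id == "b"
    assert pv.source["creatinine"].days_from_debut == -10


def test_echo_admits_values_after_debut_labs_do_not():
    pv = merge([rv("a", 60, {"lvef": 55.0, "creatinine": 1.0})], DEBUT, config())
    assert pv.values["lvef"] == 55.0
    assert "creatinine" not in pv.values


def test_equal_distance_tie_breaks_to_earlier_report():
    pv = merge([rv("late", 30, {"lvef": 60.0}), rv("early", -30, {"lvef": 50.0})],
               DEBUT, config())
    assert pv.values["lvef"] == 50.0


def test_history_window_unbounded_before_closed_after():
    pv = merge([rv("a", -4000, {"diabetes": True})], DEBUT, config())
    assert pv.values["diabetes"] is True
    pv = merge([rv("a", 10, {"diabetes": True})], DEBUT, config())
    assert "diabetes" not in pv.values


def test_multiple_patients_rejected_and_empty_allowed():
    with pytest.raises(ValueError):
        merge([rv("a", 0, {}), rv("b", 0, {}, patient="P2")], DEBUT, config())
    pv = merge([], DEBUT, config())
    assert pv.values == {} and pv.missing_count == 3


def test_merge_is_permutation_invariant():
    vectors = [rv(f"r{i}", d, {"creatinine": float(i)})
               for i, d in enumerate([-170, -10, -10, -90])]
    forward = merge(vectors, DEBUT, config())
    backward = merge(list(reversed(vectors)), DEBUT, config())
    assert forward.values == backward.values
    assert forward.source == backward.source


def test_merge_matches_bruteforce_scan_on_random_timelines():
    """500 random patient timelines: every chosen value equals the oracle's
    nearest eligible candidate and respects its window."""
    rng = np.random.default_rng(42)
    cfg = config()
    for _ in range(500):
        n = int(rng.integers(1, 8))
        vectors = []
        for i in range(n):
            values = {}
            for var in cfg.variable_class_map:
                if rng.random() < 0.6:
                    values[var] = float(np.round(rng.uniform(0, 100), 1))
            vectors.append(rv(f"r{i}", int(rng.integers(-400, 200)), values))
        pv = merge(vectors, DEBUT, cfg)
        for var in cfg.variable_class_map:
            before, after = cfg.window_for(var)
            expected = oracle_nearest_candidate(vectors, var, DEBUT, before, after)
            if expected is None:
                assert var not in pv.values
            else:
                value, report_id = expected
                assert pv.values[var] == value
                assert pv.source[var].report_id == report_id
                d = pv.source[var].days_from_debut
                assert (before is None or d >= -before) and d <= after


def test_resolve_debut_cases():
    assert resolve_debut([rv("a", 0, {})]) == (None, None)
    assert resolve_debut([rv("a", 0, {}, onset=True)]) == (DEBUT, "a")
    # an earlier prior-history report overrides the onset claim
    history_first = [rv("a", -30, {}, prior=True), rv("b", 0, {}, onset=True)]
    assert resolve_debut(history_first) == (None, None)
    # prior history on the same day does not override
    same_day = [rv("a", 0, {}, prior=True), rv("b", 0, {}, onset=True)]
    assert resolve_debut(same_day) == (DEBUT, "b")


def test_recurrence_candidates_exposed():
    vectors = [rv("a", 0, {}, onset=True), rv("b", 90, {}, prior=True),
               rv("c", -30, {}, prior=False)]
    assert recurrence_candidates(vectors, DEBUT) == ["b"]


def pv_with(patient_id, values):
    return PatientVector(patient_id=patient_id, debut_date=DEBUT, values=values)


def test_missingness_arithmetic():
    extracted = {"P1": pv_with("P1", {}), "P2": pv_with("P2", {})}
    coded = pd.DataFrame({"patient_id": ["P1", "P2"], "x": [np.nan, np.nan]})
    table = missingness(extracted, coded, ["x"])
    assert table[table.variable == "x"].reduction.item() == 0.0

    extracted = {f"P{i}": pv_with(f"P{i}", {"x": 1.0} if i < 8 else {})
                 for i in range(10)}
    coded = pd.DataFrame({"patient_id": [f"P{i}" for i in range(10)],
                          "x": [1.0] * 6 + [np.nan] * 4})
    table = missingness(extracted, coded, ["x"])
    row = table[table.variable == "x"].iloc[0]
    assert row.coded_missing == 4 and row.extracted_missing == 2
    assert row.reduction == 0.5


def test_missingness_disjoint_ids_rejected():
    with pytest.raises(ValueError):
        missingness({"P1": pv_with("P1", {})},
                    pd.DataFrame({"patient_id": ["Q9"], "x": [1.0]}), ["x"])


def test_negative_windows_rejected():
    with pytest.raises(ValueError):
        OverlapConfig(lab_window_days_before=-1)
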