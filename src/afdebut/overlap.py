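"""Temporal merging of per-report vectors into one debut-anchored vector.

Each variable class has a temporal eligibility window around the AF debut
date — labs look back 180 days, echocardiographic parameters 90 days either
side, and history/demographic/medication/procedure values any time up to
debut. Among eligible candidates the report closest to the debut date wins;
ties break toward the earlier report, then the lexicographically smaller
report id. Debut resolution scans the AF flags across a patient's reports
and refuses to pick a debut when an earlier report already asserts prior AF
history.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .types import PatientVector, ReportVector, SourceRef

DEFAULT_CLASS_WINDOWS = {
    # class -> (days_before or None for unbounded, days_after)
    "lab": (180, 0),
    "echo": (90, 90),
    "history": (None, 0),
    "demographic": (None, 0),
    "medication": (None, 0),
    "procedure": (None, 0),
}


@dataclass
class OverlapConfig:
    """Window configuration; day counts, not calendar months."""

    lab_window_days_before: int = 180
    lab_window_days_after: int = 0
    echo_window_days_before: int = 90
    echo_window_days_after: int = 90
    variable_class_map: dict[str, str] = field(default_factory=dict)
    class_windows: dict[str, tuple[Optional[int], int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for w in (self.lab_window_days_before, self.lab_window_days_after,
                  self.echo_window_days_before, self.echo_window_days_after):
            if w < 0:
                raise ValueError("windows must be >= 0")

    def window_for(self, variable_id: str) -> tuple[Optional[int], int]:
        """(days_before or None = unbounded, days_after) for a variable."""
        cls = self.variable_class_map.get(variable_id, "history")
        if cls == "lab":
            return (self.lab_window_days_before, self.lab_window_days_after)
        if cls == "echo":
            return (self.echo_window_days_before, self.echo_window_days_after)
        if cls in self.class_windows:
            return self.class_windows[cls]
        return DEFAULT_CLASS_WINDOWS.get(cls, (None, 0))


def merge(vectors: list[ReportVector], debut_date: datetime.date,
          config: OverlapConfig) -> PatientVector:
    """Merge one patient's report vectors into a debut-anchored vector.

    Raises ``ValueError`` on vectors from multiple patients; an empty list
    yields an all-missing vector.
    """
    patient_ids = {v.patient_id for v in vectors}
    if len(patient_ids) > 1:
        raise ValueError(f"vectors from multiple patients: {sorted(patient_ids)}")
    patient_id = patient_ids.pop() if patient_ids else ""

    values, source = {}, {}
    for variable_id in config.variable_class_map:
        before, after = config.window_for(variable_id)
        candidates = []
        for rv in vectors:
            if variable_id not in rv.values:
                continue
            d = (rv.report_date - debut_date).days
            if (before is None or d >= -before) and d <= after:
                candidates.append((abs(d), rv.report_date, rv.report_id, rv))
        if candidates:
            _, _, _, best = min(candidates)
            d = (best.report_date - debut_date).days
            values[variable_id] = best.values[variable_id]
            source[variable_id] = SourceRef(best.report_id, best.report_date, d)

    onset_ids = [v.report_id for v in vectors if v.af_new_onset
                 and v.report_date == debut_date]
    return PatientVector(
        patient_id=patient_id,
        debut_date=debut_date,
        values=values,
        source=source,
        af_onset_report_id=onset_ids[0] if onset_ids else None,
        missing_count=len(config.variable_class_map) - len(values),
    )


def resolve_debut(
    vectors: list[ReportVector],
) -> tuple[Optional[datetime.date], Optional[str]]:
    """Find the real new-onset report among a patient's reports.

    Debut = earliest report flagged ``af_new_onset`` with no chronologically
    earlier report asserting prior AF history; an onset claim preceded by a
    prior-history assertion resolves to "no debut" rather than guessing.
    """
    if len({v.patient_id for v in vectors}) > 1:
        raise ValueError("vectors from multiple patients")
    ordered = sorted(vectors, key=lambda v: (v.report_date, v.report_id))
    for v in ordered:
        if not v.af_new_onset:
            continue
        earlier_prior = any(
            u.af_prior_history and u.report_date < v.report_date for u in ordered
        )
        return (None, None) if earlier_prior else (v.report_date, v.report_id)
    return (None, None)


def recurrence_candidates(vectors: list[ReportVector],
                          debut_date: datetime.date) -> list[str]:
    """Reports after debut still mentioning AF: possible recurrence (exposed,
    not modelled)."""
    return sorted(
        v.report_id for v in vectors
        if v.report_date > debut_date and (v.af_new_onset or v.af_prior_history)
    )


def missingness(extracted: dict[str, PatientVector], coded: pd.DataFrame,
                variables: list[str]) -> pd.DataFrame:
    """Per-variable missing rates in both sources plus relative reduction.

    ``coded`` must have a ``patient_id`` column and one column per variable
    (NaN = missing). Rows are per-variable with an ``__aggregate__`` total;
    ``reduction = (coded_missing - extracted_missing) / coded_missing``.
    """
    coded_ids = set(coded["patient_id"])
    shared = sorted(coded_ids & set(extracted))
    if not shared:
        raise ValueError("coded and extracted patient id sets are disjoint")
    coded_idx = coded.set_index("patient_id").loc[shared]

    rows = []
    total_coded = total_extracted = 0
    for var in variables:
        n_coded_missing = int(coded_idx[var].isna().sum()) if var in coded_idx else len(shared)
        n_extr_missing = sum(1 for pid in shared if var not in extracted[pid].values)
        total_coded += n_coded_missing
        total_extracted += n_extr_missing
        reduction = ((n_coded_missing - n_extr_missing) / n_coded_missing
                     if n_coded_missing else 0.0)
        rows.append({"variable": var, "n_patients": len(shared),
                     "coded_missing": n_coded_missing,
                     "extracted_missing": n_extr_missing,
                     "reduction": reduction})
    agg_red = ((total_coded - total_extracted) / total_coded) if total_coded else 0.0
    rows.append({"variable": "__aggregate__", "n_patients": len(shared),
                 "coded_missing": total_coded, "extracted_missing": total_extracted,
                 "reduction": agg_red})
    return pd.DataFrame(rows)
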