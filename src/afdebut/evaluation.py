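"""Cell-level comparison of extracted vectors against gold annotations.

The unit of evaluation is a (report, variable) cell: TP = present in both
with matching values (numeric within a relative tolerance, boolean and
categorical exact), FP = extracted asserts a value gold lacks or
contradicts, FN = gold has a value extraction missed, TN = absent in both.
A mismatched value counts as FP by default (the extractor asserted the
wrong thing); set ``mismatch_counts_fn=True`` to also count the missed
gold value. Ratios with empty denominators are reported as None and
excluded from macro averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Mapping, Optional

from .types import ReportVector


@dataclass
class CellCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def metrics(self) -> dict[str, Optional[float]]:
        tp, fp, fn, tn = self.tp, self.fp, self.fn, self.tn
        acc = (tp + tn) / self.total if self.total else None
        prec = tp / (tp + fp) if (tp + fp) else None
        rec = tp / (tp + fn) if (tp + fn) else None
        f1 = (2 * prec * rec / (prec + rec)
              if prec is not None and rec is not None and (prec + rec) else None)
        return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


@dataclass
class VectorEvalMetrics:
    per_variable: dict[str, CellCounts]
    numeric_tolerance: float

    @property
    def aggregate(self) -> CellCounts:
        agg = CellCounts()
        for c in self.per_variable.values():
            agg.tp += c.tp
            agg.fp += c.fp
            agg.fn += c.fn
            agg.tn += c.tn
        return agg

    def macro_average(self, metric: str) -> Optional[float]:
        vals = [c.metrics()[metric] for c in self.per_variable.values()]
        vals = [v for v in vals if v is not None]
        return sum(vals) / len(vals) if vals else None

    def per_variable_metrics(self) -> dict[str, dict[str, Optional[float]]]:
        return {var: c.metrics() for var, c in self.per_variable.items()}


def _values_match(extracted: Any, gold: Any, tol: float) -> bool:
    if isinstance(gold, bool) or isinstance(extracted, bool):
        return extracted == gold
    if isinstance(gold, (int, float)) and isinstance(extracted, (int, float)):
        denom = max(abs(float(gold)), 1e-12)
        return math.isfinite(float(extracted)) and \
            abs(float(extracted) - float(gold)) / denom <= tol
    return extracted == gold


def score_vectors(extracted: list[ReportVector],
                  gold: Mapping[str, Mapping[str, Any]],
                  variables: list[str],
                  numeric_tolerance: float = 0.01,
                  mismatch_counts_fn: bool = False) -> VectorEvalMetrics:
    """Score extracted report vectors against gold per-report value maps.

    ``gold`` maps report_id → {variable_id: value}. The report id sets must
    coincide; a mismatch raises ``ValueError``.
    """
    extracted_ids = {rv.report_id for rv in extracted}
    if extracted_ids != set(gold):
        raise ValueError("extracted and gold report ids are not aligned")

    per_variable = {var: CellCounts() for var in variables}
    for rv in extracted:
        gvals = gold[rv.report_id]
        for var in variables:
            c = per_variable[var]
            has_e, has_g = var in rv.values, var in gvals
            if has_e and has_g:
                if _values_match(rv.values[var], gvals[var], numeric_tolerance):
                    c.tp += 1
                else:
                    c.fp += 1
                    if mismatch_counts_fn:
                        c.fn += 1
            elif has_e:
                c.fp += 1
            elif has_g:
                c.fn += 1
            else:
                c.tn += 1
    return VectorEvalMetrics(per_variable=per_variable, numeric_tolerance=numeric_tolerance)


def detection_rate(gold_onset_patients: set[str], detected_onset_patients: set[str]) -> float:
    """|gold ∩ detected| / |gold|; raises on empty gold."""
    if not gold_onset_patients:
        raise ValueError("gold onset set is empty")
    return len(gold_onset_patients & detected_onset_patients) / len(gold_onset_patients)
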