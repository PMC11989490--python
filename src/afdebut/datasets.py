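"""Intersection/union corpus construction from coded and regex AF detection.

The coded system and the regex pipeline each nominate AF-onset reports; the
*intersection* (agreement of both) trades sensitivity for label purity
while the *union* keeps every nomination. Both corpora share one
seed-deterministic negative sample so they are comparable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ClinicalReport, CorpusEntry, LabeledCorpus

DEFAULT_CODING_WINDOW_DAYS = 30


def link_coded_to_reports(coded_export: pd.DataFrame, reports: list[ClinicalReport],
                          window_days: int = DEFAULT_CODING_WINDOW_DAYS,
                          ) -> dict[str, list[str]]:
    """Map each coded-AF patient to reports within ``window_days`` of the
    coding date.

    Duplicate coding rows per patient collapse to one event (the earliest
    coding date).
    """
    coded = coded_export[coded_export["coded_af"].astype(bool)]
    coding_date = {}
    for row in coded.itertuples(index=False):
        date = pd.Timestamp(row.coding_date).date()
        prev = coding_date.get(row.patient_id)
        if prev is None or date < prev:
            coding_date[row.patient_id] = date
    by_patient: dict[str, list[str]] = {pid: [] for pid in coding_date}
    for report in reports:
        anchor = coding_date.get(report.patient_id)
        if anchor is not None and abs((report.date - anchor).days) <= window_days:
            by_patient[report.patient_id].append(report.report_id)
    for ids in by_patient.values():
        ids.sort()
    return by_patient


def build_corpora(coded_positive_ids: set[str], regex_positive_ids: set[str],
                  negative_pool: list[ClinicalReport], n_negatives: int, seed: int,
                  report_texts: dict[str, str],
                  ) -> tuple[LabeledCorpus, LabeledCorpus]:
    """Build the intersection and union training corpora.

    Positives: ``coded ∩ regex`` vs ``coded ∪ regex`` with provenance flags
    (so the symmetric-difference reading of "union" stays recoverable).
    Negatives are sampled without replacement from ``negative_pool``,
    seed-deterministically, and shared between the two corpora.
    """
    union_ids = coded_positive_ids | regex_positive_ids
    pool_ids = {r.report_id for r in negative_pool}
    clash = pool_ids & union_ids
    if clash:
        raise ValueError(f"negative pool overlaps positives: {sorted(clash)[:5]}")
    if n_negatives > len(negative_pool):
        raise ValueError("n_negatives exceeds negative pool size")

    rng = np.random.default_rng(seed)
    ordered_pool = sorted(negative_pool, key=lambda r: r.report_id)
    chosen = rng.choice(len(ordered_pool), size=n_negatives, replace=False)
    negatives = [
        CorpusEntry(ordered_pool[i].report_id, ordered_pool[i].text,
                    "negative", "sampled_negative")
        for i in sorted(chosen)
    ]

    def provenance(rid: str) -> str:
        in_coded, in_regex = rid in coded_positive_ids, rid in regex_positive_ids
        return "both" if (in_coded and in_regex) else ("coded_only" if in_coded else "regex_only")

    def positives(ids: set[str]) -> list[CorpusEntry]:
        return [CorpusEntry(rid, report_texts[rid], "af_onset", provenance(rid))
                for rid in sorted(ids)]

    intersection = LabeledCorpus("intersection",
                                 positives(coded_positive_ids & regex_positive_ids) + negatives)
    union = LabeledCorpus("union", positives(union_ids) + negatives)
    return intersection, union


@dataclass
class CorpusSummary:
    name: str
    n_positive: int
    n_negative: int
    by_provenance: dict[str, int]


def summarize(corpus: LabeledCorpus) -> CorpusSummary:
    by_prov: dict[str, int] = {}
    for e in corpus.entries:
        by_prov[e.provenance] = by_prov.get(e.provenance, 0) + 1
    return CorpusSummary(
        name=corpus.name,
        n_positive=sum(1 for e in corpus.entries if e.label == "af_onset"),
        n_negative=sum(1 for e in corpus.entries if e.label == "negative"),
        by_provenance=by_prov,
    )


def label_purity(corpus: LabeledCorpus, true_positive_ids: set[str]) -> float:
    """Fraction of the corpus's positive labels that are truly AF onsets."""
    pos = [e for e in corpus.entries if e.label == "af_onset"]
    if not pos:
        return float("nan")
    return sum(1 for e in pos if e.report_id in true_positive_ids) / len(pos)
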