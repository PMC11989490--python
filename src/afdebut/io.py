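"""Plain-text serialization of every pipeline artifact (JSONL / CSV).

All intermediate artifacts are line-oriented text so each stage can be
inspected and re-run independently.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .types import (ClinicalReport, CorpusEntry, LabeledCorpus, Mention,
                    PatientVector, ReportVector, SectionLabel, SectionSpan,
                    SectionedReport)


def _date(s):
    return datetime.date.fromisoformat(s) if s else None


def write_jsonl(path, records: Iterable[dict]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_jsonl(path) -> list[dict]:
    with open(path, "r", encoding="utf-8") as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_reports(path, reports: list[ClinicalReport]) -> None:
    write_jsonl(path, ({"id": r.report_id, "patient_id": r.patient_id,
                        "date": r.date.isoformat(), "text": r.text} for r in reports))


def read_reports(path) -> list[ClinicalReport]:
    return [ClinicalReport(rec["id"], rec["patient_id"], _date(rec["date"]), rec["text"])
            for rec in read_jsonl(path)]


def write_sectioned(path, sectioned: list[SectionedReport]) -> None:
    write_jsonl(path, ({"id": s.report_id,
                        "spans": [[sp.label.value, sp.start, sp.end] for sp in s.spans]}
                       for s in sectioned))


def read_sectioned(path) -> list[SectionedReport]:
    return [SectionedReport(rec["id"],
                            [SectionSpan(SectionLabel(l), s, e) for l, s, e in rec["spans"]])
            for rec in read_jsonl(path)]


def write_vectors(path, vectors: list[ReportVector]) -> None:
    def rec(v: ReportVector) -> dict:
        return {
            "id": v.report_id, "patient_id": v.patient_id,
            "date": v.report_date.isoformat(), "values": v.values,
            "af_new_onset": v.af_new_onset, "af_prior_history": v.af_prior_history,
            "mentions": [dataclasses.asdict(m) | {"section": m.section.value}
                         for m in v.mentions],
        }
    write_jsonl(path, (rec(v) for v in vectors))


def read_vectors(path) -> list[ReportVector]:
    out = []
    for rec in read_jsonl(path):
        mentions = [Mention(m["variable_id"], SectionLabel(m["section"]), m["start"],
                            m["end"], m["matched_text"], m["value"], m["negated"])
                    for m in rec.get("mentions", [])]
        out.append(ReportVector(rec["id"], rec["patient_id"], _date(rec["date"]),
                                rec["values"], rec["af_new_onset"],
                                rec["af_prior_history"], mentions))
    return out


def write_patient_vectors_csv(path, vectors: list[PatientVector],
                              variables: list[str]) -> None:
    rows = []
    for pv in vectors:
        row = {"patient_id": pv.patient_id,
               "debut_date": pv.debut_date.isoformat() if pv.debut_date else "",
               "af_onset_report_id": pv.af_onset_report_id or "",
               "missing_count": pv.missing_count}
        for var in variables:
            row[var] = pv.values.get(var, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_corpus(path, corpus: LabeledCorpus) -> None:
    write_jsonl(path, ({"id": e.report_id, "label": e.label,
                        "provenance": e.provenance, "text": e.text}
                       for e in corpus.entries))


def read_corpus(path, name: str) -> LabeledCorpus:
    return LabeledCorpus(name, [CorpusEntry(r["id"], r["text"], r["label"], r["provenance"])
                                for r in read_jsonl(path)])


def write_coded_csv(path, coded: pd.DataFrame) -> None:
    coded.to_csv(path, index=False)


def read_coded_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["coded_af"] = df["coded_af"].astype(bool)
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
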