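"""Core domain types shared across the pipeline.

A discharge report flows through the stages as:

``ClinicalReport`` → ``SectionedReport`` → ``ReportVector`` → ``PatientVector``.

All character offsets are 0-based, half-open ``[start, end)`` over the raw
report text. Dates are ``datetime.date`` everywhere; serialized form is
ISO-8601.
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass, field
from typing import Any, Optional


class SectionLabel(str, enum.Enum):
    """The nine standardized discharge-report sections, plus Unknown.

    ``Unknown`` is reserved for text before the first recognized heading
    (or text under a heading absent from the lexicon); it is never searched
    by the extractor.
    """

    HEADER = "Header"
    REASON_FOR_CONSULTATION = "ReasonForConsultation"
    PERSONAL_HISTORY = "PersonalHistory"
    CURRENT_ILLNESS = "CurrentIllness"
    GENERAL_EXPLORATION = "GeneralExploration"
    COMPLEMENTARY_TESTS = "ComplementaryTests"
    DIAGNOSIS = "Diagnosis"
    TREATMENT = "Treatment"
    EVOLUTION = "Evolution"
    UNKNOWN = "Unknown"


#: The nine "real" sections (everything except Unknown), in conventional order.
STANDARD_SECTIONS: tuple[SectionLabel, ...] = tuple(
    s for s in SectionLabel if s is not SectionLabel.UNKNOWN
)


@dataclass(frozen=True)
class ClinicalReport:
    """One plain-text discharge report: the pipeline's input unit."""

    report_id: str
    patient_id: str
    date: datetime.date
    text: str


@dataclass(frozen=True)
class SectionSpan:
    label: SectionLabel
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


@dataclass
class SectionedReport:
    """Ordered, non-overlapping labeled spans jointly covering the text."""

    report_id: str
    spans: list[SectionSpan]

    def validate(self, text_length: int) -> None:
        """Assert the coverage/ordering invariants against the text length."""
        if text_length == 0:
            if self.spans:
                raise ValueError("empty text must yield no spans")
            return
        if not self.spans:
            raise ValueError("non-empty text must be covered by spans")
        if self.spans[0].start != 0 or self.spans[-1].end != text_length:
            raise ValueError("spans must cover [0, len(text))")
        for a, b in zip(self.spans, self.spans[1:]):
            if a.end != b.start:
                raise ValueError("spans must be contiguous and sorted")

    def spans_for(self, label: SectionLabel) -> list[SectionSpan]:
        return [s for s in self.spans if s.label is label]


@dataclass(frozen=True)
class Mention:
    """A single pattern match with provenance.

    ``value`` is the typed value (float for numerics, str for
    categorical/medication ATC codes, True for booleans). ``span`` offsets
    are report-level.
    """

    variable_id: str
    section: SectionLabel
    start: int
    end: int
    matched_text: str
    value: Any
    negated: bool


@dataclass
class ReportVector:
    """Per-report extracted variable values with provenance.

    Negated boolean mentions surface as explicit ``False`` values; a negated
    mention never yields a positive value. ``af_new_onset`` and
    ``af_prior_history`` are assigned independently.
    """

    report_id: str
    patient_id: str
    report_date: datetime.date
    values: dict[str, Any] = field(default_factory=dict)
    af_new_onset: bool = False
    af_prior_history: bool = False
    mentions: list[Mention] = field(default_factory=list)


@dataclass(frozen=True)
class SourceRef:
    """Where a merged patient-level value came from."""

    report_id: str
    report_date: datetime.date
    days_from_debut: int  # negative = before debut


@dataclass
class PatientVector:
    """One debut-anchored vector per patient after temporal merging."""

    patient_id: str
    debut_date: Optional[datetime.date]
    values: dict[str, Any] = field(default_factory=dict)
    source: dict[str, SourceRef] = field(default_factory=dict)
    af_onset_report_id: Optional[str] = None
    missing_count: int = 0


@dataclass(frozen=True)
class CorpusEntry:
    report_id: str
    text: str
    label: str  # "af_onset" | "negative"
    provenance: str  # "coded_only" | "regex_only" | "both" | "sampled_negative"


@dataclass
class LabeledCorpus:
    """Report texts + binary AF-onset labels for classifier training."""

    name: str  # "intersection" | "union"
    entries: list[CorpusEntry]

    def __post_init__(self) -> None:
        ids = [e.report_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate report_ids in corpus {self.name!r}")

    @property
    def texts(self) -> list[str]:
        return [e.text for e in self.entries]

    @property
    def labels(self) -> list[int]:
        return [1 if e.label == "af_onset" else 0 for e in self.entries]
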