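"""Section-targeted regex extraction of clinical variables.

Each variable carries its own pattern bank and a list of target sections;
patterns are applied to accent-folded, lower-cased text *only* inside those
sections, every candidate match is passed through negation detection, and
numeric captures are normalized to the variable's canonical unit. AF is
deliberately excluded from the history variable bank and handled by
:func:`detect_af_flags`, which distinguishes a new-onset diagnosis
(Diagnosis / Current Illness, onset-qualified or bare) from prior AF
history (Personal History).
"""

from __future__ import annotations

import datetime
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Optional

import yaml

from .negation import NegationRuleSet, is_negated
from .textutils import fold, split_sentences
from .types import Mention, ReportVector, SectionLabel, SectionedReport

logger = logging.getLogger(__name__)

VALUE_TYPES = {"boolean", "numeric", "categorical", "medication"}


@dataclass
class VariableSpec:
    """One variable's extraction recipe.

    ``patterns`` entries are either bare regex strings or, for categorical
    variables, ``(regex, value)`` pairs. Numeric patterns must define a
    ``value`` named capture group and may define a ``unit`` group whose
    surface is looked up in ``unit_factors`` (canonical unit → 1.0).
    """

    variable_id: str
    value_type: str
    variable_class: str
    target_sections: list[SectionLabel]
    patterns: list[tuple[re.Pattern, Optional[str]]]
    canonical_unit: Optional[str] = None
    unit_factors: dict[str, float] = field(default_factory=dict)
    atc_map: dict[str, str] = field(default_factory=dict)
    window_days_before: Optional[int] = None
    window_days_after: Optional[int] = None

    def __post_init__(self) -> None:
        if self.value_type not in VALUE_TYPES:
            raise ValueError(f"unknown value_type {self.value_type!r}")
        if not self.target_sections:
            raise ValueError(f"{self.variable_id}: target_sections must be non-empty")
        if not self.patterns:
            raise ValueError(f"{self.variable_id}: patterns must be non-empty")
        if self.value_type == "numeric":
            for pat, _ in self.patterns:
                if "value" not in pat.groupindex:
                    raise ValueError(
                        f"{self.variable_id}: numeric pattern lacks (?P<value>...) group"
                    )
        if self.value_type == "medication" and not self.atc_map:
            raise ValueError(f"{self.variable_id}: medication spec needs atc_map")


@dataclass
class AfPatterns:
    """Bare AF surface forms plus onset qualifiers ("de novo", "debut"...)."""

    patterns: list[re.Pattern]
    onset_qualifiers: list[re.Pattern]


@dataclass
class Schema:
    variables: list[VariableSpec]
    af: AfPatterns

    @property
    def variable_ids(self) -> list[str]:
        return [v.variable_id for v in self.variables]

    @property
    def variable_class_map(self) -> dict[str, str]:
        return {v.variable_id: v.variable_class for v in self.variables}

    def spec(self, variable_id: str) -> VariableSpec:
        for v in self.variables:
            if v.variable_id == variable_id:
                return v
        raise KeyError(variable_id)


def _compile(pattern: str) -> re.Pattern:
    return re.compile(pattern, re.IGNORECASE)


def load_schema(source) -> Schema:
    """Load a variable schema from YAML (path or parsed mapping)."""
    if isinstance(source, dict):
        raw = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    variables = []
    for entry in raw["variables"]:
        patterns: list[tuple[re.Pattern, Optional[str]]] = []
        for p in entry["patterns"]:
            if isinstance(p, dict):
                patterns.append((_compile(p["regex"]), p.get("value")))
            else:
                patterns.append((_compile(p), None))
        variables.append(
            VariableSpec(
                variable_id=entry["variable_id"],
                value_type=entry["value_type"],
                variable_class=entry.get("variable_class", "history"),
                target_sections=[SectionLabel(s) for s in entry["target_sections"]],
                patterns=patterns,
                canonical_unit=entry.get("canonical_unit"),
                unit_factors={k.lower(): float(v) for k, v in entry.get("unit_factors", {}).items()},
                atc_map={fold(k): v for k, v in entry.get("atc_map", {}).items()},
                window_days_before=entry.get("window_days_before"),
                window_days_after=entry.get("window_days_after"),
            )
        )
    af_raw = raw["af"]
    af = AfPatterns(
        patterns=[_compile(p) for p in af_raw["patterns"]],
        onset_qualifiers=[_compile(p) for p in af_raw["onset_qualifiers"]],
    )
    return Schema(variables=variables, af=af)


def builtin_schema(language: str) -> Schema:
    fname = {"spanish": "schema_es.yaml", "english": "schema_en.yaml"}[language]
    with resources.files("afdebut.data").joinpath(fname).open("r", encoding="utf-8") as fh:
        return load_schema(yaml.safe_load(fh))


def map_medication(surface: str, atc_map: dict[str, str]) -> Optional[str]:
    """Longest-match ATC lookup after case/accent folding.

    ``"Apixabán 5 mg"`` maps via its longest known drug substring; an
    unmapped surface returns ``None`` with a logged warning.
    """
    if not atc_map:
        raise ValueError("atc_map must be non-empty")
    folded = fold(surface)
    best: Optional[str] = None
    best_len = 0
    for key, code in atc_map.items():
        if len(key) > best_len and re.search(rf"\b{re.escape(key)}\b", folded):
            best, best_len = code, len(key)
    if best is None:
        logger.warning("unmapped medication surface: %r", surface)
    return best


def _parse_numeric(match: re.Match, spec: VariableSpec) -> Optional[float]:
    raw = match.group("value")
    try:
        value = float(raw.replace(",", "."))
    except (TypeError, ValueError):
        logger.warning("%s: unparseable numeric capture %r", spec.variable_id, raw)
        return None
    unit = match.groupdict().get("unit")
    factor = 1.0
    if unit:
        factor = spec.unit_factors.get(unit.lower().strip())
        if factor is None:
            logger.warning("%s: unknown unit %r, mention dropped", spec.variable_id, unit)
            return None
    value *= factor
    if not (value == value and abs(value) != float("inf")):  # finite check
        logger.warning("%s: non-finite value from %r", spec.variable_id, raw)
        return None
    return value


def _iter_section_sentences(sectioned: SectionedReport, folded_text: str,
                            labels: list[SectionLabel]):
    """Yield (label, sent_start, sent_text) for sentences in target sections."""
    for label in labels:
        for span in sectioned.spans_for(label):
            section_text = folded_text[span.start : span.end]
            for s_start, s_end in split_sentences(section_text):
                yield label, span.start + s_start, section_text[s_start:s_end]


def _mentions_for(spec: VariableSpec, sectioned: SectionedReport, folded_text: str,
                  rules: NegationRuleSet) -> list[Mention]:
    mentions: list[Mention] = []
    for label, offset, sentence in _iter_section_sentences(
        sectioned, folded_text, spec.target_sections
    ):
        for pattern, cat_value in spec.patterns:
            for m in pattern.finditer(sentence):
                negated = is_negated(sentence, (m.start(), m.end()), rules)
                value: Any
                if spec.value_type == "numeric":
                    value = _parse_numeric(m, spec)
                    if value is None:
                        continue
                elif spec.value_type == "categorical":
                    value = cat_value
                elif spec.value_type == "medication":
                    value = map_medication(m.group(0), spec.atc_map)
                    if value is None:
                        continue
                else:
                    value = True
                mentions.append(
                    Mention(
                        variable_id=spec.variable_id,
                        section=label,
                        start=offset + m.start(),
                        end=offset + m.end(),
                        matched_text=sentence[m.start() : m.end()],
                        value=value,
                        negated=negated,
                    )
                )
    return mentions


def _resolve_value(spec: VariableSpec, mentions: list[Mention]) -> Any:
    """Affirmed mentions win over negated ones; first match in document order."""
    affirmed = [m for m in mentions if not m.negated]
    if affirmed:
        m = min(affirmed, key=lambda m: m.start)
        return True if spec.value_type == "boolean" else m.value
    if mentions and spec.value_type == "boolean":
        return False  # explicitly negated, never positive
    return None


def detect_af_flags(sectioned: SectionedReport, text: str, af: AfPatterns,
                    rules: NegationRuleSet) -> tuple[bool, bool]:
    """(af_new_onset, af_prior_history) for one report.

    Prior history: any non-negated AF mention in Personal History. New
    onset: a non-negated AF mention in Diagnosis or Current Illness whose
    sentence carries an onset qualifier, or a bare mention in a report with
    no prior-history mention.
    """
    folded = fold(text)

    def af_sentences(labels):
        hits = []  # (qualified, negated)
        for _, _, sentence in _iter_section_sentences(sectioned, folded, labels):
            for pattern in af.patterns:
                for m in pattern.finditer(sentence):
                    negated = is_negated(sentence, (m.start(), m.end()), rules)
                    qualified = any(q.search(sentence) for q in af.onset_qualifiers)
                    hits.append((qualified, negated))
        return hits

    prior_hits = af_sentences([SectionLabel.PERSONAL_HISTORY])
    af_prior_history = any(not neg for _, neg in prior_hits)
    onset_hits = af_sentences([SectionLabel.DIAGNOSIS, SectionLabel.CURRENT_ILLNESS])
    af_new_onset = any(
        not neg and (qual or not af_prior_history) for qual, neg in onset_hits
    )
    return af_new_onset, af_prior_history


def extract(
    sectioned: SectionedReport,
    text: str,
    schema: Schema,
    rules: NegationRuleSet,
    *,
    patient_id: str = "",
    report_date: Optional[datetime.date] = None,
) -> ReportVector:
    """Produce a :class:`ReportVector` from a sectioned report."""
    folded = fold(text)
    all_mentions: list[Mention] = []
    values: dict[str, Any] = {}
    for spec in schema.variables:
        mentions = _mentions_for(spec, sectioned, folded, rules)
        all_mentions.extend(mentions)
        value = _resolve_value(spec, mentions)
        if value is not None:
            values[spec.variable_id] = value
    af_new_onset, af_prior_history = detect_af_flags(sectioned, text, schema.af, rules)
    return ReportVector(
        report_id=sectioned.report_id,
        patient_id=patient_id,
        report_date=report_date or datetime.date.min,
        values=values,
        af_new_onset=af_new_onset,
        af_prior_history=af_prior_history,
        mentions=all_mentions,
    )
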