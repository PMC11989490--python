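"""Synthetic discharge-report corpus generator with known ground truth.

Emulates, at desk scale, the data universe the pipeline was designed for:
multi-section cardiology discharge reports (the nine standardized
headings), per-patient multi-report timelines anchored on an AF debut
date, a coded-system export with injectable false-positive/false-negative
AF coding at audit-like rates (defaults 23% FP among coded, 26% FN), and
gold annotations recording every injected mention so downstream stages are
testable without real data.

Reports are rendered from sentence templates (bundled per-language data
files) with slot filling; the seed fully determines the corpus
byte-for-byte. Coding false positives are drawn preferentially from
prior-AF patients, mirroring the clinical reality that miscoded "new
onset" entries are mostly prior-AF/recurrence episodes.
"""

from __future__ import annotations

import datetime
import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .types import ClinicalReport, Mention, SectionLabel, SectionSpan

_EPOCH = datetime.date(2018, 1, 1)

#: Variables reported by the coded export (the "coded analytical variables").
CODED_NUMERIC_VARIABLES = (
    "creatinine", "hemoglobin", "tsh", "potassium", "glucose", "lvef", "la_diameter",
)

# Ground-truth sampling priors: (kind, params). Booleans: prevalence;
# numerics: (low, high, decimals); categoricals: (choices, probs).
_SAMPLERS: dict[str, tuple] = {
    "age": ("numeric_int", 40, 92),
    "sex": ("categorical", ("male", "female"), (0.5, 0.5)),
    "diabetes": ("boolean", 0.25),
    "hypertension": ("boolean", 0.50),
    "heart_failure": ("boolean", 0.20),
    "copd": ("boolean", 0.15),
    "stroke": ("boolean", 0.10),
    "ckd": ("boolean", 0.15),
    "hyperthyroidism": ("boolean", 0.05),
    "sleep_apnea": ("boolean", 0.10),
    "creatinine": ("numeric", 0.6, 2.5, 2),
    "hemoglobin": ("numeric", 9.0, 17.0, 1),
    "tsh": ("numeric", 0.3, 6.0, 2),
    "potassium": ("numeric", 3.2, 5.5, 1),
    "glucose": ("numeric", 70.0, 220.0, 0),
    "lvef": ("numeric", 25.0, 70.0, 0),
    "la_diameter": ("numeric", 30.0, 55.0, 0),
}
_MEDICATION_PRESENCE = {"anticoagulant": 0.6, "beta_blocker": 0.5, "antiarrhythmic": 0.3}


class GenerationConfig(BaseModel):
    """Knobs of the synthetic study population; the seed fixes everything."""

    n_patients: int = Field(ge=0)
    af_prevalence: float = Field(default=0.3, ge=0.0, le=1.0)
    prior_af_rate: float = Field(default=0.25, ge=0.0, le=1.0)
    negation_rate: float = Field(default=0.2, ge=0.0, le=1.0)
    synonym_rate: float = Field(default=0.3, ge=0.0, le=1.0)
    distractor_rate: float = Field(default=0.2, ge=0.0, le=1.0)
    coding_fp_rate: float = Field(default=0.23, ge=0.0, lt=1.0)
    coding_fn_rate: float = Field(default=0.26, ge=0.0, le=1.0)
    date_jitter_days: int = Field(default=7, ge=0)
    seed: int = 0
    language_lexicon: str = "spanish"
    onset_documentation_rate: float = Field(default=0.9, ge=0.0, le=1.0)
    coded_missing_rate: float = Field(default=0.5, ge=0.0, le=1.0)
    variable_presence_rate: float = Field(default=0.85, ge=0.0, le=1.0)
    mention_rate: float = Field(default=0.8, ge=0.0, le=1.0)
    min_reports: int = Field(default=1, ge=1)
    max_reports: int = Field(default=4, ge=1)

    @field_validator("language_lexicon")
    @classmethod
    def _known_language(cls, v: str) -> str:
        if v not in ("spanish", "english"):
            raise ValueError("language_lexicon must be 'spanish' or 'english'")
        return v

    @model_validator(mode="after")
    def _report_range(self):
        if self.max_reports < self.min_reports:
            raise ValueError("max_reports must be >= min_reports")
        return self


@dataclass
class PatientProfile:
    patient_id: str
    debut_date: Optional[datetime.date]
    variables: dict[str, Any]
    has_prior_af: bool
    n_reports: int
    anchor_date: datetime.date
    onset_documented: bool = True


@dataclass
class GoldReport:
    """Everything injected into one rendered report."""

    report_id: str
    patient_id: str
    date: datetime.date
    section_spans: list[SectionSpan]
    mentions: list[Mention]  # span = the carrying sentence, value canonical
    values: dict[str, Any]
    af_new_onset: bool
    af_prior_history: bool


@dataclass
class GoldPatient:
    patient_id: str
    debut_date: Optional[datetime.date]
    anchor_date: datetime.date
    has_prior_af: bool
    variables: dict[str, Any]
    onset_report_id: Optional[str]


@dataclass
class GoldAnnotations:
    reports: dict[str, GoldReport] = field(default_factory=dict)
    patients: dict[str, GoldPatient] = field(default_factory=dict)


@lru_cache(maxsize=4)
def load_templates(language: str) -> dict:
    fname = {"spanish": "templates_es.yaml", "english": "templates_en.yaml"}[language]
    with resources.files("afdebut.data").joinpath(fname).open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _rng(config_seed: int, *streams) -> np.random.Generator:
    material = [config_seed % (2**31)]
    for s in streams:
        material.append(zlib.crc32(str(s).encode()) if isinstance(s, str) else int(s))
    return np.random.default_rng(np.random.SeedSequence(material))


def _format_value(value: float, decimals: int) -> str:
    if decimals == 0:
        return str(int(round(value)))
    return f"{value:.{decimals}f}"


def _norm_entry(entry) -> dict:
    return {"text": entry} if isinstance(entry, str) else dict(entry)


def generate_profile(index: int, config: GenerationConfig) -> PatientProfile:
    patient_id = f"P{index:05d}"
    rng = _rng(config.seed, patient_id, "profile")
    anchor = _EPOCH + datetime.timedelta(days=int(rng.integers(0, 730)))
    is_onset = rng.random() < config.af_prevalence
    has_prior = (not is_onset) and rng.random() < config.prior_af_rate
    onset_documented = bool(rng.random() < config.onset_documentation_rate)

    variables: dict[str, Any] = {}
    for var, sampler in _SAMPLERS.items():
        kind = sampler[0]
        if kind == "boolean":
            variables[var] = bool(rng.random() < sampler[1])
        elif kind == "numeric_int":
            variables[var] = float(rng.integers(sampler[1], sampler[2] + 1))
        elif kind == "numeric":
            if rng.random() < config.variable_presence_rate:
                low, high, decimals = sampler[1], sampler[2], sampler[3]
                variables[var] = float(_format_value(rng.uniform(low, high), decimals))
        else:  # categorical
            choices, probs = sampler[1], sampler[2]
            variables[var] = str(rng.choice(choices, p=probs))
    af_patient = is_onset or has_prior
    for med, base_p in _MEDICATION_PRESENCE.items():
        p = base_p if af_patient else base_p * 0.3
        if rng.random() < p:
            variables[med] = "__draw__"  # ATC chosen at render-profile time below
    variables["cardioversion"] = bool(rng.random() < (0.25 if af_patient else 0.02))

    profile = PatientProfile(
        patient_id=patient_id,
        debut_date=anchor if is_onset else None,
        variables=variables,
        has_prior_af=has_prior,
        n_reports=int(rng.integers(config.min_reports, config.max_reports + 1)),
        anchor_date=anchor,
        onset_documented=onset_documented,
    )
    # medication truth = a concrete ATC option from the language templates
    templates = load_templates(config.language_lexicon)
    for med in _MEDICATION_PRESENCE:
        if profile.variables.get(med) == "__draw__":
            options = templates["variables"][med]["options"]
            profile.variables[med] = str(options[int(rng.integers(len(options)))]["atc"])
    return profile


class _ReportBuilder:
    """Accumulates section texts and gold mentions with exact offsets."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.pos = 0
        self.section_spans: list[SectionSpan] = []
        self.mentions: list[tuple[str, SectionLabel, int, int, Any, bool]] = []
        self._section_start: Optional[int] = None
        self._section_label: Optional[SectionLabel] = None

    def _append(self, line: str) -> tuple[int, int]:
        start = self.pos
        self.parts.append(line + "\n")
        self.pos += len(line) + 1
        return start, start + len(line)

    def open_section(self, label: SectionLabel, heading: str) -> None:
        self.close_section()
        self._section_label = label
        self._section_start = self.pos
        self._append(heading)

    def close_section(self) -> None:
        if self._section_label is not None:
            self.section_spans.append(
                SectionSpan(self._section_label, self._section_start, self.pos)
            )
            self._section_label = None

    def sentence(self, text: str, mention: Optional[tuple[str, Any, bool]] = None) -> None:
        start, end = self._append(text)
        if mention is not None:
            var, value, negated = mention
            self.mentions.append((var, self._section_label, start, end, value, negated))

    def text(self) -> str:
        self.close_section()
        full = "".join(self.parts)
        if full.endswith("\n"):  # last span ends at len(text)
            full = full[:-1]
            if self.section_spans and self.section_spans[-1].end > len(full):
                last = self.section_spans[-1]
                self.section_spans[-1] = SectionSpan(last.label, last.start, len(full))
        return full


def _pick(rng: np.random.Generator, entries: list, synonym_rate: float) -> dict:
    """Primary entry, or a synonym variant with probability synonym_rate."""
    entries = [_norm_entry(e) for e in entries]
    if len(entries) > 1 and rng.random() < synonym_rate:
        return entries[1 + int(rng.integers(len(entries) - 1))]
    return entries[0]


def _pick_for_value(rng, entries: list, value: Any, synonym_rate: float) -> dict:
    matching = [_norm_entry(e) for e in entries if _norm_entry(e).get("value") == value]
    return _pick(rng, matching, synonym_rate)


def _render(profile: PatientProfile, report_index: int,
            config: GenerationConfig) -> tuple[ClinicalReport, GoldReport]:
    if report_index >= profile.n_reports:
        raise ValueError("report_index out of range")
    templates = load_templates(config.language_lexicon)
    rng = _rng(config.seed, profile.patient_id, "report", report_index)
    syn = config.synonym_rate

    if report_index == 0:
        date = profile.anchor_date
    else:
        date = profile.anchor_date + datetime.timedelta(days=int(rng.integers(-300, 91)))
    report_id = f"{profile.patient_id}-R{report_index}"

    is_onset_report = (
        profile.debut_date is not None and report_index == 0 and profile.onset_documented
    )
    # prior-AF phrasing: chronic for prior-AF patients; after debut for onset patients
    mentions_prior_af = False
    if profile.has_prior_af:
        mentions_prior_af = rng.random() < 0.9
    elif profile.debut_date is not None and report_index > 0 and date > profile.debut_date:
        mentions_prior_af = rng.random() < 0.7
    af_active = is_onset_report or profile.has_prior_af or mentions_prior_af

    b = _ReportBuilder()
    heading = lambda label: _pick(rng, templates["headings"][label.value], syn)["text"]
    fillers = templates["filler"]
    distractors = templates.get("distractors", {})
    vtemp = templates["variables"]

    def maybe_distractor(label: SectionLabel) -> None:
        pool = distractors.get(label.value)
        if pool and rng.random() < config.distractor_rate:
            b.sentence(str(rng.choice(pool)))

    def variable_sentence(var: str) -> None:
        truth = profile.variables.get(var)
        spec_t = vtemp[var]
        if isinstance(truth, bool):
            if truth:
                if rng.random() < config.mention_rate:
                    entry = _pick(rng, spec_t["affirm"], syn)
                    b.sentence(entry["text"], (var, True, False))
            elif spec_t.get("negated") and rng.random() < config.negation_rate:
                entry = _pick(rng, spec_t["negated"], syn)
                b.sentence(entry["text"], (var, False, True))
        elif isinstance(truth, float):
            if rng.random() < config.mention_rate:
                entry = _pick(rng, spec_t["affirm"], syn)
                shown = _format_value(truth * entry.get("unit_factor", 1.0),
                                      entry.get("decimals", 2))
                b.sentence(entry["text"].format(value=shown), (var, truth, False))
        elif isinstance(truth, str):
            if rng.random() < config.mention_rate:
                if "options" in spec_t:  # medication: truth is an ATC code
                    option = next(o for o in spec_t["options"] if o["atc"] == truth)
                    entry = _pick(rng, spec_t["affirm"], syn)
                    b.sentence(entry["text"].format(drug=option["display"],
                                                    dose=option["dose"]),
                               (var, truth, False))
                else:  # categorical
                    entry = _pick_for_value(rng, spec_t["affirm"], truth, syn)
                    b.sentence(entry["text"], (var, truth, False))

    # --- Header ---
    b.open_section(SectionLabel.HEADER, heading(SectionLabel.HEADER))
    for f in fillers["Header"]:
        b.sentence(f.format(patient_id=profile.patient_id, date=date.isoformat()))

    # --- Reason for consultation: demographics ---
    b.open_section(SectionLabel.REASON_FOR_CONSULTATION,
                   heading(SectionLabel.REASON_FOR_CONSULTATION))
    b.sentence(str(rng.choice(fillers["ReasonForConsultation"])))
    variable_sentence("age")
    variable_sentence("sex")

    # --- Personal history ---
    b.open_section(SectionLabel.PERSONAL_HISTORY, heading(SectionLabel.PERSONAL_HISTORY))
    if mentions_prior_af:
        b.sentence(str(_pick(rng, templates["af"]["prior"], syn)["text"]))
    for var in ("diabetes", "hypertension", "heart_failure", "copd", "stroke",
                "ckd", "hyperthyroidism", "sleep_apnea"):
        variable_sentence(var)
    maybe_distractor(SectionLabel.PERSONAL_HISTORY)

    # --- Current illness ---
    b.open_section(SectionLabel.CURRENT_ILLNESS, heading(SectionLabel.CURRENT_ILLNESS))
    b.sentence(str(rng.choice(fillers["CurrentIllness"])))

    # --- General exploration (optional section) ---
    if rng.random() < 0.6:
        b.open_section(SectionLabel.GENERAL_EXPLORATION,
                       heading(SectionLabel.GENERAL_EXPLORATION))
        b.sentence(str(rng.choice(fillers["GeneralExploration"])))
        maybe_distractor(SectionLabel.GENERAL_EXPLORATION)

    # --- Complementary tests: labs + echo, ECG line ---
    b.open_section(SectionLabel.COMPLEMENTARY_TESTS,
                   heading(SectionLabel.COMPLEMENTARY_TESTS))
    ecg_pool = templates["af"]["ecg"] if af_active else templates["af"]["ecg_normal"]
    b.sentence(str(rng.choice(ecg_pool)))
    for var in ("creatinine", "hemoglobin", "tsh", "potassium", "glucose",
                "lvef", "la_diameter"):
        if var in profile.variables:
            variable_sentence(var)
    b.sentence(str(rng.choice(fillers["ComplementaryTests"])))

    # --- Diagnosis ---
    b.open_section(SectionLabel.DIAGNOSIS, heading(SectionLabel.DIAGNOSIS))
    gold_onset = False
    if is_onset_report:
        if rng.random() < 0.7:
            b.sentence(str(_pick(rng, templates["af"]["onset_qualified"], syn)["text"]))
        else:
            b.sentence(str(_pick(rng, templates["af"]["onset_bare"], syn)["text"]))
        gold_onset = True
    else:
        b.sentence(str(rng.choice(templates["diagnosis_negative"])))
        if not af_active and rng.random() < 0.15:
            b.sentence(str(_pick(rng, templates["af"]["negated"], syn)["text"]))
    maybe_distractor(SectionLabel.DIAGNOSIS)

    # --- Treatment: medications ---
    b.open_section(SectionLabel.TREATMENT, heading(SectionLabel.TREATMENT))
    for var in ("anticoagulant", "beta_blocker", "antiarrhythmic"):
        if var in profile.variables:
            variable_sentence(var)
    b.sentence(str(rng.choice(fillers["Treatment"])))
    maybe_distractor(SectionLabel.TREATMENT)

    # --- Evolution: procedures ---
    b.open_section(SectionLabel.EVOLUTION, heading(SectionLabel.EVOLUTION))
    variable_sentence("cardioversion")
    b.sentence(str(rng.choice(fillers["Evolution"])))
    maybe_distractor(SectionLabel.EVOLUTION)

    text = b.text()
    gold_mentions = [
        Mention(variable_id=var, section=label, start=s, end=e,
                matched_text=text[s:e], value=value, negated=negated)
        for var, label, s, e, value, negated in b.mentions
    ]
    values: dict[str, Any] = {}
    for m in gold_mentions:
        if m.variable_id not in values or not m.negated:
            values[m.variable_id] = False if m.negated else m.value
    report = ClinicalReport(report_id=report_id, patient_id=profile.patient_id,
                            date=date, text=text)
    gold = GoldReport(
        report_id=report_id,
        patient_id=profile.patient_id,
        date=date,
        section_spans=b.section_spans,
        mentions=gold_mentions,
        values=values,
        af_new_onset=gold_onset,
        af_prior_history=mentions_prior_af,
    )
    return report, gold


def render_report(profile: PatientProfile, report_index: int,
                  config: GenerationConfig) -> ClinicalReport:
    """Render one report; deterministic given (profile, report_index, seed)."""
    return _render(profile, report_index, config)[0]


def _coded_export(profiles: list[PatientProfile], gold: GoldAnnotations,
                  config: GenerationConfig) -> pd.DataFrame:
    rng = _rng(config.seed, "coded-export")
    onset = [p for p in profiles if p.debut_date is not None]
    prior = [p for p in profiles if p.has_prior_af]
    other = [p for p in profiles if p.debut_date is None and not p.has_prior_af]

    coded_af: dict[str, Optional[datetime.date]] = {}
    n_tp_expected = len(onset) * (1.0 - config.coding_fn_rate)
    for p in onset:
        if rng.random() < 1.0 - config.coding_fn_rate:
            jitter = int(rng.integers(-config.date_jitter_days, config.date_jitter_days + 1))
            coded_af[p.patient_id] = p.debut_date + datetime.timedelta(days=jitter)

    # FP volume targets fp_rate among coded-AF rows; drawn mostly from
    # prior-AF patients (miscoded recurrence), remainder from the rest.
    fp_target = (config.coding_fp_rate / (1.0 - config.coding_fp_rate)) * n_tp_expected
    pools = []
    if prior:
        pools.append((prior, 0.8 * fp_target))
    if other:
        pools.append((other, 0.2 * fp_target + (0.8 * fp_target if not prior else 0.0)))
    carry = 0.0
    for pool, target in pools:
        target += carry
        p_code = min(1.0, target / len(pool))
        carry = max(0.0, target - p_code * len(pool))
        for patient in pool:
            if rng.random() < p_code:
                report_dates = [g.date for g in gold.reports.values()
                                if g.patient_id == patient.patient_id]
                base = report_dates[int(rng.integers(len(report_dates)))] \
                    if report_dates else patient.anchor_date
                jitter = int(rng.integers(-config.date_jitter_days,
                                          config.date_jitter_days + 1))
                coded_af[patient.patient_id] = base + datetime.timedelta(days=jitter)

    rows = []
    for p in profiles:
        row: dict[str, Any] = {
            "patient_id": p.patient_id,
            "coded_af": p.patient_id in coded_af,
            "coding_date": coded_af.get(p.patient_id),
        }
        for var in CODED_NUMERIC_VARIABLES:
            truth = p.variables.get(var)
            keep = truth is not None and rng.random() >= config.coded_missing_rate
            row[var] = truth if keep else np.nan
        rows.append(row)
    columns = ["patient_id", "coded_af", "coding_date", *CODED_NUMERIC_VARIABLES]
    return pd.DataFrame(rows, columns=columns)


def generate_corpus(
    config: GenerationConfig,
) -> tuple[list[ClinicalReport], pd.DataFrame, GoldAnnotations]:
    """Generate (reports, coded_export, gold) for the configured population."""
    reports: list[ClinicalReport] = []
    gold = GoldAnnotations()
    profiles: list[PatientProfile] = []
    for i in range(config.n_patients):
        profile = generate_profile(i, config)
        profiles.append(profile)
        onset_report_id: Optional[str] = None
        for k in range(profile.n_reports):
            report, greport = _render(profile, k, config)
            reports.append(report)
            gold.reports[report.report_id] = greport
            if greport.af_new_onset:
                onset_report_id = report.report_id
        gold.patients[profile.patient_id] = GoldPatient(
            patient_id=profile.patient_id,
            debut_date=profile.debut_date,
            anchor_date=profile.anchor_date,
            has_prior_af=profile.has_prior_af,
            variables=dict(profile.variables),
            onset_report_id=onset_report_id,
        )
    coded = _coded_export(profiles, gold, config)
    return reports, coded, gold
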