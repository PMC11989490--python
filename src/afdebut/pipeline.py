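"""End-to-end pipeline composition and the intersection-vs-union experiment.

``run_pipeline`` wires the stages — synthesize → section → extract →
overlap → corpora → classify → score — into a run directory of plain
JSONL/CSV artifacts plus a machine-readable manifest, so a run is
reproducible from (config, seed) alone.

``intersection_union_experiment`` is the label-noise study: under coded
false-positive/false-negative rates the intersection corpus (agreement of
coding and regex) is purer than the union, and a classifier trained on it
should generalize better to a clean held-out set.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel

from . import __version__, io
from .classifier import (FeedforwardConfig, HeldoutSet, TfidfConfig,
                         crossval_evaluate, heldout_error, paired_ttest)
from .datasets import build_corpora, label_purity, link_coded_to_reports, summarize
from .evaluation import detection_rate, score_vectors
from .extractor import Schema, builtin_schema, extract, load_schema
from .negation import builtin_rules, load_rules
from .overlap import OverlapConfig, merge, missingness, resolve_debut
from .sectioner import builtin_lexicon, load_lexicon, segment
from .synthetic import (CODED_NUMERIC_VARIABLES, GenerationConfig,
                        GoldAnnotations, generate_corpus)
from .types import ClinicalReport, LabeledCorpus, PatientVector, ReportVector

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Paths + stage configurations; the global seed reaches every stage."""

    corpus_path: Optional[str] = None
    coded_path: Optional[str] = None
    schema_path: Optional[str] = None
    lexicon_path: Optional[str] = None
    rules_path: Optional[str] = None
    language: str = "spanish"
    generation: Optional[GenerationConfig] = None
    n_negatives: Optional[int] = None
    coding_window_days: int = 30
    k_folds: int = 5
    heldout_fraction: float = 0.3
    seed: int = 0
    log_level: str = "INFO"

    def validate_paths(self) -> None:
        for name in ("corpus_path", "coded_path", "schema_path",
                     "lexicon_path", "rules_path"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name} does not exist: {value}")


def _load_resources(config: PipelineConfig):
    schema = load_schema(config.schema_path) if config.schema_path \
        else builtin_schema(config.language)
    lexicon = load_lexicon(config.lexicon_path) if config.lexicon_path \
        else builtin_lexicon(config.language)
    rules = load_rules(config.rules_path) if config.rules_path \
        else builtin_rules(config.language)
    return schema, lexicon, rules


def extract_corpus(reports: list[ClinicalReport], schema: Schema, lexicon,
                   rules) -> list[ReportVector]:
    """Section + extract every report."""
    vectors = []
    for report in reports:
        sectioned = segment(report.text, lexicon, report.report_id)
        vectors.append(extract(sectioned, report.text, schema, rules,
                               patient_id=report.patient_id, report_date=report.date))
    return vectors


def merge_patients(vectors: list[ReportVector], overlap_config: OverlapConfig,
                   anchor_dates: Optional[dict[str, datetime.date]] = None,
                   ) -> dict[str, PatientVector]:
    """Group report vectors per patient, resolve the debut, and merge.

    Anchor = resolved debut when available, else the supplied per-patient
    anchor date, else the latest report date (a patient snapshot with no
    debut to anchor on).
    """
    by_patient: dict[str, list[ReportVector]] = {}
    for v in vectors:
        by_patient.setdefault(v.patient_id, []).append(v)
    merged = {}
    for pid, vs in by_patient.items():
        debut, onset_rid = resolve_debut(vs)
        anchor = debut or (anchor_dates or {}).get(pid) \
            or max(v.report_date for v in vs)
        pv = merge(vs, anchor, overlap_config)
        pv.debut_date = debut
        if pv.af_onset_report_id is None:
            pv.af_onset_report_id = onset_rid
        merged[pid] = pv
    return merged


def build_training_corpora(reports: list[ClinicalReport],
                           vectors: list[ReportVector], coded: pd.DataFrame,
                           n_negatives: Optional[int], seed: int,
                           coding_window_days: int = 30,
                           ) -> tuple[LabeledCorpus, LabeledCorpus]:
    """Reconcile coded and regex AF-onset detections into the two corpora."""
    linked = link_coded_to_reports(coded, reports, coding_window_days)
    coded_positive = {rid for ids in linked.values() for rid in ids}
    regex_positive = {v.report_id for v in vectors if v.af_new_onset}
    positive_patients = {r.patient_id for r in reports
                         if r.report_id in (coded_positive | regex_positive)}
    coded_patients = set(linked)
    pool = [r for r in reports
            if r.patient_id not in positive_patients
            and r.patient_id not in coded_patients]
    if n_negatives is None:
        n_negatives = min(len(pool), 2 * len(coded_positive | regex_positive))
    texts = {r.report_id: r.text for r in reports}
    return build_corpora(coded_positive, regex_positive, pool, n_negatives,
                         seed, texts)


@dataclass
class ExperimentRun:
    seed: int
    error_intersection: float
    error_union: float
    purity_intersection: float
    purity_union: float
    n_heldout: int


def _split_patients(patient_ids: list[str], heldout_fraction: float,
                    seed: int) -> tuple[set[str], set[str]]:
    rng = np.random.default_rng(seed)
    ids = sorted(patient_ids)
    rng.shuffle(ids)
    n_held = int(round(len(ids) * heldout_fraction))
    return set(ids[n_held:]), set(ids[:n_held])


def run_noise_comparison(base: GenerationConfig, run_seed: int,
                         tfidf: Optional[TfidfConfig] = None,
                         ff: Optional[FeedforwardConfig] = None,
                         heldout_fraction: float = 0.3,
                         n_negatives: Optional[int] = None) -> ExperimentRun:
    """One seed of the intersection-vs-union held-out comparison."""
    tfidf = tfidf or TfidfConfig(min_document_frequency=2)
    ff = ff or FeedforwardConfig()
    config = base.model_copy(update={"seed": run_seed})
    reports, coded, gold = generate_corpus(config)
    schema, lexicon, rules = builtin_schema(config.language_lexicon), \
        builtin_lexicon(config.language_lexicon), builtin_rules(config.language_lexicon)
    vectors = extract_corpus(reports, schema, lexicon, rules)

    train_pat, held_pat = _split_patients([p for p in gold.patients],
                                          heldout_fraction, run_seed)
    train_reports = [r for r in reports if r.patient_id in train_pat]
    train_vectors = [v for v in vectors if v.patient_id in train_pat]
    intersection, union = build_training_corpora(
        train_reports, train_vectors, coded, n_negatives, run_seed)

    held_reports = [r for r in reports if r.patient_id in held_pat]
    heldout = HeldoutSet(
        report_ids=[r.report_id for r in held_reports],
        texts=[r.text for r in held_reports],
        labels=[1 if gold.reports[r.report_id].af_new_onset else 0
                for r in held_reports],
    )
    true_ids = {rid for rid, g in gold.reports.items() if g.af_new_onset}
    err_i = heldout_error(intersection, heldout, tfidf, ff, run_seed)
    err_u = heldout_error(union, heldout, tfidf, ff, run_seed)
    return ExperimentRun(
        seed=run_seed,
        error_intersection=err_i,
        error_union=err_u,
        purity_intersection=label_purity(intersection, true_ids),
        purity_union=label_purity(union, true_ids),
        n_heldout=len(held_reports),
    )


def intersection_union_experiment(base: GenerationConfig, seeds: list[int],
                                  **kwargs) -> tuple[list[ExperimentRun], float, float]:
    """Run the comparison over several seeds; returns (runs, t, p) with the
    paired test on per-seed held-out errors (union minus intersection)."""
    runs = [run_noise_comparison(base, s, **kwargs) for s in seeds]
    t, p = paired_ttest([r.error_union for r in runs],
                        [r.error_intersection for r in runs])
    return runs, t, p


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages and write artifacts + manifest under ``out_dir``.

    Returns the manifest dict. Fails fast on missing configured paths.
    """
    config.validate_paths()
    out = io.ensure_dir(out_dir)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {},
                      "config": json.loads(config.model_dump_json())}
    schema, lexicon, rules = _load_resources(config)

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    gold: Optional[GoldAnnotations] = None
    if config.generation is not None:
        gen = config.generation.model_copy(update={"seed": config.seed})
        reports, coded, gold = stage("synth")(lambda: generate_corpus(gen))
        io.write_reports(out / "corpus.jsonl", reports)
        io.write_coded_csv(out / "coded.csv", coded)
        manifest["stages"]["synth"] = {"n_reports": len(reports),
                                       "n_patients": len(gold.patients)}
    else:
        if not (config.corpus_path and config.coded_path):
            raise ValueError("either generation config or corpus/coded paths required")
        reports = io.read_reports(config.corpus_path)
        coded = io.read_coded_csv(config.coded_path)

    sectioned = stage("section")(
        lambda: [segment(r.text, lexicon, r.report_id) for r in reports])
    io.write_sectioned(out / "sectioned.jsonl", sectioned)
    manifest["stages"]["section"] = {"n_reports": len(sectioned)}

    vectors = stage("extract")(
        lambda: [extract(s, r.text, schema, rules, patient_id=r.patient_id,
                         report_date=r.date)
                 for s, r in zip(sectioned, reports)])
    io.write_vectors(out / "vectors.jsonl", vectors)
    manifest["stages"]["extract"] = {"n_vectors": len(vectors)}

    overlap_config = OverlapConfig(variable_class_map=schema.variable_class_map)
    anchors = {p.patient_id: p.anchor_date for p in gold.patients.values()} \
        if gold else None
    merged = stage("overlap")(lambda: merge_patients(vectors, overlap_config, anchors))
    io.write_patient_vectors_csv(out / "patients.csv", list(merged.values()),
                                 schema.variable_ids)
    miss = stage("overlap")(
        lambda: missingness(merged, coded, list(CODED_NUMERIC_VARIABLES)))
    miss.to_csv(out / "missingness.csv", index=False)
    agg = miss[miss["variable"] == "__aggregate__"].iloc[0]
    manifest["stages"]["overlap"] = {
        "n_patients": len(merged),
        "n_debuts": sum(1 for pv in merged.values() if pv.debut_date),
        "missingness_reduction": float(agg["reduction"]),
    }

    intersection, union = stage("corpora")(
        lambda: build_training_corpora(reports, vectors, coded,
                                       config.n_negatives, config.seed,
                                       config.coding_window_days))
    io.write_corpus(out / "intersection.jsonl", intersection)
    io.write_corpus(out / "union.jsonl", union)
    manifest["stages"]["corpora"] = {
        "intersection": dataclasses.asdict(summarize(intersection)),
        "union": dataclasses.asdict(summarize(union)),
    }

    tfidf, ff = TfidfConfig(min_document_frequency=2), FeedforwardConfig()
    result = stage("train")(
        lambda: crossval_evaluate(intersection, tfidf, ff, config.k_folds,
                                  config.seed))
    manifest["stages"]["train"] = {
        "corpus": "intersection", "k_folds": config.k_folds,
        "mean_accuracy": result.mean("accuracy"), "mean_f1": result.mean("f1"),
        "confusions": result.confusions,
    }

    if gold is not None:
        gold_values = {rid: g.values for rid, g in gold.reports.items()}
        metrics = stage("score")(
            lambda: score_vectors(vectors, gold_values, schema.variable_ids))
        gold_onset = {g.patient_id for g in gold.patients.values()
                      if g.debut_date is not None}
        detected = {v.patient_id for v in vectors if v.af_new_onset}
        manifest["stages"]["score"] = {
            "micro_accuracy": metrics.aggregate.metrics()["accuracy"],
            "micro_precision": metrics.aggregate.metrics()["precision"],
            "macro_accuracy": metrics.macro_average("accuracy"),
            "onset_detection_rate": detection_rate(gold_onset, detected)
            if gold_onset else None,
        }
        with open(out / "metrics.json", "w", encoding="utf-8") as fh:
            json.dump({var: m for var, m in metrics.per_variable_metrics().items()},
                      fh, indent=2)

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
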