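"""AF-onset report classification: tf-idf features + feedforward network.

The report classifier mirrors the winning pipeline of the source system:
unicode word tokens (lower-cased, accent-folded), tf-idf weights with
add-one idf smoothing and L2-normalized rows, fed to a small feedforward
network. Evaluation is stratified k-fold with per-fold confusion matrices;
corpora are compared on a shared clean held-out set with a paired t-test
across folds. Vectorization and the network are delegated to scikit-learn;
the model interface is pluggable so other feature/classifier pairs can be
dropped in.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .textutils import fold
from .types import LabeledCorpus


@dataclass
class TfidfConfig:
    min_document_frequency: int = 1
    max_features: Optional[int] = None
    sublinear_tf: bool = False

    def __post_init__(self) -> None:
        if self.min_document_frequency < 1:
            raise ValueError("min_document_frequency must be >= 1")


@dataclass
class FeedforwardConfig:
    hidden_layers: tuple[int, ...] = (128,)
    activation: str = "relu"
    max_epochs: int = 200
    learning_rate: float = 1e-3
    # A held-out-score stopping rule needs a validation split large enough
    # to be informative; at the corpus sizes this package targets a 10%
    # split stops training at the majority-class plateau, so capacity is
    # controlled by the small architecture and the epoch cap instead.
    early_stopping: bool = False

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.hidden_layers):
            raise ValueError("hidden layer widths must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def build_vectorizer(config: TfidfConfig) -> TfidfVectorizer:
    """tf-idf with idf(t) = ln((1+N)/(1+df)) + 1 and L2-normalized rows."""
    return TfidfVectorizer(
        preprocessor=fold,
        token_pattern=r"(?u)\b\w+\b",
        min_df=config.min_document_frequency,
        max_features=config.max_features,
        sublinear_tf=config.sublinear_tf,
        smooth_idf=True,
        norm="l2",
    )


def tfidf_fit_transform(texts: Sequence[str], config: TfidfConfig):
    """Fit tf-idf on a corpus; returns (weight matrix, vocabulary dict)."""
    if not texts:
        raise ValueError("corpus is empty")
    vectorizer = build_vectorizer(config)
    try:
        matrix = vectorizer.fit_transform(texts)
    except ValueError as exc:
        raise ValueError(f"tf-idf configuration yields no vocabulary: {exc}") from exc
    return matrix, vectorizer.vocabulary_


def build_network(config: FeedforwardConfig, seed: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=config.hidden_layers,
        activation=config.activation,
        max_iter=config.max_epochs,
        learning_rate_init=config.learning_rate,
        early_stopping=config.early_stopping,
        validation_fraction=0.1,
        random_state=seed,
    )


def metrics_from_confusion(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    total = tp + fp + fn + tn
    accuracy = (tp + tn) / total if total else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


@dataclass
class EvalResult:
    """Per-fold metrics, recomputable from the stored confusion matrices."""

    confusions: list[tuple[int, int, int, int]]  # (tp, fp, fn, tn) per fold
    fold_assignments: list[np.ndarray]

    @property
    def fold_metrics(self) -> list[dict[str, float]]:
        return [metrics_from_confusion(*c) for c in self.confusions]

    def metric(self, name: str) -> np.ndarray:
        return np.array([m[name] for m in self.fold_metrics])

    def mean(self, name: str) -> float:
        return float(self.metric(name).mean())


def _fit_quietly(clf: MLPClassifier, x, y) -> None:
    # hitting the epoch cap before the loss tolerance is expected at these
    # corpus sizes; the cap is the regularizer, not a failure
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(x, y)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return tp, fp, fn, tn


def crossval_evaluate(corpus: LabeledCorpus, tfidf: TfidfConfig,
                      ff: FeedforwardConfig, k_folds: int = 5,
                      seed: int = 0) -> EvalResult:
    """Stratified k-fold evaluation; tf-idf is fitted on training folds only."""
    texts = corpus.texts
    y = np.asarray(corpus.labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("corpus must contain both classes")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    confusions, assignments = [], []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        vectorizer = build_vectorizer(tfidf)
        x_train = vectorizer.fit_transform([texts[i] for i in train_idx])
        x_test = vectorizer.transform([texts[i] for i in test_idx])
        clf = build_network(ff, seed)
        _fit_quietly(clf, x_train, y[train_idx])
        confusions.append(_confusion(y[test_idx], clf.predict(x_test)))
        assignments.append(test_idx)
    return EvalResult(confusions=confusions, fold_assignments=assignments)


def paired_ttest(scores_a: Sequence[float], scores_b: Sequence[float]) -> tuple[float, float]:
    """Classic paired t-test on fold-paired score vectors.

    Degenerate contracts: identical vectors → (0, 1); zero-variance nonzero
    differences → (±inf, 0).
    """
    a, b = np.asarray(scores_a, dtype=float), np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("score vectors must be equal-length 1-d with n >= 2")
    d = a - b
    mean, sd = float(d.mean()), float(d.std(ddof=1))
    n = len(d)
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, mean), 0.0
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return t, p


@dataclass
class HeldoutSet:
    report_ids: list[str]
    texts: list[str]
    labels: list[int]


@dataclass
class ComparisonResult:
    eval_a: EvalResult
    eval_b: EvalResult
    heldout_error_a: float
    heldout_error_b: float
    t_statistic: float
    p_value: float
    extras: dict = field(default_factory=dict)


def _fit_full(corpus: LabeledCorpus, tfidf: TfidfConfig, ff: FeedforwardConfig, seed: int):
    vectorizer = build_vectorizer(tfidf)
    x = vectorizer.fit_transform(corpus.texts)
    clf = build_network(ff, seed)
    _fit_quietly(clf, x, np.asarray(corpus.labels))
    return vectorizer, clf


def heldout_error(corpus: LabeledCorpus, heldout: HeldoutSet, tfidf: TfidfConfig,
                  ff: FeedforwardConfig, seed: int) -> float:
    """Error rate on the held-out set of a model trained on the full corpus."""
    vectorizer, clf = _fit_full(corpus, tfidf, ff, seed)
    pred = clf.predict(vectorizer.transform(heldout.texts))
    return float(np.mean(pred != np.asarray(heldout.labels)))


def compare_corpora(corpus_a: LabeledCorpus, corpus_b: LabeledCorpus,
                    heldout: HeldoutSet, tfidf: TfidfConfig, ff: FeedforwardConfig,
                    k_folds: int = 5, seed: int = 0) -> ComparisonResult:
    """Train identically on two corpora; evaluate both on one clean held-out
    set and compare per-fold F1 with a paired t-test."""
    train_ids = {e.report_id for e in corpus_a.entries} | \
                {e.report_id for e in corpus_b.entries}
    overlap = train_ids & set(heldout.report_ids)
    if overlap:
        raise ValueError(f"held-out set overlaps training corpora: {sorted(overlap)[:5]}")
    eval_a = crossval_evaluate(corpus_a, tfidf, ff, k_folds, seed)
    eval_b = crossval_evaluate(corpus_b, tfidf, ff, k_folds, seed)
    err_a = heldout_error(corpus_a, heldout, tfidf, ff, seed)
    err_b = heldout_error(corpus_b, heldout, tfidf, ff, seed)
    t, p = paired_ttest(eval_a.metric("f1"), eval_b.metric("f1"))
    return ComparisonResult(eval_a=eval_a, eval_b=eval_b,
                            heldout_error_a=err_a, heldout_error_b=err_b,
                            t_statistic=t, p_value=p)
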