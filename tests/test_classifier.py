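"""tf-idf weights, metric identities, paired t-test, cross-validation."""

import math

import numpy as np
import pytest
from scipy import stats

from afdebut.classifier import (EvalResult, FeedforwardConfig, HeldoutSet,
                                TfidfConfig, compare_corpora, crossval_evaluate,
                                metrics_from_confusion, paired_ttest,
                                tfidf_fit_transform)
from afdebut.types import CorpusEntry, LabeledCorpus

from oracles import oracle_tfidf

FAST_FF = FeedforwardConfig(hidden_layers=(16,), max_epochs=80)


def make_corpus(name, texts, labels):
    return LabeledCorpus(name, [
        CorpusEntry(f"r{i}", t, "af_onset" if y else "negative",
                    "both" if y else "sampled_negative")
        for i, (t, y) in enumerate(zip(texts, labels))])


def test_tfidf_single_document_closed_form():
    matrix, vocab = tfidf_fit_transform(["a a b"], TfidfConfig())
    row = matrix.toarray()[0]
    expected = np.array([2.0, 1.0]) / math.sqrt(5.0)
    assert row[vocab["a"]] == pytest.approx(expected[0])
    assert row[vocab["b"]] == pytest.approx(expected[1])


def test_tfidf_ubiquitous_term_has_unit_idf():
    texts = ["x common", "y common", "z common"]
    matrix, vocab = tfidf_fit_transform(texts, TfidfConfig())
    idf = math.log((1 + 3) / (1 + 3)) + 1.0
    # row "x common": weights (idf_x, 1.0), L2-normalized
    idf_x = math.log(4 / 2) + 1.0
    norm = math.sqrt(idf_x ** 2 + idf ** 2)
    assert matrix.toarray()[0][vocab["common"]] == pytest.approx(idf / norm)


def test_tfidf_matches_bruteforce_counts_oracle():
    rng = np.random.default_rng(1)
    words = [f"w{i}" for i in range(30)]
    texts = [" ".join(rng.choice(words, size=rng.integers(3, 15)))
             for _ in range(50)]
    matrix, vocab = tfidf_fit_transform(texts, TfidfConfig())
    oracle_vocab, oracle_rows = oracle_tfidf(texts)
    assert sorted(vocab) == oracle_vocab
    dense = matrix.toarray()
    for j, word in enumerate(oracle_vocab):
        np.testing.assert_allclose(dense[:, vocab[word]],
                                   [r[j] for r in oracle_rows], atol=1e-12)


def test_empty_vocabulary_is_configuration_error():
    with pytest.raises(ValueError):
        tfidf_fit_transform(["a b", "c d"], TfidfConfig(min_document_frequency=3))
    with pytest.raises(ValueError):
        tfidf_fit_transform([], TfidfConfig())


def test_confusion_metric_identities():
    m = metrics_from_confusion(2, 0, 0, 2)
    assert m == {"accuracy": 1.0, "precision": 1.0, "recall": 1.0, "f1": 1.0}
    m = metrics_from_confusion(3, 1, 2, 4)
    assert m["accuracy"] == pytest.approx(7 / 10)
    assert m["precision"] == pytest.approx(3 / 4)
    assert m["recall"] == pytest.approx(3 / 5)
    assert m["f1"] == pytest.approx(2 * (3 / 4) * (3 / 5) / ((3 / 4) + (3 / 5)))


def test_eval_result_metrics_recomputable_from_confusions():
    result = EvalResult(confusions=[(5, 1, 2, 10), (4, 0, 1, 12)],
                        fold_assignments=[np.arange(2)] * 2)
    for conf, metrics in zip(result.confusions, result.fold_metrics):
        tp, fp, fn, tn = conf
        total = tp + fp + fn + tn
        assert metrics["accuracy"] == (tp + tn) / total
        prec, rec = tp / (tp + fp) if tp + fp else 0, tp / (tp + fn) if tp + fn else 0
        assert metrics["precision"] == prec and metrics["recall"] == rec


def test_paired_ttest_identical_and_degenerate():
    assert paired_ttest([0.5, 0.6, 0.7], [0.5, 0.6, 0.7]) == (0.0, 1.0)
    t, p = paired_ttest([1, 1, 1, 1], [0, 0, 0, 0])
    assert math.isinf(t) and t > 0 and p == 0.0
    with pytest.raises(ValueError):
        paired_ttest([1.0], [2.0])


def test_paired_ttest_matches_hand_formula_and_scipy():
    a = [0.9, 0.8, 0.85, 0.95]
    b = [0.7, 0.75, 0.8, 0.7]
    t, p = paired_ttest(a, b)
    d = np.array(a) - np.array(b)
    t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
    assert t == pytest.approx(t_hand)
    t_sp, p_sp = stats.ttest_rel(a, b)
    assert t == pytest.approx(t_sp) and p == pytest.approx(p_sp)


def test_separable_corpus_reaches_near_perfect_f1():
    """Distinct marker tokens per class are linearly separable; the tf-idf +
    feedforward pipeline should be nearly perfect."""
    rng = np.random.default_rng(0)
    filler = [f"f{i}" for i in range(20)]
    texts, labels = [], []
    for i in range(400):
        label = i % 2
        marker = "onsetmarker" if label else "negativemarker"
        words = list(rng.choice(filler, size=6)) + [marker]
        rng.shuffle(words)
        texts.append(" ".join(words))
        labels.append(label)
    corpus = make_corpus("sep", texts, labels)
    result = crossval_evaluate(corpus, TfidfConfig(), FeedforwardConfig(),
                               k_folds=5, seed=0)
    assert result.mean("f1") >= 0.99


def test_single_class_corpus_rejected():
    corpus = make_corpus("one", ["a b", "a c"], [1, 1])
    with pytest.raises(ValueError):
        crossval_evaluate(corpus, TfidfConfig(), FAST_FF, k_folds=2, seed=0)


def test_crossval_is_seed_deterministic():
    rng = np.random.default_rng(3)
    texts = [" ".join(rng.choice([f"w{i}" for i in range(15)], size=8))
             for _ in range(60)]
    labels = [i % 2 for i in range(60)]
    corpus = make_corpus("det", texts, labels)
    r1 = crossval_evaluate(corpus, TfidfConfig(), FAST_FF, k_folds=3, seed=5)
    r2 = crossval_evaluate(corpus, TfidfConfig(), FAST_FF, k_folds=3, seed=5)
    assert r1.confusions == r2.confusions
    assert all((a == b).all() for a, b in zip(r1.fold_assignments, r2.fold_assignments))


def test_compare_corpora_smoke_and_overlap_guard():
    rng = np.random.default_rng(4)
    filler = [f"w{i}" for i in range(10)]
    def doc(label):
        words = list(rng.choice(filler, size=5)) + (["onsetmarker"] if label else [])
        return " ".join(words)
    labels = [i % 2 for i in range(20)]
    corpus = make_corpus("a", [doc(y) for y in labels], labels)
    heldout = HeldoutSet(report_ids=[f"h{i}" for i in range(10)],
                         texts=[doc(i % 2) for i in range(10)],
                         labels=[i % 2 for i in range(10)])
    result = compare_corpora(corpus, corpus, heldout, TfidfConfig(), FAST_FF,
                             k_folds=2, seed=0)
    # identical corpora: identical models, same held-out error, t = 0
    assert result.heldout_error_a == result.heldout_error_b
    assert result.t_statistic == 0.0 and result.p_value == 1.0

    bad = HeldoutSet(report_ids=["r0"], texts=["x"], labels=[0])
    with pytest.raises(ValueError):
        compare_corpora(corpus, corpus, bad, TfidfConfig(), FAST_FF, 2, 0)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        TfidfConfig(min_document_frequency=0)
    with pytest.raises(ValueError):
        FeedforwardConfig(hidden_layers=(0,))
    with pytest.raises(ValueError):
        FeedforwardConfig(learning_rate=0.0)
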