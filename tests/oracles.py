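"""Independent brute-force reference implementations used by the tests.

Each oracle recomputes a quantity by direct enumeration, deliberately
avoiding the package's own code paths (shared tokenization/folding
primitives excepted).
"""

from __future__ import annotations

import collections
import math
import re

from afdebut.negation import NegationRuleSet
from afdebut.textutils import fold, tokenize


def oracle_is_negated(text: str, span: tuple[int, int], rules: NegationRuleSet) -> bool:
    """Exhaustive scan over every trigger occurrence in the sentence."""
    toks = tokenize(fold(text))
    words = [t for t, _, _ in toks]
    idx = [i for i, (_, s, e) in enumerate(toks) if s < span[1] and e > span[0]]
    if not idx:
        return False
    first, last = idx[0], idx[-1]
    terms = set(rules.terminators)

    def occurrences(phrase):
        ptoks = [t for t, _, _ in tokenize(phrase)]
        n = len(ptoks)
        return [i for i in range(len(words) - n + 1) if words[i:i + n] == ptoks], n

    for phrase in rules.pre_triggers:
        positions, n = occurrences(phrase)
        for i in positions:
            trigger_end = i + n - 1
            if trigger_end < first:
                distance = first - trigger_end
                between = words[trigger_end + 1:first]
                if distance <= rules.scope_window and not any(w in terms for w in between):
                    return True
    for phrase in rules.post_triggers:
        positions, _ = occurrences(phrase)
        for i in positions:
            if i > last:
                distance = i - last
                between = words[last + 1:i]
                if distance <= rules.scope_window and not any(w in terms for w in between):
                    return True
    return False


def oracle_tfidf(texts):
    """Two-pass tf/df computation: idf = ln((1+N)/(1+df)) + 1, L2 rows."""
    docs = [re.findall(r"\w+", fold(t)) for t in texts]
    vocab = sorted({w for d in docs for w in d})
    n_docs = len(docs)
    df = {w: sum(1 for d in docs if w in d) for w in vocab}
    rows = []
    for d in docs:
        tf = collections.Counter(d)
        vec = [tf[w] * (math.log((1 + n_docs) / (1 + df[w])) + 1.0) for w in vocab]
        norm = math.sqrt(sum(v * v for v in vec))
        rows.append([v / norm if norm else 0.0 for v in vec])
    return vocab, rows


def oracle_nearest_candidate(vectors, variable_id, debut_date, before, after):
    """Linear scan for the eligible candidate closest to debut.

    Returns (value, report_id) or None. Tie-break: earlier report date,
    then smaller report id.
    """
    best = None
    for rv in vectors:
        if variable_id not in rv.values:
            continue
        d = (rv.report_date - debut_date).days
        if before is not None and d < -before:
            continue
        if d > after:
            continue
        key = (abs(d), rv.report_date, rv.report_id)
        if best is None or key < best[0]:
            best = (key, rv.values[variable_id], rv.report_id)
    return None if best is None else (best[1], best[2])


def oracle_cell_counts(extracted_values, gold_values, variables, tol):
    """Enumerate every (report, variable) cell directly."""
    counts = {v: [0, 0, 0, 0] for v in variables}  # tp, fp, fn, tn
    for rid, gvals in gold_values.items():
        evals = extracted_values[rid]
        for var in variables:
            has_e, has_g = var in evals, var in gvals
            if has_e and has_g:
                e, g = evals[var], gvals[var]
                if isinstance(g, bool) or isinstance(e, bool):
                    ok = e == g
                elif isinstance(g, (int, float)) and isinstance(e, (int, float)):
                    ok = abs(float(e) - float(g)) <= tol * max(abs(float(g)), 1e-12)
                else:
                    ok = e == g
                counts[var][0 if ok else 1] += 1
            elif has_e:
                counts[var][1] += 1
            elif has_g:
                counts[var][2] += 1
            else:
                counts[var][3] += 1
    return counts
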