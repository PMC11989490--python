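"""NegEx-style negation detection with token-distance scope.

Decides whether a candidate mention inside one sentence is negated: a
pre-trigger phrase ("no", "sin", "denies" ...) within ``scope_window``
tokens *before* the mention negates it, as does a post-trigger within
``scope_window`` tokens *after*, unless a scope terminator (a conjunction
or listed punctuation) intervenes. Hedging ("possible AF") is not negation.

Callers are expected to pass sentence text (see
:func:`afdebut.textutils.split_sentences`); scope never crosses sentences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

from .textutils import fold, tokenize

DEFAULT_SCOPE_WINDOW = 5


@dataclass(frozen=True)
class NegationRuleSet:
    pre_triggers: tuple[str, ...]
    post_triggers: tuple[str, ...]
    terminators: tuple[str, ...]
    scope_window: int = DEFAULT_SCOPE_WINDOW

    def __post_init__(self) -> None:
        if self.scope_window < 1:
            raise ValueError("scope_window must be >= 1")
        if not self.pre_triggers or not self.post_triggers:
            raise ValueError("trigger lists must be non-empty")
        for phrase in (*self.pre_triggers, *self.post_triggers, *self.terminators):
            if phrase != phrase.lower():
                raise ValueError(f"trigger phrases must be lower-cased: {phrase!r}")


def load_rules(source) -> NegationRuleSet:
    """Load a rule set from YAML (path or parsed mapping)."""
    if isinstance(source, dict):
        raw = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    return NegationRuleSet(
        pre_triggers=tuple(fold(p) for p in raw["pre_triggers"]),
        post_triggers=tuple(fold(p) for p in raw["post_triggers"]),
        terminators=tuple(fold(p) for p in raw.get("terminators", [])),
        scope_window=int(raw.get("scope_window", DEFAULT_SCOPE_WINDOW)),
    )


def builtin_rules(language: str) -> NegationRuleSet:
    fname = {"spanish": "negation_es.yaml", "english": "negation_en.yaml"}[language]
    with resources.files("afdebut.data").joinpath(fname).open("r", encoding="utf-8") as fh:
        return load_rules(yaml.safe_load(fh))


def _phrase_tokens(phrase: str) -> tuple[str, ...]:
    return tuple(t for t, _, _ in tokenize(phrase))


def _ends_with_phrase(tokens: list[str], end: int, phrase: tuple[str, ...]) -> bool:
    n = len(phrase)
    return end >= n and tuple(tokens[end - n : end]) == phrase


def _starts_with_phrase(tokens: list[str], start: int, phrase: tuple[str, ...]) -> bool:
    n = len(phrase)
    return tuple(tokens[start : start + n]) == phrase


def is_negated(text: str, mention: tuple[int, int], rules: NegationRuleSet) -> bool:
    """True iff the mention span in ``text`` falls in a negation scope.

    A pre-trigger negates if its last token lies within ``scope_window``
    tokens before the mention's first token and no terminator token occurs
    strictly between trigger and mention; symmetrically for post-triggers.

    Raises ``ValueError`` if the span lies outside the text.
    """
    start, end = mention
    if not (0 <= start < end <= len(text)):
        raise ValueError(f"mention span ({start}, {end}) outside text of length {len(text)}")

    folded = fold(text)
    toks = tokenize(folded)
    words = [t for t, _, _ in toks]
    # token indices overlapping the mention span
    overlap = [i for i, (_, ts, te) in enumerate(toks) if ts < end and te > start]
    if not overlap:
        return False
    first, last = overlap[0], overlap[-1]

    # terminators are single tokens (conjunctions, punctuation)
    term_tokens = set(rules.terminators)

    def blocked(lo: int, hi: int) -> bool:
        """A terminator token strictly inside tokens[lo:hi] breaks the scope."""
        return any(w in term_tokens for w in words[lo:hi])

    window = rules.scope_window
    for phrase in rules.pre_triggers:
        ptoks = _phrase_tokens(phrase)
        # trigger's last token at index j-1; distance first-(j-1) must be <= window
        lo = max(len(ptoks), first - window + 1)
        for j in range(lo, first + 1):
            if _ends_with_phrase(words, j, ptoks) and not blocked(j, first):
                return True
    for phrase in rules.post_triggers:
        ptoks = _phrase_tokens(phrase)
        # trigger's first token at index j; distance j-last must be <= window
        hi = min(len(words) - len(ptoks), last + window)
        for j in range(last + 1, hi + 1):
            if _starts_with_phrase(words, j, ptoks) and not blocked(last + 1, j):
                return True
    return False
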