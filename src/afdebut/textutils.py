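"""Text normalization primitives used by every matching stage.

Matching throughout the package happens on *accent-folded, lower-cased*
text. Folding is length-preserving (each input character maps to exactly
one output character), so match offsets on the folded text are valid
offsets into the original text.
"""

from __future__ import annotations

import re
import unicodedata
from functools import lru_cache


@lru_cache(maxsize=4096)
def _fold_char(ch: str) -> str:
    decomposed = unicodedata.normalize("NFD", ch)
    for d in decomposed:
        if unicodedata.category(d) != "Mn":
            return d
    return " "  # a bare combining mark: keep length, lose the mark


def fold(text: str) -> str:
    """Lower-case and strip diacritics, preserving string length.

    ``fold("Apixabán")`` → ``"apixaban"``; offsets are unchanged because a
    precomposed accented character folds to a single base character.
    """
    return "".join(_fold_char(ch) for ch in text).lower()


_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Split into word and punctuation tokens with ``(token, start, end)``."""
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


# A sentence ends at a newline or at a period followed by whitespace and an
# upper-case letter; negation never crosses a sentence boundary.
_SENT_BOUNDARY_RE = re.compile(r"\n|\.(?=\s+[A-ZÁÉÍÓÚÜÑ])")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Return ``(start, end)`` sentence spans covering ``text``.

    Boundaries: newline, or period followed by whitespace + capital letter.
    Empty segments are dropped.
    """
    spans: list[tuple[int, int]] = []
    pos = 0
    for m in _SENT_BOUNDARY_RE.finditer(text):
        end = m.end() if m.group(0) != "\n" else m.start()
        if end > pos:
            spans.append((pos, end))
        pos = m.end()
    if len(text) > pos:
        spans.append((pos, len(text)))
    return spans
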