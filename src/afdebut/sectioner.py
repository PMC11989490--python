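"""Rule-based segmentation of a report into standardized sections.

A deterministic heading-lexicon segmenter: a line whose content (after
accent folding, lower-casing and stripping an optional trailing colon)
equals one of the lexicon's surface forms opens a new section that runs to
the next recognized heading or the end of the text. Text before the first
recognized heading is labeled ``Unknown`` and excluded from extraction.
The module boundary allows a learned segmenter to be swapped in later.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .textutils import fold
from .types import SectionLabel, SectionSpan, SectionedReport

HeadingLexicon = dict[str, SectionLabel]
"""Maps a folded heading surface form → its section label."""


def load_lexicon(source) -> HeadingLexicon:
    """Load a heading lexicon from a YAML mapping ``label -> [surface, ...]``.

    ``source`` may be a path or an already-parsed mapping. Surface forms are
    folded; a trailing colon in a surface form is stripped.
    """
    if isinstance(source, dict):
        raw = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    lexicon: HeadingLexicon = {}
    for label_name, surfaces in raw.items():
        label = SectionLabel(label_name)
        for surface in surfaces:
            key = fold(surface).strip().rstrip(":").strip()
            if not key:
                raise ValueError(f"empty heading surface for {label_name}")
            lexicon[key] = label
    if not lexicon:
        raise ValueError("heading lexicon is empty")
    return lexicon


def builtin_lexicon(language: str) -> HeadingLexicon:
    """Bundled heading lexicon: ``"spanish"`` or ``"english"``."""
    fname = {"spanish": "lexicon_es.yaml", "english": "lexicon_en.yaml"}[language]
    with resources.files("afdebut.data").joinpath(fname).open("r", encoding="utf-8") as fh:
        return load_lexicon(yaml.safe_load(fh))


def _match_heading(line: str, lexicon: HeadingLexicon) -> SectionLabel | None:
    key = fold(line).strip().rstrip(":").strip()
    return lexicon.get(key)


def segment(text: str, lexicon: HeadingLexicon, report_id: str = "") -> SectionedReport:
    """Segment ``text`` into full-coverage, non-overlapping section spans.

    A section extends from the start of its heading line to the next
    recognized heading line (exclusive) or end of text. With no recognized
    heading the whole text is one ``Unknown`` span; empty text yields no
    spans.
    """
    if not text:
        return SectionedReport(report_id=report_id, spans=[])

    # (line_start_offset, label) for every recognized heading line
    headings: list[tuple[int, SectionLabel]] = []
    pos = 0
    for line in text.splitlines(keepends=True):
        stripped = line.rstrip("\n").rstrip("\r")
        label = _match_heading(stripped, lexicon)
        if label is not None:
            headings.append((pos, label))
        pos += len(line)

    spans: list[SectionSpan] = []
    if not headings or headings[0][0] > 0:
        first = headings[0][0] if headings else len(text)
        spans.append(SectionSpan(SectionLabel.UNKNOWN, 0, first))
    for i, (start, label) in enumerate(headings):
        end = headings[i + 1][0] if i + 1 < len(headings) else len(text)
        spans.append(SectionSpan(label, start, end))
    sectioned = SectionedReport(report_id=report_id, spans=spans)
    sectioned.validate(len(text))
    return sectioned
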