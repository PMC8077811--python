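"""Text normalization, sentence splitting, and tokenization.

The pipeline mirrors common French clinical-text preprocessing:

1. acronym-internal periods are removed (``I.V.`` -> ``IV``) so that only
   sentence-final periods survive as boundary candidates;
2. decimal points between digits become commas (``2.5`` -> ``2,5``), the
   French convention, which also keeps them out of sentence splitting;
3. line breaks introduced when documents were converted to plain text
   (hard-wrapped lines) are replaced by spaces; deliberate line breaks are
   kept as sentence-boundary candidates;
4. accents are stripped to their ASCII base letters (``à jeûn`` -> ``a jeun``);
5. apostrophes become spaces (``d'aspirine`` -> ``d aspirine``).

Every character of the normalized text carries the index of the raw character
it came from (the *offset map*), so downstream annotations — which all live in
normalized coordinates — can be projected back onto the original document.

Sentence boundaries are the remaining periods and retained line breaks,
except when the word immediately before or after the candidate is a
continuation word (French prepositions and coordinating conjunctions, shipped
as a config file): a prescription line ending in "traitement par" continues on
the next line.

Tokens are maximal alphanumeric runs, or maximal runs of one repeated
non-alphanumeric character: ``3x/jour !!!`` -> ``3x``, ``/``, ``jour``,
``!!!``.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "NormalizationResult",
    "Token",
    "normalize_text",
    "split_sentences",
    "tokenize",
    "load_continuation_words",
    "default_continuation_words",
]


@dataclass(frozen=True)
class Token:
    """A token anchored in the normalized document text (half-open offsets)."""

    text: str
    char_start: int
    char_end: int
    sentence_index: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.char_start < self.char_end):
            raise ValueError(f"bad token offsets [{self.char_start}, {self.char_end})")


@dataclass(frozen=True)
class NormalizationResult:
    """Normalized text plus a per-character map back to raw-text indices."""

    normalized_text: str
    offset_map: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.offset_map) != len(self.normalized_text):
            raise ValueError("offset map length must equal normalized text length")


# Periods inside uppercase acronyms: at least "X.Y", not preceded/followed by
# other letters ("I.V." matched in full including a trailing period).
_ACRONYM_RE = re.compile(r"(?<![A-Za-z0-9])[A-Z](?:\.[A-Z])+\.?(?![A-Za-z0-9])")
_APOSTROPHES = {"'", "’", "ʼ"}


def _acronym_period_indices(raw: str) -> set[int]:
    drop: set[int] = set()
    for m in _ACRONYM_RE.finditer(raw):
        for i in range(m.start(), m.end()):
            if raw[i] == ".":
                drop.add(i)
    return drop


def _decimal_period_indices(raw: str) -> set[int]:
    return {
        m.start() + 1
        for m in re.finditer(r"\d\.\d", raw)
    }


def _wrap_break_indices(raw: str) -> set[int]:
    """Indices of line breaks that are conversion artifacts, not boundaries.

    A break is a wrap artifact when the line before it does not end with a
    period and the next line starts with a lowercase letter.
    """
    wraps: set[int] = set()
    for m in re.finditer(r"\n", raw):
        i = m.start()
        prev_nl = raw.rfind("\n", 0, i)
        next_nl = raw.find("\n", i + 1)
        prev_line = raw[prev_nl + 1 : i].strip(" \t\r")
        next_line = raw[i + 1 : next_nl if next_nl != -1 else len(raw)].strip(" \t\r")
        if (
            prev_line
            and not prev_line.endswith(".")
            and next_line
            and next_line[0].islower()
        ):
            wraps.add(i)
    return wraps


def _strip_accents(ch: str) -> str:
    decomposed = unicodedata.normalize("NFKD", ch)
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    return stripped if stripped else ch


def normalize_text(raw: str) -> NormalizationResult:
    """Normalize raw clinical text; total function, offset-mapped."""
    acro = _acronym_period_indices(raw)
    decimals = _decimal_period_indices(raw)
    wraps = _wrap_break_indices(raw)

    out: list[str] = []
    offmap: list[int] = []
    for i, ch in enumerate(raw):
        if ch == "\r":
            continue
        if i in acro:
            continue
        if i in decimals:
            out.append(",")
            offmap.append(i)
            continue
        if ch in _APOSTROPHES:
            out.append(" ")
            offmap.append(i)
            continue
        if ch == "\n":
            out.append(" " if i in wraps else "\n")
            offmap.append(i)
            continue
        for sub in _strip_accents(ch):
            out.append(sub)
            offmap.append(i)
    return NormalizationResult("".join(out), tuple(offmap))


def load_continuation_words(path) -> frozenset[str]:
    """Read a continuation-word list: one word per line, '#' comments."""
    words = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            word = line.split("#", 1)[0].strip().lower()
            if word:
                words.add(word)
    return frozenset(words)


def default_continuation_words() -> frozenset[str]:
    """The shipped French preposition / coordinating-conjunction list."""
    text = resources.files("medextract.data").joinpath("continuation_words.txt").read_text(
        encoding="utf-8"
    )
    words = set()
    for line in text.splitlines():
        word = line.split("#", 1)[0].strip().lower()
        if word:
            words.add(word)
    return frozenset(words)


_WORD_RE = re.compile(r"[A-Za-z0-9]+")


def _word_before(text: str, pos: int) -> str:
    m = None
    for m in _WORD_RE.finditer(text, max(0, pos - 40), pos):
        pass
    if m is None or text[m.end() : pos].strip(" \t"):
        return ""
    return m.group(0)


def _word_after(text: str, pos: int) -> str:
    m = _WORD_RE.search(text, pos)
    if m is None or text[pos : m.start()].strip(" \t\n"):
        return ""
    return m.group(0)


def split_sentences(
    normalized: str, continuation_words: frozenset[str] | None = None
) -> list[tuple[int, int]]:
    """Sentence spans (half-open, whitespace-trimmed) over normalized text.

    Boundary candidates are periods and retained line breaks; a candidate is
    suppressed when the adjacent word on either side is a continuation word.
    """
    if continuation_words is None:
        continuation_words = default_continuation_words()

    boundaries: list[int] = []  # index just after the boundary character
    for m in re.finditer(r"[.\n]", normalized):
        i = m.start()
        before = _word_before(normalized, i).lower()
        after = _word_after(normalized, i + 1).lower()
        if before in continuation_words or after in continuation_words:
            continue
        boundaries.append(i + 1)

    spans: list[tuple[int, int]] = []
    start = 0
    for cut in boundaries + [len(normalized)]:
        seg = normalized[start:cut]
        lead = len(seg) - len(seg.lstrip())
        trail = len(seg) - len(seg.rstrip())
        lo, hi = start + lead, cut - trail
        if hi > lo:
            spans.append((lo, hi))
        start = cut
    return spans


_TOKEN_RE = re.compile(r"[A-Za-z0-9]+|([^A-Za-z0-9\s])\1*")


def tokenize(
    sentence: str, offset: int = 0, sentence_index: int = 0
) -> list[Token]:
    """Tokenize one normalized sentence.

    ``offset`` shifts token offsets into document coordinates when the
    sentence is a slice of a larger text.
    """
    return [
        Token(m.group(0), offset + m.start(), offset + m.end(), sentence_index)
        for m in _TOKEN_RE.finditer(sentence)
    ]
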