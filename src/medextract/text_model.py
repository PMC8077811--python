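"""Document and annotation data model; standoff and CoNLL-column IO.

All entity offsets are 0-based, half-open, into the *normalized* text; the
document's offset map projects them back onto the raw text for display.
Gold, rule, and model annotations live side by side, distinguished by the
span's ``source``.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .labels import LABELS, UnknownLabelError, check_label, parse_tag
from .preprocessing import (
    NormalizationResult,
    Token,
    normalize_text,
    split_sentences,
    tokenize,
)

__all__ = [
    "EntitySpan",
    "AnnotatedDocument",
    "MalformedAnnotationError",
    "AlignmentError",
    "preprocess_document",
    "read_standoff",
    "write_standoff",
    "spans_to_iob",
    "iob_to_spans",
    "resolve_overlaps",
    "write_conll",
    "read_conll",
]

SOURCES = ("gold", "rule", "model")


class MalformedAnnotationError(ValueError):
    """A standoff annotation that does not match the document text."""


class AlignmentError(ValueError):
    """Token/label sequences of mismatched length."""


@dataclass(frozen=True, order=True)
class EntitySpan:
    """A labeled character span (normalized-text coordinates, half-open)."""

    char_start: int
    char_end: int
    label: str
    source: str = "gold"

    def __post_init__(self) -> None:
        if not (0 <= self.char_start < self.char_end):
            raise ValueError(f"bad span offsets [{self.char_start}, {self.char_end})")
        check_label(self.label)
        if self.source not in SOURCES:
            raise ValueError(f"unknown span source: {self.source!r}")

    def __len__(self) -> int:
        return self.char_end - self.char_start

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.char_start < other.char_end and other.char_start < self.char_end


@dataclass
class AnnotatedDocument:
    doc_id: str
    raw_text: str
    normalized_text: str
    offset_map: tuple[int, ...]
    sentences: list[list[Token]]
    spans: list[EntitySpan] = field(default_factory=list)

    def spans_for(self, source: str) -> list[EntitySpan]:
        if source not in SOURCES:
            raise ValueError(f"unknown span source: {source!r}")
        return sorted(s for s in self.spans if s.source == source)

    def replace_spans(self, source: str, new_spans: Iterable[EntitySpan]) -> None:
        self.spans = [s for s in self.spans if s.source != source]
        self.spans.extend(new_spans)

    def span_text(self, span: EntitySpan) -> str:
        return self.normalized_text[span.char_start : span.char_end]

    def iob(self, source: str, **kwargs) -> list[list[str]]:
        """Per-sentence IOB sequences for one annotation source."""
        spans = self.spans_for(source)
        return [spans_to_iob(sent, spans, **kwargs) for sent in self.sentences]


def preprocess_document(
    raw_text: str,
    doc_id: str = "doc",
    continuation_words: frozenset[str] | None = None,
) -> AnnotatedDocument:
    """Run the full preprocessing pipeline on raw text."""
    norm: NormalizationResult = normalize_text(raw_text)
    sentences = []
    for idx, (lo, hi) in enumerate(
        split_sentences(norm.normalized_text, continuation_words)
    ):
        sentences.append(tokenize(norm.normalized_text[lo:hi], offset=lo, sentence_index=idx))
    return AnnotatedDocument(
        doc_id=doc_id,
        raw_text=raw_text,
        normalized_text=norm.normalized_text,
        offset_map=norm.offset_map,
        sentences=sentences,
    )


def _raw_to_normalized(offset_map: Sequence[int], start: int, end: int) -> tuple[int, int]:
    """Project a raw-text span onto normalized coordinates via the offset map."""
    n_start = next((i for i, r in enumerate(offset_map) if r >= start), len(offset_map))
    n_end = next(
        (i for i in range(len(offset_map) - 1, -1, -1) if offset_map[i] < end), -1
    ) + 1
    return n_start, n_end


def read_standoff(
    text_path, ann_path, doc_id: str | None = None,
    continuation_words: frozenset[str] | None = None,
) -> AnnotatedDocument:
    """Read a BRAT-style .txt/.ann pair into a preprocessed document.

    Annotation offsets refer to the raw text; each surface string is verified
    against the raw slice before the span is projected into normalized
    coordinates and stored with ``source='gold'``.
    """
    text_path, ann_path = Path(text_path), Path(ann_path)
    raw = text_path.read_text(encoding="utf-8")
    doc = preprocess_document(raw, doc_id or text_path.stem, continuation_words)

    gold: list[EntitySpan] = []
    for lineno, line in enumerate(ann_path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or not line.startswith("T"):
            continue
        try:
            _tid, middle, surface = line.split("\t", 2)
            label, start_s, end_s = middle.split(" ")
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise MalformedAnnotationError(
                f"{ann_path.name}:{lineno}: unparseable T-line: {line!r}"
            ) from exc
        if label not in LABELS:
            raise UnknownLabelError(f"{ann_path.name}:{lineno}: unknown label {label!r}")
        if not (0 <= start < end <= len(raw)):
            raise MalformedAnnotationError(
                f"{ann_path.name}:{lineno}: offsets [{start}, {end}) outside text"
            )
        if raw[start:end] != surface:
            raise MalformedAnnotationError(
                f"{ann_path.name}:{lineno}: surface {surface!r} != text "
                f"{raw[start:end]!r}"
            )
        n_start, n_end = _raw_to_normalized(doc.offset_map, start, end)
        if n_end <= n_start:
            raise MalformedAnnotationError(
                f"{ann_path.name}:{lineno}: span vanished under normalization"
            )
        gold.append(EntitySpan(n_start, n_end, label, "gold"))
    doc.spans.extend(gold)
    return doc


def write_standoff(doc: AnnotatedDocument, source: str, txt_path, ann_path) -> None:
    """Write the normalized text and one annotation layer as a .txt/.ann pair."""
    Path(txt_path).write_text(doc.normalized_text, encoding="utf-8")
    lines = []
    for i, span in enumerate(doc.spans_for(source), 1):
        lines.append(
            f"T{i}\t{span.label} {span.char_start} {span.char_end}\t{doc.span_text(span)}"
        )
    Path(ann_path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def resolve_overlaps(spans: Iterable[EntitySpan]) -> list[EntitySpan]:
    """Drop overlapping spans within one layer: longer wins, ties earlier start."""
    kept: list[EntitySpan] = []
    for span in sorted(spans, key=lambda s: (-len(s), s.char_start, s.label)):
        if not any(span.overlaps(k) for k in kept):
            kept.append(span)
    return sorted(kept)


def spans_to_iob(
    tokens: Sequence[Token],
    spans: Iterable[EntitySpan],
    dropped: list[EntitySpan] | None = None,
) -> list[str]:
    """Project character spans onto a sentence's tokens as IOB tags.

    Any character overlap labels a token; the first overlapped token of a
    span gets ``B-``, the rest ``I-``. Overlapping spans are resolved first
    (longer wins, ties to the earlier start). Spans touching no token of this
    sentence are ignored; spans touching no token of *any* sentence can be
    collected by passing a ``dropped`` accumulator at the document level.
    """
    tags = ["O"] * len(tokens)
    if not tokens:
        return tags
    lo, hi = tokens[0].char_start, tokens[-1].char_end
    for span in resolve_overlaps(spans):
        covered = [
            i
            for i, tok in enumerate(tokens)
            if tok.char_start < span.char_end and span.char_start < tok.char_end
        ]
        if not covered:
            if dropped is not None and span.char_start < hi and span.char_end > lo:
                dropped.append(span)
            continue
        tags[covered[0]] = f"B-{span.label}"
        for i in covered[1:]:
            tags[i] = f"I-{span.label}"
    return tags


def iob_to_spans(
    tokens: Sequence[Token],
    iob: Sequence[str],
    source: str = "model",
    strict: bool = False,
) -> list[EntitySpan]:
    """Decode an IOB sequence into character spans.

    Lenient by default: an orphan ``I-`` (no preceding tag of the same class)
    opens a new span, as neural taggers emit such sequences. With
    ``strict=True`` orphan ``I-`` tokens are treated as ``O``.
    """
    if len(tokens) != len(iob):
        raise AlignmentError(f"{len(tokens)} tokens vs {len(iob)} tags")
    spans: list[EntitySpan] = []
    open_label: str | None = None
    open_start = open_end = 0
    for tok, tag in zip(tokens, iob):
        prefix, label = parse_tag(tag)
        starts_new = (
            prefix == "B"
            or (prefix == "I" and label != open_label and not strict)
        )
        continues = prefix == "I" and label == open_label
        if open_label is not None and not continues:
            spans.append(EntitySpan(open_start, open_end, open_label, source))
            open_label = None
        if starts_new:
            open_label, open_start = label, tok.char_start
        if open_label is not None and (starts_new or continues):
            open_end = tok.char_end
    if open_label is not None:
        spans.append(EntitySpan(open_start, open_end, open_label, source))
    return spans


def write_conll(
    doc: AnnotatedDocument,
    gold: Sequence[Sequence[str]],
    rule: Sequence[Sequence[str]],
    path_or_buf,
) -> None:
    """Write ``token<TAB>rule_tag<TAB>gold_tag`` lines, blank line between sentences."""
    if len(gold) != len(doc.sentences) or len(rule) != len(doc.sentences):
        raise AlignmentError("per-sentence sequences do not match sentence count")
    close = False
    if isinstance(path_or_buf, (str, Path)):
        fh = open(path_or_buf, "w", encoding="utf-8", newline="")
        close = True
    else:
        fh = path_or_buf
    try:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n", quoting=csv.QUOTE_NONE)
        for sent, g_seq, r_seq in zip(doc.sentences, gold, rule):
            if len(g_seq) != len(sent) or len(r_seq) != len(sent):
                raise AlignmentError(
                    f"sentence has {len(sent)} tokens but tag sequences of length "
                    f"{len(r_seq)}/{len(g_seq)}"
                )
            for tok, r_tag, g_tag in zip(sent, r_seq, g_seq):
                writer.writerow([tok.text, r_tag, g_tag])
            fh.write("\n")
    finally:
        if close:
            fh.close()


def read_conll(path_or_buf) -> tuple[list[list[str]], list[list[str]], list[list[str]]]:
    """Read the three-column CoNLL dialect back: (tokens, rule tags, gold tags)."""
    if isinstance(path_or_buf, (str, Path)):
        content = Path(path_or_buf).read_text(encoding="utf-8")
    else:
        content = path_or_buf.read()
    tokens: list[list[str]] = []
    rule: list[list[str]] = []
    gold: list[list[str]] = []
    cur_t: list[str] = []
    cur_r: list[str] = []
    cur_g: list[str] = []
    for line in content.splitlines():
        if not line.strip():
            if cur_t:
                tokens.append(cur_t)
                rule.append(cur_r)
                gold.append(cur_g)
                cur_t, cur_r, cur_g = [], [], []
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise MalformedAnnotationError(f"expected 3 columns, got {len(parts)}: {line!r}")
        cur_t.append(parts[0])
        cur_r.append(parts[1])
        cur_g.append(parts[2])
    if cur_t:
        tokens.append(cur_t)
        rule.append(cur_r)
        gold.append(cur_g)
    for seqs in (rule, gold):
        for seq in seqs:
            for tag in seq:
                parse_tag(tag)
    return tokens, rule, gold
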