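"""Anchor-centered attribute extraction with handcrafted rules.

The rule-based layer works in two strictly ordered steps: dictionary anchors
first (exact lexicon matching of drug and drug-class mentions), then
regular-expression attribute rules applied only in a window around each
anchor. A sentence without an anchor yields nothing — extraction is
anchor-gated, which is what gives the rule layer its high-precision /
low-recall profile on text whose drug mentions escape the dictionary.

The resulting spans serve two purposes: pre-annotation output (standoff /
CoNLL), and extra input features for the neural tagger.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .labels import ATTRIBUTE_LABELS
from .lexicon import DrugLexicon, match_exact
from .preprocessing import Token
from .text_model import AnnotatedDocument, EntitySpan

__all__ = ["AttributeRule", "RuleSet", "load_ruleset", "default_ruleset",
           "find_attributes", "annotate_document", "rule_iob"]


@dataclass(frozen=True)
class AttributeRule:
    """One attribute pattern searched in a window around drug anchors."""

    attribute: str
    pattern: str
    window: int = 10          # max token distance from the anchor
    direction: str = "both"   # left | right | both
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        if self.attribute not in ATTRIBUTE_LABELS:
            raise ValueError(
                f"rule attribute must be one of {ATTRIBUTE_LABELS}, got {self.attribute!r}"
            )
        if self.direction not in ("left", "right", "both"):
            raise ValueError(f"bad direction {self.direction!r}")
        re.compile(self.pattern)  # fail fast on bad patterns

    @property
    def regex(self) -> re.Pattern:
        flags = 0 if self.case_sensitive else re.IGNORECASE
        return re.compile(self.pattern, flags)


@dataclass
class RuleSet:
    """Ordered attribute rules; list order is priority."""

    rules: list[AttributeRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        present = {r.attribute for r in self.rules}
        missing = set(ATTRIBUTE_LABELS) - present
        if self.rules and missing:
            raise ValueError(f"rule set lacks rules for: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.rules)


def _parse_ruleset(payload: dict) -> RuleSet:
    rules = [
        AttributeRule(
            attribute=entry["attribute"],
            pattern=entry["pattern"],
            window=int(entry.get("window", 10)),
            direction=entry.get("direction", "both"),
            case_sensitive=bool(entry.get("case_sensitive", False)),
        )
        for entry in payload["rules"]
    ]
    return RuleSet(rules)


def load_ruleset(path) -> RuleSet:
    """Load a rule set from a YAML config file."""
    with open(path, encoding="utf-8") as fh:
        return _parse_ruleset(yaml.safe_load(fh))


def default_ruleset() -> RuleSet:
    """The shipped default French rule inventory."""
    text = resources.files("medextract.data").joinpath("rules.yml").read_text("utf-8")
    return _parse_ruleset(yaml.safe_load(text))


def _window_range(
    tokens: Sequence[Token], anchor: EntitySpan, rule: AttributeRule
) -> tuple[int, int]:
    """Character range searched for one rule around one anchor."""
    idx = [
        i
        for i, t in enumerate(tokens)
        if t.char_start < anchor.char_end and anchor.char_start < t.char_end
    ]
    if not idx:
        return anchor.char_start, anchor.char_end
    first, last = idx[0], idx[-1]
    lo_tok = first if rule.direction == "right" else max(0, first - rule.window)
    hi_tok = last if rule.direction == "left" else min(len(tokens) - 1, last + rule.window)
    return tokens[lo_tok].char_start, tokens[hi_tok].char_end


def _candidate_matches(
    tokens: Sequence[Token],
    sentence_text: str,
    sent_offset: int,
    anchors: Sequence[EntitySpan],
    ruleset: RuleSet,
) -> list[tuple[int, EntitySpan]]:
    """(rule_priority, span) candidates intersecting any anchor window."""
    out: list[tuple[int, EntitySpan]] = []
    for prio, rule in enumerate(ruleset.rules):
        windows = [_window_range(tokens, a, rule) for a in anchors]
        for m in rule.regex.finditer(sentence_text):
            start, end = sent_offset + m.start(), sent_offset + m.end()
            if start == end:
                continue
            if not any(start < hi and lo < end for lo, hi in windows):
                continue
            span = EntitySpan(start, end, rule.attribute, "rule")
            if any(span.overlaps(a) for a in anchors):
                continue
            out.append((prio, span))
    return out


def _select(candidates: list[tuple[int, EntitySpan]]) -> list[EntitySpan]:
    """Resolve overlaps: rule priority first, then longest, then leftmost."""
    kept: list[EntitySpan] = []
    for _, span in sorted(
        candidates, key=lambda c: (c[0], -len(c[1]), c[1].char_start)
    ):
        if not any(span.overlaps(k) for k in kept):
            kept.append(span)
    return sorted(kept)


def find_attributes(
    tokens: Sequence[Token],
    sentence_text: str,
    sent_offset: int,
    anchor: EntitySpan,
    ruleset: RuleSet,
) -> list[EntitySpan]:
    """Attribute spans for a single anchor within its search window."""
    return _select(
        _candidate_matches(tokens, sentence_text, sent_offset, [anchor], ruleset)
    )


def annotate_document(
    doc: AnnotatedDocument,
    lexicon: DrugLexicon,
    ruleset: RuleSet | None = None,
) -> AnnotatedDocument:
    """Run anchors-then-attributes over every sentence; store rule spans.

    Spans are stored document-absolute (normalized-text offsets). Output is
    deterministic for fixed inputs; rerunning replaces the rule layer.
    """
    if ruleset is None:
        ruleset = default_ruleset()
    spans: list[EntitySpan] = []
    for tokens in doc.sentences:
        if not tokens:
            continue
        anchors = match_exact(tokens, lexicon)
        if not anchors:
            continue
        spans.extend(anchors)
        lo, hi = tokens[0].char_start, tokens[-1].char_end
        spans.extend(
            _select(
                _candidate_matches(
                    tokens, doc.normalized_text[lo:hi], lo, anchors, ruleset
                )
            )
        )
    doc.replace_spans("rule", spans)
    return doc


def rule_iob(doc: AnnotatedDocument) -> list[list[str]]:
    """The rule layer as per-sentence IOB sequences (tagger feature input)."""
    return doc.iob("rule")
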