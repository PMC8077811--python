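"""Token-level micro-averaged metrics and slot error rate (SER).

Token scoring ignores the B/I prefix and compares entity classes only: a
token is a true positive of class c when gold and prediction both assign c;
a predicted class on a token whose gold class differs counts as a false
positive of the predicted class *and* a false negative of the gold class;
a missed entity token is a false negative. Precision, recall, and F-measure
are micro-averaged by pooling counts over classes, and reported on the
percent scale.

Slot-level scoring extracts slots (maximal B,I+ runs of one class) from both
sequences and aligns them greedily by maximal token overlap. A matched pair
with the right class and boundaries is correct; right boundaries but wrong
class is a *type* error; right class but clipped/extended boundaries is a
*frontier* error; wrong on both counts as one type plus one frontier error.
Unmatched gold slots are *deletions*, unmatched predicted slots *insertions*.
Type and frontier errors weigh half in the aggregate:

    SER = (D + I + 0.5 * (T + Fr)) / R

with R the number of reference (gold) slots. The same half-weight identity
applied to already-normalized error rates gives the aggregate rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .labels import LABELS, tag_class
from .text_model import AlignmentError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "Slot",
    "SERReport",
    "token_confusion",
    "micro_prf",
    "iob_to_slots",
    "extract_and_align_slots",
    "aggregate_ser",
]


@dataclass
class ConfusionCounts:
    """Per-class token-level TP/FP/FN tallies."""

    tp: dict[str, int] = field(default_factory=lambda: {c: 0 for c in LABELS})
    fp: dict[str, int] = field(default_factory=lambda: {c: 0 for c in LABELS})
    fn: dict[str, int] = field(default_factory=lambda: {c: 0 for c in LABELS})

    def add(self, other: "ConfusionCounts") -> "ConfusionCounts":
        for c in LABELS:
            self.tp[c] += other.tp[c]
            self.fp[c] += other.fp[c]
            self.fn[c] += other.fn[c]
        return self


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f_measure: float
    support: int
    degenerate: bool = False  # a zero denominator was coerced to 0


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and pooled (micro-averaged) P/R/F on the percent scale."""

    per_class: dict[str, ClassMetrics]
    overall: ClassMetrics

    def format_table(self) -> str:
        rows = [f"{'class':<18}{'P':>8}{'R':>8}{'F':>8}{'support':>9}"]
        for c, m in list(self.per_class.items()) + [("overall", self.overall)]:
            rows.append(
                f"{c:<18}{m.precision:>8.2f}{m.recall:>8.2f}"
                f"{m.f_measure:>8.2f}{m.support:>9d}"
            )
        return "\n".join(rows)


def token_confusion(gold: Sequence[str], pred: Sequence[str]) -> ConfusionCounts:
    """Token-level confusion counts between two aligned IOB sequences."""
    if len(gold) != len(pred):
        raise AlignmentError(f"gold length {len(gold)} != pred length {len(pred)}")
    counts = ConfusionCounts()
    for g_tag, p_tag in zip(gold, pred):
        g, p = tag_class(g_tag), tag_class(p_tag)
        if g is not None and g == p:
            counts.tp[g] += 1
        else:
            if p is not None:
                counts.fp[p] += 1
            if g is not None:
                counts.fn[g] += 1
    return counts


def _prf(tp: int, fp: int, fn: int) -> ClassMetrics:
    degenerate = (tp + fp == 0) or (tp + fn == 0)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return ClassMetrics(100 * p, 100 * r, 100 * f, support=tp + fn, degenerate=degenerate)


def micro_prf(counts: ConfusionCounts) -> MetricsReport:
    """Micro-averaged precision/recall/F (percent); zero denominators -> 0."""
    per_class = {c: _prf(counts.tp[c], counts.fp[c], counts.fn[c]) for c in LABELS}
    overall = _prf(
        sum(counts.tp.values()), sum(counts.fp.values()), sum(counts.fn.values())
    )
    return MetricsReport(per_class=per_class, overall=overall)


@dataclass(frozen=True, order=True)
class Slot:
    """A contiguous entity mention as a token-index range (half-open)."""

    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad slot range [{self.start}, {self.end})")

    def overlap(self, other: "Slot") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def iob_to_slots(iob: Sequence[str], strict: bool = False) -> list[Slot]:
    """Slots of an IOB sequence (lenient decoding by default)."""
    slots: list[Slot] = []
    open_label = None
    start = 0
    for i, tag in enumerate(iob):
        label = tag_class(tag)
        prefix = tag[0] if tag != "O" else None
        continues = prefix == "I" and label == open_label
        starts_new = prefix == "B" or (
            prefix == "I" and label != open_label and not strict
        )
        if open_label is not None and not continues:
            slots.append(Slot(start, i, open_label))
            open_label = None
        if starts_new:
            open_label, start = label, i
    if open_label is not None:
        slots.append(Slot(start, len(iob), open_label))
    return slots


@dataclass(frozen=True)
class SERReport:
    """Slot alignment outcome with the error-type decomposition."""

    reference_slots: int
    correct: int
    deletions: int
    insertions: int
    type_errors: int
    frontier_errors: int
    matches: tuple[tuple[Slot, Slot], ...] = ()

    @property
    def ser(self) -> float:
        if self.reference_slots == 0:
            return 0.0 if self.insertions == 0 else float("inf")
        return (
            self.deletions
            + self.insertions
            + 0.5 * (self.type_errors + self.frontier_errors)
        ) / self.reference_slots

    def rate(self, count: int) -> float:
        return count / self.reference_slots if self.reference_slots else 0.0

    def combine(self, other: "SERReport") -> "SERReport":
        return SERReport(
            self.reference_slots + other.reference_slots,
            self.correct + other.correct,
            self.deletions + other.deletions,
            self.insertions + other.insertions,
            self.type_errors + other.type_errors,
            self.frontier_errors + other.frontier_errors,
        )


def extract_and_align_slots(gold: Sequence[str], pred: Sequence[str]) -> SERReport:
    """Extract slots from both sequences, align them, and score errors.

    Greedy maximal-overlap matching: repeatedly pair the unmatched gold/pred
    slots with the largest token overlap, breaking ties toward the earlier
    gold slot, then the earlier predicted slot.
    """
    if len(gold) != len(pred):
        raise AlignmentError(f"gold length {len(gold)} != pred length {len(pred)}")
    gold_slots = iob_to_slots(gold)
    pred_slots = iob_to_slots(pred)

    pairs = sorted(
        (
            (-g.overlap(p), gi, pi)
            for gi, g in enumerate(gold_slots)
            for pi, p in enumerate(pred_slots)
            if g.overlap(p) > 0
        ),
    )
    used_g: set[int] = set()
    used_p: set[int] = set()
    matches: list[tuple[Slot, Slot]] = []
    for _neg, gi, pi in pairs:
        if gi in used_g or pi in used_p:
            continue
        used_g.add(gi)
        used_p.add(pi)
        matches.append((gold_slots[gi], pred_slots[pi]))

    correct = type_err = frontier = 0
    for g, p in matches:
        same_class = g.label == p.label
        same_bounds = (g.start, g.end) == (p.start, p.end)
        if same_class and same_bounds:
            correct += 1
        elif same_bounds:
            type_err += 1
        elif same_class:
            frontier += 1
        else:
            type_err += 1
            frontier += 1
    return SERReport(
        reference_slots=len(gold_slots),
        correct=correct,
        deletions=len(gold_slots) - len(matches),
        insertions=len(pred_slots) - len(matches),
        type_errors=type_err,
        frontier_errors=frontier,
        matches=tuple(matches),
    )


def aggregate_ser(
    insertion: float, deletion: float, type_error: float, frontier_error: float,
    ndigits: int | None = 2,
) -> float:
    """Aggregate SER from the four error rates under the half-weight convention.

    Works equally on raw counts divided by a common reference or on
    already-normalized rates, since the identity is linear.
    """
    value = deletion + insertion + 0.5 * (type_error + frontier_error)
    return round(value, ndigits) if ndigits is not None else value
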