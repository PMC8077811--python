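"""Entity label set and IOB tag inventory.

Seven entity categories are extracted: the two drug categories
(``medication_name``, ``medication_class``) and five attributes attached to a
drug mention (``dosage``, ``frequency``, ``duration``, ``route``,
``condition``). The IOB tagging scheme over these categories yields 15 tags:
``O`` plus a ``B-``/``I-`` pair per category. Tag order is fixed (``O`` first,
then the B/I pair of each category in label order) and shared by the rule
feature encoding and the tagger output layer.
"""

from __future__ import annotations

# Ordered by (approximate) corpus frequency: drug names dominate, then the
# two most common attributes, then the drug-class and rare attribute classes.
LABELS: tuple[str, ...] = (
    "medication_name",
    "medication_class",
    "dosage",
    "frequency",
    "duration",
    "route",
    "condition",
)

DRUG_LABELS: tuple[str, str] = ("medication_name", "medication_class")
ATTRIBUTE_LABELS: tuple[str, ...] = (
    "dosage",
    "frequency",
    "duration",
    "route",
    "condition",
)

#: Fixed IOB tag order: O, then B-c, I-c for each category in LABELS order.
TAGS: tuple[str, ...] = ("O",) + tuple(
    f"{prefix}-{label}" for label in LABELS for prefix in ("B", "I")
)

TAG_TO_INDEX: dict[str, int] = {tag: i for i, tag in enumerate(TAGS)}
N_TAGS: int = len(TAGS)  # 15


class UnknownLabelError(ValueError):
    """An entity label outside the seven-category schema."""


def check_label(label: str) -> str:
    if label not in LABELS:
        raise UnknownLabelError(f"unknown entity label: {label!r}")
    return label


def parse_tag(tag: str) -> tuple[str | None, str | None]:
    """Split an IOB tag into (prefix, label); ``O`` parses to (None, None).

    Raises :class:`UnknownLabelError` for anything outside the tag grammar.
    """
    if tag == "O":
        return None, None
    if len(tag) > 2 and tag[1] == "-" and tag[0] in "BI":
        label = tag[2:]
        if label in LABELS:
            return tag[0], label
    raise UnknownLabelError(f"malformed IOB tag: {tag!r}")


def tag_class(tag: str) -> str | None:
    """Category of a tag, ignoring the B/I prefix; None for ``O``."""
    return parse_tag(tag)[1]
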