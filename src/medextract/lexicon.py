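"""Unified drug dictionary and exact-match anchor detection.

The lexicon emulates a merge of the French national drug databases: each entry
is a drug surface form (a normalized, case-folded token sequence), its
normalized name, an ATC code, and whether it denotes a specific medication or
a therapeutic class. Matching is *exact* at the token level — the design goal
is maximal precision for the pre-annotation step, so no stemming or edit
distance is applied. Overlapping candidate matches are resolved
longest-leftmost.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .preprocessing import Token, normalize_text, tokenize
from .text_model import EntitySpan

__all__ = ["LexiconEntry", "DrugLexicon", "build_lexicon", "match_exact",
           "read_lexicon_csv", "write_lexicon_csv"]

logger = logging.getLogger(__name__)

# Full ATC: letter, 2 digits, 2 letters, 2 digits; hierarchical prefixes allowed.
_ATC_RE = re.compile(r"^[A-Z](\d{2}([A-Z]([A-Z](\d{2})?)?)?)?$")
_ENTRY_TYPES = ("medication_name", "medication_class")


@dataclass(frozen=True)
class LexiconEntry:
    surface: tuple[str, ...]  # normalized, case-folded token texts
    normalized_name: str
    atc_code: str
    entry_type: str

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("empty lexicon surface")
        if self.entry_type not in _ENTRY_TYPES:
            raise ValueError(f"entry_type must be one of {_ENTRY_TYPES}")


def normalize_surface(name: str) -> tuple[str, ...]:
    """Normalize and tokenize a dictionary surface form, case-folded."""
    normalized = normalize_text(name).normalized_text
    return tuple(tok.text.casefold() for tok in tokenize(normalized))


@dataclass
class DrugLexicon:
    entries: list[LexiconEntry] = field(default_factory=list)
    skipped_rows: int = 0
    _index: dict[tuple[str, ...], LexiconEntry] = field(default_factory=dict, repr=False)
    _max_len: int = 0

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        self._index = {}
        self._max_len = 0
        for entry in self.entries:
            prev = self._index.get(entry.surface)
            # A surface present as both name and class resolves to the name:
            # specific medications dominate the corpus.
            if prev is None or (
                prev.entry_type == "medication_class"
                and entry.entry_type == "medication_name"
            ):
                if prev is not None:
                    logger.info(
                        "ambiguous surface %r: keeping medication_name", entry.surface
                    )
                self._index[entry.surface] = entry
            self._max_len = max(self._max_len, len(entry.surface))

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, surface: tuple[str, ...]) -> bool:
        return surface in self._index

    def lookup(self, surface: tuple[str, ...]) -> LexiconEntry | None:
        return self._index.get(surface)

    @property
    def max_surface_length(self) -> int:
        return self._max_len


def build_lexicon(rows: Iterable[Mapping[str, str] | Sequence[str]]) -> DrugLexicon:
    """Build the deduplicated lexicon from drug-table rows.

    Rows are mappings with ``name`` / ``atc`` / ``type`` keys (``surface`` /
    ``atc_code`` / ``entry_type`` accepted as aliases) or 3-sequences.
    Surfaces are normalized with the preprocessing pipeline and case-folded;
    identical (surface, entry_type) pairs from different tables or years
    collapse to one entry. Empty names are skipped and counted; malformed ATC
    codes are kept with a warning and the code set to ``"unknown"``.
    """
    seen: dict[tuple[tuple[str, ...], str], LexiconEntry] = {}
    skipped = 0
    for row in rows:
        if isinstance(row, Mapping):
            name = row.get("name", row.get("surface", ""))
            atc = row.get("atc", row.get("atc_code", ""))
            etype = row.get("type", row.get("entry_type", ""))
            normalized_name = row.get("normalized_name", "") or name
        else:
            name, atc, etype = row[0], row[1], row[2]
            normalized_name = name
        surface = normalize_surface(name or "")
        if not surface:
            skipped += 1
            continue
        atc = (atc or "").strip().upper()
        if not _ATC_RE.match(atc):
            logger.warning("malformed ATC code %r for %r; set to unknown", atc, name)
            atc = "unknown"
        entry = LexiconEntry(surface, normalized_name.strip(), atc, etype)
        seen.setdefault((surface, etype), entry)
    return DrugLexicon(entries=list(seen.values()), skipped_rows=skipped)


def match_exact(tokens: Sequence[Token], lexicon: DrugLexicon) -> list[EntitySpan]:
    """Exact dictionary matching over a sentence's tokens (source='rule').

    Scans left to right; at each position the longest lexicon surface equal
    to the case-folded token subsequence wins, and scanning resumes after it,
    so matches never overlap (longest-leftmost selection).
    """
    folded = [tok.text.casefold() for tok in tokens]
    spans: list[EntitySpan] = []
    i = 0
    while i < len(tokens):
        best = 0
        best_entry = None
        for n in range(min(lexicon.max_surface_length, len(tokens) - i), 0, -1):
            entry = lexicon.lookup(tuple(folded[i : i + n]))
            if entry is not None:
                best, best_entry = n, entry
                break
        if best_entry is not None:
            spans.append(
                EntitySpan(
                    tokens[i].char_start,
                    tokens[i + best - 1].char_end,
                    best_entry.entry_type,
                    "rule",
                )
            )
            i += best
        else:
            i += 1
    return spans


def read_lexicon_csv(path) -> DrugLexicon:
    """Read a ``surface,normalized_name,atc_code,entry_type`` CSV (with header)."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        rows = [
            {
                "name": r["surface"],
                "normalized_name": r.get("normalized_name", ""),
                "atc": r.get("atc_code", ""),
                "type": r.get("entry_type", ""),
            }
            for r in reader
        ]
    return build_lexicon(rows)


def write_lexicon_csv(lexicon: DrugLexicon, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["surface", "normalized_name", "atc_code", "entry_type"])
        for entry in sorted(
            lexicon.entries, key=lambda e: (e.surface, e.entry_type)
        ):
            writer.writerow(
                [" ".join(entry.surface), entry.normalized_name, entry.atc_code, entry.entry_type]
            )
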