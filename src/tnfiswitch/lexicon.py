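"""Normalization of free-text medication names to canonical TNF-inhibitor categories.

Medication orders in EHR data carry free-text drug strings ("HUMIRA 40 mg/0.8 mL
syringe", "infliximab-dyyb 100 mg IV") that mix generic names, brand names,
biosimilar suffixed names, doses and routes.  This module maps such strings onto
a closed set of six canonical TNFi categories, treating the infliximab
biosimilars as a category distinct from the bio-originator.

The bundled default lexicon covers the generic names, the major US brand names
and the suffixed infliximab biosimilar names.  It is a replaceable data file:
any CSV with columns ``pattern,canonical,name_kind`` can be supplied instead.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

#: The closed set of canonical TNFi categories.
CANONICAL_DRUGS: tuple[str, ...] = (
    "adalimumab",
    "etanercept",
    "certolizumab",
    "golimumab",
    "infliximab-biooriginator",
    "infliximab-biosimilar",
)

NAME_KINDS = frozenset({"generic", "brand", "biosimilar"})

_DEFAULT_RESOURCE = "default_lexicon.csv"


def _fold(text: str) -> str:
    """Case/punctuation folding used for matching: lowercase, hyphen and
    underscore mapped to a space, character-for-character (positions are
    preserved so spans in the folded text index into the original)."""
    return text.lower().replace("-", " ").replace("_", " ")


@dataclass(frozen=True)
class LexiconEntry:
    """One match rule: a case-insensitive pattern and its canonical category."""

    pattern: str
    canonical: str
    name_kind: str

    def __post_init__(self) -> None:
        if self.canonical not in CANONICAL_DRUGS:
            raise ValueError(
                f"unknown canonical category {self.canonical!r}; "
                f"expected one of {CANONICAL_DRUGS}"
            )
        if self.name_kind not in NAME_KINDS:
            raise ValueError(
                f"unknown name_kind {self.name_kind!r}; expected one of {sorted(NAME_KINDS)}"
            )
        if not self.pattern.strip():
            raise ValueError("empty pattern")


class Lexicon:
    """A validated set of :class:`LexiconEntry` with substring matching.

    Matching is case-insensitive substring search with hyphen/space folding.
    When several patterns match, the longest pattern wins, so a biosimilar
    suffixed name ("infliximab-dyyb") beats the bare originator generic
    ("infliximab") that it contains.
    """

    def __init__(self, entries: Iterable[LexiconEntry]):
        entries = tuple(entries)
        seen: dict[str, LexiconEntry] = {}
        for e in entries:
            key = _fold(e.pattern)
            if key in seen:
                raise ValueError(
                    f"duplicate pattern after case-folding: {e.pattern!r} "
                    f"(conflicts with {seen[key].pattern!r})"
                )
            seen[key] = e
        # canonical category labels are implicit patterns, so normalization is
        # idempotent (the compound "infliximab-biosimilar" label would
        # otherwise fall through to its embedded originator substring)
        implicit = []
        for canonical in sorted({e.canonical for e in entries}):
            if _fold(canonical) not in seen:
                kind = "biosimilar" if canonical.endswith("biosimilar") else "generic"
                implicit.append(LexiconEntry(canonical, canonical, kind))
        self._explicit: frozenset[str] = frozenset(_fold(e.pattern) for e in entries)
        entries = entries + tuple(implicit)
        # longest-first so the first hit is the winning (most specific) pattern;
        # pattern text breaks length ties deterministically
        self.entries: tuple[LexiconEntry, ...] = tuple(
            sorted(entries, key=lambda e: (-len(_fold(e.pattern)), _fold(e.pattern)))
        )
        self._compiled = [
            (re.compile(re.escape(_fold(e.pattern))), e) for e in self.entries
        ]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def canonicals(self) -> set[str]:
        return {e.canonical for e in self.entries}

    def synonyms(self, canonical: str) -> list[str]:
        """All explicitly listed spellings for one canonical category
        (implicit category-label patterns are not spellings)."""
        return [
            e.pattern
            for e in self.entries
            if e.canonical == canonical and _fold(e.pattern) in self._explicit
        ]

    def normalize(self, raw: str) -> Optional[str]:
        """Canonical category for a free-text drug string, or None."""
        if not raw or not raw.strip():
            return None
        folded = _fold(raw)
        for rx, entry in self._compiled:
            if rx.search(folded):
                return entry.canonical
        return None

    def find_all(self, text: str) -> list[tuple[int, str]]:
        """All non-overlapping pattern matches in a text.

        Returns (start position, canonical) pairs sorted by position.  Longer
        patterns claim their span first, so "infliximab-dyyb" suppresses the
        embedded "infliximab" match.
        """
        folded = _fold(text)
        claimed: list[tuple[int, int]] = []
        hits: list[tuple[int, str]] = []
        for rx, entry in self._compiled:
            for m in rx.finditer(folded):
                span = (m.start(), m.end())
                if any(span[0] < c[1] and c[0] < span[1] for c in claimed):
                    continue
                claimed.append(span)
                hits.append((m.start(), entry.canonical))
        hits.sort()
        return hits


def load_lexicon(path: str | Path | None = None) -> Lexicon:
    """Load a lexicon from a CSV file (header ``pattern,canonical,name_kind``).

    With no path, the bundled default lexicon is returned.  Malformed rows
    raise a ValueError naming the offending line; duplicate patterns (after
    case-folding) raise a ValueError; an empty file yields an empty lexicon
    with a logged warning.
    """
    if path is None:
        ref = resources.files("tnfiswitch.data").joinpath(_DEFAULT_RESOURCE)
        with ref.open("r", encoding="utf-8") as fh:
            return _parse_lexicon(fh, source=_DEFAULT_RESOURCE)
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        return _parse_lexicon(fh, source=str(path))


def _parse_lexicon(fh, source: str) -> Lexicon:
    reader = csv.reader(fh)
    rows = [r for r in reader if r and any(cell.strip() for cell in r)]
    if not rows:
        logger.warning("lexicon file %s is empty; returning empty lexicon", source)
        return Lexicon(())
    header = [c.strip().lower() for c in rows[0]]
    if header != ["pattern", "canonical", "name_kind"]:
        raise ValueError(
            f"{source}: expected header 'pattern,canonical,name_kind', got {rows[0]!r}"
        )
    entries = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != 3:
            raise ValueError(f"{source}: line {lineno}: expected 3 fields, got {len(row)}")
        try:
            entries.append(
                LexiconEntry(pattern=row[0].strip(), canonical=row[1].strip(),
                             name_kind=row[2].strip())
            )
        except ValueError as exc:
            raise ValueError(f"{source}: line {lineno}: {exc}") from exc
    if not entries:
        logger.warning("lexicon file %s has a header but no rows", source)
    return Lexicon(entries)


def default_lexicon() -> Lexicon:
    """The bundled TNFi lexicon (generics, brands, infliximab biosimilars)."""
    return load_lexicon(None)


def normalize_drug_name(raw: str, lexicon: Lexicon) -> Optional[str]:
    """Map a free-text medication string to its canonical TNFi category.

    Returns None for strings matching no lexicon pattern (e.g. non-TNFi
    drugs); never raises on non-matches.
    """
    return lexicon.normalize(raw)
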