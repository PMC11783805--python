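"""Preferred-term → category dictionaries emulating the anticholinergic
syndrome standardised MedDRA query (SMQ).

Each MedDRA preferred term (PT) in the query belongs to exactly one of
four categories: A (the anticholinergic-syndrome PT itself), B
(nervous-system PTs such as dizziness and somnolence), C (psychiatric
PTs such as delirium and hallucinations), D (other anticholinergic PTs
such as dry mouth and urinary retention).  The licensed MedDRA
terminology cannot be bundled; users supply a CSV, and a small built-in
synthetic dictionary exercises all category logic in tests.  Whether a
narrow or broad SMQ scope underlies a supplied table is the supplier's
choice — this module only enforces the mapping contract.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

from ._text import normalize
from .errors import ValidationError

CATEGORIES = ("A", "B", "C", "D")


@dataclass(frozen=True)
class PtCategoryEntry:
    preferred_term: str
    category: str

    def __post_init__(self):
        if not str(self.preferred_term).strip():
            raise ValidationError("preferred_term must be non-empty")
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"category for {self.preferred_term!r} must be one of "
                f"{CATEGORIES}, got {self.category!r}"
            )


class SmqDictionary:
    """PT → category mapping with disjoint category sets.

    PTs absent from the dictionary are implicitly outside the query
    (``category_of`` returns None for them).
    """

    def __init__(self, entries: Iterable[PtCategoryEntry] = ()):
        self._by_pt: dict[str, PtCategoryEntry] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: PtCategoryEntry) -> None:
        key = normalize(entry.preferred_term)
        if key in self._by_pt:
            raise ValidationError(
                f"duplicate preferred term {entry.preferred_term!r}"
            )
        self._by_pt[key] = entry

    @property
    def entries(self) -> tuple[PtCategoryEntry, ...]:
        return tuple(self._by_pt.values())

    def category_of(self, preferred_term: str) -> Optional[str]:
        entry = self._by_pt.get(normalize(preferred_term))
        return None if entry is None else entry.category

    def pts_in_category(self, category: str) -> tuple[str, ...]:
        if category not in CATEGORIES:
            raise ValidationError(f"unknown category {category!r}")
        return tuple(
            e.preferred_term for e in self._by_pt.values() if e.category == category
        )

    def __len__(self) -> int:
        return len(self._by_pt)

    def __contains__(self, preferred_term: str) -> bool:
        return normalize(preferred_term) in self._by_pt

    def __iter__(self) -> Iterator[PtCategoryEntry]:
        return iter(self._by_pt.values())

    @classmethod
    def from_csv(cls, path: str | Path) -> "SmqDictionary":
        return load_dictionary(path)

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["preferred_term", "category"])
            for entry in self:
                writer.writerow([entry.preferred_term, entry.category])


def load_dictionary(path: str | Path) -> SmqDictionary:
    """Load a PT-category table from CSV columns ``preferred_term,category``."""
    path = Path(path)
    dictionary = SmqDictionary()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        for col in ("preferred_term", "category"):
            if col not in fields:
                raise ValidationError(f"{path}: missing required column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            try:
                dictionary.add(
                    PtCategoryEntry(row["preferred_term"], row["category"].strip())
                )
            except ValidationError as exc:
                raise ValidationError(f"{path} row {lineno}: {exc}") from None
    return dictionary


# Synthetic stand-in for the licensed terminology: plausible PT strings,
# >= 3 per category, used as the default dictionary in tests and demos.
_EXAMPLE_ENTRIES = [
    ("Anticholinergic syndrome", "A"),
    ("Dizziness", "B"),
    ("Somnolence", "B"),
    ("Memory impairment", "B"),
    ("Balance disorder", "B"),
    ("Delirium", "C"),
    ("Hallucination", "C"),
    ("Confusional state", "C"),
    ("Agitation", "C"),
    ("Dry mouth", "D"),
    ("Urinary retention", "D"),
    ("Constipation", "D"),
    ("Vision blurred", "D"),
    ("Tachycardia", "D"),
]


def example_dictionary() -> SmqDictionary:
    """Built-in synthetic anticholinergic-syndrome dictionary.

    A stand-in for the licensed SMQ with at least three PTs per
    category B/C/D plus the single category-A syndrome term.
    """
    return SmqDictionary(PtCategoryEntry(pt, cat) for pt, cat in _EXAMPLE_ENTRIES)
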