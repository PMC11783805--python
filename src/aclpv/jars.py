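"""Anticholinergic risk-scale registries (J-ARS-style drug scoring).

A registry maps active-ingredient names to an integer anticholinergic
risk score in {1, 2, 3}.  The published Japanese scale covers 158 oral
and transdermal drugs (37 scored 3, 27 scored 2, 94 scored 1) but its
drug list cannot be redistributed, so users supply their own CSV; a
synthesized registry with the published per-score counts serves as the
default fixture.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np

from ._text import normalize
from .errors import ValidationError

VALID_SCORES = (1, 2, 3)

#: Published per-score drug counts of the Japan Anticholinergic Risk
#: Scale: 37 drugs scored 3, 27 scored 2, 94 scored 1 (158 total).
JARS_SCORE_COUNTS = {3: 37, 2: 27, 1: 94}


@dataclass(frozen=True)
class JarsEntry:
    """One scored drug: active-ingredient name and risk score 1-3."""

    drug_name: str
    score: int

    def __post_init__(self):
        if not str(self.drug_name).strip():
            raise ValidationError("drug_name must be a non-empty string")
        if self.score not in VALID_SCORES:
            raise ValidationError(
                f"score for {self.drug_name!r} must be one of {VALID_SCORES}, "
                f"got {self.score!r}"
            )


class JarsRegistry:
    """A validated collection of scored drugs with normalized-name lookup.

    Lookup is case-insensitive after whitespace trimming; duplicate
    normalized names are rejected.
    """

    def __init__(self, entries: Iterable[JarsEntry] = ()):
        self._by_name: dict[str, JarsEntry] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: JarsEntry) -> None:
        key = normalize(entry.drug_name)
        if key in self._by_name:
            raise ValidationError(
                f"duplicate drug name {entry.drug_name!r} "
                f"(collides with {self._by_name[key].drug_name!r})"
            )
        self._by_name[key] = entry

    @property
    def entries(self) -> tuple[JarsEntry, ...]:
        return tuple(self._by_name.values())

    def score_of(self, drug_name: str) -> Optional[int]:
        """Score of ``drug_name`` after normalization, or None if unlisted."""
        entry = self._by_name.get(normalize(drug_name))
        return None if entry is None else entry.score

    def counts_by_score(self) -> dict[int, int]:
        counts = {s: 0 for s in VALID_SCORES}
        for entry in self._by_name.values():
            counts[entry.score] += 1
        return counts

    def __len__(self) -> int:
        return len(self._by_name)

    def __contains__(self, drug_name: str) -> bool:
        return normalize(drug_name) in self._by_name

    def __iter__(self) -> Iterator[JarsEntry]:
        return iter(self._by_name.values())

    @classmethod
    def from_csv(cls, path: str | Path) -> "JarsRegistry":
        return load_registry(path)

    def to_csv(self, path: str | Path) -> None:
        write_registry(self, path)


def load_registry(path: str | Path) -> JarsRegistry:
    """Load a risk-scale table from a CSV with columns ``drug_name,score``.

    Raises :class:`ValidationError` naming the offending row for scores
    outside {1,2,3}, duplicate (normalized) names, or missing columns.
    """
    path = Path(path)
    registry = JarsRegistry()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        for col in ("drug_name", "score"):
            if col not in fields:
                raise ValidationError(f"{path}: missing required column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            raw_score = row["score"].strip()
            try:
                score = int(raw_score)
            except ValueError:
                raise ValidationError(
                    f"{path} row {lineno}: score {raw_score!r} is not an integer"
                ) from None
            try:
                registry.add(JarsEntry(row["drug_name"], score))
            except ValidationError as exc:
                raise ValidationError(f"{path} row {lineno}: {exc}") from None
    return registry


def write_registry(registry: JarsRegistry, path: str | Path) -> None:
    """Write a registry back to the two-column CSV dialect read by load."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["drug_name", "score"])
        for entry in registry:
            writer.writerow([entry.drug_name, entry.score])


_SYLLABLES = [
    "lo", "ra", "ti", "ne", "pro", "mez", "dol", "fex", "qui", "zol",
    "cla", "ven", "dar", "oxi", "tri", "pam", "sul", "ket", "bro", "fen",
]
_SUFFIXES = ["ine", "ol", "ide", "am", "ate", "one"]


def _generated_names(n: int, rng: np.random.Generator) -> list[str]:
    names: list[str] = []
    seen: set[str] = set()
    while len(names) < n:
        stem = "".join(rng.choice(_SYLLABLES, size=int(rng.integers(2, 4))))
        name = stem + _SUFFIXES[int(rng.integers(0, len(_SUFFIXES)))]
        if name not in seen:
            seen.add(name)
            names.append(name)
    return names


def synthesize_registry(
    n_score3: int, n_score2: int, n_score1: int, seed: int
) -> JarsRegistry:
    """Build a registry with exactly the requested per-score counts.

    Drug names are pseudo-pharmaceutical strings generated
    deterministically from ``seed``; two calls with identical arguments
    return identical registries.
    """
    for n in (n_score3, n_score2, n_score1):
        if n < 0:
            raise ValidationError("per-score counts must be non-negative")
    rng = np.random.default_rng(seed)
    total = n_score3 + n_score2 + n_score1
    names = _generated_names(total, rng)
    scores = [3] * n_score3 + [2] * n_score2 + [1] * n_score1
    return JarsRegistry(JarsEntry(n, s) for n, s in zip(names, scores))


def default_registry(seed: int = 0) -> JarsRegistry:
    """The default fixture: 37/27/94 drugs scored 3/2/1 (158 entries)."""
    return synthesize_registry(
        JARS_SCORE_COUNTS[3], JARS_SCORE_COUNTS[2], JARS_SCORE_COUNTS[1], seed
    )
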