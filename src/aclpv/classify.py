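"""Case classification by anticholinergic-syndrome category.

A case is *anticholinergic syndrome* (group ``SYNDROME``) when it
carries a category-A preferred term, or at least one PT in each of
categories B, C and D.  Cases carrying any other non-empty combination
of B/C/D flags form the *syndrome-related adverse event* subgroups
(``B``, ``C``, ``D``, ``B&C``, ``B&D``, ``C&D``); cases with no listed
PT at all are ``OTHER`` (the control group downstream).  Category A
dominates: adding a category-A PT to any case yields ``SYNDROME``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .smq import SmqDictionary
from .tables import CaseProfile

SYNDROME = "SYNDROME"
OTHER = "OTHER"
RELATED_GROUPS = ("B", "C", "D", "B&C", "B&D", "C&D")
GROUPS = (SYNDROME,) + RELATED_GROUPS + (OTHER,)

#: Display order for composition tables, including the split of the
#: syndrome group into its category-A and B&C&D routes.
_DISPLAY_ORDER = ("A", "B&C&D", SYNDROME) + RELATED_GROUPS + (OTHER,)


@dataclass(frozen=True)
class CategoryProfile:
    """Per-case category flags and the resulting analysis group."""

    has_a: bool
    has_b: bool
    has_c: bool
    has_d: bool
    group_label: str
    #: how a SYNDROME label was reached: "A" (category-A PT present) or
    #: "BCD" (all three of B, C, D present without A); None otherwise.
    syndrome_via: Optional[str] = None

    @property
    def is_related(self) -> bool:
        """True for the syndrome group and every related-ADE subgroup."""
        return self.group_label != OTHER


def classify_case(profile: CaseProfile, dictionary: SmqDictionary) -> CategoryProfile:
    """Assign category flags and the analysis group for one case.

    PTs outside the dictionary are ignored for grouping.
    """
    cats = {dictionary.category_of(pt) for pt in profile.pts}
    has_a = "A" in cats
    has_b = "B" in cats
    has_c = "C" in cats
    has_d = "D" in cats
    if has_a:
        return CategoryProfile(has_a, has_b, has_c, has_d, SYNDROME, "A")
    if has_b and has_c and has_d:
        return CategoryProfile(has_a, has_b, has_c, has_d, SYNDROME, "BCD")
    present = [c for c, flag in zip("BCD", (has_b, has_c, has_d)) if flag]
    label = "&".join(present) if present else OTHER
    return CategoryProfile(has_a, has_b, has_c, has_d, label, None)


def classify_all(
    profiles: Iterable[CaseProfile], dictionary: SmqDictionary
) -> list[CategoryProfile]:
    return [classify_case(p, dictionary) for p in profiles]


def format_percent(count: int, total: int) -> str:
    """Render ``100*count/total`` the way composition tables print it.

    Half-up rounding at two decimals; values exact at one decimal are
    printed with a single decimal (e.g. an exact 50% half prints
    ``50.0``, while 1/16008 prints ``0.01``).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    exact_at_one_decimal = (count * 1000) % total == 0
    pct = Decimal(count) * 100 / Decimal(total)
    quantum = Decimal("0.1") if exact_at_one_decimal else Decimal("0.01")
    return str(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def tabulate_groups(
    classified: Union[Iterable[CategoryProfile], Mapping[str, int]],
    split_syndrome: bool = False,
) -> pd.DataFrame:
    """Composition table: count and percentage per analysis group.

    Accepts either classified cases or a pre-computed ``label -> count``
    mapping.  With ``split_syndrome`` the syndrome group is reported as
    its two routes (``A`` and ``B&C&D``) instead of one ``SYNDROME``
    row; this requires classified cases (or a mapping that already uses
    the split labels).  Percentages use :func:`format_percent`; the
    ``percent_value`` column keeps the unrounded number.
    """
    if isinstance(classified, Mapping):
        counts = Counter(dict(classified))
    else:
        counts = Counter()
        for cp in classified:
            if split_syndrome and cp.group_label == SYNDROME:
                counts["A" if cp.syndrome_via == "A" else "B&C&D"] += 1
            else:
                counts[cp.group_label] += 1
    total = sum(counts.values())
    if total == 0:
        return pd.DataFrame(columns=["group", "count", "percent", "percent_value"])
    order = [g for g in _DISPLAY_ORDER if g in counts]
    order += [g for g in counts if g not in _DISPLAY_ORDER]
    rows = [
        {
            "group": g,
            "count": counts[g],
            "percent": format_percent(counts[g], total),
            "percent_value": 100.0 * counts[g] / total,
        }
        for g in order
    ]
    return pd.DataFrame(rows)


def related_total(table: pd.DataFrame) -> int:
    """Sum of counts over all non-control groups of a composition table."""
    return int(table.loc[table["group"] != OTHER, "count"].sum())
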