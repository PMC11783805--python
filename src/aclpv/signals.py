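"""Disproportionality analysis: reporting odds ratios and volcano data.

For each adverse event (MedDRA preferred term) a 2x2 contingency table
is built against case-level exposure, where *exposed* means the case
reports at least one registry-scored drug as a suspect drug.  The
reporting odds ratio (ROR) is computed with the Haldane–Anscombe
correction — 0.5 added to every cell unconditionally — so it is finite
for any table; the p-value comes from the two-sided Fisher exact test
on the uncorrected integer counts.  Events with fewer than
``min_reports`` total reports (default 100) are flagged as excluded
from observation.  Volcano coordinates are ln(ROR) on the horizontal
axis and -log10(p) on the vertical axis, with the significance
reference line at -log10(0.05) ≈ 1.3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._text import normalize
from .errors import ValidationError
from .smq import SmqDictionary
from .tables import CaseProfile

DEFAULT_MIN_REPORTS = 100
#: Volcano-plot significance reference: -log10(0.05).
REFERENCE_NEGLOG10_P = -math.log10(0.05)

SIGNAL_COLUMNS = [
    "preferred_term", "category", "n_reports", "a", "b", "c", "d",
    "ror", "ln_ror", "p_value", "neglog10_p", "included",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts (exposed&event, exposed only, event only, neither)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(
                    f"contingency cell {name} must be a non-negative integer, "
                    f"got {v!r}"
                )

    @property
    def n_reports(self) -> int:
        """Total reports of the event in the analysis set (a + c)."""
        return self.a + self.c

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def is_exposed(profile: CaseProfile) -> bool:
    """Case-level exposure: any registry-scored drug reported as suspect."""
    return any(
        d.jars_score is not None and d.involvement == "suspect"
        for d in profile.drugs
    )


def build_contingency(profiles: Sequence[CaseProfile], pt: str) -> ContingencyTable:
    """2x2 table of case-level exposure against one preferred term."""
    key = normalize(pt)
    a = b = c = d = 0
    for p in profiles:
        exposed = is_exposed(p)
        event = key in {normalize(x) for x in p.pts}
        if exposed and event:
            a += 1
        elif exposed:
            b += 1
        elif event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def ror_haldane(t: ContingencyTable) -> float:
    """Reporting odds ratio with 0.5 added to every cell.

    Always finite and positive, including for tables with zero cells.
    """
    return ((t.a + 0.5) * (t.d + 0.5)) / ((t.b + 0.5) * (t.c + 0.5))


def fisher_exact_p(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p on the uncorrected integer counts.

    Uses the "probability at most that of the observed table" rule over
    all tables with the same margins.
    """
    return float(
        stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1]
    )


def scan_events(
    profiles: Sequence[CaseProfile],
    dictionary: Optional[SmqDictionary] = None,
    min_reports: int = DEFAULT_MIN_REPORTS,
    pt_universe: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """One signal row per distinct preferred term, sorted by -log10(p).

    ``category`` is the dictionary category of the PT (empty string for
    PTs outside the query).  ``included`` marks events with at least
    ``min_reports`` total reports (a + c).
    """
    exposed_flags = [is_exposed(p) for p in profiles]
    n_total = len(profiles)
    n_exposed = sum(exposed_flags)

    display: dict[str, str] = {}
    n_event: dict[str, int] = {}
    n_event_exposed: dict[str, int] = {}
    for p, exposed in zip(profiles, exposed_flags):
        for pt in p.pts:
            key = normalize(pt)
            display.setdefault(key, pt)
            n_event[key] = n_event.get(key, 0) + 1
            if exposed:
                n_event_exposed[key] = n_event_exposed.get(key, 0) + 1
    if pt_universe is not None:
        for pt in pt_universe:
            key = normalize(pt)
            display.setdefault(key, pt)
            n_event.setdefault(key, 0)

    rows = []
    for key, pt in display.items():
        a = n_event_exposed.get(key, 0)
        c = n_event[key] - a
        t = ContingencyTable(a, n_exposed - a, c, n_total - n_exposed - c)
        ror = ror_haldane(t)
        p = fisher_exact_p(t)
        category = dictionary.category_of(pt) if dictionary is not None else None
        rows.append(
            {
                "preferred_term": pt,
                "category": category or "",
                "n_reports": t.n_reports,
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "ror": ror,
                "ln_ror": math.log(ror),
                "p_value": p,
                "neglog10_p": -math.log10(p) if p > 0 else math.inf,
                "included": t.n_reports >= min_reports,
            }
        )
    df = pd.DataFrame(rows, columns=SIGNAL_COLUMNS)
    if len(df):
        df = df.sort_values("neglog10_p", ascending=False, kind="stable")
        df = df.reset_index(drop=True)
    return df


def volcano_export(
    results: pd.DataFrame,
    path: str | Path,
    plot: Optional[str | Path] = None,
) -> dict:
    """Write volcano coordinates to CSV; optionally render the figure.

    Returns the reference-line metadata (the horizontal significance
    line at -log10(0.05)).
    """
    cols = ["preferred_term", "category", "ln_ror", "neglog10_p", "included"]
    out = results[cols] if len(results) else pd.DataFrame(columns=cols)
    out.to_csv(path, index=False)
    meta = {"reference_neglog10_p": REFERENCE_NEGLOG10_P}
    if plot is not None:
        _render_volcano(out, Path(plot))
    return meta


def _render_volcano(data: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    palette = {"A": "tab:red", "B": "tab:blue", "C": "tab:green",
               "D": "tab:orange", "": "0.6"}
    shown = data[data["included"]] if "included" in data else data
    for cat, sub in shown.groupby("category", dropna=False):
        ax.scatter(sub["ln_ror"], sub["neglog10_p"], s=14,
                   color=palette.get(cat, "0.6"),
                   label=cat if cat else "non-SMQ", alpha=0.8)
    ax.axhline(REFERENCE_NEGLOG10_P, color="k", linestyle="--", linewidth=0.8)
    ax.set_xlabel("ln ROR")
    ax.set_ylabel("-log10(P-value)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
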