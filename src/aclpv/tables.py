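"""Reading and cleaning JADER-style spontaneous-report tables.

Four long-format CSV tables describe each report: a case list with
demographics, a drug table (one row per reported drug with its
involvement and administration route), a reaction table (one MedDRA
preferred term per row), and an indication table (primary diseases).

The cleaning cascade mirrors the analysis-table construction used for
risk-scale studies of this kind:

* step 1 — drop cases with unknown sex or age; drop drug records whose
  route is neither oral nor transdermal (the routes the risk scale
  covers); drop cases left with no drug records;
* step 2 — drop cases in which no remaining drug appears in the risk
  registry (the scale cannot score them).

Counts for every exclusion are accumulated in a :class:`CleaningLog`
whose case-level numbers always satisfy
``input = removed(unknown demo) + removed(route) + removed(no scored drug) + remaining``.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from ._text import normalize
from .errors import ValidationError
from .jars import JarsRegistry

SEXES = ("male", "female")
AGE_BANDS = ("10s", "20s", "30s", "40s", "50s", "60s", "70s", "80s", "90s+")
#: Ordinal rank per age band (used as a matching covariate).
AGE_RANK = {band: i + 1 for i, band in enumerate(AGE_BANDS)}
INVOLVEMENTS = ("suspect", "concomitant", "interaction")
ELIGIBLE_ROUTES = ("oral", "transdermal")
ROUTES = ELIGIBLE_ROUTES + ("other",)

UNKNOWN = "unknown"

_REQUIRED_COLUMNS = {
    "demo": ("case_id", "sex", "age_band"),
    "drug": ("case_id", "drug_name", "involvement", "route"),
    "reac": ("case_id", "preferred_term"),
    "indication": ("case_id", "indication"),
}


@dataclass(frozen=True)
class DemoRecord:
    case_id: str
    sex: str
    age_band: str


@dataclass(frozen=True)
class DrugRecord:
    case_id: str
    drug_name: str
    involvement: str
    route: str


@dataclass(frozen=True)
class ReactionRecord:
    case_id: str
    preferred_term: str


@dataclass(frozen=True)
class IndicationRecord:
    case_id: str
    indication: str


@dataclass(frozen=True)
class DrugEntry:
    """A drug within an assembled case, annotated with its registry score."""

    drug_name: str
    involvement: str
    route: str
    jars_score: Optional[int]


@dataclass(frozen=True)
class CaseProfile:
    """One report after cleaning: demographics, drugs, events, indications."""

    case_id: str
    sex: str
    age_band: str
    drugs: tuple[DrugEntry, ...]
    pts: frozenset[str]
    indications: frozenset[str]

    def scored_drugs(self) -> tuple[DrugEntry, ...]:
        return tuple(d for d in self.drugs if d.jars_score is not None)

    def has_pt(self, preferred_term: str) -> bool:
        return normalize(preferred_term) in {normalize(p) for p in self.pts}


@dataclass
class CleaningLog:
    """Per-step exclusion counts of the cleaning cascade."""

    n_input_cases: int = 0
    n_removed_unknown_demo: int = 0
    n_removed_route: int = 0
    n_removed_no_jars: int = 0
    n_remaining: int = 0
    n_drug_rows_dropped_route: int = 0
    n_orphan_drug_rows: int = 0
    n_orphan_reaction_rows: int = 0
    n_orphan_indication_rows: int = 0
    vocabulary_warnings: dict = field(default_factory=dict)

    def is_conserved(self) -> bool:
        return (
            self.n_input_cases
            == self.n_removed_unknown_demo
            + self.n_removed_route
            + self.n_removed_no_jars
            + self.n_remaining
        )

    def to_dict(self) -> dict:
        return {
            "n_input_cases": self.n_input_cases,
            "n_removed_unknown_demo": self.n_removed_unknown_demo,
            "n_removed_route": self.n_removed_route,
            "n_removed_no_jars": self.n_removed_no_jars,
            "n_remaining": self.n_remaining,
            "n_drug_rows_dropped_route": self.n_drug_rows_dropped_route,
            "n_orphan_drug_rows": self.n_orphan_drug_rows,
            "n_orphan_reaction_rows": self.n_orphan_reaction_rows,
            "n_orphan_indication_rows": self.n_orphan_indication_rows,
            "vocabulary_warnings": dict(self.vocabulary_warnings),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class RawTables:
    """Typed records from the four source tables plus read-time counters."""

    demo: list[DemoRecord]
    drugs: list[DrugRecord]
    reactions: list[ReactionRecord]
    indications: list[IndicationRecord]
    vocabulary_warnings: Counter = field(default_factory=Counter)
    n_orphan_drug_rows: int = 0
    n_orphan_reaction_rows: int = 0
    n_orphan_indication_rows: int = 0

    def case_ids(self) -> set[str]:
        return {d.case_id for d in self.demo}


def _require_columns(df: pd.DataFrame, table: str, source: str) -> None:
    for col in _REQUIRED_COLUMNS[table]:
        if col not in df.columns:
            raise ValidationError(f"{source}: missing required column {col!r}")


def _map_vocab(value: str, vocab: tuple[str, ...], fallback: str,
               warnings: Counter, label: str) -> str:
    v = normalize(value)
    if v in vocab:
        return v
    if v:  # blank fields are ordinary missingness, not vocabulary violations
        warnings[f"{label}:{v}"] += 1
    return fallback


def read_frames(
    demo: pd.DataFrame,
    drug: pd.DataFrame,
    reac: pd.DataFrame,
    indication: pd.DataFrame,
    source: str = "<frame>",
) -> RawTables:
    """Typed records from in-memory frames (the CSV reader delegates here).

    Sex and age values outside their vocabularies map to ``unknown``;
    routes outside oral/transdermal/other map to ``other``; unrecognized
    involvement values map to ``concomitant`` (the neutral non-causal
    label, which never inflates suspect-drug exposure).  Each such
    mapping increments a warning counter.  Drug/reaction/indication rows
    whose case_id does not appear in the demographics table are dropped
    and counted as orphans.
    """
    for name, df in (("demo", demo), ("drug", drug), ("reac", reac),
                     ("indication", indication)):
        _require_columns(df, name, f"{source}:{name}")

    warnings: Counter = Counter()
    demo_records = []
    for row in demo.itertuples(index=False):
        cid = str(row.case_id).strip()
        if not cid:
            raise ValidationError(f"{source}:demo contains an empty case_id")
        demo_records.append(
            DemoRecord(
                case_id=cid,
                sex=_map_vocab(row.sex, SEXES, UNKNOWN, warnings, "sex"),
                age_band=_map_vocab(row.age_band, AGE_BANDS, UNKNOWN,
                                    warnings, "age_band"),
            )
        )
    known_ids = {d.case_id for d in demo_records}

    drug_records, orphan_drug = [], 0
    for row in drug.itertuples(index=False):
        cid = str(row.case_id).strip()
        if cid not in known_ids:
            orphan_drug += 1
            continue
        drug_records.append(
            DrugRecord(
                case_id=cid,
                drug_name=str(row.drug_name).strip(),
                involvement=_map_vocab(row.involvement, INVOLVEMENTS,
                                       "concomitant", warnings, "involvement"),
                route=_map_vocab(row.route, ROUTES, "other", warnings, "route"),
            )
        )

    reac_records, orphan_reac = [], 0
    for row in reac.itertuples(index=False):
        cid = str(row.case_id).strip()
        if cid not in known_ids:
            orphan_reac += 1
            continue
        pt = str(row.preferred_term).strip()
        if pt:
            reac_records.append(ReactionRecord(case_id=cid, preferred_term=pt))

    ind_records, orphan_ind = [], 0
    for row in indication.itertuples(index=False):
        cid = str(row.case_id).strip()
        if cid not in known_ids:
            orphan_ind += 1
            continue
        ind = str(row.indication).strip()
        if ind:
            ind_records.append(IndicationRecord(case_id=cid, indication=ind))

    return RawTables(
        demo=demo_records,
        drugs=drug_records,
        reactions=reac_records,
        indications=ind_records,
        vocabulary_warnings=warnings,
        n_orphan_drug_rows=orphan_drug,
        n_orphan_reaction_rows=orphan_reac,
        n_orphan_indication_rows=orphan_ind,
    )


def read_tables(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    indication_path: str | Path,
    encoding: str = "utf-8",
) -> RawTables:
    """Read the four source CSVs into typed records.

    ``encoding`` defaults to UTF-8; pass ``cp932`` for real Shift-JIS
    exports.  Missing required columns raise a hard error naming the
    file and column.
    """

    def _read(path):
        return pd.read_csv(path, dtype=str, keep_default_na=False,
                           encoding=encoding)

    frames = {}
    for name, path in (("demo", demo_path), ("drug", drug_path),
                       ("reac", reac_path), ("indication", indication_path)):
        df = _read(path)
        _require_columns(df, name, str(path))
        frames[name] = df
    return read_frames(frames["demo"], frames["drug"], frames["reac"],
                       frames["indication"], source="<csv>")


def clean_step1(raw: RawTables) -> tuple[RawTables, dict]:
    """Demographic and route exclusions.

    Removes cases with unknown sex or age entirely; removes drug records
    with route ``other`` (record level); removes cases left with zero
    drug records.  Reaction and indication rows follow their cases.
    """
    kept_demo = [d for d in raw.demo
                 if d.sex != UNKNOWN and d.age_band != UNKNOWN]
    n_removed_demo = len(raw.demo) - len(kept_demo)
    kept_ids = {d.case_id for d in kept_demo}

    eligible_drugs = [d for d in raw.drugs
                      if d.case_id in kept_ids and d.route in ELIGIBLE_ROUTES]
    n_rows_dropped = sum(1 for d in raw.drugs if d.case_id in kept_ids) - len(
        eligible_drugs
    )
    ids_with_drugs = {d.case_id for d in eligible_drugs}
    n_removed_route = len(kept_ids - ids_with_drugs)

    surviving = ids_with_drugs
    out = RawTables(
        demo=[d for d in kept_demo if d.case_id in surviving],
        drugs=eligible_drugs,
        reactions=[r for r in raw.reactions if r.case_id in surviving],
        indications=[i for i in raw.indications if i.case_id in surviving],
        vocabulary_warnings=raw.vocabulary_warnings,
        n_orphan_drug_rows=raw.n_orphan_drug_rows,
        n_orphan_reaction_rows=raw.n_orphan_reaction_rows,
        n_orphan_indication_rows=raw.n_orphan_indication_rows,
    )
    fragment = {
        "n_removed_unknown_demo": n_removed_demo,
        "n_removed_route": n_removed_route,
        "n_drug_rows_dropped_route": n_rows_dropped,
    }
    return out, fragment


def clean_step2(raw: RawTables, registry: JarsRegistry) -> tuple[RawTables, dict]:
    """Drop cases in which no remaining drug is in the risk registry."""
    scored_ids = {d.case_id for d in raw.drugs
                  if registry.score_of(d.drug_name) is not None}
    surviving = {d.case_id for d in raw.demo} & scored_ids
    n_removed = len(raw.demo) - len(surviving)
    out = RawTables(
        demo=[d for d in raw.demo if d.case_id in surviving],
        drugs=[d for d in raw.drugs if d.case_id in surviving],
        reactions=[r for r in raw.reactions if r.case_id in surviving],
        indications=[i for i in raw.indications if i.case_id in surviving],
        vocabulary_warnings=raw.vocabulary_warnings,
        n_orphan_drug_rows=raw.n_orphan_drug_rows,
        n_orphan_reaction_rows=raw.n_orphan_reaction_rows,
        n_orphan_indication_rows=raw.n_orphan_indication_rows,
    )
    return out, {"n_removed_no_jars": n_removed}


def assemble_profiles(raw: RawTables, registry: JarsRegistry) -> list[CaseProfile]:
    """One :class:`CaseProfile` per surviving case.

    Duplicate (drug_name, involvement) rows within a case collapse to
    one entry (spontaneous-report tables repeat rows per dosage form;
    double counting would inflate the anticholinergic load); duplicate
    reaction rows collapse into the PT set.
    """
    known_ids = raw.case_ids()
    drugs_by_case: dict[str, dict[tuple[str, str], DrugEntry]] = {}
    for d in raw.drugs:
        if d.case_id not in known_ids:
            continue
        key = (normalize(d.drug_name), d.involvement)
        per_case = drugs_by_case.setdefault(d.case_id, {})
        if key not in per_case:
            per_case[key] = DrugEntry(
                drug_name=d.drug_name,
                involvement=d.involvement,
                route=d.route,
                jars_score=registry.score_of(d.drug_name),
            )
    pts_by_case: dict[str, set[str]] = {}
    for r in raw.reactions:
        if r.case_id in known_ids:
            pts_by_case.setdefault(r.case_id, set()).add(r.preferred_term)
    inds_by_case: dict[str, set[str]] = {}
    for i in raw.indications:
        if i.case_id in known_ids:
            inds_by_case.setdefault(i.case_id, set()).add(i.indication)

    profiles = []
    for demo in raw.demo:
        profiles.append(
            CaseProfile(
                case_id=demo.case_id,
                sex=demo.sex,
                age_band=demo.age_band,
                drugs=tuple(drugs_by_case.get(demo.case_id, {}).values()),
                pts=frozenset(pts_by_case.get(demo.case_id, set())),
                indications=frozenset(inds_by_case.get(demo.case_id, set())),
            )
        )
    return profiles


def build_profiles(
    raw: RawTables, registry: JarsRegistry
) -> tuple[list[CaseProfile], CleaningLog]:
    """Full cleaning cascade: step 1, step 2, assembly, with a complete log."""
    n_input = len(raw.demo)
    step1, frag1 = clean_step1(raw)
    step2, frag2 = clean_step2(step1, registry)
    profiles = assemble_profiles(step2, registry)
    log = CleaningLog(
        n_input_cases=n_input,
        n_removed_unknown_demo=frag1["n_removed_unknown_demo"],
        n_removed_route=frag1["n_removed_route"],
        n_removed_no_jars=frag2["n_removed_no_jars"],
        n_remaining=len(profiles),
        n_drug_rows_dropped_route=frag1["n_drug_rows_dropped_route"],
        n_orphan_drug_rows=raw.n_orphan_drug_rows,
        n_orphan_reaction_rows=raw.n_orphan_reaction_rows,
        n_orphan_indication_rows=raw.n_orphan_indication_rows,
        vocabulary_warnings=dict(raw.vocabulary_warnings),
    )
    assert log.is_conserved()
    return profiles, log


# ---------------------------------------------------------------------------
# Profile (de)serialization for the CLI.  Drugs are packed as
# "name|involvement|route|score" joined by ";"; PT and indication sets
# are ";"-joined.  Field values must therefore not contain "|" or ";".

def profiles_to_frame(profiles: Iterable[CaseProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {
                "case_id": p.case_id,
                "sex": p.sex,
                "age_band": p.age_band,
                "drugs": ";".join(
                    f"{d.drug_name}|{d.involvement}|{d.route}|"
                    f"{'' if d.jars_score is None else d.jars_score}"
                    for d in p.drugs
                ),
                "pts": ";".join(sorted(p.pts)),
                "indications": ";".join(sorted(p.indications)),
            }
        )
    return pd.DataFrame(
        rows, columns=["case_id", "sex", "age_band", "drugs", "pts", "indications"]
    )


def write_profiles(profiles: Iterable[CaseProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_profiles(path: str | Path) -> list[CaseProfile]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    profiles = []
    for row in df.itertuples(index=False):
        drugs = []
        for packed in filter(None, row.drugs.split(";")):
            name, involvement, route, score = packed.split("|")
            drugs.append(
                DrugEntry(name, involvement, route,
                          int(score) if score else None)
            )
        profiles.append(
            CaseProfile(
                case_id=row.case_id,
                sex=row.sex,
                age_band=row.age_band,
                drugs=tuple(drugs),
                pts=frozenset(filter(None, row.pts.split(";"))),
                indications=frozenset(filter(None, row.indications.split(";"))),
            )
        )
    return profiles
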