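"""Synthetic spontaneous-report tables with known ground truth.

The generator emits the four JADER-shaped CSV tables (case list, drug,
reaction, indication) from an explicit mechanism so that every pipeline
stage can be tested without the non-redistributable source data:

* each case draws binary confounders (emitted as indications) that
  shift both the propensity to receive registry-scored drugs and the
  event odds — the confounding structure the matching stage must undo;
* drugs are drawn per case; each slot is a registry drug with a
  confounder-shifted probability, otherwise a filler drug; routes are
  drawn from a configurable mix;
* adverse events follow a per-category logistic model in the case's
  true anticholinergic load: logit P(category c event) =
  beta0[c] + beta_tal * TAL + confounder effects.  This cumulative-load
  mechanism is the minimal generative model consistent with the
  hypothesis the pipeline is built to examine.  The category-A
  (syndrome) term appears with a small probability only above a high
  TAL cutoff;
* involvement is assigned the way reporters assign it — after the
  event: the first registry drug is labelled *suspect* with a higher
  probability when a query-category event occurred than when none did,
  reflecting causality attribution in spontaneous reports; the rest
  are concomitant, with a small interaction fraction;
* background (non-query) preferred terms and demographic missingness
  complete the tables.

A single master seed drives per-case substreams, so enlarging a
simulation never perturbs earlier cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ValidationError
from .jars import JarsRegistry, synthesize_registry, _generated_names
from .smq import SmqDictionary, example_dictionary
from .tables import AGE_BANDS, ELIGIBLE_ROUTES, RawTables, read_frames

EVENT_CATEGORIES = ("B", "C", "D")

_BACKGROUND_PTS = (
    "Nausea", "Headache", "Rash", "Pyrexia", "Fatigue",
    "Vomiting", "Diarrhoea", "Pruritus", "Decreased appetite", "Malaise",
)
_BACKGROUND_INDICATIONS = (
    "hypertension", "diabetes mellitus", "gastric ulcer", "chronic pain",
)
# Age distribution skewed towards older reporters, as in spontaneous
# reporting systems.
_AGE_WEIGHTS = (0.03, 0.05, 0.07, 0.10, 0.12, 0.15, 0.20, 0.18, 0.10)


@dataclass(frozen=True)
class ConfounderSpec:
    """A binary baseline condition affecting exposure and event odds."""

    name: str
    prevalence: float
    beta_exposure: float  # shift on the per-slot registry-drug log-odds
    beta_event: float     # shift on every event-category log-odds


@dataclass
class SimulationConfig:
    """Generator parameters; the defaults are the package's study
    conditions (see the methods note for their rationale)."""

    n_cases: int = 5000
    seed: int = 0
    # registry (published per-score counts)
    n_score3: int = 37
    n_score2: int = 27
    n_score1: int = 94
    # drug assignment
    mean_drugs: float = 3.5
    max_drugs: int = 8
    p_registry_drug: float = 0.6
    p_suspect: float = 0.8            # first registry drug, given an event
    p_suspect_no_event: float = 0.45  # first registry drug, no query event
    p_interaction: float = 0.05
    route_mix: tuple = (0.78, 0.12, 0.10)  # oral, transdermal, other
    # demographics
    female_rate: float = 0.55
    missing_demo_rate: float = 0.08
    # confounding
    confounders: tuple = (
        ConfounderSpec("dementia", 0.10, 0.9, 0.7),
        ConfounderSpec("insomnia", 0.20, 0.5, 0.4),
    )
    background_indication_rate: float = 0.3
    # event mechanism
    beta0: dict = field(
        default_factory=lambda: {"B": -3.6, "C": -3.8, "D": -3.2}
    )
    beta_tal: float = 0.25
    p_A: float = 0.02
    a_tal_cutoff: int = 6
    background_pt_mean: float = 1.5

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValidationError("n_cases must be >= 1")
        probs = [self.p_registry_drug, self.p_suspect,
                 self.p_suspect_no_event, self.p_interaction,
                 self.female_rate, self.missing_demo_rate, self.p_A,
                 self.background_indication_rate, *self.route_mix]
        probs += [c.prevalence for c in self.confounders]
        if any(not (0 <= p <= 1) for p in probs):
            raise ValidationError("probabilities must lie in [0, 1]")
        if abs(sum(self.route_mix) - 1.0) > 1e-9:
            raise ValidationError("route_mix must sum to 1")
        if self.max_drugs < 1 or self.mean_drugs < 1:
            raise ValidationError("drug-count distribution is malformed")


def null_config(**overrides) -> SimulationConfig:
    """A no-effect configuration: events independent of TAL.

    ``beta_tal`` and the confounder event effects are zero (confounding
    with a zero direct effect would still couple TAL to the event
    groups, which is not a null for the rank test), and baseline event
    rates are raised so every group is populated at small n.
    """
    cfg = SimulationConfig(
        beta_tal=0.0,
        p_A=0.0,
        confounders=(),
        beta0={"B": -1.5, "C": -1.6, "D": -1.2},
        **overrides,
    )
    return cfg


@dataclass
class SimulatedData:
    """Emitted tables plus the per-case ground truth."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    indication: pd.DataFrame
    truth: pd.DataFrame
    registry: JarsRegistry
    dictionary: SmqDictionary
    config: SimulationConfig

    def to_raw_tables(self) -> RawTables:
        return read_frames(self.demo, self.drug, self.reac, self.indication,
                           source="<simulated>")

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("demo", "drug", "reac", "indication", "truth"):
            path = outdir / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False)
            paths[name] = path
        reg_path = outdir / "registry.csv"
        self.registry.to_csv(reg_path)
        paths["registry"] = reg_path
        dict_path = outdir / "smq.csv"
        self.dictionary.to_csv(dict_path)
        paths["dictionary"] = dict_path
        return paths


def _case_rng(seed: int, index: int) -> np.random.Generator:
    # per-case substream: stable under changes to n_cases
    return np.random.default_rng([seed, index])


def simulate(config: SimulationConfig) -> SimulatedData:
    """Generate the four tables and ground truth for ``config``.

    Deterministic: identical (config, seed) yields identical frames.
    """
    config.validate()
    registry = synthesize_registry(
        config.n_score3, config.n_score2, config.n_score1, config.seed
    )
    dictionary = example_dictionary()
    registry_names = [e.drug_name for e in registry.entries]
    registry_scores = {e.drug_name: e.score for e in registry.entries}
    filler_rng = np.random.default_rng([config.seed, 2**31 - 1])
    filler_names = [
        n for n in _generated_names(60, filler_rng) if n not in registry_scores
    ]
    cat_pts = {c: list(dictionary.pts_in_category(c)) for c in EVENT_CATEGORIES}
    a_pt = dictionary.pts_in_category("A")[0] if dictionary.pts_in_category("A") else None

    demo_rows, drug_rows, reac_rows, ind_rows, truth_rows = [], [], [], [], []
    for i in range(config.n_cases):
        rng = _case_rng(config.seed, i)
        cid = f"C{i:06d}"

        conf_active = {
            c.name: bool(rng.random() < c.prevalence) for c in config.confounders
        }
        conf_exp = sum(c.beta_exposure for c in config.confounders
                       if conf_active[c.name])
        conf_evt = sum(c.beta_event for c in config.confounders
                       if conf_active[c.name])

        # demographics
        sex = "female" if rng.random() < config.female_rate else "male"
        age_band = AGE_BANDS[rng.choice(len(AGE_BANDS), p=_AGE_WEIGHTS)]
        missing = rng.random() < config.missing_demo_rate
        sex_out, age_out = sex, age_band
        if missing:
            if rng.random() < 0.5:
                sex_out = ""
            else:
                age_out = ""
        demo_rows.append({"case_id": cid, "sex": sex_out, "age_band": age_out})

        # drugs: identities and routes first (involvement is assigned
        # after the events, the way reporters attribute causality)
        n_drugs = min(
            1 + rng.poisson(max(config.mean_drugs - 1, 0)), config.max_drugs
        )
        p_reg = float(expit(logit(np.clip(config.p_registry_drug, 1e-6, 1 - 1e-6))
                            + conf_exp))
        route_labels = ("oral", "transdermal", "other")
        case_drugs = []  # (name, route, is_registry)
        for _ in range(n_drugs):
            if rng.random() < p_reg:
                name = registry_names[int(rng.integers(len(registry_names)))]
                is_registry = True
            else:
                name = filler_names[int(rng.integers(len(filler_names)))]
                is_registry = False
            route = route_labels[rng.choice(3, p=config.route_mix)]
            case_drugs.append((name, route, is_registry))

        # ground-truth load over route-eligible distinct registry drugs
        eligible_scores = {
            name: registry_scores[name]
            for name, route, is_reg in case_drugs
            if is_reg and route in ELIGIBLE_ROUTES
        }
        tal_true = sum(eligible_scores.values())

        # events
        pts: set[str] = set()
        mechanism = {}
        for cat in EVENT_CATEGORIES:
            p_evt = float(expit(config.beta0[cat]
                                + config.beta_tal * tal_true + conf_evt))
            hit = rng.random() < p_evt
            mechanism[cat] = hit
            if hit and cat_pts[cat]:
                n_pts = 1 + int(rng.random() < 0.3)
                chosen = rng.choice(len(cat_pts[cat]),
                                    size=min(n_pts, len(cat_pts[cat])),
                                    replace=False)
                pts.update(cat_pts[cat][j] for j in chosen)
        has_a = (
            a_pt is not None
            and tal_true >= config.a_tal_cutoff
            and rng.random() < config.p_A
        )
        if has_a:
            pts.add(a_pt)
        n_bg = 1 + rng.poisson(max(config.background_pt_mean - 1, 0))
        pts.update(
            _BACKGROUND_PTS[int(rng.integers(len(_BACKGROUND_PTS)))]
            for _ in range(n_bg)
        )
        for pt in sorted(pts):
            reac_rows.append({"case_id": cid, "preferred_term": pt})

        # involvement: causality attribution in light of the event
        any_query_event = has_a or any(mechanism.values())
        p_susp = config.p_suspect if any_query_event else config.p_suspect_no_event
        seen_registry = False
        exposed = False
        for name, route, is_reg in case_drugs:
            if is_reg and not seen_registry:
                seen_registry = True
                if rng.random() < p_susp:
                    involvement = "suspect"
                    if route in ELIGIBLE_ROUTES:
                        exposed = True
                else:
                    involvement = "concomitant"
            else:
                involvement = ("interaction"
                               if rng.random() < config.p_interaction
                               else "concomitant")
            drug_rows.append({"case_id": cid, "drug_name": name,
                              "involvement": involvement, "route": route})

        # indications: active confounders plus occasional background disease
        for name, active in conf_active.items():
            if active:
                ind_rows.append({"case_id": cid, "indication": name})
        if rng.random() < config.background_indication_rate:
            ind_rows.append({
                "case_id": cid,
                "indication": _BACKGROUND_INDICATIONS[
                    int(rng.integers(len(_BACKGROUND_INDICATIONS)))],
            })

        truth_rows.append({
            "case_id": cid,
            "tal_true": tal_true,
            "n_registry_drugs": len(eligible_scores),
            "exposed": exposed,
            "demo_missing": missing,
            "event_A": has_a,
            **{f"event_{c}": mechanism[c] for c in EVENT_CATEGORIES},
            **{f"conf_{k}": v for k, v in conf_active.items()},
        })

    return SimulatedData(
        demo=pd.DataFrame(demo_rows, columns=["case_id", "sex", "age_band"]),
        drug=pd.DataFrame(
            drug_rows, columns=["case_id", "drug_name", "involvement", "route"]
        ),
        reac=pd.DataFrame(reac_rows, columns=["case_id", "preferred_term"]),
        indication=pd.DataFrame(ind_rows, columns=["case_id", "indication"]),
        truth=pd.DataFrame(truth_rows),
        registry=registry,
        dictionary=dictionary,
        config=config,
    )


def recover_pipeline(
    sim: SimulatedData,
    min_reports: Optional[int] = None,
    n_permutations: int = 2000,
    seed: int = 0,
    with_matching: bool = True,
    with_signals: bool = True,
    with_steel: bool = True,
) -> dict:
    """Run the full pipeline on simulated tables; report recovery checks.

    Returns a dict with the cleaning log, group composition, the median
    ln(ROR) over mechanism (query-category) preferred terms, TAL means
    for the related and control groups, Steel p-values, and the
    post-match balance.  ``min_reports`` defaults to the standard 100
    at full scale, scaled down proportionally for small simulations.
    """
    from .classify import classify_all, tabulate_groups, OTHER
    from .matching import (balance_report, default_covariate_spec,
                           extract_design, fit_logistic, nn_match)
    from .signals import scan_events
    from .tal import compute_tal, summarize_groups
    from .tables import build_profiles
    from .errors import StageError

    report: dict = {}
    try:
        raw = sim.to_raw_tables()
        profiles, log = build_profiles(raw, sim.registry)
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("build", str(exc)) from exc
    report["cleaning"] = log.to_dict()
    if not profiles:
        report["n_cleaned"] = 0
        return report
    report["n_cleaned"] = len(profiles)

    try:
        classified = classify_all(profiles, sim.dictionary)
        composition = tabulate_groups(classified)
    except Exception as exc:  # pragma: no cover
        raise StageError("classify", str(exc)) from exc
    report["composition"] = composition.to_dict(orient="records")
    related = [cp.is_related for cp in classified]
    report["n_related"] = int(sum(related))

    if with_signals:
        try:
            if min_reports is None:
                min_reports = max(5, round(100 * len(profiles) / 16000))
            signals = scan_events(profiles, sim.dictionary,
                                  min_reports=min_reports)
            mech = signals[signals["category"].isin(list(EVENT_CATEGORIES))]
            report["median_ln_ror_mechanism"] = (
                float(mech["ln_ror"].median()) if len(mech) else float("nan")
            )
            report["n_signals_included"] = int(signals["included"].sum())
        except Exception as exc:
            raise StageError("signal", str(exc)) from exc

    try:
        tal_records = [compute_tal(p, sim.registry) for p in profiles]
        labels = [cp.group_label for cp in classified]
        tal_by_related = {
            True: [r.tal for r, rel in zip(tal_records, related) if rel],
            False: [r.tal for r, rel in zip(tal_records, related) if not rel],
        }
        report["tal_mean_related"] = float(np.mean(tal_by_related[True]))
        report["tal_mean_other"] = float(np.mean(tal_by_related[False]))
    except Exception as exc:  # pragma: no cover
        raise StageError("tal", str(exc)) from exc

    if with_steel:
        try:
            summary = summarize_groups(
                tal_records, labels, control_label=OTHER,
                n_permutations=n_permutations, seed=seed,
            )
            report["group_summary"] = summary.to_dict(orient="records")
        except Exception as exc:
            raise StageError("steel", str(exc)) from exc

    if with_matching and 0 < sum(related) < len(related):
        try:
            spec = default_covariate_spec(profiles)
            X, y, names = extract_design(profiles, classified, spec)
            model = fit_logistic(X, y, column_names=names)
            scores = model.predict(X)
            match = nn_match(scores, y, seed=seed,
                             ids=[p.case_id for p in profiles])
            balance = balance_report(X, y, match.pair_indices, names)
            report["n_pairs"] = len(match.pairs)
            report["balance"] = balance.table.to_dict(orient="records")
            report["balanced"] = balance.balanced
            report["max_smd_after"] = balance.max_smd_after
        except Exception as exc:
            raise StageError("match", str(exc)) from exc
    return report
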