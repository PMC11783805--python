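"""Consolidated run configuration and report models.

:class:`RunConfig` drives :func:`run_all`, which chains the pipeline
stages (optionally starting from the synthetic generator) and writes
every intermediate plus a consolidated :class:`RunReport`.  Both models
are pydantic, so the report JSON is validated against a schema that
ships with the package; ``aclpv schema`` exports it.  Timestamps and
host details are quarantined in the single ``environment`` field, so
the remainder of a report is byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import datetime as _dt
import json
import platform
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .errors import ConfigurationError, StageError


class Thresholds(BaseModel):
    min_reports: int = 100
    balance_percent: float = 10.0
    alpha: float = 0.05

    @field_validator("min_reports", "balance_percent", "alpha")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("thresholds must be positive")
        return v


class Stages(BaseModel):
    generate: bool = True
    signal: bool = True
    match: bool = True
    tal: bool = True


class RunConfig(BaseModel):
    seed: int = 0
    outdir: str = "out"
    encoding: str = "utf-8"
    stages: Stages = Field(default_factory=Stages)
    thresholds: Thresholds = Field(default_factory=Thresholds)
    n_permutations: int = 2000
    #: overrides applied to the synthetic generator when generating
    simulation: dict = Field(default_factory=dict)
    # input paths, used when stages.generate is false
    demo: Optional[str] = None
    drug: Optional[str] = None
    reac: Optional[str] = None
    indication: Optional[str] = None
    registry: Optional[str] = None
    dictionary: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)


class MatchSection(BaseModel):
    n_treated: int
    n_control: int
    n_pairs: int
    balanced: bool
    max_smd_after: float


class RunReport(BaseModel):
    seed: int
    versions: dict
    environment: dict  # timestamp/host quarantine; everything else is stable
    cleaning: dict
    composition: list[dict]
    n_signals_included: Optional[int] = None
    n_signals_significant: Optional[int] = None
    match: Optional[MatchSection] = None
    group_summary: Optional[list[dict]] = None

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))

    def to_text(self) -> str:
        lines = [f"aclpv run report (seed={self.seed})", ""]
        c = self.cleaning
        lines += [
            "Cleaning cascade:",
            f"  input cases:                 {c['n_input_cases']}",
            f"  removed (unknown sex/age):   {c['n_removed_unknown_demo']}",
            f"  removed (route exclusion):   {c['n_removed_route']}",
            f"  removed (no scored drug):    {c['n_removed_no_jars']}",
            f"  analysis set:                {c['n_remaining']}",
            "",
            "Group composition:",
        ]
        for row in self.composition:
            lines.append(
                f"  {row['group']:<10} {row['count']:>7}  {row['percent']}%"
            )
        if self.n_signals_included is not None:
            lines += ["", f"Signals passing report threshold: "
                          f"{self.n_signals_included} "
                          f"({self.n_signals_significant} significant)"]
        if self.match is not None:
            m = self.match
            lines += ["", f"Matching: {m.n_pairs} pairs from "
                          f"{m.n_treated} related vs {m.n_control} other; "
                          f"max post-match SMD {m.max_smd_after:.2f}% "
                          f"({'balanced' if m.balanced else 'NOT balanced'})"]
        if self.group_summary is not None:
            lines += ["", "TAL by group (Steel vs other ADEs):"]
            for row in self.group_summary:
                sd = row["tal_sd"]
                sd_s = "-" if sd is None or (isinstance(sd, float) and np.isnan(sd)) else f"{sd:.2f}"
                p = row["steel_p"]
                p_s = "-" if p is None or (isinstance(p, float) and np.isnan(p)) else f"{p:.4f}"
                lines.append(
                    f"  {row['group']:<10} n={row['n']:<6} "
                    f"mean={row['tal_mean']:.2f} sd={sd_s} "
                    f"drugs={row['mean_jars_drugs']:.2f} p={p_s}"
                )
        return "\n".join(lines) + "\n"


def _versions() -> dict:
    return {
        "aclpv": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }


def run_all(config: RunConfig) -> RunReport:
    """Execute the configured stages in order and write all outputs.

    A stage failure aborts with the stage name while preserving the
    outputs of completed stages.
    """
    from .classify import OTHER, classify_all, tabulate_groups
    from .jars import default_registry, load_registry
    from .matching import (balance_report, default_covariate_spec,
                           extract_design, fit_logistic, nn_match)
    from .signals import scan_events, volcano_export
    from .simulate import SimulationConfig, simulate
    from .smq import example_dictionary, load_dictionary
    from .tal import compute_tal, summarize_groups
    from .tables import build_profiles, read_tables, write_profiles

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    if config.stages.generate:
        sim_cfg = SimulationConfig(seed=config.seed, **config.simulation)
        sim = simulate(sim_cfg)
        paths = sim.write(outdir / "data")
        raw = sim.to_raw_tables()
        registry = sim.registry
        dictionary = sim.dictionary
    else:
        for name in ("demo", "drug", "reac", "indication"):
            if getattr(config, name) is None:
                raise ConfigurationError(
                    f"input path {name!r} required when generate stage is off"
                )
        raw = read_tables(config.demo, config.drug, config.reac,
                          config.indication, encoding=config.encoding)
        registry = (load_registry(config.registry) if config.registry
                    else default_registry(config.seed))
        dictionary = (load_dictionary(config.dictionary) if config.dictionary
                      else example_dictionary())

    # --- build + classify (always run) ------------------------------------
    try:
        profiles, log = build_profiles(raw, registry)
    except Exception as exc:
        raise StageError("build", str(exc)) from exc
    write_profiles(profiles, outdir / "profiles.csv")
    log.to_json(outdir / "cleaning.json")

    try:
        classified = classify_all(profiles, dictionary)
        composition = tabulate_groups(classified)
    except Exception as exc:
        raise StageError("classify", str(exc)) from exc
    composition.to_csv(outdir / "composition.csv", index=False)
    assert int(composition["count"].sum()) == log.n_remaining

    n_sig_included = n_sig_significant = None
    if config.stages.signal:
        try:
            signals = scan_events(profiles, dictionary,
                                  min_reports=config.thresholds.min_reports)
            signals.to_csv(outdir / "signals.csv", index=False)
            volcano_export(signals, outdir / "volcano.csv")
            n_sig_included = int(signals["included"].sum())
            n_sig_significant = int(
                (signals["included"]
                 & (signals["p_value"] < config.thresholds.alpha)).sum()
            )
        except Exception as exc:
            raise StageError("signal", str(exc)) from exc

    match_section = None
    if config.stages.match:
        try:
            y_related = [cp.is_related for cp in classified]
            if 0 < sum(y_related) < len(y_related):
                spec = default_covariate_spec(profiles)
                X, y, names = extract_design(profiles, classified, spec)
                model = fit_logistic(X, y, column_names=names)
                match = nn_match(model.predict(X), y, seed=config.seed,
                                 ids=[p.case_id for p in profiles])
                balance = balance_report(
                    X, y, match.pair_indices, names,
                    threshold=config.thresholds.balance_percent,
                )
                pd.DataFrame(match.pairs,
                             columns=["treated", "control"]).to_csv(
                    outdir / "pairs.csv", index=False)
                balance.table.to_csv(outdir / "balance.csv", index=False)
                match_section = MatchSection(
                    n_treated=int(sum(y)),
                    n_control=int(len(y) - sum(y)),
                    n_pairs=len(match.pairs),
                    balanced=balance.balanced,
                    max_smd_after=balance.max_smd_after,
                )
        except Exception as exc:
            raise StageError("match", str(exc)) from exc

    group_summary = None
    if config.stages.tal:
        try:
            tal_records = [compute_tal(p, registry) for p in profiles]
            labels = [cp.group_label for cp in classified]
            if OTHER in labels:
                summary = summarize_groups(
                    tal_records, labels,
                    n_permutations=config.n_permutations, seed=config.seed,
                )
                summary.to_csv(outdir / "summary.csv", index=False)
                group_summary = json.loads(
                    summary.to_json(orient="records")
                )
        except Exception as exc:
            raise StageError("tal", str(exc)) from exc

    report = RunReport(
        seed=config.seed,
        versions=_versions(),
        environment={
            "timestamp": _dt.datetime.now().isoformat(),
            "platform": platform.platform(),
        },
        cleaning=log.to_dict(),
        composition=composition.to_dict(orient="records"),
        n_signals_included=n_sig_included,
        n_signals_significant=n_sig_significant,
        match=match_section,
        group_summary=group_summary,
    )
    report.write(outdir / "report.json")
    (outdir / "report.txt").write_text(report.to_text())
    return report
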