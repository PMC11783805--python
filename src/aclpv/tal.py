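"""Total anticholinergic load (TAL) and Steel many-to-one comparisons.

The TAL of a case is the sum of risk-scale scores over its *distinct*
registry-scored drugs — suspect, concomitant and interaction drugs
alike, each distinct drug name counted once (report tables repeat rows
per dosage form, and double counting would inflate the load).

Group comparisons use Steel's many-to-one procedure: each event group
is compared to the shared other-ADE control by a rank-sum statistic
computed within the pooled (group + control) sample using mid-ranks,
standardized by its tie-corrected null mean and variance.  Familywise
adjustment is by the max-T resampling principle: all observations are
jointly relabelled across the k+1 samples, and each group's adjusted
p-value is the probability that the maximum absolute standardized
statistic over the permuted groups reaches its observed value.  Small
inputs are enumerated exhaustively; larger ones use seeded Monte Carlo
permutation.  The classical large-sample normal approximation is also
available for cross-checking (``method="normal"``), using the Dunnett
many-to-one critical surface via scipy's multivariate normal.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._text import normalize
from .classify import GROUPS, OTHER, SYNDROME
from .errors import ValidationError
from .jars import JarsRegistry
from .tables import CaseProfile, ELIGIBLE_ROUTES

DEFAULT_PERMUTATIONS = 10_000
#: Largest number of distinct relabelings enumerated exhaustively.
EXACT_ENUMERATION_LIMIT = 20_000
_TIE_EPS = 1e-9


@dataclass(frozen=True)
class TalRecord:
    case_id: str
    tal: int
    n_jars_drugs: int


def compute_tal(
    profile: CaseProfile,
    registry: JarsRegistry,
    route: Optional[str] = None,
) -> TalRecord:
    """TAL and scored-drug count for one case.

    Every involvement category contributes; distinct drug names count
    once.  ``route`` optionally restricts the drug records considered
    (the route-stratified supplementary analysis hook).
    """
    if route is not None and route not in ELIGIBLE_ROUTES:
        raise ValidationError(f"route must be one of {ELIGIBLE_ROUTES}")
    scores: dict[str, int] = {}
    for d in profile.drugs:
        if route is not None and d.route != route:
            continue
        score = registry.score_of(d.drug_name)
        if score is not None:
            scores[normalize(d.drug_name)] = score
    return TalRecord(
        case_id=profile.case_id,
        tal=sum(scores.values()),
        n_jars_drugs=len(scores),
    )


# ---------------------------------------------------------------------------
# Steel many-to-one rank test


@dataclass
class SteelResult:
    """Per-group standardized statistics and (adjusted) p-values.

    ``p_adjusted`` controls the familywise error over the many-to-one
    family via max-T; ``p_unadjusted`` is the single-comparison
    permutation rank-sum p on the same relabelings, so
    ``p_adjusted >= p_unadjusted`` always holds.
    """

    statistic: np.ndarray
    p_adjusted: np.ndarray
    p_unadjusted: np.ndarray
    method: str
    n_resamples: int


def _standardized_ranksum(group: np.ndarray, control: np.ndarray) -> float:
    """Mid-rank sum of ``group`` within group+control, standardized.

    Null mean is n1(N+1)/2; variance carries the mid-rank tie
    correction: Var = n0*n1/(N(N-1)) * sum((r - rbar)^2).  Returns 0
    when the pooled sample is entirely tied (zero variance).
    """
    n1, n0 = len(group), len(control)
    pooled = np.concatenate([control, group])
    r = rankdata(pooled)
    w = r[n0:].sum()
    n = n0 + n1
    mu = n1 * (n + 1) / 2.0
    ss = np.sum((r - (n + 1) / 2.0) ** 2)
    var = n0 * n1 * ss / (n * (n - 1))
    if var <= 0:
        return 0.0
    return float((w - mu) / math.sqrt(var))


def _stats_for_assignment(
    pooled: np.ndarray, sizes: Sequence[int]
) -> np.ndarray:
    """Standardized statistics for each group vs control, given pooled
    values ordered control-first then groups in sequence."""
    n0 = sizes[0]
    control = pooled[:n0]
    out = np.empty(len(sizes) - 1)
    start = n0
    for i, ni in enumerate(sizes[1:]):
        out[i] = _standardized_ranksum(pooled[start:start + ni], control)
        start += ni
    return out


def _n_arrangements(sizes: Sequence[int]) -> int:
    total = sum(sizes)
    n = math.factorial(total)
    for s in sizes:
        n //= math.factorial(s)
    return n


def _enumerate_assignments(values: np.ndarray, sizes: Sequence[int]):
    """Yield every distinct assignment of indices to samples of the given
    sizes, as the pooled array reordered control-first."""
    idx = tuple(range(len(values)))

    def rec(remaining: tuple, sizes_left: Sequence[int], chosen: list):
        if not sizes_left:
            yield np.concatenate([values[list(c)] for c in chosen])
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in combo)
            yield from rec(rest, sizes_left[1:], chosen + [list(combo)])

    yield from rec(idx, list(sizes), [])


def steel_test(
    treatments: Sequence[Sequence[float]],
    control: Sequence[float],
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: Optional[int] = None,
    method: str = "auto",
) -> SteelResult:
    """Steel's many-to-one rank test of k groups against one control.

    Two-sided throughout.  ``method`` is ``"exact"`` (full enumeration
    of relabelings; the default for small inputs), ``"permutation"``
    (seeded Monte Carlo max-T), ``"normal"`` (large-sample equicorrelated
    multivariate-normal approximation), or ``"auto"``.  With k=1 the
    adjusted p equals the two-sample permutation rank-sum p.
    """
    groups = [np.asarray(g, dtype=float) for g in treatments]
    control = np.asarray(control, dtype=float)
    if len(control) == 0 or any(len(g) == 0 for g in groups) or not groups:
        raise ValidationError("control and every group must be non-empty")

    sizes = [len(control)] + [len(g) for g in groups]
    pooled_obs = np.concatenate([control] + groups)
    obs = _stats_for_assignment(pooled_obs, sizes)
    k = len(groups)

    if method == "auto":
        method = (
            "exact"
            if _n_arrangements(sizes) <= EXACT_ENUMERATION_LIMIT
            else "permutation"
        )

    if method == "normal":
        return _steel_normal(obs, sizes)
    if method not in ("exact", "permutation"):
        raise ValidationError(f"unknown method {method!r}")

    abs_obs = np.abs(obs)
    if method == "exact":
        n_total = 0
        ge_max = np.zeros(k)
        ge_single = np.zeros(k)
        for arrangement in _enumerate_assignments(pooled_obs, sizes):
            z = np.abs(_stats_for_assignment(arrangement, sizes))
            m = z.max()
            n_total += 1
            ge_max += m >= abs_obs - _TIE_EPS
            ge_single += z >= abs_obs - _TIE_EPS
        p_adj = ge_max / n_total
        p_un = ge_single / n_total
        return SteelResult(obs, p_adj, p_un, "exact", n_total)

    rng = np.random.default_rng(seed)
    ge_max = np.ones(k)  # observed relabeling counted once
    ge_single = np.ones(k)
    for _ in range(n_permutations):
        perm = rng.permutation(pooled_obs)
        z = np.abs(_stats_for_assignment(perm, sizes))
        m = z.max()
        ge_max += m >= abs_obs - _TIE_EPS
        ge_single += z >= abs_obs - _TIE_EPS
    denom = n_permutations + 1
    return SteelResult(obs, ge_max / denom, ge_single / denom,
                       "permutation", n_permutations)


def _steel_normal(obs: np.ndarray, sizes: Sequence[int]) -> SteelResult:
    """Large-sample approximation: the max of k standardized rank sums is
    referenced to an equicorrelated multivariate normal with
    rho_ij = sqrt(ni nj / ((n0+ni)(n0+nj)))."""
    from scipy.stats import multivariate_normal, norm

    k = len(obs)
    n0 = sizes[0]
    ns = np.array(sizes[1:], dtype=float)
    corr = np.eye(k)
    for i in range(k):
        for j in range(k):
            if i != j:
                corr[i, j] = math.sqrt(
                    ns[i] * ns[j] / ((n0 + ns[i]) * (n0 + ns[j]))
                )
    p_adj = np.empty(k)
    for i, z in enumerate(np.abs(obs)):
        if k == 1:
            p_adj[i] = 2 * norm.sf(z)
        else:
            inner = multivariate_normal(
                mean=np.zeros(k), cov=corr, allow_singular=True
            ).cdf(np.full(k, z), lower_limit=np.full(k, -z))
            p_adj[i] = min(1.0, 1.0 - float(inner))
    p_un = 2 * norm.sf(np.abs(obs))
    return SteelResult(obs, p_adj, np.minimum(p_un, 1.0), "normal", 0)


# ---------------------------------------------------------------------------
# Group summaries


#: Table-2-style blocks that share one printed concomitant-drug average.
_DRUG_MEAN_BLOCKS = (
    (SYNDROME,),
    ("B", "C", "D"),
    ("B&C", "B&D", "C&D"),
    (OTHER,),
)

SUMMARY_COLUMNS = ["group", "n", "tal_mean", "tal_sd", "mean_jars_drugs",
                   "steel_p"]


def summarize_groups(
    tal_records: Sequence[TalRecord],
    labels: Sequence[str],
    control_label: str = OTHER,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: Optional[int] = None,
    method: str = "auto",
) -> pd.DataFrame:
    """Per-group TAL mean/SD, pooled scored-drug averages, Steel p-values.

    ``labels`` aligns with ``tal_records``.  The control group carries
    no p-value; groups absent from the data are omitted.  SD uses the
    sample convention (ddof=1) and is reported as NaN for n=1.  The
    concomitant-drug mean is pooled across the block of groups that
    share one printed value (syndrome; single categories; paired
    categories; control).
    """
    if len(tal_records) != len(labels):
        raise ValidationError("tal_records and labels must align")
    by_group: dict[str, list[TalRecord]] = {}
    for rec, lab in zip(tal_records, labels):
        by_group.setdefault(lab, []).append(rec)
    if control_label not in by_group or not by_group[control_label]:
        raise ValidationError(f"control group {control_label!r} is empty")

    present = [g for g in GROUPS if g in by_group]
    present += [g for g in by_group if g not in GROUPS]
    test_groups = [g for g in present if g != control_label]

    control_tal = np.array([r.tal for r in by_group[control_label]], float)
    steel_p: dict[str, float] = {}
    if test_groups:
        result = steel_test(
            [np.array([r.tal for r in by_group[g]], float) for g in test_groups],
            control_tal,
            n_permutations=n_permutations,
            seed=seed,
            method=method,
        )
        steel_p = dict(zip(test_groups, result.p_adjusted))

    block_mean: dict[str, float] = {}
    for block in _DRUG_MEAN_BLOCKS:
        members = [g for g in block if g in by_group]
        if members:
            pooled = [r.n_jars_drugs for g in members for r in by_group[g]]
            m = float(np.mean(pooled))
            for g in members:
                block_mean[g] = m

    rows = []
    for g in present:
        tals = np.array([r.tal for r in by_group[g]], float)
        rows.append(
            {
                "group": g,
                "n": len(tals),
                "tal_mean": float(tals.mean()),
                "tal_sd": float(tals.std(ddof=1)) if len(tals) > 1 else float("nan"),
                "mean_jars_drugs": block_mean.get(
                    g, float(np.mean([r.n_jars_drugs for r in by_group[g]]))
                ),
                "steel_p": steel_p.get(g, float("nan")),
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
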