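"""Propensity-score estimation, 1:1 nearest-neighbor matching, balance.

The anticholinergic-related group (syndrome plus every related-ADE
subgroup) is matched 1:1 without replacement to the other-ADE control
group on the logit of a logistic-regression propensity score.  Greedy
matching proceeds over treated cases in descending score order; ties in
nearest-neighbor distance are broken by a seeded uniform draw so runs
are reproducible.  No caliper is applied by default.  Balance is
summarized by absolute standardized differences (in percent) before and
after matching, with the conventional 10% threshold.

The logistic fit is iteratively reweighted least squares (IRLS) with
step-halving, which makes the per-iteration log-likelihood observable
and provably non-decreasing; separation and degenerate labels are
flagged rather than silently fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .classify import CategoryProfile
from .errors import ConfigurationError, ValidationError
from .tables import AGE_RANK, CaseProfile

DEFAULT_BALANCE_THRESHOLD = 10.0  # percent
_SEPARATION_COEF = 30.0


@dataclass(frozen=True)
class Covariate:
    """One matching covariate.

    kind:
      * ``binary`` — 0/1 value (``sex`` → female indicator, or
        ``ind:<name>`` → indication indicator);
      * ``ordinal`` — integer rank (``age_rank`` maps age bands
        10s..90s+ to 1..9);
      * ``categorical`` — expands to indicator columns over the levels
        observed in the data, reference (first) level dropped; valid
        for the ``sex`` and ``age_band`` fields.
    """

    name: str
    kind: str = "binary"

    def __post_init__(self):
        if self.kind not in ("binary", "ordinal", "categorical"):
            raise ConfigurationError(f"unknown covariate kind {self.kind!r}")


@dataclass(frozen=True)
class CovariateSpec:
    covariates: tuple[Covariate, ...]

    def __post_init__(self):
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigurationError("covariate names must be unique")


def default_covariate_spec(
    profiles: Sequence[CaseProfile], top_k_indications: int = 3
) -> CovariateSpec:
    """Sex + ordinal age + indicators for the top-k observed indications."""
    counts: dict[str, int] = {}
    for p in profiles:
        for ind in p.indications:
            counts[ind] = counts.get(ind, 0) + 1
    top = sorted(counts, key=lambda k: (-counts[k], k))[:top_k_indications]
    covs = [Covariate("sex", "binary"), Covariate("age_rank", "ordinal")]
    covs += [Covariate(f"ind:{name}", "binary") for name in top]
    return CovariateSpec(tuple(covs))


def _raw_value(profile: CaseProfile, cov: Covariate):
    if cov.name == "sex":
        return profile.sex
    if cov.name == "age_band":
        return profile.age_band
    if cov.name == "age_rank":
        try:
            return AGE_RANK[profile.age_band]
        except KeyError:
            raise ConfigurationError(
                f"age_rank unresolvable for band {profile.age_band!r}"
            ) from None
    if cov.name.startswith("ind:"):
        return int(cov.name[4:] in profile.indications)
    raise ConfigurationError(f"unresolvable covariate {cov.name!r}")


def extract_design(
    profiles: Sequence[CaseProfile],
    classified: Sequence[CategoryProfile],
    spec: Optional[CovariateSpec] = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix (intercept first), group indicator, column names.

    The indicator is 1 for anticholinergic-related cases (syndrome or
    any subgroup) and 0 for other-ADE cases.
    """
    if spec is None:
        spec = default_covariate_spec(profiles)
    n = len(profiles)
    columns: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for cov in spec.covariates:
        raw = [_raw_value(p, cov) for p in profiles]
        if cov.kind == "categorical":
            levels = sorted(set(raw))
            for level in levels[1:]:
                columns.append(np.array([float(v == level) for v in raw]))
                names.append(f"{cov.name}[{level}]")
        elif cov.kind == "binary" and cov.name == "sex":
            columns.append(np.array([float(v == "female") for v in raw]))
            names.append("sex[female]")
        else:
            columns.append(np.asarray(raw, dtype=float))
            names.append(cov.name)
    X = np.column_stack(columns)
    y = np.array([1.0 if cp.is_related else 0.0 for cp in classified])
    return X, y, names


@dataclass
class PropensityModel:
    coefficients: np.ndarray
    converged: bool
    separated: bool
    loglik_path: list[float] = field(default_factory=list)
    column_names: Optional[list[str]] = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Propensity scores, strictly inside (0, 1)."""
        p = expit(X @ self.coefficients)
        return np.clip(p, 1e-12, 1 - 1e-12)


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    column_names: Optional[list[str]] = None,
) -> PropensityModel:
    """Maximum-likelihood logistic regression by IRLS with step-halving.

    Convergence is declared when the gradient's infinity norm drops
    below ``tol``.  Non-convergence returns the model with
    ``converged=False``; perfect separation (diverging coefficients or
    one-class labels) sets ``separated=True``.  A non-intercept column
    with zero variance raises :class:`ValidationError` (it is collinear
    with the intercept).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("design and labels have incompatible shapes")
    for j in range(1, X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            name = column_names[j] if column_names else f"column {j}"
            raise ValidationError(
                f"design column {name} is constant (collinear with intercept)"
            )
    beta = np.zeros(X.shape[1])
    model = PropensityModel(beta, False, False, [], column_names)
    if y.min() == y.max():  # degenerate: only one class present
        model.separated = True
        return model

    ll = _loglik(X, y, beta)
    model.loglik_path.append(ll)
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        grad = X.T @ (y - p)
        if np.max(np.abs(grad)) < tol:
            model.converged = True
            # a saturated fit (every case predicted at its label) means
            # the MLE lies at infinity: perfect separation
            if np.all(np.abs(y - p) < 1e-6):
                model.separated = True
                model.converged = False
            break
        w = np.clip(p * (1 - p), 1e-10, None)
        hess = X.T @ (X * w[:, None])
        try:
            delta = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(hess, grad, rcond=None)[0]
        step = 1.0
        for _ in range(40):  # step-halving keeps the log-likelihood monotone
            candidate = beta + step * delta
            if _loglik(X, y, candidate) >= ll - 1e-12:
                break
            step /= 2
        beta = beta + step * delta
        new_ll = _loglik(X, y, beta)
        assert new_ll >= ll - 1e-9, "log-likelihood decreased during IRLS"
        ll = new_ll
        model.loglik_path.append(ll)
        if np.max(np.abs(beta)) > _SEPARATION_COEF:
            model.separated = True
            break
    model.coefficients = beta
    return model


@dataclass
class MatchResult:
    pairs: list[tuple]           # (treated_id, control_id)
    pair_indices: list[tuple]    # positional indices into the input arrays
    unmatched_treated: list
    unmatched_control: list


def nn_match(
    scores: np.ndarray,
    groups: np.ndarray,
    seed: int = 0,
    ids: Optional[Sequence] = None,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbor matching on the logit of the score.

    Treated cases are visited in descending propensity order; each
    consumes the closest unconsumed control by absolute logit
    difference (ties broken by a seeded uniform draw).  Without
    replacement, so the pair count is min(#treated, #controls) and each
    id appears in at most one pair.
    """
    scores = np.clip(np.asarray(scores, dtype=float), 1e-12, 1 - 1e-12)
    groups = np.asarray(groups).astype(int)
    if ids is None:
        ids = np.arange(len(scores))
    lp = logit(scores)
    rng = np.random.default_rng(seed)

    treated_idx = np.flatnonzero(groups == 1)
    control_idx = np.flatnonzero(groups == 0)
    order = treated_idx[np.argsort(-scores[treated_idx], kind="stable")]

    control_lp = lp[control_idx]
    consumed = np.zeros(len(control_idx), dtype=bool)
    pairs, pair_positions = [], []
    unmatched_treated = []
    for t in order:
        if consumed.all():
            unmatched_treated.append(ids[t])
            continue
        dist = np.abs(control_lp - lp[t])
        dist[consumed] = np.inf
        best = dist.min()
        candidates = np.flatnonzero(dist == best)
        pick = candidates[0] if len(candidates) == 1 else rng.choice(candidates)
        consumed[pick] = True
        c = control_idx[pick]
        pairs.append((ids[t], ids[c]))
        pair_positions.append((int(t), int(c)))
    unmatched_control = [ids[c] for c, used in zip(control_idx, consumed)
                         if not used]
    return MatchResult(pairs, pair_positions, unmatched_treated,
                       unmatched_control)


def standardized_difference(
    x1: Iterable[float], x2: Iterable[float], kind: str = "continuous"
) -> float:
    """Absolute standardized difference between two samples, in percent.

    continuous: ``100 |m1-m2| / sqrt((s1^2+s2^2)/2)`` with sample
    variances; binary: proportions with variance ``p(1-p)``.  A 0/0
    ratio is defined as 0.
    """
    a = np.asarray(list(x1), dtype=float)
    b = np.asarray(list(x2), dtype=float)
    if kind == "binary":
        p1, p2 = a.mean(), b.mean()
        denom = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2)
        num = abs(p1 - p2)
    elif kind == "continuous":
        if len(a) < 2 or len(b) < 2:
            raise ValidationError(
                "continuous standardized difference needs >=2 values per group"
            )
        denom = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        num = abs(a.mean() - b.mean())
    else:
        raise ValidationError(f"unknown kind {kind!r}")
    if num == 0:
        return 0.0
    if denom == 0:
        return float("inf")
    return float(100 * num / denom)


@dataclass
class BalanceReport:
    table: pd.DataFrame  # covariate, smd_before, smd_after
    threshold: float
    balanced: bool

    @property
    def max_smd_after(self) -> float:
        return float(self.table["smd_after"].max()) if len(self.table) else 0.0


def _is_binary(col: np.ndarray) -> bool:
    return set(np.unique(col)).issubset({0.0, 1.0})


def balance_report(
    X: np.ndarray,
    y: np.ndarray,
    pair_indices: Sequence[tuple],
    column_names: Sequence[str],
    threshold: float = DEFAULT_BALANCE_THRESHOLD,
) -> BalanceReport:
    """Standardized differences before and after matching, per covariate.

    "Before" compares all treated against all controls; "after"
    compares the matched treated to their matched controls.  Balanced
    means every post-match value is strictly below the threshold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    t_all = X[y == 1]
    c_all = X[y == 0]
    t_idx = [t for t, _ in pair_indices]
    c_idx = [c for _, c in pair_indices]
    rows = []
    for j, name in enumerate(column_names):
        if name == "intercept":
            continue
        kind = "binary" if _is_binary(X[:, j]) else "continuous"
        before = standardized_difference(t_all[:, j], c_all[:, j], kind)
        if pair_indices:
            after = standardized_difference(X[t_idx, j], X[c_idx, j], kind)
        else:
            after = float("nan")
        rows.append({"covariate": name, "smd_before": before,
                     "smd_after": after})
    table = pd.DataFrame(rows, columns=["covariate", "smd_before", "smd_after"])
    balanced = bool(len(table)) and bool((table["smd_after"] < threshold).all())
    return BalanceReport(table=table, threshold=threshold, balanced=balanced)
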