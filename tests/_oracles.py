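"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid the implementation's code paths: exact
rational arithmetic for the Fisher test, explicit enumeration with a
hand-rolled mid-rank routine for the Steel test.
"""

import itertools
import math
from fractions import Fraction

import numpy as np


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Sums the exact (rational) probabilities of every table with the
    observed margins whose probability does not exceed the observed
    table's.
    """
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    denom = math.comb(n, col1)

    def prob(x: int) -> Fraction:
        return Fraction(math.comb(row1, x) * math.comb(row2, col1 - x), denom)

    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    p_obs = prob(a)
    total = sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs)
    return float(total)


def midranks(values) -> list:
    """Mid-ranks computed by explicit sorting (no scipy)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def standardized_ranksum(group, control) -> float:
    """Tie-corrected standardized rank sum of group within group+control."""
    pooled = list(control) + list(group)
    r = midranks(pooled)
    n0, n1 = len(control), len(group)
    n = n0 + n1
    w = sum(r[n0:])
    mu = n1 * (n + 1) / 2.0
    rbar = (n + 1) / 2.0
    ss = sum((x - rbar) ** 2 for x in r)
    var = n0 * n1 * ss / (n * (n - 1))
    if var <= 0:
        return 0.0
    return (w - mu) / math.sqrt(var)


def _assignments(values, sizes):
    idx = tuple(range(len(values)))

    def rec(remaining, sizes_left):
        if not sizes_left:
            yield []
            return
        for combo in itertools.combinations(remaining, sizes_left[0]):
            rest = tuple(i for i in remaining if i not in combo)
            for tail in rec(rest, sizes_left[1:]):
                yield [list(combo)] + tail

    for chosen in rec(idx, list(sizes)):
        yield [[values[i] for i in c] for c in chosen]


def steel_maxt_exact(groups, control, eps=1e-9):
    """Exhaustive max-T adjusted (and unadjusted) p-values.

    Enumerates every distinct split of the pooled observations into
    samples of the observed sizes and compares the max absolute
    standardized rank sum against each observed statistic.
    """
    values = list(control) + [x for g in groups for x in g]
    sizes = [len(control)] + [len(g) for g in groups]
    obs = [abs(standardized_ranksum(g, control)) for g in groups]
    n_total = 0
    ge_max = [0] * len(groups)
    ge_single = [0] * len(groups)
    for split in _assignments(values, sizes):
        ctrl = split[0]
        zs = [abs(standardized_ranksum(g, ctrl)) for g in split[1:]]
        m = max(zs)
        n_total += 1
        for i in range(len(groups)):
            if m >= obs[i] - eps:
                ge_max[i] += 1
            if zs[i] >= obs[i] - eps:
                ge_single[i] += 1
    return (
        np.array(ge_max) / n_total,
        np.array(ge_single) / n_total,
        n_total,
    )


def ranksum_permutation_p(group, control) -> float:
    """Two-sided exhaustive permutation p of the rank-sum statistic.

    Standardization-free: for fixed sizes the pooled rank multiset is
    the same for every relabeling, so |W - E(W)| orders relabelings
    identically to the standardized statistic.
    """
    values = list(control) + list(group)
    n0, n1 = len(control), len(group)
    mu = n1 * (n0 + n1 + 1) / 2.0
    r_all = midranks(values)
    obs = abs(sum(r_all[n0:]) - mu)
    count = total = 0
    for combo in itertools.combinations(range(len(values)), n1):
        r = midranks(values)
        w = sum(r[i] for i in combo)
        total += 1
        if abs(w - mu) >= obs - 1e-9:
            count += 1
    return count / total
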