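"""Hand-coded oracles, independent of the package implementation.

Each oracle is written the dumb, obviously-correct way (explicit loops,
exhaustive enumeration, fractions) so it can arbitrate the vectorised
implementations.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np


def brute_logrank_two_group(time, event, group) -> float:
    """Two-group log-rank chi-square via explicit O/E/V tabulation."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    levels = np.unique(group)
    assert levels.size == 2
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n_j = at_risk.sum()
        n_1j = (at_risk & (group == levels[0])).sum()
        d_j = ((time == t) & (event == 1)).sum()
        d_1j = ((time == t) & (event == 1) & (group == levels[0])).sum()
        o_minus_e += d_1j - d_j * n_1j / n_j
        if n_j > 1:
            var += d_j * (n_1j / n_j) * (1 - n_1j / n_j) * (n_j - d_j) / (n_j - 1)
    if var == 0:
        return 0.0
    return float(o_minus_e**2 / var)


def enum_hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(overlap >= k) by exhaustive enumeration of all C(N, n) draws."""
    members = set(range(K))
    total = 0
    hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(members.intersection(draw)) >= k:
            hits += 1
    return float(Fraction(hits, total))


def brute_tsp_delta(X: np.ndarray, labels: np.ndarray, i: int, j: int):
    """(delta, p1, p2) for genes i, j by explicit per-sample counting."""
    c1 = [s for s in range(X.shape[1]) if labels[s] == 1]
    c2 = [s for s in range(X.shape[1]) if labels[s] == 0]

    def freq(samples):
        f = 0.0
        for s in samples:
            if X[i, s] < X[j, s]:
                f += 1.0
            elif X[i, s] == X[j, s]:
                f += 0.5
        return f / len(samples)

    p1, p2 = freq(c1), freq(c2)
    return abs(p1 - p2), p1, p2


def brute_best_two_group_cut(score, time, event, min_count: int):
    """(best_p, best_cut) by scanning every midpoint with lifelines' log-rank."""
    from lifelines.statistics import logrank_test as ll_logrank

    u = np.unique(score)
    best = None
    for c in (u[:-1] + u[1:]) / 2:
        low = score <= c
        if low.sum() < min_count or (~low).sum() < min_count:
            continue
        res = ll_logrank(time[low], time[~low], event[low], event[~low])
        p = res.p_value
        if best is None or p < best[0]:
            best = (p, c)
    return best
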