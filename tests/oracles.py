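"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the Mann-Whitney oracle
enumerates every group-label assignment, the hypergeometric oracle enumerates
every draw, and the KS oracle simulates uniform samples directly.
"""

from itertools import combinations

import numpy as np


def u_statistic(x, y) -> float:
    return sum(1.0 if xi > yj else (0.5 if xi == yj else 0.0)
               for xi in x for yj in y)


def mwu_permutation_p(x, y) -> float:
    """Two-sided Mann-Whitney p by full enumeration of label assignments."""
    pooled = list(x) + list(y)
    n1, n2 = len(x), len(y)
    center = n1 * n2 / 2.0
    dev = abs(u_statistic(x, y) - center)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        total += 1
        if abs(u_statistic(xs, ys) - center) >= dev - 1e-12:
            hits += 1
    return hits / total


def hypergeom_enumeration_p(k: int, K: int, n: int, N: int) -> float:
    """P(overlap >= k) by exhaustive enumeration of all C(N, n) draws."""
    marked = set(range(K))
    hits = total = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def ks_dplus_mc_tail(d: float, n: int, reps: int = 10**6,
                     seed: int = 123) -> tuple[float, float]:
    """Monte-Carlo estimate of P(D+ >= d) with its standard error."""
    rng = np.random.default_rng(seed)
    u = np.sort(rng.random((reps, n)), axis=1)
    dplus = ((np.arange(1, n + 1) / n)[None, :] - u).max(axis=1)
    phat = float(np.mean(dplus >= d))
    se = float(np.sqrt(max(phat * (1 - phat), 1e-12) / reps))
    return phat, se
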