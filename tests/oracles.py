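"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive the statistics from first principles (naive
loops, exhaustive enumeration) and share no code with the package.
"""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd


def ssgsea_brute(values: pd.DataFrame, gene_set, alpha: float) -> pd.Series:
    """Naive per-position running-sum ssGSEA (genes x samples input)."""
    scores = {}
    inset = set(gene_set) & set(values.index)
    N = len(values.index)
    n_out = N - len(inset)
    for s in values.columns:
        col = values[s]
        ordered = sorted(values.index, key=lambda g: (-col[g], g))
        rank = {g: N - i for i, g in enumerate(ordered)}
        denom = sum(rank[g] ** alpha for g in inset)
        p_in = p_out = total = 0.0
        for g in ordered:
            if g in inset:
                p_in += rank[g] ** alpha / denom
            else:
                p_out += 1.0 / n_out
            total += p_in - p_out
        scores[s] = total
    return pd.Series(scores)


def mann_whitney_exact_enumeration(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group
    assignments of the pooled sample (no ties assumed)."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(group1):
        rest = list(pooled)
        g1 = []
        for v in group1:
            g1.append(v)
            rest.remove(v)
        return sum(1 for a in g1 for b in rest if a > b) + 0.5 * sum(
            1 for a in g1 for b in rest if a == b
        )

    u_obs = u_of(list(x))
    mu = n1 * (len(pooled) - n1) / 2.0
    dev = abs(u_obs - mu)
    count = total = 0
    for combo in combinations(range(len(pooled)), n1):
        u = u_of([pooled[i] for i in combo])
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            count += 1
    return count / total


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p: sum of hypergeometric probabilities of all
    tables with the observed margins no more probable than observed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def chi2_by_hand(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-squared statistic from the expected-count formula."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    total = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    return float(((obs - exp) ** 2 / exp).sum())
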