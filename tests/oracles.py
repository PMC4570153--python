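"""Independent brute-force oracles used to cross-check the implementation.

Each oracle takes a route deliberately different from the library code:
direct double loops, exact rational arithmetic, or full enumeration.  They
are only feasible on small instances, which is all the tests need.
"""

from fractions import Fraction
from math import comb, factorial

import numpy as np

MISSING = -1


def ibs_brute(values: np.ndarray) -> np.ndarray:
    """Pairwise IBS by explicit per-locus loops."""
    n = values.shape[0]
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i == j:
                out[i, j] = 1.0
                continue
            num = den = 0.0
            for k in range(values.shape[1]):
                gi, gj = values[i, k], values[j, k]
                if gi == MISSING or gj == MISSING:
                    continue
                num += (2 - abs(int(gi) - int(gj))) / 2.0
                den += 1.0
            out[i, j] = num / den if den else np.nan
    return out


def hwe_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional HWE P by direct factorial enumeration (rationals)."""
    n = n_AA + n_Aa + n_aa
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    n_common = 2 * n - n_rare
    if n_rare == 0:
        return 1.0

    def weight(h):
        hom_r = (n_rare - h) // 2
        hom_c = (n_common - h) // 2
        return Fraction(
            factorial(n) * 2 ** h, factorial(hom_r) * factorial(h) * factorial(hom_c)
        )

    hets = range(n_rare % 2, min(n_rare, n_common) + 1, 2)
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    obs = weights[n_Aa]
    p = sum(w for w in weights.values() if w <= obs)
    return float(Fraction(p, total))


def bh_brute(p: np.ndarray) -> np.ndarray:
    """BH step-up via the textbook definition, no sorting tricks."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos - 1, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def fisher_brute(n_a: int, n_b: int, overlap: int, n_universe: int) -> float:
    """Two-sided Fisher P by hypergeometric enumeration in exact rationals."""
    def hyper(k):
        return Fraction(
            comb(n_a, k) * comb(n_universe - n_a, n_b - k), comb(n_universe, n_b)
        )

    lo = max(0, n_a + n_b - n_universe)
    hi = min(n_a, n_b)
    probs = {k: hyper(k) for k in range(lo, hi + 1)}
    obs = probs[overlap]
    return float(sum(v for v in probs.values() if v <= obs))


def bray_curtis_brute(x: np.ndarray) -> np.ndarray:
    """BC(i,j) = 1 - 2 sum min / sum totals, by explicit loops."""
    n = x.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s_min = sum(min(x[i, k], x[j, k]) for k in range(x.shape[1]))
            tot = x[i].sum() + x[j].sum()
            out[i, j] = 1.0 - 2.0 * s_min / tot if tot else np.nan
    return out


def fold_brute(query, universe_ids, universe_p, cutoff):
    """Recount the fold-enrichment statistic from raw set operations."""
    m = set(query)
    g = {i for i, p in zip(universe_ids, universe_p) if p <= cutoff}
    bg = set(universe_ids) - g
    observed = len(m & g)
    if not g or not bg or not (m & bg):
        return observed, np.nan, np.nan
    rate = len(m & bg) / len(bg)
    expected = rate * len(g)
    return observed, expected, observed / expected
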