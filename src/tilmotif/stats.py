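"""Shared statistical primitives: Fisher exact tests, BH correction,
Wilcoxon rank-sum with exact small-sample enumeration.

The two-sided Fisher exact p-value follows the conventional definition: the
sum of probabilities of all tables (with the observed margins) whose
hypergeometric probability does not exceed the observed table's.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = [
    "fisher_two_sided",
    "fisher_greater_vec",
    "bh_adjust",
    "rank_sum_test",
]


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_greater_vec(a: np.ndarray, n1: int, b: np.ndarray, n2: int) -> np.ndarray:
    """Vectorised one-sided (greater) Fisher exact p for tables
    [[a, n1-a], [b, n2-b]] — the hypergeometric survival function."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    return sps.hypergeom.sf(a - 1, n1 + n2, a + b, n1)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone).

    Textbook form: adj_(i) = min_{j>=i} p_(j) * m / j, clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    scaled = p[order] * m / ranks
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney) — exact for small groups, else normal
# approximation with tie and continuity corrections.  Written in-package
# because the pooled-frequency comparisons are heavily zero-inflated: exact
# enumeration must honour ties, which rules out the tie-free exact tables.
# ---------------------------------------------------------------------------

_EXACT_MAX_COMB = 200_000


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def rank_sum_test(x, y, exact_max_comb: int = _EXACT_MAX_COMB) -> float:
    """Two-sided Wilcoxon rank-sum p-value for independent samples.

    Exact: full enumeration of rank-sum assignments (tie-aware) when
    C(n1+n2, n1) <= ``exact_max_comb`` (covers up to 10 per group);
    p = min(1, 2 * min(lower tail, upper tail)).
    Otherwise: normal approximation with tie correction and a 0.5
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("rank_sum_test requires non-empty groups")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w_obs = ranks[:n1].sum()

    if comb(n1 + n2, n1) <= exact_max_comb:
        # enumerate every assignment of n1 ranks to group x
        total = lo = hi = 0
        tol = 1e-9
        for idx in combinations(range(n1 + n2), n1):
            w = ranks[list(idx)].sum()
            total += 1
            if w <= w_obs + tol:
                lo += 1
            if w >= w_obs - tol:
                hi += 1
        return min(1.0, 2.0 * min(lo, hi) / total)

    mu = n1 * (n1 + n2 + 1) / 2.0
    # tie-corrected variance of the rank sum
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n * (n - 1)) or 1)
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(w_obs - mu) - 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
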