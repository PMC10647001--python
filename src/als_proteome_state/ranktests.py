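"""Rank-based two-sample tests shared by the differential and evaluation layers.

The exact Mann-Whitney path enumerates every assignment of the pooled
observations into the two groups (feasible for the cohort sizes here,
C(11,5)=462) using mid-ranks for ties, and doubles the smaller tail for a
two-sided p. scipy's exact method declines tied data, and the cohort tables
contain ties, so the enumeration is implemented here. Larger samples fall
back to the tie-corrected normal approximation.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy import stats

#: Largest pooled sample size for which full enumeration is used by default.
EXACT_N_MAX = 15


@lru_cache(maxsize=32)
def _combination_index(n: int, k: int) -> np.ndarray:
    """All C(n, k) index subsets as a (C, k) integer array."""
    return np.array(list(combinations(range(n), k)), dtype=np.intp)


def exact_mann_whitney(values_a, values_b) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration with mid-ranks.

    p = 2 * min(P(S <= s_obs), P(S >= s_obs)) capped at 1, where S is the
    group-A rank sum over all equally likely group assignments.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n = a.size + b.size
    if n > EXACT_N_MAX:
        return mann_whitney_p(a, b)
    ranks = stats.rankdata(np.concatenate([a, b]))
    obs = ranks[: a.size].sum()
    comb = _combination_index(n, a.size)
    sums = ranks[comb].sum(axis=1)
    lo = np.mean(sums <= obs + 1e-9)
    hi = np.mean(sums >= obs - 1e-9)
    return float(min(1.0, 2.0 * min(lo, hi)))


def mann_whitney_p(values_a, values_b, exact_n_max: int = EXACT_N_MAX) -> float:
    """Two-sided Mann-Whitney p: exact enumeration for small pooled n,
    tie-corrected normal approximation otherwise."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size + b.size <= exact_n_max:
        return exact_mann_whitney(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)
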