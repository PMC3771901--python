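"""Independent brute-force oracles used only to cross-check the
implementation; they never share code with the pipeline path."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import rankdata


def mann_whitney_exact_oracle(a, b) -> float:
    """Two-sided Mann-Whitney p by full enumeration of all C(n+m, n)
    group assignments of the pooled sample (tie-free data)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n = len(a)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = []
    for idx in combinations(range(len(pooled)), n):
        r = ranks[list(idx)].sum()
        us.append(r - n * (n + 1) / 2)
    us = np.asarray(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return float(min(p, 1.0))


def fisher_exact_oracle(k_a: int, n_a: int, k_b: int, n_b: int) -> float:
    """Two-sided Fisher p by exact-rational hypergeometric tail
    enumeration: sum of all table probabilities not exceeding the
    observed table's."""
    K, N = k_a + k_b, n_a + n_b
    def pmf(k: int) -> Fraction:
        return Fraction(comb(n_a, k) * comb(n_b, K - k), comb(N, K))
    lo, hi = max(0, K - n_b), min(K, n_a)
    obs = pmf(k_a)
    return float(sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= obs))
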