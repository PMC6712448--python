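"""Independent brute-force oracles used to validate the statistics."""

from fractions import Fraction
from math import comb

import numpy as np


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact rational enumeration over same-margin tables.

    Sums the hypergeometric point probabilities of every table whose
    probability does not exceed the observed one (with a tiny relative
    slack for ties), computed in exact rational arithmetic.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    cutoff = prob(a) * (1 + Fraction(1, 10**7))
    total = sum((p for x in range(lo, hi + 1) if (p := prob(x)) <= cutoff),
                Fraction(0))
    return float(total)


def exposures_match(a, b, weight_tol: float = 0.02, error_tol: float = 1e-6) -> bool:
    """Whether two refits agree: same kept signatures with close weights,
    or reconstruction errors tied within tolerance."""
    if abs(a.reconstruction_error - b.reconstruction_error) < error_tol:
        return True
    if set(a.weights) != set(b.weights):
        return False
    return all(abs(a.weights[k] - b.weights[k]) <= weight_tol for k in a.weights)


def mann_whitney_permutation_p(x, y, n_perm: int = 20000, seed: int = 0) -> float:
    """Two-sided permutation p-value for the Mann-Whitney U statistic.

    Uses |U - n1*n2/2| as the two-sided ordering; ranks are midranks.
    """
    from scipy.stats import rankdata

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1 = x.size
    ranks = rankdata(pooled)
    mu = n1 * y.size / 2.0

    def stat(idx_first):
        r1 = ranks[idx_first].sum()
        u = r1 - n1 * (n1 + 1) / 2.0
        return abs(u - mu)

    obs = stat(np.arange(n1))
    rng = np.random.default_rng(seed)
    count = 0
    idx = np.arange(pooled.size)
    for _ in range(n_perm):
        rng.shuffle(idx)
        if stat(idx[:n1]) >= obs - 1e-12:
            count += 1
    return count / n_perm
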