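"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own code paths: the coincidence
oracle is a double loop over time and lag, the combinatorial oracles are
explicit enumerations of labeled unit configurations, and the binomial
oracle sums exact tail probabilities from binomial coefficients.
"""

from fractions import Fraction
from itertools import combinations
from math import comb


def naive_coincidence_profile(xa, xb, max_lag, binarize=True):
    xa = [1 if v > 0 else 0 for v in xa] if binarize else list(xa)
    xb = [1 if v > 0 else 0 for v in xb] if binarize else list(xb)
    T = len(xa)
    out = []
    for lag in range(-max_lag, max_lag + 1):
        c = 0
        for t in range(T):
            u = t + lag
            if 0 <= u < T:
                c += min(xa[t], xb[u])
        out.append(c)
    return out


def enumerate_internal_pairs(n_a):
    """Unordered pairs from a set of n_a labeled units."""
    return len(list(combinations(range(n_a), 2)))


def enumerate_loop_chains(n_a, n_b):
    """Ordered A->B->A and B->A->B chains over labeled units.

    Returns (n_aba_ordered, n_bab_ordered).  The number of unordered
    loop-like unit-triples of each structure is half the ordered count
    (reversing the chain swaps first and last unit).
    """
    A = [("A", i) for i in range(n_a)]
    B = [("B", i) for i in range(n_b)]
    aba = [(a1, b, a2) for a1 in A for b in B for a2 in A if a2 != a1]
    bab = [(b1, a, b2) for b1 in B for a in A for b2 in B if b2 != b1]
    return len(aba), len(bab)


def exact_binom_symmetric_two_sided(k, n):
    """Two-sided p at p0 = 0.5 by direct tail summation (symmetric null:
    both two-sided rules coincide)."""
    lo = min(k, n - k)
    tail = sum(Fraction(comb(n, i), 2**n) for i in range(0, lo + 1))
    other = sum(Fraction(comb(n, i), 2**n) for i in range(n - lo, n + 1))
    return float(min(Fraction(1), tail + other))


def exact_binom_minlike_two_sided(k, n, p0):
    """Minimum-likelihood two-sided p: sum of P(X = i) over all i whose
    probability does not exceed P(X = k), with a relative tolerance for
    floating-point ties."""
    from scipy.stats import binom

    pk = binom.pmf(k, n, p0)
    total = sum(
        binom.pmf(i, n, p0)
        for i in range(n + 1)
        if binom.pmf(i, n, p0) <= pk * (1 + 1e-9)
    )
    return min(1.0, float(total))
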