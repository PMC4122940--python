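"""Exact two-sided tests used throughout the package.

Both tests use the *minimum-likelihood* definition of the two-sided
p-value: the p-value is the total probability of all outcomes whose
point probability does not exceed that of the observed outcome.  All
arithmetic is carried out on exact integers (``math.comb``), so ties
between point probabilities are resolved exactly rather than through a
floating-point epsilon; only the final ratio is converted to a float.

This matters because read depths in the analyses are capped at a few
hundred, where exact enumeration is cheap, and because downstream
significance cutoffs (e.g. 5e-7) sit deep in the tail where relative
floating-point error in tie comparisons would be the dominant source of
irreproducibility.
"""

from __future__ import annotations

from math import comb

__all__ = [
    "fisher_exact_two_sided",
    "fisher_p_values_for_margins",
    "binom_two_sided_half",
]


def fisher_p_values_for_margins(r1: int, r2: int, c1: int) -> dict[int, float]:
    """Two-sided Fisher p-values for every table with the given margins.

    Returns a mapping from the top-left cell ``a`` to its p-value, for a
    2x2 table ``[[a, r1-a], [c1-a, r2-(c1-a)]]``.  Enumerating the whole
    support at once lets callers score many tables sharing margins in a
    single pass.
    """
    n = r1 + r2
    if c1 < 0 or c1 > n:
        raise ValueError("column margin outside table total")
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    weights = [comb(r1, a) * comb(r2, c1 - a) for a in range(lo, hi + 1)]
    total = comb(n, c1)
    out: dict[int, float] = {}
    for i, w_obs in enumerate(weights):
        s = sum(w for w in weights if w <= w_obs)
        out[lo + i] = s / total
    return out


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums the hypergeometric probabilities of all tables with the same
    margins whose probability is <= that of the observed table (exact
    integer comparison).  p lies in (0, 1].
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0:
        raise ValueError("zero row margin: table is untestable")
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    weights = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    return sum(w for w in weights if w <= w_obs) / comb(r1 + r2, c1)


def binom_two_sided_half(k: int, n: int) -> float:
    """Two-sided exact binomial p for k successes in n trials at p=0.5.

    With a symmetric null the minimum-likelihood definition reduces to
    summing C(n, i) over all i with C(n, i) <= C(n, k), divided by 2^n.
    """
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if n == 0:
        raise ValueError("n must be positive")
    w_obs = comb(n, k)
    s = sum(w for w in (comb(n, i) for i in range(n + 1)) if w <= w_obs)
    return s / (1 << n)
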