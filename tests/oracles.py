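"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the implementation paths they check: the
alignment oracle is a plain three-state Gotoh dynamic program, the
Poisson oracle sums probability masses directly, and the Fisher oracle
enumerates hypergeometric tables in exact rational arithmetic.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from scipy import stats


def sw_score_oracle(
    read: str,
    ref: str,
    match: float = 4.0,
    mismatch: float = -2.0,
    gap_open: float = -6.0,
    gap_extend: float = -1.0,
) -> float:
    """Full-matrix affine-gap local alignment score (Gotoh, three states).

    Reference 'N' matches any base at +match.  A gap of length g costs
    gap_open + (g - 1) * gap_extend.
    """
    n, m = len(ref), len(read)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in reference row
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in read column
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (ref[i - 1] == "N" or ref[i - 1] == read[j - 1]) else mismatch
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def poisson_tail_oracle(k: int, lam: float) -> float:
    """P(X >= k) by direct summation of Poisson masses."""
    if lam == 0:
        return 0.0
    hi = int(max(k + 400, lam + 40 * np.sqrt(lam) + 400))
    j = np.arange(k, hi)
    return float(stats.poisson.pmf(j, lam).sum())


def fisher_oracle(table) -> Fraction:
    """Two-sided Fisher p by exact rational enumeration over all tables
    with the observed margins (probability <= observed is summed)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return Fraction(1)
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if p_k <= p_obs:
            total += p_k
    return total


def levenshtein_oracle(a: str, b: str) -> int:
    """Plain edit distance."""
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, y in enumerate(b, 1):
            cur[j] = min(prev[j - 1] + (x != y), prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return prev[-1]
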