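"""Independent brute-force oracles used by the test suite.

Everything here is computed with exact integer arithmetic (math.comb on
Python's arbitrary-precision ints), entirely independent of the package's
log-space implementation.
"""

from __future__ import annotations

import math
from math import comb

_LOG10_2 = math.log10(2.0)


def log10_bigint(x: int) -> float:
    """log10 of a positive integer of any size."""
    if x <= 0:
        raise ValueError("log10 of non-positive integer")
    shift = x.bit_length() - 500
    if shift <= 0:
        return math.log10(x)
    return math.log10(x >> shift) + shift * _LOG10_2


def exact_log10_tail(k: int, K: int, n: int, N: int,
                     tail: str = "upper") -> float:
    """Exact log10 hypergeometric tail via integer PMF summation."""
    lo_support = max(0, n - (N - K))
    hi_support = min(n, K)
    if tail == "upper":
        lo, hi = k, hi_support
    else:
        lo, hi = lo_support, k
    numerator = sum(comb(K, i) * comb(N - K, n - i)
                    for i in range(lo, hi + 1))
    denominator = comb(N, n)
    if numerator == 0:
        raise ValueError("empty tail")
    if numerator == denominator:
        return 0.0
    return log10_bigint(numerator) - log10_bigint(denominator)


def exact_hgt(k: int, K: int, n: int, N: int) -> float:
    """Exact signed HGT score (same sign convention: ties go upper)."""
    if k * N >= K * n:
        return -exact_log10_tail(k, K, n, N, "upper")
    return exact_log10_tail(k, K, n, N, "lower")


def brute_force_aspecificity(f2: float, fmean: float, freqs, window: int,
                             span: int, start_position: int = 3) -> float:
    """Direct enumeration of every sliding window (NaN-aware)."""
    ref = 0.9 * f2 if f2 > fmean else 1.1 * f2
    region = list(freqs[start_position - 1:span])
    best = 0.0
    for start in range(0, len(region) - window + 1):
        chunk = region[start:start + window]
        valid = [f for f in chunk if f == f]  # drop NaN
        if not valid:
            continue
        if f2 > fmean:
            hits = sum(1 for f in valid if f > ref)
        else:
            hits = sum(1 for f in valid if f <= ref)
        best = max(best, 100.0 * hits / len(valid))
    return best
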