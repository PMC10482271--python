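"""Signed hypergeometric bias scores computed entirely in log space.

The HGT score is the significance measure used throughout the package:
``|HGT| = |log10(p)|`` for a one-tailed hypergeometric test, with a negative
sign when the subset frequency falls below the reference frequency.  Position-2
biases in a proteome routinely reach p-values far below the smallest positive
double (e.g. 1e-268 for serine in yeast), so tail probabilities are
accumulated as log-probabilities (log-sum-exp over the exact log PMF) and
never materialised on the linear scale.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln

__all__ = ["log_hypergeom_tail", "hgt_score"]

_LN10 = math.log(10.0)

# growing cache of log-factorials: _LOG_FACT[i] = ln(i!)
_LOG_FACT = gammaln(np.arange(1024, dtype=np.float64) + 1.0)


def _log_fact(limit: int) -> np.ndarray:
    """Log-factorial table covering 0..limit (cached, grows on demand)."""
    global _LOG_FACT
    if limit >= len(_LOG_FACT):
        size = max(limit + 1, 2 * len(_LOG_FACT))
        _LOG_FACT = gammaln(np.arange(size, dtype=np.float64) + 1.0)
    return _LOG_FACT


def _check_params(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (max(0, n - (N - K)) <= k <= min(n, K)):
        raise ValueError(
            f"k={k} outside support [{max(0, n - (N - K))}, {min(n, K)}] "
            f"for K={K}, n={n}, N={N}"
        )


def _log_pmf_range(lo: int, hi: int, K: int, n: int, N: int) -> np.ndarray:
    """Natural-log hypergeometric PMF for all counts in [lo, hi]."""
    lf = _log_fact(N)
    i = np.arange(lo, hi + 1)
    return (
        lf[K] - lf[i] - lf[K - i]
        + lf[N - K] - lf[n - i] - lf[N - K - n + i]
        + lf[n] + lf[N - n] - lf[N]
    )


def log_hypergeom_tail(k: int, K: int, n: int, N: int,
                       tail: str = "upper") -> float:
    """log10 tail probability of the hypergeometric distribution.

    For X ~ Hypergeometric(N, K, n) — ``n`` draws without replacement from a
    pool of ``N`` items of which ``K`` are successes — returns
    ``log10 P(X >= k)`` (``tail="upper"``) or ``log10 P(X <= k)``
    (``tail="lower"``).  The summation runs over log PMF terms, so tail
    probabilities as small as 1e-300000 keep full relative precision on the
    log scale.
    """
    _check_params(k, K, n, N)
    support_lo = max(0, n - (N - K))
    support_hi = min(n, K)
    if tail == "upper":
        lo, hi = k, support_hi
    elif tail == "lower":
        lo, hi = support_lo, k
    else:
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")
    if lo == support_lo and hi == support_hi:
        return 0.0  # whole support: p = 1 exactly
    terms = _log_pmf_range(lo, hi, K, n, N)
    m = terms.max()
    log_p = m + math.log(np.exp(terms - m).sum())
    # rounding can push the sum a hair above 0 (p > 1); clamp
    return min(float(log_p) / _LN10, 0.0)


def hgt_score(k: int, K: int, n: int, N: int) -> float:
    """Signed hypergeometric bias score for an observed subset count.

    ``k`` of ``n`` subset members carry the feature versus ``K`` of ``N`` in
    the reference pool.  Over-representation (``k/n >= K/N``, ties included)
    is scored with the upper tail and a positive sign; under-representation
    with the lower tail and a negative sign.  The magnitude is
    ``-log10(tail p)``, so a score of 4 corresponds to p = 1e-4.
    """
    if n == 0:
        raise ValueError("subset size n must be positive (F_obs undefined)")
    _check_params(k, K, n, N)
    if k * N >= K * n:  # F_obs >= F_ref, exact integer comparison
        return -log_hypergeom_tail(k, K, n, N, tail="upper") + 0.0
    return log_hypergeom_tail(k, K, n, N, tail="lower")
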