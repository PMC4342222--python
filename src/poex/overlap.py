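"""Hypergeometric enrichment testing between gene sets.

Used to ask whether an observed overlap between, say, candidate PEGs and the
endosperm-specific gene set is larger than sampling from the expression
universe would produce.  The upper-tail probability P(X >= k) is computed by
log-space summation of the hypergeometric pmf (log-gamma binomial
coefficients; a universe of ~15,000 genes overflows naive factorials), with a
tiny-universe enumeration oracle for independent verification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import UsageError


@dataclass(frozen=True)
class OverlapTest:
    """Result of a one-sided (enrichment) hypergeometric overlap test."""

    k: int  # observed overlap
    n: int  # query-set size
    K: int  # reference-set size
    N: int  # universe size
    expected: float  # n * K / N
    p_upper: float  # P(X >= k)


def _log_binom(a: int, b) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeometric_overlap(k: int, n: int, K: int, N: int) -> OverlapTest:
    """Exact upper-tail hypergeometric test of an overlap of ``k`` genes.

    ``n`` genes are drawn from a universe of ``N`` containing ``K`` reference
    genes; ``p_upper = sum_{i>=k} C(K,i) C(N-K,n-i) / C(N,n)``, evaluated in
    log space.  Bounds: ``0 <= k <= min(n, K)`` and ``n, K <= N``.
    """
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if int(v) != v or v < 0:
            raise UsageError(f"{name} must be a non-negative integer")
    k, n, K, N = int(k), int(n), int(K), int(N)
    if n > N or K > N or k > min(n, K):
        raise UsageError("bounds violated: need k <= min(n, K) and n, K <= N")
    expected = n * K / N
    lower_support = max(0, n + K - N)
    if k <= lower_support:
        p_upper = 1.0
    else:
        i = np.arange(k, min(n, K) + 1)
        log_terms = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
        p_upper = float(np.exp(logsumexp(log_terms)))
        p_upper = min(p_upper, 1.0)
    return OverlapTest(k=k, n=n, K=K, N=N, expected=expected, p_upper=p_upper)


def enumerate_oracle(k: int, n: int, K: int, N: int) -> float:
    """Exact tail probability by enumerating every n-subset of the universe.

    Independent of the log-space route; restricted to ``N <= 25``.  The
    impossible event ``k > min(n, K)`` returns 0 with a warning rather than an
    error, so grid comparisons can sweep k freely.
    """
    if N > 25:
        raise UsageError("enumeration oracle is restricted to N <= 25")
    if n > N or K > N or min(k, n, K, N) < 0:
        raise UsageError("invalid enumeration bounds")
    if k > min(n, K):
        warnings.warn("impossible event (k > min(n, K)); p = 0", stacklevel=2)
        return 0.0
    universe = range(N)
    successes = set(range(K))  # which labels are "reference" genes
    hits = sum(1 for draw in combinations(universe, n) if len(successes.intersection(draw)) >= k)
    return hits / comb(N, n)
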