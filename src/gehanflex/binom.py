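"""Exact binomial tail machinery and Clopper-Pearson interval utilities.

Every design construction and testing step in this package reduces to exact
binomial probability statements.  This module is the single numeric layer the
rest of the package builds on: binomial mass/tail probabilities, exact
(Clopper-Pearson) confidence limits and their lengths, and the standard
normal quantile.  Tail probabilities are evaluated through scipy's
regularised incomplete-beta machinery rather than naive summation, so they
remain accurate for trial counts well beyond anything a phase II design
needs.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special, stats

#: Absolute tolerance for comparisons of exact tail probabilities against
#: design thresholds.  Chosen so that matching a conditional error value to
#: an attainable binomial tail is exact in practice.
TOL = 1e-12


def _check_count_pair(s: int, m: int) -> None:
    if m < 0 or int(m) != m:
        raise ValueError(f"trial count must be a non-negative integer, got {m}")
    if int(s) != s or s < 0 or s > m:
        raise ValueError(f"success count must lie in 0..{m}, got {s}")


def _check_probability(pi: float, name: str = "pi") -> None:
    if not 0.0 <= pi <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {pi}")


def binom_pmf(s: int, m: int, pi: float) -> float:
    """Exact binomial mass P(S = s) for S ~ Bin(m, pi)."""
    _check_count_pair(s, m)
    _check_probability(pi)
    return float(stats.binom.pmf(s, m, pi))


def binom_cdf(s: int, m: int, pi: float) -> float:
    """Exact binomial CDF P(S <= s) for S ~ Bin(m, pi)."""
    _check_count_pair(s, m)
    _check_probability(pi)
    return float(stats.binom.cdf(s, m, pi))


def upper_tail(k: int, m: int, pi: float) -> float:
    """P(S >= k) for S ~ Bin(m, pi), for any integer k.

    Returns 1 for k <= 0 and 0 for k > m, which is the convention used to
    encode stage-one stopping decisions as stage-two rejection cutoffs.
    """
    _check_probability(pi)
    if k <= 0:
        return 1.0
    if k > m:
        return 0.0
    return float(stats.binom.sf(k - 1, m, pi))


def pmf_vector(m: int, pi: float) -> np.ndarray:
    """Vector of binomial masses b(s | m, pi) for s = 0..m."""
    _check_probability(pi)
    return stats.binom.pmf(np.arange(m + 1), m, pi)


def normal_quantile(p: float) -> float:
    """Inverse standard normal CDF."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"normal quantile requires p in (0, 1), got {p}")
    return float(special.ndtri(p))


def cp_interval(s: int, n: int, level_alpha: float) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided confidence interval for a proportion.

    The lower limit is the level_alpha/2 Beta quantile with shapes
    (s, n - s + 1), taken as 0 when s = 0; the upper limit is the
    1 - level_alpha/2 Beta quantile with shapes (s + 1, n - s), taken as 1
    when s = n.
    """
    _check_count_pair(s, n)
    if not 0.0 < level_alpha < 1.0:
        raise ValueError(f"level_alpha must lie in (0, 1), got {level_alpha}")
    lo = 0.0 if s == 0 else float(stats.beta.ppf(level_alpha / 2, s, n - s + 1))
    hi = 1.0 if s == n else float(stats.beta.ppf(1 - level_alpha / 2, s + 1, n - s))
    return lo, hi


def cp_length(s: int, n: int, level_alpha: float) -> float:
    """Length of the exact confidence interval, with the boundary convention.

    For s in {0, n} the length is 1 - (level_alpha/2)^(1/n), i.e. the length
    of the one-sided exact interval; otherwise it is the difference of the
    two Beta quantiles.
    """
    if n <= 0:
        raise ValueError("interval length requires n >= 1")
    _check_count_pair(s, n)
    if not 0.0 < level_alpha < 1.0:
        raise ValueError(f"level_alpha must lie in (0, 1), got {level_alpha}")
    if s == 0 or s == n:
        return 1.0 - (level_alpha / 2) ** (1.0 / n)
    lo, hi = cp_interval(s, n, level_alpha)
    return hi - lo


def cp_length_many(s: np.ndarray, n: int, level_alpha: float) -> np.ndarray:
    """Vectorised ``cp_length`` over an array of success counts at fixed n."""
    if n <= 0:
        raise ValueError("interval length requires n >= 1")
    s = np.asarray(s, dtype=np.int64)
    if s.size and (s.min() < 0 or s.max() > n):
        raise ValueError(f"success counts must lie in 0..{n}")
    out = np.empty(s.shape, dtype=float)
    boundary = (s == 0) | (s == n)
    out[boundary] = 1.0 - (level_alpha / 2) ** (1.0 / n)
    si = s[~boundary]
    if si.size:
        lo = stats.beta.ppf(level_alpha / 2, si, n - si + 1)
        hi = stats.beta.ppf(1 - level_alpha / 2, si + 1, n - si)
        out[~boundary] = hi - lo
    return out


def cp_coverage(n: int, pi: float, level_alpha: float) -> float:
    """Exact coverage probability of the two-sided interval at a true rate.

    Sums the binomial mass over the outcomes whose interval contains pi.
    Used to verify the interval's defining guarantee (coverage at least
    1 - level_alpha everywhere).
    """
    _check_probability(pi)
    pmf = pmf_vector(n, pi)
    total = 0.0
    for s in range(n + 1):
        lo, hi = cp_interval(s, n, level_alpha)
        if lo - TOL <= pi <= hi + TOL:
            total += pmf[s]
    return float(total)


def log_pmf(s: int, m: int, pi: float) -> float:
    """Log of the binomial mass, for numerically delicate cross-checks."""
    _check_count_pair(s, m)
    if pi in (0.0, 1.0):
        return math.log(binom_pmf(s, m, pi))
    return (
        math.lgamma(m + 1)
        - math.lgamma(s + 1)
        - math.lgamma(m - s + 1)
        + s * math.log(pi)
        + (m - s) * math.log1p(-pi)
    )
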