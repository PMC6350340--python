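"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — direct products, summations,
bisection and exhaustive enumeration — and shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

import itertools
import math


def pmf(s: int, m: int, pi: float) -> float:
    """Binomial mass by direct product."""
    return math.comb(m, s) * pi**s * (1.0 - pi) ** (m - s)


def cdf(s: int, m: int, pi: float) -> float:
    """Binomial CDF by direct summation."""
    return sum(pmf(t, m, pi) for t in range(s + 1))


def tail(k: int, m: int, pi: float) -> float:
    """P(S >= k) by direct summation, with the package's 0/1 saturation."""
    if k <= 0:
        return 1.0
    if k > m:
        return 0.0
    return sum(pmf(t, m, pi) for t in range(k, m + 1))


def normal_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def normal_quantile_bisect(p: float, tol: float = 1e-12) -> float:
    """Inverse normal CDF by bisection on erf."""
    lo, hi = -10.0, 10.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if normal_cdf(mid) < p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def cp_bounds_bisect(s: int, n: int, level_alpha: float) -> tuple[float, float]:
    """Clopper-Pearson limits by root-finding on the exact binomial tails.

    The lower limit solves P(S >= s | n, p) = level_alpha/2; the upper
    limit solves P(S <= s | n, p) = level_alpha/2.
    """

    def bisect(f, target):
        lo, hi = 0.0, 1.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(mid) < target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    lower = 0.0 if s == 0 else bisect(lambda p: tail(s, n, p), level_alpha / 2)
    upper = 1.0 if s == n else bisect(lambda p: 1 - cdf(s, n, p), 1 - level_alpha / 2)
    return lower, upper


def dcef_candidates(n2: int, pi0: float) -> list[float]:
    """Allowed conditional error values for one continuing/stopping stage."""
    if n2 == 0:
        return [0.0, 1.0]
    return [tail(k, n2, pi0) for k in range(n2 + 1, 0, -1)][1:]  # interior only


def enumerate_monotone_dcefs(schedule: tuple[int, ...], pi0: float):
    """Yield every valid DCEF value vector (monotone, D(0) = 0)."""
    per_stage = []
    for s1, n2 in enumerate(schedule):
        if s1 == 0:
            per_stage.append([0.0])
        elif n2 == 0:
            per_stage.append([0.0, 1.0])
        else:
            per_stage.append([tail(k, n2, pi0) for k in range(n2, 0, -1)])
    for combo in itertools.product(*per_stage):
        if all(combo[i] >= combo[i - 1] - 1e-12 for i in range(1, len(combo))):
            yield combo


def best_power_by_enumeration(
    schedule: tuple[int, ...], pi0: float, pi1: float, alpha: float
):
    """(max power, its type-I error) over all valid DCEFs, or None if none fit.

    For a value vector D the type-I error is sum D(s1) b(s1 | n1, pi0); the
    power maps each D(s1) back to its rejection region and sums the exact
    rejection mass at pi1.
    """
    n1 = len(schedule) - 1
    b0 = [pmf(s1, n1, pi0) for s1 in range(n1 + 1)]
    b1 = [pmf(s1, n1, pi1) for s1 in range(n1 + 1)]
    best = None
    for combo in enumerate_monotone_dcefs(schedule, pi0):
        a = sum(D * p for D, p in zip(combo, b0))
        if a > alpha + 1e-12:
            continue
        power = 0.0
        for s1, D in enumerate(combo):
            n2 = schedule[s1]
            if n2 == 0:
                power += D * b1[s1]
            else:
                k = min(
                    k for k in range(1, n2 + 1) if tail(k, n2, pi0) <= D + 1e-12
                )
                power += tail(k, n2, pi1) * b1[s1]
        if best is None or power > best[0] + 1e-12:
            best = (power, a)
    return best


def min_type_one_relaxed(schedule: tuple[int, ...], pi0: float) -> float:
    """Minimal type-I error ignoring monotonicity among interior values.

    Stop stages that follow any scheduled stage-two sampling are still
    forced to reject (their futility option would violate monotonicity in
    any completion), matching the most-conservative assignment's class.
    """
    n1 = len(schedule) - 1
    b0 = [pmf(s1, n1, pi0) for s1 in range(n1 + 1)]
    total = 0.0
    seen_positive = False
    for s1 in range(1, n1 + 1):
        n2 = schedule[s1]
        if n2 > 0:
            seen_positive = True
            total += tail(n2, n2, pi0) * b0[s1]
        elif seen_positive:
            total += b0[s1]
    return total


def simon_enumeration(pi0, pi1, alpha, beta, n_max):
    """Exhaustive Simon design search by direct double summation."""
    best_opt = None
    best_mm = None
    for n1 in range(1, n_max):
        for n2 in range(1, n_max - n1 + 1):
            for f1 in range(n1):
                cont = sum(pmf(s1, n1, pi0) for s1 in range(f1 + 1, n1 + 1))
                ess0 = n1 + n2 * cont
                for f2 in range(f1, n1 + n2):
                    t1 = sum(
                        pmf(s1, n1, pi0) * tail(f2 - s1 + 1, n2, pi0)
                        for s1 in range(f1 + 1, n1 + 1)
                    )
                    if t1 > alpha + 1e-12:
                        continue
                    pow1 = sum(
                        pmf(s1, n1, pi1) * tail(f2 - s1 + 1, n2, pi1)
                        for s1 in range(f1 + 1, n1 + 1)
                    )
                    if 1 - pow1 > beta + 1e-12:
                        continue
                    cand_opt = (ess0, n1 + n2, n1, f1, f2, n2)
                    cand_mm = (n1 + n2, ess0, n1, f1, f2, n2)
                    if best_opt is None or cand_opt < best_opt:
                        best_opt = cand_opt
                    if best_mm is None or cand_mm < best_mm:
                        best_mm = cand_mm
    return best_opt, best_mm


def count_monotone_prefixes(schedule: tuple[int, ...], pi0: float) -> int:
    """Nodes of the unpruned search tree: monotone partial assignments.

    Counts every partial value vector (D(0), ..., D(s)) for s >= 1 that is
    monotone and stage-wise admissible; this is the space an enumeration
    without type-I/power bounds would visit.
    """
    n1 = len(schedule) - 1
    per_stage = []
    for s1 in range(1, n1 + 1):
        n2 = schedule[s1]
        if n2 == 0:
            per_stage.append([0.0, 1.0])
        else:
            per_stage.append([tail(k, n2, pi0) for k in range(n2, 0, -1)])

    total = 0

    def recurse(depth: int, d_prev: float) -> None:
        nonlocal total
        if depth > n1:
            return
        for D in per_stage[depth - 1]:
            if D < d_prev - 1e-12:
                continue
            total += 1
            recurse(depth + 1, D)

    recurse(1, 0.0)
    return total
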