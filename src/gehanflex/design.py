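"""Construction of Gehan-type two-stage designs.

Gehan's single-arm phase II design screens for activity in stage one (stop
for futility if no responses are seen among n1 patients) and then sizes
stage two, adaptively in the stage-one response count s1, so that the
response rate can be estimated to a prescribed precision at the end of the
trial.  This module implements:

* the stage-one sample size rule: the smallest n1 whose probability of zero
  responses under the interesting rate pi1 is at most beta1;
* two interim estimators of the response rate used to drive stage-two
  sizing: Gehan's Wald-style upper confidence limit ("original") and an
  exact-interval alternative that picks, among the Clopper-Pearson limits
  and the MLE, the candidate closest to 1/2 ("conservative");
* three stage-two sizing rules: f_G (bound the estimated standard error by
  gamma), f_L (bound the worst-case exact confidence interval length), and
  f_EL (bound the expected exact interval length under the interim
  estimate), each returning the minimal n2 satisfying its constraint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .binom import (
    TOL,
    cp_length_many,
    normal_quantile,
    pmf_vector,
)
from scipy import stats

METHODS = ("original", "conservative")
RULES = ("f_G", "f_L", "f_EL")


class CappedSearchError(RuntimeError):
    """Raised when a stage-two size search exhausts its cap."""

    def __init__(self, cap: int, message: str):
        super().__init__(message)
        self.cap = cap


@dataclass(frozen=True)
class DesignParams:
    """Full parameterisation of a Gehan-type design.

    Attributes
    ----------
    pi0 : float
        Null (uninteresting) response rate; the hypothesis test is of
        H0: pi = pi0.
    pi1 : float
        Interesting response rate warranting further study; pi0 < pi1.
    alpha : float
        Type-I error budget for the embedded hypothesis test.
    beta1 : float
        Stage-one rejection probability: n1 is the smallest size for which
        the chance of seeing no responses when pi >= pi1 is at most beta1.
    gamma : float
        Precision bound for stage-two sizing (maximal estimated standard
        error under f_G; half-length target, via 2*gamma*z_{1-alpha/2},
        under f_L and f_EL).
    coverage : float
        Coverage of the interim confidence interval used by the estimators
        (default 0.75, i.e. 12.5% in each tail).
    method : str
        Interim estimator: "original" or "conservative".
    rule : str
        Stage-two sizing rule: "f_G", "f_L" or "f_EL".
    n2_cap : int
        Upper bound for the linear stage-two size searches.
    """

    pi0: float
    pi1: float
    alpha: float
    beta1: float
    gamma: float
    coverage: float = 0.75
    method: str = "original"
    rule: str = "f_G"
    n2_cap: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.pi0 < self.pi1:
            raise ValueError(f"need 0 < pi0 < pi1, got pi0={self.pi0}, pi1={self.pi1}")
        if not self.pi1 <= 1.0:
            raise ValueError(f"pi1 must lie in (0, 1], got {self.pi1}")
        for name in ("alpha", "beta1"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in (0, 1], got {self.gamma}")
        if not 0.0 < self.coverage < 1.0:
            raise ValueError(f"coverage must lie in (0, 1), got {self.coverage}")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}, got {self.rule!r}")
        if self.n2_cap < 0:
            raise ValueError("n2_cap must be non-negative")


@dataclass(frozen=True)
class GehanDesign:
    """A stage-one size together with the stage-two size schedule.

    ``n2_schedule[s1]`` is the stage-two sample size prescribed after
    observing s1 responses among the first n1 patients; the trial always
    stops for futility at s1 = 0, so ``n2_schedule[0] = 0``.
    """

    n1: int
    n2_schedule: tuple[int, ...]
    params: DesignParams | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.n1 < 1:
            raise ValueError("n1 must be a positive integer")
        if len(self.n2_schedule) != self.n1 + 1:
            raise ValueError(
                f"schedule must have n1+1={self.n1 + 1} entries, "
                f"got {len(self.n2_schedule)}"
            )
        if self.n2_schedule[0] != 0:
            raise ValueError("n2_schedule[0] must be 0 (futility stop at s1 = 0)")
        if any(n2 < 0 for n2 in self.n2_schedule):
            raise ValueError("stage-two sizes must be non-negative")

    @property
    def max_n(self) -> int:
        """Maximal possible total sample size n1 + max n2(s1)."""
        return self.n1 + max(self.n2_schedule)


def stage_one_size(pi1: float, beta1: float) -> int:
    """Smallest positive n1 with (1 - pi1)^n1 <= beta1."""
    if not 0.0 < pi1 <= 1.0:
        raise ValueError(f"pi1 must lie in (0, 1], got {pi1}")
    if not 0.0 < beta1 < 1.0:
        raise ValueError(f"beta1 must lie in (0, 1), got {beta1}")
    if pi1 == 1.0:
        return 1
    # Closed-form guess, then correct against the tolerance-aware predicate.
    n1 = max(1, math.ceil(math.log(beta1) / math.log1p(-pi1) - TOL))
    while (1.0 - pi1) ** n1 > beta1 + TOL:
        n1 += 1
    while n1 > 1 and (1.0 - pi1) ** (n1 - 1) <= beta1 + TOL:
        n1 -= 1
    return n1


def interim_original(s1: int, n1: int, coverage: float = 0.75) -> float:
    """Gehan's Wald-style interim estimate: the upper confidence limit.

    Returns min{ s1/n1 + z * sqrt(s1 (n1-s1) / n1^3), 1 } where z is the
    normal quantile at 1 - (1-coverage)/2.
    """
    if n1 < 1 or not 0 <= s1 <= n1:
        raise ValueError(f"need 0 <= s1 <= n1 with n1 >= 1, got s1={s1}, n1={n1}")
    z = normal_quantile(1.0 - (1.0 - coverage) / 2.0)
    se = math.sqrt(s1 * (n1 - s1) / n1**3)
    return min(s1 / n1 + z * se, 1.0)


def _conservative_candidates(s1: int, n1: int, coverage: float) -> list[float]:
    """Candidate interim estimates for the exact-interval method.

    The candidates are the lower and upper Clopper-Pearson limits at the
    interim coverage, plus the MLE s1/n1, sorted by distance to 1/2 (ties
    broken towards the smaller estimate for determinism; callers that size
    stage two evaluate all tied candidates and keep the larger n2).
    """
    tail = (1.0 - coverage) / 2.0
    lo = float(stats.beta.ppf(tail, s1, n1 - s1 + 1))
    hi = float(stats.beta.ppf(1.0 - tail, s1 + 1, n1 - s1))
    cands = [lo, hi, s1 / n1]
    cands.sort(key=lambda x: (abs(x - 0.5), x))
    best = abs(cands[0] - 0.5)
    return [x for x in cands if abs(x - 0.5) <= best + TOL]


def interim_conservative(s1: int, n1: int, coverage: float = 0.75) -> float:
    """Exact-interval interim estimate: the candidate closest to 1/2.

    For s1 = n1 the estimate is ((1-coverage)/2)^(1/n1), the lower limit of
    the one-sided exact interval.  For 1 <= s1 <= n1 - 1 it is the member of
    {lower CP limit, upper CP limit, s1/n1} minimising |estimate - 1/2|.
    Undefined at s1 = 0 (the trial has already stopped for futility).
    """
    if n1 < 1 or not 0 <= s1 <= n1:
        raise ValueError(f"need 0 <= s1 <= n1 with n1 >= 1, got s1={s1}, n1={n1}")
    if s1 == 0:
        raise ValueError("the conservative interim estimator is undefined at s1 = 0")
    if s1 == n1:
        return ((1.0 - coverage) / 2.0) ** (1.0 / n1)
    return _conservative_candidates(s1, n1, coverage)[0]


def n2_fG(pi_hat: float, n1: int, gamma: float) -> int:
    """Gehan's rule: smallest n2 with pi_hat(1-pi_hat)/(n1+n2) <= gamma^2."""
    if not 0.0 <= pi_hat <= 1.0:
        raise ValueError(f"pi_hat must lie in [0, 1], got {pi_hat}")
    if not 0.0 < gamma <= 1.0:
        raise ValueError(f"gamma must lie in (0, 1], got {gamma}")
    var = pi_hat * (1.0 - pi_hat)

    def ok(n2: int) -> bool:
        return var <= gamma * gamma * (n1 + n2) + TOL

    n2 = max(0, math.ceil(var / (gamma * gamma) - n1 - TOL))
    while not ok(n2):
        n2 += 1
    while n2 > 0 and ok(n2 - 1):
        n2 -= 1
    return n2


def n2_fL(s1: int, n1: int, gamma: float, alpha: float, cap: int = 10_000) -> int:
    """Worst-case-length rule: bound the exact interval length for every s2.

    Returns the smallest n2 >= 0 such that
    0.5 / z_{1-alpha/2} * max_{s2} L(s1+s2, n1+n2) <= gamma, with L the
    exact (Clopper-Pearson) interval length at level alpha.  The target
    corresponds to the length 2*gamma*z_{1-alpha/2} of the Wald interval
    Gehan's precision requirement implicitly aims for.
    """
    if not 1 <= s1 <= n1:
        raise ValueError(f"need 1 <= s1 <= n1, got s1={s1}, n1={n1}")
    z = normal_quantile(1.0 - alpha / 2.0)
    limit = 2.0 * gamma * z
    for n2 in range(cap + 1):
        n = n1 + n2
        s = np.arange(s1, s1 + n2 + 1)
        if float(cp_length_many(s, n, alpha).max()) <= limit + TOL:
            return n2
    raise CappedSearchError(
        cap, f"f_L: no n2 <= {cap} meets the length bound for s1={s1}, n1={n1}"
    )


def n2_fEL(
    pi_hat: float,
    s1: int,
    n1: int,
    gamma: float,
    alpha: float,
    cap: int = 10_000,
) -> int:
    """Expected-length rule: bound the expected exact interval length.

    Returns the smallest n2 >= 0 such that
    0.5 / z_{1-alpha/2} * sum_{s2} b(s2 | n2, pi_hat) L(s1+s2, n1+n2) <= gamma.
    """
    if not 1 <= s1 <= n1:
        raise ValueError(f"need 1 <= s1 <= n1, got s1={s1}, n1={n1}")
    if not 0.0 <= pi_hat <= 1.0:
        raise ValueError(f"pi_hat must lie in [0, 1], got {pi_hat}")
    z = normal_quantile(1.0 - alpha / 2.0)
    limit = 2.0 * gamma * z
    for n2 in range(cap + 1):
        n = n1 + n2
        s = np.arange(s1, s1 + n2 + 1)
        lengths = cp_length_many(s, n, alpha)
        weights = pmf_vector(n2, pi_hat)
        if float(weights @ lengths) <= limit + TOL:
            return n2
    raise CappedSearchError(
        cap, f"f_EL: no n2 <= {cap} meets the length bound for s1={s1}, n1={n1}"
    )


def _interim_estimates(params: DesignParams, s1: int, n1: int) -> list[float]:
    if params.method == "original":
        return [interim_original(s1, n1, params.coverage)]
    return _conservative_candidates(s1, n1, params.coverage) if s1 < n1 else [
        interim_conservative(s1, n1, params.coverage)
    ]


def build_gehan_design(params: DesignParams) -> GehanDesign:
    """Construct the full design: n1 and the stage-two size schedule.

    ``n2_schedule[0]`` is fixed to 0 by the futility-stop rule; for each
    s1 >= 1 the configured rule and estimator produce the minimal n2.  When
    the conservative estimator has candidates tied in distance to 1/2, the
    candidate yielding the larger (more conservative) n2 is used.
    """
    n1 = stage_one_size(params.pi1, params.beta1)
    schedule = [0]
    for s1 in range(1, n1 + 1):
        if params.rule == "f_L":
            n2 = n2_fL(s1, n1, params.gamma, params.alpha, params.n2_cap)
        else:
            estimates = _interim_estimates(params, s1, n1)
            if params.rule == "f_G":
                n2 = max(n2_fG(p, n1, params.gamma) for p in estimates)
            else:
                n2 = max(
                    n2_fEL(p, s1, n1, params.gamma, params.alpha, params.n2_cap)
                    for p in estimates
                )
        schedule.append(n2)
    return GehanDesign(n1=n1, n2_schedule=tuple(schedule), params=params)
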