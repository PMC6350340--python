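"""Discrete conditional error functions (DCEFs) and exact error rates.

A DCEF attaches to each stage-one outcome s1 a conditional significance
level D(s1) in [0, 1] for the stage-two test of H0: pi = pi0.  D(s1) = 0
encodes a futility stop, D(s1) = 1 an efficacy stop, and interior values
mean the trial continues and rejects H0 when the stage-two p-value
P(S2 >= s2 | n2(s1), pi0) is at most D(s1).

Because the stage-two p-value is a binomial upper tail, only finitely many
values of D(s1) are attainable, and every interior D(s1) corresponds to an
integer rejection cutoff k(s1): reject at stage two iff s2 >= k(s1).  DCEFs
are therefore stored as integer cutoffs, with the D values derived, so that
equality against attainable thresholds is exact rather than float-matched.

Cutoff conventions (uniform across stage-two sizes n2):

* reject at stage two iff s2 >= k;
* k = 0 means certain rejection (D = 1, efficacy stop when n2 = 0);
* k = n2 + 1 means certain acceptance (D = 0, futility stop when n2 = 0).

The restrictions on a valid DCEF are:

1. D is monotone in s1 (non-strict by default; see ``validate_dcef``);
2. every interior D(s1) is an attainable stage-two tail probability;
3. D(s1) in {0, 1} when n2(s1) = 0, with D(0) = 0;
4. D(s1) not in {0, 1} when n2(s1) > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

from .binom import TOL, pmf_vector, upper_tail
from .design import GehanDesign


def attainable_thresholds(n2: int, pi0: float) -> tuple[float, ...]:
    """All values a conditional error level can take for a stage-two size.

    For n2 > 0 these are {0} plus the upper-tail probabilities
    P(S2 >= k | n2, pi0) for k = n2, ..., 1, plus {1}, in increasing order.
    For n2 = 0 only {0, 1} are available (stop decisions).
    """
    if n2 < 0:
        raise ValueError("n2 must be non-negative")
    if n2 == 0:
        return (0.0, 1.0)
    tails = [upper_tail(k, n2, pi0) for k in range(n2, 0, -1)]
    return (0.0, *tails, 1.0)


def rejection_cutoff(D: float, n2: int, pi0: float) -> int:
    """Minimal integer k with P(S2 >= k | n2, pi0) <= D.

    Rejection at stage two then occurs iff s2 >= k.  If D lies below the
    smallest positive tail, returns n2 + 1 (never reject).
    """
    if not 0.0 < D < 1.0:
        raise ValueError(f"conditional error level must lie in (0, 1), got {D}")
    if n2 <= 0:
        raise ValueError("rejection_cutoff requires a positive stage-two size")
    # Relative tolerance: attainable tails can be far below any fixed
    # absolute tolerance (e.g. pi0^n2), and matching must stay exact there.
    for k in range(1, n2 + 2):
        if upper_tail(k, n2, pi0) <= D * (1.0 + 1e-9) + 1e-300:
            return k
    raise AssertionError("unreachable: upper_tail(n2 + 1) is 0")


@dataclass(frozen=True)
class DCEF:
    """A discrete conditional error function bound to a design.

    Parameters
    ----------
    design : GehanDesign
        The design whose stage-two schedule the DCEF attaches to.
    pi0 : float
        Null response rate defining the stage-two p-values.
    cutoffs : tuple of int
        Rejection cutoffs k(s1) for s1 = 0..n1 under the conventions above.
    """

    design: GehanDesign
    pi0: float
    cutoffs: tuple[int, ...]

    def __post_init__(self) -> None:
        n1 = self.design.n1
        if len(self.cutoffs) != n1 + 1:
            raise ValueError(
                f"cutoffs must have n1+1={n1 + 1} entries, got {len(self.cutoffs)}"
            )
        for s1, k in enumerate(self.cutoffs):
            n2 = self.design.n2_schedule[s1]
            if not 0 <= k <= n2 + 1:
                raise ValueError(
                    f"cutoff k({s1})={k} outside 0..{n2 + 1} for n2={n2}"
                )

    @cached_property
    def values(self) -> tuple[float, ...]:
        """Conditional error values D(s1) derived from the stored cutoffs."""
        return tuple(
            upper_tail(k, n2, self.pi0)
            for k, n2 in zip(self.cutoffs, self.design.n2_schedule)
        )


def dcef_from_values(
    design: GehanDesign, pi0: float, values: tuple[float, ...] | list[float]
) -> DCEF:
    """Build a DCEF from conditional error values, matching attainable tails.

    Interior values are mapped to the minimal cutoff whose tail probability
    does not exceed them, so a rounded D value maps onto the attainable
    threshold at or just below it (the conservative direction).
    """
    if len(values) != design.n1 + 1:
        raise ValueError("values must have one entry per stage-one outcome")
    cutoffs = []
    for s1, D in enumerate(values):
        n2 = design.n2_schedule[s1]
        if D >= 1.0 - TOL:
            k = 0
        elif D <= TOL:
            k = n2 + 1
        elif n2 == 0:
            raise ValueError(
                f"D({s1})={D} is interior but n2({s1})=0 admits only 0 or 1"
            )
        else:
            k = rejection_cutoff(D, n2, pi0)
        cutoffs.append(k)
    return DCEF(design=design, pi0=pi0, cutoffs=tuple(cutoffs))


@dataclass(frozen=True)
class DCEFValidation:
    """Verdict of ``validate_dcef``: validity flag plus violation labels."""

    valid: bool
    violations: tuple[str, ...]


def validate_dcef(dcef: DCEF, strict: bool = False) -> DCEFValidation:
    """Check a DCEF against the four structural restrictions.

    Monotonicity (restriction 1) is checked non-strictly by default, since
    optimal designs routinely contain ties among adjacent conditional error
    values; pass ``strict=True`` to require strictly increasing values.
    Returns a verdict listing every violated restriction rather than
    raising.
    """
    violations: list[str] = []
    values = dcef.values
    sched = dcef.design.n2_schedule
    if values[0] > TOL:
        violations.append("R3: D(0) must be 0 (futility stop at s1 = 0)")
    for s1 in range(1, len(values)):
        if values[s1] < values[s1 - 1] - TOL:
            violations.append(f"R1: D({s1}) < D({s1 - 1})")
        elif strict and values[s1] <= values[s1 - 1] + TOL:
            violations.append(f"R1 (strict): D({s1}) = D({s1 - 1})")
    for s1, (D, n2, k) in enumerate(zip(values, sched, dcef.cutoffs)):
        interior = TOL < D < 1.0 - TOL
        if n2 == 0 and interior:
            violations.append(f"R3: D({s1}) must be 0 or 1 when n2({s1}) = 0")
        if n2 > 0 and not interior:
            violations.append(f"R4: D({s1}) must lie in (0, 1) when n2({s1}) > 0")
        if n2 > 0 and interior:
            # Attainability (restriction 2) is structural for cutoff-backed
            # DCEFs; re-derive as a guard against mismatched pi0.
            if abs(upper_tail(k, n2, dcef.pi0) - D) > TOL:
                violations.append(f"R2: D({s1}) is not an attainable tail")
    return DCEFValidation(valid=not violations, violations=tuple(violations))


def type_one_error(dcef: DCEF, pi0: float | None = None) -> float:
    """Exact type-I error: sum of D(s1) b(s1 | n1, pi0) over s1."""
    if pi0 is None:
        pi0 = dcef.pi0
    pmf = pmf_vector(dcef.design.n1, pi0)
    return float(sum(D * p for D, p in zip(dcef.values, pmf)))


def rejection_probability(dcef: DCEF, pi: float) -> float:
    """Exact probability of rejecting H0 at a true response rate pi.

    Sums, over stage-one outcomes, the probability that the stage-two
    p-value falls at or below D(s1), which for cutoff k(s1) is the upper
    tail P(S2 >= k(s1) | n2(s1), pi); stop decisions enter as 0/1 terms.
    """
    pmf = pmf_vector(dcef.design.n1, pi)
    total = 0.0
    for s1, (k, n2) in enumerate(zip(dcef.cutoffs, dcef.design.n2_schedule)):
        total += upper_tail(k, n2, pi) * pmf[s1]
    return float(total)


def most_conservative_dcef(design: GehanDesign, pi0: float) -> DCEF:
    """The least-rejecting assignment compatible with the stop structure.

    Takes D(s1) = 0 while no stage-two sampling has yet been scheduled,
    the smallest attainable interior value (all stage-two successes
    required) when n2(s1) > 0, and D(s1) = 1 at stop outcomes that follow a
    continuation region (monotonicity forbids a futility stop there).  Its
    type-I error is the minimal rejection probability over all assignments
    respecting restrictions 2-4 and the forced stop decisions; if that
    minimum exceeds alpha, no valid DCEF can control the test.  Note the
    interior values here need not themselves be monotone, so the result can
    fail restriction 1; it serves as the feasibility lower bound.
    """
    cutoffs = [1]  # D(0) = 0
    seen_positive = False
    for s1 in range(1, design.n1 + 1):
        n2 = design.n2_schedule[s1]
        if n2 > 0:
            seen_positive = True
            cutoffs.append(n2)  # D = P(S2 = n2 | n2, pi0) = pi0^n2
        elif seen_positive:
            cutoffs.append(0)  # forced efficacy stop, D = 1
        else:
            cutoffs.append(1)  # still in the initial futility run, D = 0
    return DCEF(design=design, pi0=pi0, cutoffs=tuple(cutoffs))
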