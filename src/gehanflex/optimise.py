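"""Branch-and-bound search for the power-maximising DCEF.

Given a Gehan design (whose stage-two sizes are fixed by the precision
requirement, not by the test), the free quantities are the conditional
error values D(s1).  This module finds the assignment maximising the
rejection probability at the interesting rate pi1 subject to exact type-I
error control at pi0 and the structural restrictions on a DCEF.

The search branches over stage-one outcomes in ascending order, assigning
each stage its rejection cutoff; candidates at each stage are iterated in
decreasing order of conditional error, so strong incumbents appear early.
Two exact bounds prune subtrees:

* a type-I lower bound — the error already spent plus the current level
  carried over all remaining stage-one mass (conditional error values are
  monotone, so no completion can spend less);
* a power upper bound — the power already accrued plus all remaining
  stage-one mass at pi1 (no completion can reject more often).

Because candidates are visited in decreasing order of conditional error,
both bounds are monotone along a stage's candidate list, allowing whole
tails of the list to be skipped or the loop exited outright.

Ties in power are broken towards smaller type-I error, then towards the
lexicographically smallest cutoff vector, making the returned DCEF
deterministic.  (Equal-power optima can genuinely differ in their D values,
so reported designs are compared on power and error rates, not on
individual conditional error values.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .binom import TOL, pmf_vector, upper_tail
from .dcef import DCEF, most_conservative_dcef, type_one_error
from .design import GehanDesign
from .oc import ess

logger = logging.getLogger(__name__)


class InfeasibleDesignError(ValueError):
    """No DCEF controls the type-I error for this design.

    Carries ``min_type_one``, the minimal achievable type-I error (infinity
    if the schedule admits no valid DCEF at all).
    """

    def __init__(self, min_type_one: float, message: str):
        super().__init__(message)
        self.min_type_one = min_type_one


@dataclass(frozen=True)
class SearchNode:
    """A partial DCEF assignment during the search.

    ``depth`` is the last stage-one outcome assigned, ``partial_cutoffs``
    the cutoffs for s1 = 0..depth, and ``alpha_spent`` / ``power_accrued``
    the exact running sums of the type-I error and power terms.
    """

    depth: int
    partial_cutoffs: tuple[int, ...]
    alpha_spent: float
    power_accrued: float


def alpha_lower_bound(node: SearchNode, design: GehanDesign, pi0: float) -> float:
    """Minimal type-I error over all completions of a partial assignment.

    Equals the error spent through the node's depth plus the current
    conditional error level carried over the remaining stage-one mass
    (monotonicity forbids any smaller level later).
    """
    d_here = upper_tail(
        node.partial_cutoffs[-1], design.n2_schedule[node.depth], pi0
    )
    pmf = pmf_vector(design.n1, pi0)
    return node.alpha_spent + d_here * float(pmf[node.depth + 1 :].sum())


def power_upper_bound(node: SearchNode, design: GehanDesign, pi1: float) -> float:
    """Maximal power over all completions of a partial assignment.

    Accrued power plus all remaining stage-one mass at pi1 (attained only if
    every remaining outcome could reject with certainty).
    """
    pmf = pmf_vector(design.n1, pi1)
    return node.power_accrued + float(pmf[node.depth + 1 :].sum())


@dataclass(frozen=True)
class OptimisedDesign:
    """A Gehan design with its optimal DCEF and exact operating characteristics."""

    design: GehanDesign
    dcef: DCEF
    type_one: float
    power: float
    ess_null: float
    ess_alt: float
    nodes_expanded: int


def _minimal_monotone_cutoffs(
    design: GehanDesign, pi0: float
) -> tuple[int, ...] | None:
    """Greedy least-rejecting valid DCEF: smallest D(s1) >= D(s1-1) per stage.

    Per-stage minimisation is globally optimal here because a smaller level
    at one stage never shrinks the candidate set at later stages.  Returns
    None when some stage has no candidate at or above the running level
    (then no valid DCEF exists for this schedule).
    """
    cutoffs = [1]
    d_prev = 0.0
    for s1 in range(1, design.n1 + 1):
        n2 = design.n2_schedule[s1]
        if n2 == 0:
            if d_prev <= TOL:
                cutoffs.append(1)  # continue the futility run, D = 0
            else:
                cutoffs.append(0)  # forced efficacy stop, D = 1
                d_prev = 1.0
            continue
        chosen = None
        for k in range(n2, 0, -1):  # tails increase as k decreases
            if upper_tail(k, n2, pi0) >= d_prev - TOL:
                chosen = k
                break
        if chosen is None:
            return None
        d_prev = upper_tail(chosen, n2, pi0)
        cutoffs.append(chosen)
    return tuple(cutoffs)


def optimise_dcef(
    design: GehanDesign,
    pi0: float,
    pi1: float,
    alpha: float,
) -> OptimisedDesign:
    """Find the valid DCEF maximising power at pi1 under type-I control at pi0.

    Raises ``InfeasibleDesignError`` (carrying the minimal achievable
    type-I error) when even the least-rejecting valid DCEF exceeds alpha.
    """
    n1 = design.n1
    sched = design.n2_schedule
    b0 = pmf_vector(n1, pi0)
    b1 = pmf_vector(n1, pi1)
    # rem[s] = sum of stage-one mass strictly beyond outcome s - 1.
    rem0 = [0.0] * (n1 + 2)
    rem1 = [0.0] * (n1 + 2)
    for s in range(n1, -1, -1):
        rem0[s] = rem0[s + 1] + float(b0[s])
        rem1[s] = rem1[s + 1] + float(b1[s])

    # Feasibility and incumbent: the least-rejecting valid DCEF.
    greedy = _minimal_monotone_cutoffs(design, pi0)
    if greedy is None:
        raise InfeasibleDesignError(
            float("inf"),
            "the stage-two schedule admits no valid DCEF "
            "(a continuation region follows a forced efficacy stop)",
        )
    greedy_dcef = DCEF(design=design, pi0=pi0, cutoffs=greedy)
    min_type_one = type_one_error(greedy_dcef)
    if min_type_one > alpha + TOL:
        raise InfeasibleDesignError(
            min_type_one,
            f"minimal achievable type-I error {min_type_one:.6f} exceeds "
            f"alpha={alpha}; no DCEF controls the test for this schedule",
        )

    # Per-stage candidate lists (D, cutoff, power term), descending in D.
    candidates: list[list[tuple[float, int, float]]] = []
    for s1 in range(1, n1 + 1):
        n2 = sched[s1]
        if n2 == 0:
            stage = [(1.0, 0, float(b1[s1])), (0.0, 1, 0.0)]
        else:
            stage = [
                (
                    upper_tail(k, n2, pi0),
                    k,
                    upper_tail(k, n2, pi1) * float(b1[s1]),
                )
                for k in range(1, n2 + 2)
            ]
            # k = n2 + 1 gives D = 0, excluded for continuation stages (R4).
            stage = [c for c in stage if c[0] > TOL]
        candidates.append(stage)

    best = {
        "power": sum(
            upper_tail(k, sched[s1], pi1) * float(b1[s1])
            for s1, k in enumerate(greedy)
        ),
        "alpha": min_type_one,
        "cutoffs": greedy,
    }
    nodes = 0

    def dfs(
        s1: int, d_prev: float, alpha_spent: float, power_accrued: float,
        cutoffs: tuple[int, ...],
    ) -> None:
        nonlocal nodes
        if s1 > n1:
            better = power_accrued > best["power"] + TOL
            tied = abs(power_accrued - best["power"]) <= TOL
            if not better and tied:
                if alpha_spent < best["alpha"] - TOL:
                    better = True
                elif abs(alpha_spent - best["alpha"]) <= TOL:
                    better = cutoffs < best["cutoffs"]
            if better:
                best["power"] = power_accrued
                best["alpha"] = alpha_spent
                best["cutoffs"] = cutoffs
            return
        for D, k, pow_term in candidates[s1 - 1]:
            if D < d_prev - TOL:
                break  # candidates descend; monotonicity fails from here on
            spent = alpha_spent + D * float(b0[s1])
            if spent + D * rem0[s1 + 1] > alpha + TOL:
                continue  # type-I bound; smaller D may still be feasible
            if power_accrued + pow_term + rem1[s1 + 1] < best["power"] - TOL:
                break  # power bound; smaller D only gets worse
            nodes += 1
            dfs(s1 + 1, D, spent, power_accrued + pow_term, cutoffs + (k,))

    dfs(1, 0.0, 0.0, 0.0, (1,))

    dcef = DCEF(design=design, pi0=pi0, cutoffs=best["cutoffs"])
    from .dcef import rejection_probability

    type_one = type_one_error(dcef)
    power = rejection_probability(dcef, pi1)
    logger.debug(
        "branch-and-bound: %d nodes expanded, power %.6f, type-I %.6f",
        nodes, power, type_one,
    )
    return OptimisedDesign(
        design=design,
        dcef=dcef,
        type_one=type_one,
        power=power,
        ess_null=ess(design, pi0),
        ess_alt=ess(design, pi1),
        nodes_expanded=nodes,
    )


def feasibility_lower_bound(design: GehanDesign, pi0: float) -> float:
    """Rejection probability at pi0 of the most conservative assignment.

    A lower bound on the type-I error of any DCEF respecting the attainable
    thresholds and forced stop decisions; if it exceeds alpha the design is
    certainly infeasible.
    """
    return type_one_error(most_conservative_dcef(design, pi0))
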