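"""Exact search for Simon's two-stage null-optimal and minimax designs.

Simon's designs are the standard group-sequential comparators for a
single-arm phase II trial: enrol n1 patients, continue to a further n2 iff
s1 > f1, and reject H0: pi = pi0 iff s1 + s2 > f2.  (This strict-inequality
decision convention differs by an index shift from tables that use
"reject iff s >= r"; the boundaries reported here follow the strict
convention throughout.)

Among all (f1, n1, f2, n2) whose exact type-I and type-II error rates meet
(alpha, beta), the null-optimal design minimises the expected sample size
under pi0, and the minimax design minimises the maximal sample size
n1 + n2, with ties broken by ESS(pi0) and then by smaller n1.  The search
is exhaustive over a vectorised (f1, f2) grid per (n1, n2) pair, with rows
pruned by the necessary condition that the stage-one futility probability
at pi1 not already exceed beta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .binom import TOL, pmf_vector, upper_tail
from .design import GehanDesign


@dataclass(frozen=True)
class SimonDesign:
    """A Simon two-stage design with its exact operating characteristics."""

    f1: int
    n1: int
    f2: int
    n2: int
    type1: float
    type2: float
    ess_null: float

    @property
    def max_n(self) -> int:
        return self.n1 + self.n2

    def as_gehan_schedule(self) -> GehanDesign:
        """Express the design as a stage-two size schedule.

        The schedule is 0 for s1 <= f1 and the constant n2 above, so the
        operating-characteristic machinery for adaptive schedules applies
        uniformly to Simon designs.
        """
        sched = tuple(
            0 if s1 <= self.f1 else self.n2 for s1 in range(self.n1 + 1)
        )
        return GehanDesign(n1=self.n1, n2_schedule=sched, params=None)


class SimonSearchError(RuntimeError):
    """No feasible Simon design exists within the sample-size cap."""


def _rejection_probability(
    f1: int, n1: int, f2: int, n2: int, pi: float
) -> float:
    """P(s1 > f1 and s1 + s2 > f2) by direct double-binomial summation."""
    pmf1 = pmf_vector(n1, pi)
    total = 0.0
    for s1 in range(f1 + 1, n1 + 1):
        total += pmf1[s1] * upper_tail(f2 - s1 + 1, n2, pi)
    return float(total)


def simon_error_rates(
    design: SimonDesign, pi0: float, pi1: float
) -> tuple[float, float]:
    """Exact (type-I, type-II) error rates of a Simon design."""
    if not 0 <= design.f1 < design.n1:
        raise ValueError("need 0 <= f1 < n1")
    if design.f2 < design.f1:
        raise ValueError("need f2 >= f1")
    t1 = _rejection_probability(design.f1, design.n1, design.f2, design.n2, pi0)
    t2 = 1.0 - _rejection_probability(design.f1, design.n1, design.f2, design.n2, pi1)
    return t1, t2


def _feasible_cells(
    n1: int, n2: int, pi0: float, pi1: float, alpha: float, beta: float
):
    """Vectorised feasibility grid over (f1, f2) for fixed stage sizes.

    Returns (f1_values, per-f1 minimal feasible f2, ESS at pi0 per f1), or
    None when no cell is feasible.
    """
    N = n1 + n2
    b0 = pmf_vector(n1, pi0)
    b1 = pmf_vector(n1, pi1)
    cdf1 = np.cumsum(b1)
    # Necessary: power <= P(S1 > f1 | pi1), so B(f1 | n1, pi1) <= beta.
    f1_ok = np.flatnonzero(cdf1[:n1] <= beta + TOL)
    if f1_ok.size == 0:
        return None
    # T[j + n1] = P(S2 > j | n2, pi) for j = -n1..N-1 (sf saturates at 1/0).
    j = np.arange(-n1, N)
    t0 = stats.binom.sf(j, n2, pi0)
    t1 = stats.binom.sf(j, n2, pi1)
    idx = np.arange(N)[None, :] - np.arange(n1 + 1)[:, None] + n1
    W0 = b0[:, None] * t0[idx]  # (s1, f2) rejection mass at pi0
    W1 = b1[:, None] * t1[idx]
    # S[s1, f2] = sum over s1' >= s1; reject prob for bound f1 is S[f1+1].
    S0 = np.cumsum(W0[::-1], axis=0)[::-1]
    S1 = np.cumsum(W1[::-1], axis=0)[::-1]
    reject0 = S0[f1_ok + 1, :]  # rows: candidate f1; cols: f2 = 0..N-1
    reject1 = S1[f1_ok + 1, :]
    feasible = (reject0 <= alpha + TOL) & (reject1 >= 1.0 - beta - TOL)
    # f2 >= f1 by construction of the decision rule.
    col = np.arange(N)[None, :]
    feasible &= col >= f1_ok[:, None]
    rows = feasible.any(axis=1)
    if not rows.any():
        return None
    f1_vals = f1_ok[rows]
    f2_min = feasible[rows].argmax(axis=1)
    ess0 = n1 + n2 * (1.0 - np.cumsum(b0)[f1_vals])
    return f1_vals, f2_min, ess0


def simon_search(
    pi0: float,
    pi1: float,
    alpha: float,
    beta: float,
    n_max: int = 100,
) -> tuple[SimonDesign, SimonDesign]:
    """Exhaustive search for the null-optimal and minimax Simon designs.

    Considers n1 = 1..n_max-1, n2 = 1..n_max-n1, f1 = 0..n1-1 and
    f2 = f1..n1+n2-1.  Raises ``SimonSearchError`` when no design within
    n_max patients meets the error constraints.
    """
    if not 0.0 < pi0 < pi1 <= 1.0:
        raise ValueError("need 0 < pi0 < pi1 <= 1")
    best_opt: tuple | None = None  # (ess, N, n1, f1, f2, n2)
    best_mm: tuple | None = None  # (N, ess, n1, f1, f2, n2)
    for n1 in range(1, n_max):
        for n2 in range(1, n_max - n1 + 1):
            N = n1 + n2
            # ESS >= n1 for any design; skip pairs that can improve neither
            # objective.
            if (
                best_opt is not None
                and n1 >= best_opt[0] - TOL
                and best_mm is not None
                and N > best_mm[0]
            ):
                continue
            cells = _feasible_cells(n1, n2, pi0, pi1, alpha, beta)
            if cells is None:
                continue
            f1_vals, f2_min, ess0 = cells
            for f1, f2, e in zip(f1_vals, f2_min, ess0):
                cand_opt = (float(e), N, n1, int(f1), int(f2), n2)
                if best_opt is None or cand_opt < best_opt:
                    best_opt = cand_opt
                cand_mm = (N, float(e), n1, int(f1), int(f2), n2)
                if best_mm is None or cand_mm < best_mm:
                    best_mm = cand_mm
    if best_opt is None:
        raise SimonSearchError(
            f"no feasible Simon design with at most {n_max} patients for "
            f"pi0={pi0}, pi1={pi1}, alpha={alpha}, beta={beta}"
        )

    def realise(ess0: float, n1: int, f1: int, f2: int, n2: int) -> SimonDesign:
        probe = SimonDesign(
            f1=f1, n1=n1, f2=f2, n2=n2, type1=0.0, type2=0.0, ess_null=0.0
        )
        t1, t2 = simon_error_rates(probe, pi0, pi1)
        return SimonDesign(
            f1=f1, n1=n1, f2=f2, n2=n2, type1=t1, type2=t2, ess_null=ess0
        )

    e, N, n1, f1, f2, n2 = best_opt
    null_optimal = realise(e, n1, f1, f2, n2)
    N, e, n1, f1, f2, n2 = best_mm
    minimax = realise(e, n1, f1, f2, n2)
    return null_optimal, minimax
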