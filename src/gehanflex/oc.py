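"""Exact operating characteristics of two-stage designs.

All quantities are exhaustive sums over trial outcomes — no simulation:

* ``ess``: expected total sample size as a function of the true rate;
* ``futility_boundary``: the largest stage-one count at which the trial
  still stops without rejecting (D = 0);
* ``el_given_s1``: expected final confidence-interval length conditional on
  the stage-one outcome;
* ``cel``: expected final interval length conditional on continuing past
  stage one.

Interval lengths enter through a pluggable ``length_fn(s, n)`` contract so
that adjusted intervals for adaptive designs can be swapped in; the default
is the pooled exact (Clopper-Pearson) length on the combined data.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .binom import TOL, cp_length_many, pmf_vector
from .design import GehanDesign
from .dcef import DCEF

LengthFn = Callable[[int, int], float]


def ess(design: GehanDesign, pi: float) -> float:
    """Expected sample size n1 + sum_s1 n2(s1) b(s1 | n1, pi)."""
    pmf = pmf_vector(design.n1, pi)
    extra = float(np.asarray(design.n2_schedule, dtype=float) @ pmf)
    return design.n1 + extra


def futility_boundary(dcef: DCEF) -> int:
    """Largest s1 with D(s1) = 0; exists because D(0) = 0."""
    f1 = 0
    for s1, D in enumerate(dcef.values):
        if D <= TOL:
            f1 = s1
    return f1


def _default_length_fn(level_alpha: float) -> LengthFn:
    def length(s: int, n: int) -> float:
        return float(cp_length_many(np.asarray([s]), n, level_alpha)[0])

    return length


def _stage_lengths(
    design: GehanDesign, s1: int, level_alpha: float, length_fn: LengthFn | None
) -> np.ndarray:
    n2 = design.n2_schedule[s1]
    n = design.n1 + n2
    if length_fn is None:
        return cp_length_many(np.arange(s1, s1 + n2 + 1), n, level_alpha)
    return np.asarray([length_fn(s1 + s2, n) for s2 in range(n2 + 1)], dtype=float)


def el_given_s1(
    design: GehanDesign,
    pi: float,
    s1: int,
    level_alpha: float,
    length_fn: LengthFn | None = None,
) -> float:
    """Expected final interval length conditional on S1 = s1.

    Averages length_fn(s1 + s2, n1 + n2(s1)) over the stage-two outcome
    distribution Bin(n2(s1), pi).
    """
    if not 1 <= s1 <= design.n1:
        raise ValueError(f"need 1 <= s1 <= n1, got s1={s1}")
    lengths = _stage_lengths(design, s1, level_alpha, length_fn)
    weights = pmf_vector(design.n2_schedule[s1], pi)
    return float(weights @ lengths)


def cel(
    design: GehanDesign,
    dcef: DCEF,
    pi: float,
    level_alpha: float,
    length_fn: LengthFn | None = None,
) -> float:
    """Conditional expected length given the trial continues past stage one.

    Probability-weighted average of ``el_given_s1`` over s1 above the
    futility boundary f1 of the DCEF, normalised by P(S1 > f1).  Both the
    numerator and the denominator run over s1 = f1+1..n1, matching the
    conditioning event.
    """
    f1 = futility_boundary(dcef)
    pmf = pmf_vector(design.n1, pi)
    den = float(pmf[f1 + 1 :].sum())
    if den <= TOL:
        raise ValueError(
            f"P(S1 > f1) is zero at pi={pi}; the conditional length is undefined"
        )
    num = sum(
        el_given_s1(design, pi, s1, level_alpha, length_fn) * pmf[s1]
        for s1 in range(f1 + 1, design.n1 + 1)
    )
    return float(num / den)


def default_grid(step: float = 0.001) -> np.ndarray:
    """Open-interval response-rate grid for curve export.

    The endpoints pi in {0, 1} are excluded: there the trial outcome is
    deterministic and conditional quantities degenerate.
    """
    return np.arange(step, 1.0, step)


def ess_curve(design: GehanDesign, grid: Sequence[float] | None = None) -> pd.DataFrame:
    """ESS(pi) on a grid, as a two-column (pi, value) frame."""
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    return pd.DataFrame({"pi": grid, "value": [ess(design, p) for p in grid]})


def power_curve(dcef: DCEF, grid: Sequence[float] | None = None) -> pd.DataFrame:
    """Rejection probability P(pi) on a grid."""
    from .dcef import rejection_probability

    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    return pd.DataFrame(
        {"pi": grid, "value": [rejection_probability(dcef, p) for p in grid]}
    )


def cel_curve(
    design: GehanDesign,
    dcef: DCEF,
    level_alpha: float,
    grid: Sequence[float] | None = None,
    length_fn: LengthFn | None = None,
) -> pd.DataFrame:
    """CEL(pi) on a grid (endpoints excluded)."""
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    return pd.DataFrame(
        {
            "pi": grid,
            "value": [cel(design, dcef, p, level_alpha, length_fn) for p in grid],
        }
    )
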