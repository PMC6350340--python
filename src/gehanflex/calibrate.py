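"""Power calibration of the precision parameter gamma.

Gehan's design takes the precision bound gamma as given, which can leave
the embedded test badly under- or over-powered.  Treating gamma as a free
parameter, this module scans a descending grid for the maximal gamma whose
power-optimised design reaches a target power at pi1.

The scan is descending and returns the first qualifying gamma because the
power of the optimal test need not be monotone in gamma (the design is
discrete), while the expected sample size decreases monotonically as gamma
grows — so the largest qualifying gamma is the cheapest.  Many grid points
induce the same integer stage-two schedule, so optimisation results are
memoised by schedule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .design import DesignParams, build_gehan_design
from .optimise import InfeasibleDesignError, OptimisedDesign, optimise_dcef


class CalibrationError(RuntimeError):
    """No gamma on the grid reaches the target power.

    Carries the best (gamma, power) pair seen during the scan.
    """

    def __init__(self, best_gamma: float | None, best_power: float, message: str):
        super().__init__(message)
        self.best_gamma = best_gamma
        self.best_power = best_power


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the gamma search.

    ``gamma_star`` is the largest grid value whose optimised design reaches
    the target power; ``trace`` records every (gamma, power) pair examined,
    in scan (descending-gamma) order, with NaN power at infeasible points.
    """

    gamma_star: float
    achieved_power: float
    design: OptimisedDesign
    trace: tuple[tuple[float, float], ...]


def calibrate_gamma(
    params: DesignParams,
    target_power: float,
    grid_step: float = 1e-4,
    ceiling: float = 0.2,
    floor: float = 1e-4,
) -> CalibrationResult:
    """Scan gamma downward for the largest value meeting the target power.

    ``params.gamma`` is ignored; every grid gamma rebuilds the stage-two
    schedule under the configured estimator and rule and re-optimises the
    DCEF.  Raises ``CalibrationError`` when no grid point at or above the
    floor qualifies.
    """
    if not 0.0 <= target_power < 1.0:
        raise ValueError(f"target_power must lie in [0, 1), got {target_power}")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if not 0.0 < floor <= ceiling <= 1.0:
        raise ValueError("need 0 < floor <= ceiling <= 1")

    memo: dict[tuple[int, ...], OptimisedDesign | None] = {}
    trace: list[tuple[float, float]] = []
    best_gamma: float | None = None
    best_power = -math.inf

    i = 0
    while True:
        gamma = round(ceiling - i * grid_step, 12)
        if gamma < floor - 1e-15:
            break
        i += 1
        design = build_gehan_design(replace(params, gamma=gamma))
        key = design.n2_schedule
        if key not in memo:
            try:
                memo[key] = optimise_dcef(
                    design, params.pi0, params.pi1, params.alpha
                )
            except InfeasibleDesignError:
                memo[key] = None
        opt = memo[key]
        power = math.nan if opt is None else opt.power
        trace.append((gamma, power))
        if opt is not None and power > best_power:
            best_gamma, best_power = gamma, power
        if opt is not None and power >= target_power:
            return CalibrationResult(
                gamma_star=gamma,
                achieved_power=power,
                design=opt,
                trace=tuple(trace),
            )
    raise CalibrationError(
        best_gamma,
        best_power,
        f"no gamma in [{floor}, {ceiling}] reaches power {target_power}; "
        f"best was {best_power:.4f} at gamma={best_gamma}",
    )
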