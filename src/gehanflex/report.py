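"""Tabular export, round-tripping, and the reproduction registry.

Design tables serialise as CSV with one row per stage-one outcome
(s1, n2, D, cutoff_k) preceded by ``# key: value`` header comments echoing
the configuration and the design's exact operating characteristics.  The
reader reconstructs the design and DCEF from such a file, so a written
design re-evaluates to identical operating characteristics.

The reproduction registry maps labels to published reference values for the
worked examples this package re-derives (the bevacizumab trial of
Dupuis-Girod et al. 2012, Gehan's tabulated parameter combinations, and the
comparator Simon designs); ``run_reproduce`` recomputes each quantity from
scratch and reports computed vs reference at a 3-decimal tolerance.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Callable

import pandas as pd

from .calibrate import calibrate_gamma
from .dcef import DCEF
from .design import DesignParams, GehanDesign, build_gehan_design, stage_one_size
from .oc import ess
from .optimise import OptimisedDesign, optimise_dcef
from .simon import simon_search


def design_frame(opt: OptimisedDesign) -> pd.DataFrame:
    """One row per stage-one outcome: (s1, n2, D, cutoff_k)."""
    return pd.DataFrame(
        {
            "s1": range(opt.design.n1 + 1),
            "n2": opt.design.n2_schedule,
            "D": opt.dcef.values,
            "cutoff_k": opt.dcef.cutoffs,
        }
    )


def _header_lines(opt: OptimisedDesign) -> list[str]:
    params = opt.design.params
    lines = []
    if params is not None:
        for key in ("pi0", "pi1", "alpha", "beta1", "gamma", "coverage",
                    "method", "rule"):
            lines.append(f"# {key}: {getattr(params, key)}")
    lines += [
        f"# n1: {opt.design.n1}",
        f"# type_one_error: {opt.type_one:.10f}",
        f"# power: {opt.power:.10f}",
        f"# ess_pi0: {opt.ess_null:.10f}",
        f"# ess_pi1: {opt.ess_alt:.10f}",
    ]
    return lines


def write_design_csv(opt: OptimisedDesign, path: str) -> None:
    """Write the design table with a config/summary comment header."""
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(opt)) + "\n")
        design_frame(opt).to_csv(fh, index=False)


def read_design_csv(path: str) -> tuple[GehanDesign, DCEF]:
    """Reconstruct a design and its DCEF from a written design table."""
    meta: dict[str, str] = {}
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            else:
                body.write(line)
    body.seek(0)
    table = pd.read_csv(body)
    params = None
    if "pi0" in meta:
        params = DesignParams(
            pi0=float(meta["pi0"]),
            pi1=float(meta["pi1"]),
            alpha=float(meta["alpha"]),
            beta1=float(meta["beta1"]),
            gamma=float(meta["gamma"]),
            coverage=float(meta["coverage"]),
            method=meta["method"],
            rule=meta["rule"],
        )
    design = GehanDesign(
        n1=int(meta["n1"]),
        n2_schedule=tuple(int(v) for v in table["n2"]),
        params=params,
    )
    dcef = DCEF(
        design=design,
        pi0=float(meta["pi0"]),
        cutoffs=tuple(int(v) for v in table["cutoff_k"]),
    )
    return design, dcef


def write_curve_csv(df: pd.DataFrame, path: str, label: str, **meta) -> None:
    """Write a two-column (pi, value) curve with identifying comments."""
    with open(path, "w") as fh:
        fh.write(f"# characteristic: {label}\n")
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


# --------------------------------------------------------------------------
# Reproduction registry
# --------------------------------------------------------------------------

#: The bevacizumab trial parameterisation (Dupuis-Girod et al. 2012):
#: beta1 = 0.1, pi1 = 0.3, gamma = 0.1, with the test at alpha = 0.05
#: against pi0 = pi1 - 0.15 = 0.15.
DUPUIS = dict(pi0=0.15, pi1=0.3, alpha=0.05, beta1=0.1, gamma=0.1)


@dataclass(frozen=True)
class ReproduceOutcome:
    label: str
    computed: float
    reference: float
    tolerance: float
    passed: bool


def _dupuis_params(method: str, rule: str, gamma: float = 0.1) -> DesignParams:
    return DesignParams(method=method, rule=rule, **{**DUPUIS, "gamma": gamma})


def _optimised(method: str, rule: str, gamma: float = 0.1) -> OptimisedDesign:
    params = _dupuis_params(method, rule, gamma)
    design = build_gehan_design(params)
    return optimise_dcef(design, params.pi0, params.pi1, params.alpha)


def _table1_power(beta1: float, gamma: float, pi1: float, method: str) -> float:
    params = DesignParams(
        pi0=pi1 - 0.15, pi1=pi1, alpha=0.05, beta1=beta1, gamma=gamma,
        method=method, rule="f_G",
    )
    design = build_gehan_design(params)
    return optimise_dcef(design, params.pi0, params.pi1, params.alpha).power


def _table1_ess_null(beta1: float, gamma: float, pi1: float, method: str) -> float:
    params = DesignParams(
        pi0=pi1 - 0.15, pi1=pi1, alpha=0.05, beta1=beta1, gamma=gamma,
        method=method, rule="f_G",
    )
    return ess(build_gehan_design(params), params.pi0)


def _gamma_star(method: str) -> float:
    params = _dupuis_params(method, "f_G")
    return calibrate_gamma(params, target_power=0.8).gamma_star


def _gamma_star_power(method: str) -> float:
    params = _dupuis_params(method, "f_G")
    return calibrate_gamma(params, target_power=0.8).achieved_power


#: label -> (compute thunk, reference value, absolute tolerance)
REPRODUCE_TARGETS: dict[str, tuple[Callable[[], float], float, float]] = {
    "dupuis_n1": (lambda: stage_one_size(0.3, 0.1), 7, 0),
    "dupuis_fG_original_power": (
        lambda: _optimised("original", "f_G").power, 0.404, 5e-4),
    "dupuis_fG_original_type1": (
        lambda: _optimised("original", "f_G").type_one, 0.021, 5e-4),
    "dupuis_fG_original_ess_pi0": (
        lambda: _optimised("original", "f_G").ess_null, 17.42, 5e-3),
    "dupuis_fG_original_ess_pi1": (
        lambda: _optimised("original", "f_G").ess_alt, 20.83, 5e-3),
    "dupuis_fG_conservative_power": (
        lambda: _optimised("conservative", "f_G").power, 0.572, 5e-4),
    "dupuis_fG_conservative_type1": (
        lambda: _optimised("conservative", "f_G").type_one, 0.049, 5e-4),
    "dupuis_fL_n2": (
        lambda: build_gehan_design(_dupuis_params("original", "f_L")).n2_schedule[7],
        21, 0),
    "dupuis_fL_power": (
        lambda: _optimised("original", "f_L").power, 0.619, 5e-4),
    "dupuis_fEL_original_power": (
        lambda: _optimised("original", "f_EL").power, 0.107, 5e-4),
    "dupuis_fEL_conservative_power": (
        lambda: _optimised("conservative", "f_EL").power, 0.586, 5e-4),
    "dupuis_gamma_original": (lambda: _gamma_star("original"), 0.0658, 5e-5),
    "dupuis_gamma_original_power": (
        lambda: _gamma_star_power("original"), 0.800, 5e-4),
    "dupuis_gamma_conservative": (
        lambda: _gamma_star("conservative"), 0.0686, 5e-5),
    "table1_b10_g10_p20_original_power": (
        lambda: _table1_power(0.1, 0.1, 0.2, "original"), 0.188, 5e-4),
    "table1_b05_g05_p20_original_ess_pi0": (
        lambda: _table1_ess_null(0.05, 0.05, 0.2, "original"), 37.595, 5e-4),
    "simon_null_optimal_f1": (
        lambda: simon_search(0.15, 0.3, 0.05, 0.2)[0].f1, 3, 0),
    "simon_null_optimal_n1": (
        lambda: simon_search(0.15, 0.3, 0.05, 0.2)[0].n1, 19, 0),
    "simon_null_optimal_f2": (
        lambda: simon_search(0.15, 0.3, 0.05, 0.2)[0].f2, 12, 0),
    "simon_null_optimal_n2": (
        lambda: simon_search(0.15, 0.3, 0.05, 0.2)[0].n2, 36, 0),
    "simon_minimax_n1": (
        lambda: simon_search(0.15, 0.3, 0.05, 0.2)[1].n1, 23, 0),
    "simon_minimax_n2": (
        lambda: simon_search(0.15, 0.3, 0.05, 0.2)[1].n2, 25, 0),
}


def run_reproduce(label: str) -> ReproduceOutcome:
    """Recompute a registered quantity and compare it to its reference value."""
    if label not in REPRODUCE_TARGETS:
        raise KeyError(
            f"unknown reproduction target {label!r}; "
            f"known: {', '.join(sorted(REPRODUCE_TARGETS))}"
        )
    thunk, reference, tolerance = REPRODUCE_TARGETS[label]
    computed = float(thunk())
    passed = abs(computed - reference) <= tolerance
    return ReproduceOutcome(
        label=label, computed=computed, reference=reference,
        tolerance=tolerance, passed=passed,
    )
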