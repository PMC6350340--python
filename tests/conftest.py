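"""Shared fixtures: the bevacizumab-trial worked designs.

The motivating parameterisation (beta1 = 0.1, pi1 = 0.3, gamma = 0.1,
tested at alpha = 0.05 against pi0 = 0.15) is used across the suite;
optimised designs are session-scoped so each variant is computed once.
"""

import pytest

from gehanflex import DesignParams, build_gehan_design, optimise_dcef

DUPUIS = dict(pi0=0.15, pi1=0.3, alpha=0.05, beta1=0.1, gamma=0.1)


def dupuis_params(method: str = "original", rule: str = "f_G", **overrides):
    return DesignParams(method=method, rule=rule, **{**DUPUIS, **overrides})


@pytest.fixture(scope="session")
def dupuis_original_fg():
    params = dupuis_params("original", "f_G")
    design = build_gehan_design(params)
    return optimise_dcef(design, params.pi0, params.pi1, params.alpha)


@pytest.fixture(scope="session")
def dupuis_conservative_fg():
    params = dupuis_params("conservative", "f_G")
    design = build_gehan_design(params)
    return optimise_dcef(design, params.pi0, params.pi1, params.alpha)


@pytest.fixture(scope="session")
def dupuis_original_fl():
    params = dupuis_params("original", "f_L")
    design = build_gehan_design(params)
    return optimise_dcef(design, params.pi0, params.pi1, params.alpha)


@pytest.fixture(scope="session")
def dupuis_original_fel():
    params = dupuis_params("original", "f_EL")
    design = build_gehan_design(params)
    return optimise_dcef(design, params.pi0, params.pi1, params.alpha)
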