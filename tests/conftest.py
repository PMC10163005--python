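"""Shared fixtures: parameter sets, steady states, reusable simulations.

Expensive objects (steady states, reference trajectories) are session
scoped so the suite integrates each of them once.
"""

import numpy as np
import pytest

import sectorsize as ss


@pytest.fixture(scope="session")
def upshift_setup():
    """Strong-upshift parameters with their poor/rich nutrient qualities."""
    params, kn_low, kn_high = ss.preset("upshift")
    return params, kn_low, kn_high


@pytest.fixture(scope="session")
def stationary_setup():
    params, kn_low, kn_high = ss.preset("stationary")
    return params, kn_low, kn_high


@pytest.fixture(scope="session")
def separated_params():
    """Parameters with alpha/beta split out (full mass-balance mode)."""
    base = ss.preset("upshift")[0]
    alpha = 0.1
    gamma = base.gamma_alpha / alpha
    return base.evolve(alpha=alpha, beta=base.gamma_beta / gamma)


@pytest.fixture(scope="session")
def rich_steady(upshift_setup):
    params, _, kn_high = upshift_setup
    return ss.solve(kn_high, params)


@pytest.fixture(scope="session")
def poor_steady(upshift_setup):
    params, kn_low, _ = upshift_setup
    return ss.solve(kn_low, params)


@pytest.fixture(scope="session")
def rich_initial(rich_steady):
    return ss.CellState(a=rich_steady.a_star, phi_R=rich_steady.phi_R_star,
                        phi_X=0.0, V=rich_steady.V0_star, X_tilde=0.0)


@pytest.fixture(scope="session")
def poor_initial(poor_steady):
    return ss.CellState(a=poor_steady.a_star, phi_R=poor_steady.phi_R_star,
                        phi_X=0.0, V=poor_steady.V0_star, X_tilde=0.0)


def steady_initial(steady_state, params):
    return ss.CellState(
        a=steady_state.a_star, phi_R=steady_state.phi_R_star,
        phi_X=steady_state.phi_X_star if params.separated else 0.0,
        V=steady_state.V0_star, X_tilde=0.0)
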