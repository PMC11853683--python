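"""Shared fixtures.

The expensive steady-state computations (condition grid, variable-topology
model, 3-D flux curves) are session-scoped so the acceptance tests and the
behavioural tests share one solve each.
"""

import numpy as np
import pytest

import cristaflux as cf
from cristaflux import analysis, experiments


@pytest.fixture(scope="session")
def params():
    return cf.default_params()


@pytest.fixture(scope="session")
def cparams():
    return cf.curve_params()


@pytest.fixture(scope="session")
def grid_df(params):
    """18-condition grid plus crista-free baselines at 4 nm resolution."""
    return cf.run_condition_grid(params, h=0.004)


@pytest.fixture(scope="session")
def vartop(params):
    """Variable-topology (trunk + branches) steady state at 0.0185 mM."""
    return experiments.variable_topology(params, h=0.004)


@pytest.fixture(scope="session")
def curves3d():
    """3-D lamellar flux-length curves (10 nm resolution)."""
    return experiments.flux_length_curves(h=0.01)


@pytest.fixture(scope="session")
def census_scores(curves3d):
    return experiments.census_pipeline(curves=curves3d)


@pytest.fixture(scope="session")
def small_solve(params):
    """One cheap uniform-model steady state shared by behavioural tests."""
    model = cf.build_uniform_2d(0.32, "both_ends", h=0.005)
    bc = cf.BoundaryConditions(ADP_cyt=0.037)
    return cf.solve_steady_state(model, params, bc), model, bc
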