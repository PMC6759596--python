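"""Shared fixtures.

The expensive objects (toy root model and its pre-salt steady state) are
session-scoped and reused across test modules; the "micro" root (3 layers)
exists for tests that need many forward simulations.
"""

import numpy as np
import pytest

from rootflux.assembly import RootModel
from rootflux.geometry import apply_barriers, build_root_grid
from rootflux.parameters import BoundaryConditions, ModelParams, TransporterDistribution
from rootflux.simulate import Protocol, run_protocol, solve_presalt_steady_state

PRE_SALT = dict(NaCl=0.5, KCl=11.9, Ca=0.5, pH=5.5)
SALT_50 = dict(NaCl=50.0, KCl=11.9, Ca=0.5, pH=5.5)
DAY = 86400.0


@pytest.fixture(scope="session")
def toy_geometry():
    return build_root_grid(6, 2)


@pytest.fixture(scope="session")
def toy_graph(toy_geometry):
    return apply_barriers(toy_geometry)


@pytest.fixture(scope="session")
def toy_params():
    return ModelParams()


@pytest.fixture(scope="session")
def toy_bc():
    return BoundaryConditions(**PRE_SALT)


@pytest.fixture(scope="session")
def toy_model(toy_geometry, toy_graph, toy_params, toy_bc):
    dist = TransporterDistribution.wild_type(toy_params)
    return RootModel(toy_geometry, toy_graph, toy_params, dist, toy_bc)


@pytest.fixture(scope="session")
def toy_steady(toy_model, toy_bc):
    return solve_presalt_steady_state(toy_model, toy_bc)


@pytest.fixture(scope="session")
def toy_salt_traj(toy_model, toy_steady, toy_bc):
    """One day of 50 mM NaCl exposure from the pre-salt steady state."""
    protocol = Protocol(
        pre_salt=toy_bc,
        salt=BoundaryConditions(**SALT_50),
        salt_onset=0.0,
        duration=DAY,
        output_times=[0.0, 600.0, 3600.0, DAY / 2, DAY],
    )
    return run_protocol(toy_model, toy_steady, protocol)


@pytest.fixture(scope="session")
def micro_model():
    """3-layer root for tests that need many cheap forward runs."""
    geometry = build_root_grid(3, 1)
    graph = apply_barriers(geometry, 0.5)
    params = ModelParams()
    dist = TransporterDistribution.wild_type(params)
    bc = BoundaryConditions(**PRE_SALT)
    return RootModel(geometry, graph, params, dist, bc)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
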