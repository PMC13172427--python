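"""Shared fixtures: a toy model and a few pre-built trajectories that are
expensive enough to be worth reusing across test modules."""

import numpy as np
import pytest

from sfgmultipole.core_io import DepthGrid, SpectralGrid
from sfgmultipole.synthetic import (SlabSpec, ToyWaterModel, _assemble_frame,
                                    build_bulk, build_slab,
                                    biaxial_triple_layer, langevin_dynamics)


@pytest.fixture(scope="session")
def model():
    return ToyWaterModel()


@pytest.fixture(scope="session")
def small_slab(model):
    """Static isotropic slab, 96 molecules in a 14×14×45 Å box."""
    spec = SlabSpec(box=(14.0, 14.0, 45.0), n_molecules=96, thickness=14.7)
    return build_slab(spec, model, seed=11)


@pytest.fixture(scope="session")
def vibrating_slab(model, small_slab):
    """Langevin dynamics on the static slab: 6144 stored frames at 1 fs."""
    return langevin_dynamics(small_slab.frames[0], model, steps=6144,
                             dt=1.0, T=298.0, seed=12)


@pytest.fixture(scope="session")
def vibrating_bulk(model):
    """Isotropic bulk box with internal dynamics, 64 molecules."""
    bulk = build_bulk(model, seed=21, n_molecules=64)
    return langevin_dynamics(bulk.frames[0], model, steps=8192, dt=1.0,
                             T=298.0, seed=22)


@pytest.fixture(scope="session")
def oriented_replicas(model):
    """100 identically oriented (θ=0) molecules with independent internal
    dynamics — an ensemble of single-molecule systems for closed-form
    response checks."""
    rng = np.random.default_rng(31)
    n = 100
    centers = np.column_stack([rng.uniform(0, 20, n), rng.uniform(0, 20, n),
                               rng.uniform(5, 25, n)])
    rots = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    frame = _assemble_frame(model, centers, rots,
                            np.array([20.0, 20.0, 30.0]))
    return langevin_dynamics(frame, model, steps=16384, dt=1.0, T=298.0,
                             seed=32)


@pytest.fixture()
def lab_grid():
    return DepthGrid.regular(0.0, 30.0, 0.5, reference="lab")


@pytest.fixture()
def bend_sgrid():
    return SpectralGrid(dt=1.0, n_lags=2048, nu_max=4100.0)
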