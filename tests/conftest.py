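import numpy as np
import pytest

from ensemblefit.density import SpreadParams, spread_density
from ensemblefit.geometry import FramePoolSpec, build_structure_pool
from ensemblefit.models import AtomRecord, GridSpec, StructureModel
from ensemblefit.synthetic import (
    CHAIN_SELECTION,
    fit_frames_to_scaffold,
    minimal_scenario,
    realize,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_chain_model(n_atoms=20, seed=0, scale=10.0):
    rng = np.random.default_rng(seed)
    atoms = [
        AtomRecord(
            atom_name="CA",
            element="C",
            residue_name="GLY",
            residue_index=i + 1,
            chain_id="A",
            position=rng.uniform(-scale, scale, 3),
        )
        for i in range(n_atoms)
    ]
    return StructureModel(atoms=atoms, label="chain")


@pytest.fixture
def chain_model():
    return make_chain_model()


@pytest.fixture
def small_grid():
    return GridSpec(origin=(-8.0, -8.0, -8.0), spacing=(1.0, 1.0, 1.0), shape=(17, 17, 17))


@pytest.fixture(scope="session")
def minimal_data():
    """One realized minimal synthetic scenario, shared read-only."""
    return realize(minimal_scenario(seed=3))


@pytest.fixture(scope="session")
def minimal_pool_maps(minimal_data):
    """Spread density maps for every pooled frame of the minimal scenario."""
    data = minimal_data
    spec = data.spec
    pool = build_structure_pool(data.ensembles, FramePoolSpec())
    chain_idx = CHAIN_SELECTION.resolve(data.topology)
    params = SpreadParams(sigma=spec.sigma)
    fitted = {}
    maps = []
    for p in pool:
        if p.ensemble_index not in fitted:
            fitted[p.ensemble_index] = fit_frames_to_scaffold(
                data.ensembles[p.ensemble_index], data.topology
            )
        coords = fitted[p.ensemble_index].coordinates[p.frame_index][chain_idx]
        maps.append(spread_density(coords, spec.grid, params))
    return maps
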