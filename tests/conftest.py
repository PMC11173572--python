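import numpy as np
import pytest

from hydrashell import SyntheticBoxSpec, generate_water_box, compute_molecular_dipoles


@pytest.fixture(scope="session")
def small_box():
    """8 rigid waters, 64 stored frames — shared cheap fixture."""
    spec = SyntheticBoxSpec(n_water=8, n_steps=64, seed=11, cell_edge=10.0)
    traj, topo = generate_water_box(spec)
    return spec, traj, topo


@pytest.fixture(scope="session")
def solute_box():
    """1 hydroxyurea-like solute + 6 waters, 128 frames."""
    spec = SyntheticBoxSpec(n_water=6, n_solute=1, n_steps=128, seed=5, cell_edge=11.0)
    traj, topo = generate_water_box(spec)
    return spec, traj, topo


@pytest.fixture(scope="session")
def solute_series(solute_box):
    spec, traj, topo = solute_box
    return compute_molecular_dipoles(traj, topo)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
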