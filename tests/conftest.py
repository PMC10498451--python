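import numpy as np
import pytest

from hvmech import synthetic
from hvmech.model import Trajectory


@pytest.fixture
def flat_bilayer():
    """Uniform 4 nm bilayer, 64 molecules/leaflet on an 8x8 lattice."""
    topo, frame, truth = synthetic.gen_bilayer_frame(
        n_per_leaflet=64, area_per_molecule=0.64, head_separation=4.0, seed=11
    )
    return topo, frame, truth


@pytest.fixture
def bimodal_bilayer():
    """Half 4.0 nm / half 7.0 nm bilayer on a 16x16 lattice."""
    layout = np.full((16, 16), 7.0)
    layout[:, :8] = 4.0
    topo, frame, truth = synthetic.gen_bilayer_frame(
        n_per_leaflet=256, area_per_molecule=0.64, head_separation=layout, seed=12
    )
    return topo, frame, truth


def make_trajectory(coords, box=(10.0, 10.0, 10.0), timestep=1.0):
    return Trajectory.from_coordinates(np.asarray(coords, dtype=float), box, timestep)
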