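import numpy as np
import pytest

from mdcompare.structure_io import Structure
from mdcompare.synthetic_data import gaussian_ensemble, toy_dimer
from mdcompare.trajectory import Trajectory


@pytest.fixture
def dimer() -> Structure:
    return toy_dimer(6)


@pytest.fixture
def small_gaussian():
    """20-atom isotropic Gaussian ensemble (sigma 0.05 nm), 500 frames."""
    traj, truth = gaussian_ensemble(500, seed=11, n_atoms=20, sigma_nm=0.05)
    return traj, truth


def make_trajectory(coords_nm: np.ndarray, topology: Structure,
                    dt_ps: float = 10.0) -> Trajectory:
    coords_nm = np.asarray(coords_nm, dtype=float)
    return Trajectory(
        topology=topology,
        coords=coords_nm,
        times_ps=dt_ps * np.arange(coords_nm.shape[0], dtype=float),
    )
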