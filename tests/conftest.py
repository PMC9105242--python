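import numpy as np
import pytest

from oilcluster import synth
from oilcluster.io import Topology, Trajectory


@pytest.fixture(scope="session")
def brownian_big():
    """1000 Brownian walkers, D = 1 nm^2/ps, dt = 0.01 ps, 2000 steps."""
    return synth.gen_brownian(N=1000, D=1.0, dt=0.01, steps=2000, seed=42)


@pytest.fixture(scope="session")
def ideal_gas_dense():
    """500 uniform points, 200 frames, L = 5 nm (rho = 4 nm^-3)."""
    return synth.gen_ideal_gas(N=500, L=5.0, n_frames=200, seed=7)


@pytest.fixture(scope="session")
def aggregation_small():
    """A short, small attractive-only aggregation run for trend tests."""
    params = synth.hpg_like(
        seed=3, n_oil=30, n_polymer=4, L=5.0, steps=8000, save_stride=40
    )
    return synth.gen_aggregation(params)


def toy_topology(n_mol=3, atoms_per_mol=2, species="OIL", role="terpenoid"):
    """Minimal homogeneous one-species topology for geometry tests."""
    n = n_mol * atoms_per_mol
    return Topology(
        atom_names=np.array(["C"] * n),
        mol_index=np.repeat(np.arange(n_mol), atoms_per_mol),
        mol_species=np.array([species] * n_mol),
        roles={species: role},
        masses=np.full(n, 12.011),
    )


def particle_trajectory(coords, box, species="OIL", role="terpenoid", dt=1.0):
    """Wrap (T, N, 3) single-atom-molecule coordinates into a Trajectory."""
    coords = np.asarray(coords, dtype=float)
    T, n, _ = coords.shape
    topo = toy_topology(n_mol=n, atoms_per_mol=1, species=species, role=role)
    return Trajectory(
        times=np.arange(T) * dt,
        boxes=np.asarray(box, dtype=float),
        coords=coords,
        topology=topo,
    )
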