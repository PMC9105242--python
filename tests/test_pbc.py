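"""Minimum-image arithmetic, molecule reassembly, COM series, unwrapping."""

import numpy as np
import pytest

from oilcluster.pbc import (
    ComSeries,
    center_of_mass,
    com_series,
    min_image,
    min_image_vector,
    reassemble_molecule,
    unwrap,
    wrap_coordinates,
)
from tests.conftest import particle_trajectory


def brute_force_min_image(a, b, L):
    """Shortest displacement a->b over all 27 periodic images."""
    best = None
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                d = np.asarray(b) + L * np.array([i, j, k]) - np.asarray(a)
                if best is None or np.linalg.norm(d) < np.linalg.norm(best):
                    best = d
    return best


def test_min_image_wrap_case():
    v = min_image_vector([0.5, 0, 0], [9.5, 0, 0], 10.0)
    assert np.linalg.norm(v) == pytest.approx(1.0)
    assert v[0] == pytest.approx(-1.0)


def test_min_image_identity():
    assert np.allclose(min_image_vector([1.2, 3.4, 5.6], [1.2, 3.4, 5.6], 10.0), 0.0)


def test_min_image_matches_brute_force_and_bounds():
    rng = np.random.default_rng(11)
    L = 7.3
    for _ in range(100):
        a, b = rng.random((2, 3)) * L
        v = min_image_vector(a, b, L)
        assert np.allclose(np.linalg.norm(v), np.linalg.norm(brute_force_min_image(a, b, L)))
        assert np.linalg.norm(v) <= np.linalg.norm(b - a) + 1e-12
        assert np.linalg.norm(v) <= np.sqrt(3) * L / 2 + 1e-12
        assert np.all(v >= -L / 2) and np.all(v < L / 2)


def test_min_image_triangle_inequality_on_torus():
    rng = np.random.default_rng(5)
    L = 4.0
    for _ in range(50):
        a, b, c = rng.random((3, 3)) * L
        dab = np.linalg.norm(min_image_vector(a, b, L))
        dbc = np.linalg.norm(min_image_vector(b, c, L))
        dac = np.linalg.norm(min_image_vector(a, c, L))
        assert dac <= dab + dbc + 1e-12
        assert dab == pytest.approx(np.linalg.norm(min_image_vector(b, a, L)))


def test_reassemble_diatomic_across_face():
    coords = np.array([[9.8, 5.0, 5.0], [0.2, 5.0, 5.0]])
    out = reassemble_molecule(coords, 10.0)
    assert np.linalg.norm(out[1] - out[0]) == pytest.approx(0.4)


def test_reassemble_interior_identity():
    rng = np.random.default_rng(2)
    coords = 4.0 + rng.random((10, 3))  # well inside a 10 nm box, compact
    assert np.allclose(reassemble_molecule(coords, 10.0), coords)


def test_reassemble_corner_straddling_molecule_recovers_shape():
    # build a compact 25-atom chain unwrapped at a box corner, wrap, reassemble
    rng = np.random.default_rng(9)
    L = 10.0
    steps = rng.normal(0, 0.05, (24, 3))
    unwrapped = np.concatenate([[np.array([9.95, 9.97, 0.02])],
                                np.array([9.95, 9.97, 0.02]) + np.cumsum(steps, 0)])
    wrapped = wrap_coordinates(unwrapped, L)
    out = reassemble_molecule(wrapped, L)
    # identical up to a global lattice shift
    shift = out[0] - unwrapped[0]
    assert np.allclose(shift, np.round(shift / L) * L, atol=1e-9)
    assert np.allclose(out - out[0], unwrapped - unwrapped[0], atol=1e-9)


def test_reassemble_stretched_molecule_warns():
    coords = np.array([[0.0, 0.0, 0.0], [4.9, 4.9, 4.9]])
    with pytest.warns(UserWarning, match="half a box edge"):
        reassemble_molecule(coords, 10.0)


def test_center_of_mass_examples():
    assert np.allclose(
        center_of_mass([[0, 0, 0], [2, 0, 0]], [1.0, 1.0]), [1, 0, 0]
    )
    assert center_of_mass([[0, 0, 0], [4, 0, 0]], [1.0, 3.0])[0] == pytest.approx(3.0)
    with pytest.raises(ValueError, match="positive"):
        center_of_mass([[0, 0, 0]], [0.0])


def test_com_of_straddling_diatomic_wraps_to_origin():
    traj = particle_trajectory(np.array([[[9.8, 0, 0], [0.2, 0, 0]]]), [10.0] * 3)
    traj.topology.mol_index[:] = 0  # make both atoms one molecule
    traj.topology.mol_species = traj.topology.mol_species[:1]
    traj.topology._mol_atoms = [np.array([0, 1])]
    series = com_series(traj, "OIL")
    assert series.coords[0, 0, 0] == pytest.approx(0.0, abs=1e-12)


def test_unwrap_recovers_multi_crossing_walk():
    rng = np.random.default_rng(1)
    L = 5.0
    drift = np.full((400, 1, 3), [0.04, 0.0, 0.0]) + rng.normal(0, 0.02, (400, 1, 3))
    true = np.concatenate([np.zeros((1, 1, 3)), np.cumsum(drift, axis=0)])
    wrapped = ComSeries(
        times=np.arange(401.0),
        coords=wrap_coordinates(true, L),
        box=[L] * 3,
        wrapped=True,
    )
    out = unwrap(wrapped)
    assert not out.wrapped
    assert np.allclose(out.coords, true, atol=1e-9)
    assert true[-1, 0, 0] > 3 * L  # the walk really crossed the face repeatedly


def test_unwrap_static_molecule_constant():
    coords = np.tile(np.array([[1.0, 2.0, 3.0]]), (50, 1)).reshape(50, 1, 3)
    s = ComSeries(times=np.arange(50.0), coords=coords, box=[5.0] * 3)
    assert np.allclose(unwrap(s).coords, coords)


def test_unwrap_wrap_identity_random_walks():
    rng = np.random.default_rng(77)
    L = 3.0
    for _ in range(10):
        steps = rng.normal(0, 0.2, (100, 4, 3))
        steps = np.clip(steps, -L / 2 + 1e-6, L / 2 - 1e-6)
        true = np.concatenate([rng.random((1, 4, 3)) * L, np.cumsum(steps, 0)])
        true[1:] += true[:1]
        wrapped = ComSeries(
            times=np.arange(101.0), coords=wrap_coordinates(true, L), box=[L] * 3
        )
        rec = unwrap(wrapped).coords
        # identical up to the initial wrap of the starting point
        assert np.allclose(rec - rec[0], true - true[0], atol=1e-9)


def test_com_series_lattice_translation_equivariance():
    rng = np.random.default_rng(4)
    L = 6.0
    coords = rng.random((5, 8, 3)) * L
    t1 = particle_trajectory(coords, [L] * 3)
    t2 = particle_trajectory(coords + np.array([L, 2 * L, -L]), [L] * 3)
    s1 = com_series(t1, "OIL")
    s2 = com_series(t2, "OIL")
    assert np.allclose(s1.coords, s2.coords, atol=1e-9)


def test_com_series_requires_known_species():
    traj = particle_trajectory(np.zeros((2, 3, 3)) + 1.0, [5.0] * 3)
    with pytest.raises(ValueError, match="no molecules"):
        com_series(traj, "WAT")
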