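"""Geometric hydrogen-bond detection, counting, and ACF kinetics."""

import numpy as np
import pytest

from oilcluster.hbonds import (
    HBondCriterion,
    HBondSeries,
    HBondTables,
    acf_from_occupancy,
    classify_pair,
    detect_hbonds,
    hbond_acf,
    hbond_counts,
    integrate_acf,
)
from oilcluster.io import Topology, Trajectory
from oilcluster.synth import gen_markov_bonds


def two_molecule_system(d_da=0.30, angle_deg=10.0):
    """A donor molecule (O, H) and an acceptor molecule (O) with a tunable
    donor-acceptor distance and H-D-A angle."""
    theta = np.radians(angle_deg)
    coords = np.array(
        [
            [1.0, 1.0, 1.0],  # donor O
            [1.0 + 0.1 * np.cos(theta), 1.0 + 0.1 * np.sin(theta), 1.0],  # H
            [1.0 + d_da, 1.0, 1.0],  # acceptor O
        ]
    )
    tables = HBondTables(
        donor_atoms=np.array([0]),
        donor_hydrogens=np.array([1]),
        acceptor_atoms=np.array([0, 2]),
        atom_mol=np.array([0, 0, 1]),
        mol_role=np.array(["polymer", "terpenoid"]),
    )
    return coords, tables


@pytest.mark.parametrize(
    "d,angle,expected",
    [
        (0.30, 10.0, 1),   # inside both cutoffs
        (0.36, 10.0, 0),   # distance fail
        (0.30, 40.0, 0),   # angle fail
        (0.349, 29.0, 1),  # just inside both
    ],
)
def test_detect_hbonds_geometry(d, angle, expected):
    coords, tables = two_molecule_system(d, angle)
    bonds = detect_hbonds(coords, 10.0, tables, HBondCriterion())
    assert len(bonds) == expected
    if expected:
        assert bonds == {(0, 1, 2)}


def test_detect_hbonds_across_periodic_face():
    coords, tables = two_molecule_system(0.30, 10.0)
    coords[2] += np.array([10.0, 0.0, 0.0])  # same geometry, next image
    coords %= 10.0
    assert len(detect_hbonds(coords, 10.0, tables, HBondCriterion())) == 1


def test_intramolecular_pairs_excluded():
    coords, tables = two_molecule_system(0.30, 10.0)
    tables.atom_mol[:] = 0  # everything one molecule
    assert detect_hbonds(coords, 10.0, tables, HBondCriterion()) == set()


def hbond_toy_trajectory(n_frames=4):
    coords, tables = two_molecule_system(0.30, 10.0)
    topo = Topology(
        atom_names=np.array(["O1", "HO1", "O1"]),
        mol_index=np.array([0, 0, 1]),
        mol_species=np.array(["POL", "CAR"]),
        roles={"POL": "polymer", "CAR": "terpenoid"},
        masses=np.array([15.999, 1.008, 15.999]),
        hbond_spec={
            "POL": {"donors": ["O1"], "acceptors": ["O1"], "hydrogens": {"O1": ["HO1"]}},
            "CAR": {"donors": [], "acceptors": ["O1"], "hydrogens": {}},
        },
    )
    frames = np.tile(coords, (n_frames, 1, 1))
    return Trajectory(
        times=np.arange(n_frames, dtype=float),
        boxes=np.array([10.0] * 3),
        coords=frames,
        topology=topo,
    )


def test_hbond_counts_classification():
    series = hbond_counts(hbond_toy_trajectory())
    assert (series.counts["polymer-compound"] == 1).all()
    assert (series.counts["polymer-polymer"] == 0).all()
    assert (series.counts["compound-compound"] == 0).all()


def test_species_without_hydroxyl_contribute_no_bonds():
    traj = hbond_toy_trajectory()
    # a species with no donor/acceptor designations (p-cymene-like) is inert
    traj.topology.hbond_spec = {
        "POL": {"donors": ["O1"], "acceptors": ["O1"], "hydrogens": {"O1": ["HO1"]}}
    }
    series = hbond_counts(traj)
    assert (series.counts[list(series.counts.columns[1:])].to_numpy() == 0).all()


def test_donor_without_hydrogens_rejected():
    traj = hbond_toy_trajectory()
    traj.topology.hbond_spec["POL"] = {
        "donors": ["O1"], "acceptors": ["O1"], "hydrogens": {}
    }
    with pytest.raises(ValueError, match="no mapped hydrogens"):
        HBondTables.from_topology(traj.topology)


def test_classify_pair_other():
    assert classify_pair("water", "polymer") == "other"
    assert classify_pair("terpenoid", "polymer") == "polymer-compound"


def make_series_from_occupancy(h):
    """Build an HBondSeries whose polymer-compound class follows ``h``."""
    h = np.asarray(h)
    triples = [(3 * j, 3 * j + 1, 3 * j + 2) for j in range(h.shape[1])]
    bonds = [
        {triples[j] for j in range(h.shape[1]) if h[t, j]} for t in range(h.shape[0])
    ]
    return HBondSeries(
        times=np.arange(h.shape[0], dtype=float),
        bonds=bonds,
        bond_class={tr: "polymer-compound" for tr in triples},
    )


def test_acf_always_present_bond_is_one():
    series = make_series_from_occupancy(np.ones((20, 1), dtype=int))
    acf = hbond_acf(series, "polymer-compound")
    assert np.allclose(acf.c, 1.0)


def test_acf_bond_present_only_at_start():
    h = np.zeros((10, 1), dtype=int)
    h[0, 0] = 1
    acf = hbond_acf(make_series_from_occupancy(h), "polymer-compound")
    assert acf.c[0] == pytest.approx(1.0)
    assert np.allclose(acf.c[1:], 0.0)


def test_acf_empty_class_is_empty_not_nan():
    series = make_series_from_occupancy(np.ones((5, 1), dtype=int))
    acf = hbond_acf(series, "compound-compound")
    assert acf.n_bonds == 0 and acf.c.size == 0


def test_markov_acf_matches_closed_form():
    mk = gen_markov_bonds(k_on=0.02, k_off=0.05, dt=1.0, steps=10_000,
                          n_chains=100, seed=17)
    acf = acf_from_occupancy(mk.occupancy, mk.times, lags=np.arange(0, 300, 5))
    assert acf.c[0] == pytest.approx(1.0)
    assert np.abs(acf.c - mk.analytic_acf(acf.lag_times)).max() < 0.02


def test_markov_acf_rate_recovery():
    k_on, k_off = 0.03, 0.07
    mk = gen_markov_bonds(k_on, k_off, dt=1.0, steps=10_000, n_chains=100, seed=23)
    lags = np.arange(0, 60)
    acf = acf_from_occupancy(mk.occupancy, mk.times, lags=lags)
    p = mk.p
    decay = np.clip((acf.c - p) / (1 - p), 1e-6, None)
    k_fit = -np.polyfit(acf.lag_times[:30], np.log(decay[:30]), 1)[0]
    assert k_fit == pytest.approx(k_on + k_off, rel=0.05)


def test_acf_stationarity_plateau():
    mk = gen_markov_bonds(0.02, 0.05, dt=1.0, steps=20_000, n_chains=50, seed=5)
    acf = acf_from_occupancy(mk.occupancy, mk.times, lags=np.arange(400, 500))
    # unnormalized long-lag plateau equals <h>^2 <=> C plateau equals p
    assert acf.c.mean() == pytest.approx(mk.p, abs=0.03)


def test_integrate_acf_exponential():
    tau0 = 40.0
    t = np.arange(0.0, 400.0, 0.5)
    from oilcluster.hbonds import HBondACF

    acf = HBondACF(lag_times=t, c=np.exp(-t / tau0), n_bonds=1, mean_occupancy=0.5)
    res = integrate_acf(acf)
    assert res.tau == pytest.approx(tau0, rel=0.02)
    assert not res.truncated


def test_integrate_acf_plateau_flagged_and_two_point():
    from oilcluster.hbonds import HBondACF

    t = np.arange(0.0, 10.0)
    res = integrate_acf(HBondACF(lag_times=t, c=np.ones(10), n_bonds=1,
                                 mean_occupancy=1.0))
    assert res.truncated and res.tau == pytest.approx(9.0)
    res2 = integrate_acf(
        HBondACF(lag_times=np.array([0.0, 2.0]), c=np.array([1.0, 0.0]),
                 n_bonds=1, mean_occupancy=0.5)
    )
    assert res2.tau == pytest.approx(1.0)  # trapezoid: dt/2
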