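"""PBC-aware DBSCAN, cluster populations, swarm radius of gyration."""

import numpy as np
import pytest

from oilcluster.clustering import (
    ClusterParams,
    cluster_time_series,
    coordination_vs_cluster_check,
    dbscan_pbc,
    mean_neighbors_within,
    pairwise_min_image_distances,
    swarm_radius_of_gyration,
    swarm_series,
)
from oilcluster.pbc import ComSeries, wrap_coordinates
from oilcluster.synth import gen_ideal_gas, gen_planted_clusters


def eps_graph_components(points, box, eps):
    """Brute-force connected components of the eps-neighborhood graph."""
    d = pairwise_min_image_distances(points, box)
    n = len(points)
    labels = np.full(n, -1)
    visited = np.zeros(n, dtype=bool)
    comp = 0
    for start in range(n):
        if visited[start]:
            continue
        stack = [start]
        members = []
        visited[start] = True
        while stack:
            i = stack.pop()
            members.append(i)
            for j in np.nonzero(d[i] <= eps)[0]:
                if not visited[j] and j != i:
                    visited[j] = True
                    stack.append(j)
        if len(members) >= 2:
            labels[members] = comp
            comp += 1
    # canonical ordering by smallest member index
    order = {}
    out = np.full(n, -1)
    nxt = 0
    for i in range(n):
        if labels[i] == -1:
            continue
        if labels[i] not in order:
            order[labels[i]] = nxt
            nxt += 1
        out[i] = order[labels[i]]
    return out


def test_dbscan_equals_eps_graph_components_many_random_configs():
    rng = np.random.default_rng(123)
    for _ in range(200):
        m = int(rng.integers(2, 200))
        L = float(rng.uniform(3.0, 8.0))
        eps = float(rng.uniform(0.2, 0.45)) * L / 2
        pts = rng.random((m, 3)) * L
        got = dbscan_pbc(pts, L, ClusterParams(eps=eps, min_samples=2))
        want = eps_graph_components(pts, L, eps)
        assert np.array_equal(got, want)


def test_planted_clusters_recovered_exactly():
    pts, truth = gen_planted_clusters(3, [20, 15, 10], spread=0.1, L=12.0, seed=5)
    labels = dbscan_pbc(pts, 12.0, ClusterParams(eps=0.65, min_samples=2))
    assert np.array_equal(labels, truth)


def test_face_straddling_cluster_is_one_cluster():
    rng = np.random.default_rng(8)
    L = 10.0
    blob = rng.normal(0, 0.15, (30, 3))
    centered = wrap_coordinates(blob + L / 2, L)
    straddling = wrap_coordinates(blob + np.array([L, L, L]) - 0.01, L)
    params = ClusterParams(eps=0.65)
    lab_c = dbscan_pbc(centered, L, params)
    lab_s = dbscan_pbc(straddling, L, params)
    assert np.array_equal(lab_c, lab_s)
    assert set(lab_s) == {0}


def test_isolated_point_is_noise():
    pts = np.array([[1.0, 1.0, 1.0], [4.0, 4.0, 4.0]])
    labels = dbscan_pbc(pts, 10.0, ClusterParams(eps=0.5, min_samples=2))
    assert np.array_equal(labels, [-1, -1])


def test_eps_too_large_rejected():
    with pytest.raises(ValueError, match="half the smallest box edge"):
        dbscan_pbc(np.zeros((3, 3)), 1.0, ClusterParams(eps=0.6))


def test_permutation_consistency():
    rng = np.random.default_rng(3)
    pts = rng.random((50, 3)) * 5.0
    perm = rng.permutation(50)
    params = ClusterParams(eps=0.8)
    base = dbscan_pbc(pts, 5.0, params)
    permuted = dbscan_pbc(pts[perm], 5.0, params)
    # same partition: co-membership must agree under the permutation
    same_base = (base[perm][:, None] == base[perm][None, :]) & (base[perm][:, None] >= 0)
    same_perm = (permuted[:, None] == permuted[None, :]) & (permuted[:, None] >= 0)
    assert np.array_equal(same_base, same_perm)


def test_cluster_time_series_extremes():
    # all molecules far apart -> nothing clustered
    grid = np.stack(np.meshgrid([1.0, 5.0], [1.0, 5.0], [1.0, 5.0]), -1).reshape(-1, 3)
    series = ComSeries(times=[0.0], coords=grid[None], box=[10.0] * 3)
    cts = cluster_time_series(series, ClusterParams(eps=0.5))
    assert cts.n_clusters[0] == 0 and cts.n_clustered[0] == 0
    # a chain of near neighbors -> one cluster holding everyone
    chain = np.stack([np.arange(8) * 0.4, np.zeros(8), np.zeros(8)], -1) + 1.0
    series = ComSeries(times=[0.0], coords=chain[None], box=[10.0] * 3)
    cts = cluster_time_series(series, ClusterParams(eps=0.5))
    assert cts.n_clusters[0] == 1 and cts.largest[0] == 8
    assert cts.sizes[0].sum() == cts.n_clustered[0]


def test_aggregation_run_clusters_grow(aggregation_small):
    oil = aggregation_small.subset("oil")
    cts = cluster_time_series(oil, ClusterParams(eps=0.65))
    smooth = np.convolve(cts.n_clustered, np.ones(10) / 10, mode="valid")
    # attractive-only dynamics: clustered population trends upward
    assert smooth[-1] > smooth[0]
    assert smooth[-1] >= 0.6 * oil.n_molecules


def test_swarm_rg_trivial_and_bounds():
    pts = np.tile([[2.0, 2.0, 2.0]], (5, 1))
    assert swarm_radius_of_gyration(pts, 10.0) == 0.0
    with pytest.warns(UserWarning, match="< 2 points"):
        assert swarm_radius_of_gyration(np.zeros((1, 3)), 10.0) == 0.0
    rng = np.random.default_rng(0)
    rg = swarm_radius_of_gyration(rng.random((100, 3)) * 10.0, 10.0)
    assert 0 <= rg <= np.sqrt(3) * 5.0


def test_swarm_rg_matches_unwrapped_for_straddling_blob():
    rng = np.random.default_rng(12)
    L = 10.0
    blob = rng.normal(0, 0.3, (200, 3))
    rg_direct = float(np.sqrt(((blob - blob.mean(0)) ** 2).sum(1).mean()))
    for shift in ([0, 0, 0], [L - 0.05, 0.02, L - 0.01], [L / 3, L - 0.1, 0.3]):
        wrapped = wrap_coordinates(blob + np.asarray(shift), L)
        assert swarm_radius_of_gyration(wrapped, L) == pytest.approx(
            rg_direct, abs=1e-9
        )


def test_swarm_rg_lattice_translation_invariant():
    rng = np.random.default_rng(21)
    L = 8.0
    pts = rng.random((60, 3)) * L
    shifted = wrap_coordinates(pts + L / 2, L)
    assert swarm_radius_of_gyration(pts, L) == pytest.approx(
        swarm_radius_of_gyration(shifted, L), abs=1e-9
    )


def test_swarm_shrinks_during_aggregation(aggregation_small):
    table = swarm_series(aggregation_small.subset("oil"))
    rg = table["rg_nm"].to_numpy()
    assert rg[-5:].mean() < 0.6 * rg[:5].mean()


def test_coordination_vs_cluster_check_ideal_gas():
    gas = gen_ideal_gas(N=400, L=8.0, n_frames=40, seed=2)
    eps = 0.8
    rho = 399 / 8.0**3
    expected = rho * 4.0 / 3.0 * np.pi * eps**3
    table = coordination_vs_cluster_check(gas, expected, eps, window=10)
    assert len(table) == 4
    assert np.allclose(table["mean_neighbors"], expected, rtol=0.15)


def test_coordination_vs_cluster_check_droplet_inequality(aggregation_small):
    oil = aggregation_small.subset("oil").sliced(slice(-10, None))
    eps = 0.65
    per_frame = mean_neighbors_within(oil, eps)
    rho = (oil.n_molecules - 1) / float(np.prod(oil.box))
    ideal = rho * 4.0 / 3.0 * np.pi * eps**3
    # a condensed droplet is far denser locally than the ideal-gas baseline
    assert per_frame.mean() > ideal


def test_coordination_vs_cluster_check_empty():
    empty = ComSeries(times=np.empty(0), coords=np.empty((0, 5, 3)), box=[5.0] * 3)
    assert coordination_vs_cluster_check(empty, 1.0, 0.5).empty
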