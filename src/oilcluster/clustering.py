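"""DBSCAN clustering of molecular centers of mass under periodic boundaries,
cluster-population time series, and the swarm radius of gyration.

Clustering operates on wrapped molecular COM coordinates with the
minimum-image metric.  The default ``min_samples`` of 2 makes every
non-noise point a core point, so the labeling equals the connected
components of the eps-neighborhood graph: a molecule is either part of a
cluster or freely floating — the dichotomy used to count clustered
molecules over time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .pbc import ComSeries, min_image


@dataclass(frozen=True)
class ClusterParams:
    """DBSCAN parameters: neighborhood radius ``eps`` (nm) and the
    core-point threshold ``min_samples``.

    ``eps`` defaults to 0.65 nm, a close-contact COM distance for terpenoid
    size molecules; prefer the first-shell boundary of the species' COM rdf
    when one is measurable.
    """

    eps: float = 0.65
    min_samples: int = 2

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


def pairwise_min_image_distances(points, box) -> np.ndarray:
    """Dense matrix of minimum-image distances between all point pairs."""
    x = np.asarray(points, dtype=float)
    delta = min_image(x[:, None, :] - x[None, :, :], box)
    return np.linalg.norm(delta, axis=-1)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by ascending smallest member index; noise stays -1."""
    out = np.full_like(labels, -1)
    next_id = 0
    seen: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == -1:
            continue
        if lab not in seen:
            seen[lab] = next_id
            next_id += 1
        out[i] = seen[lab]
    return out


def dbscan_pbc(points, box, params: ClusterParams = ClusterParams()) -> np.ndarray:
    """DBSCAN labels for wrapped points with the minimum-image metric.

    Returns one integer label per point; -1 marks noise (free molecules).
    Cluster IDs are assigned in order of each cluster's smallest member
    index, which makes the labeling deterministic and permutation-consistent.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("points must be (M, 3)")
    b = np.min(np.atleast_1d(np.asarray(box, dtype=float)))
    if params.eps >= b / 2:
        raise ValueError(
            f"eps={params.eps} must be < half the smallest box edge ({b / 2}); "
            "the minimum-image metric is ill-posed for larger neighborhoods"
        )
    if x.shape[0] == 0:
        return np.empty(0, dtype=int)
    if x.shape[0] == 1:
        return np.array([0 if params.min_samples <= 1 else -1])
    dist = pairwise_min_image_distances(x, box)
    labels = DBSCAN(
        eps=params.eps, min_samples=params.min_samples, metric="precomputed"
    ).fit_predict(dist)
    return _canonical_labels(labels)


@dataclass
class ClusterTimeSeries:
    """Per-frame cluster populations of one species."""

    times: np.ndarray
    labels: np.ndarray  # (T, M) int, -1 = free
    params: ClusterParams
    species: str = ""
    n_clusters: np.ndarray = field(init=False)
    n_clustered: np.ndarray = field(init=False)
    largest: np.ndarray = field(init=False)
    sizes: list = field(init=False)

    def __post_init__(self) -> None:
        T = self.labels.shape[0]
        self.n_clusters = np.zeros(T, dtype=int)
        self.n_clustered = np.zeros(T, dtype=int)
        self.largest = np.zeros(T, dtype=int)
        self.sizes = []
        for t in range(T):
            lab = self.labels[t]
            members = lab[lab >= 0]
            if members.size:
                counts = np.bincount(members)
                self.n_clusters[t] = counts.size
                self.n_clustered[t] = int(counts.sum())
                self.largest[t] = int(counts.max())
                self.sizes.append(np.sort(counts)[::-1])
            else:
                self.sizes.append(np.empty(0, dtype=int))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ps": self.times,
                "n_clusters": self.n_clusters,
                "n_clustered": self.n_clustered,
                "largest": self.largest,
            }
        )


def cluster_time_series(
    series: ComSeries, params: ClusterParams = ClusterParams()
) -> ClusterTimeSeries:
    """Cluster every frame of a wrapped COM series."""
    if not series.wrapped:
        raise ValueError("cluster_time_series expects a wrapped COM series")
    T, M = series.n_frames, series.n_molecules
    labels = np.empty((T, M), dtype=int)
    for t in range(T):
        labels[t] = dbscan_pbc(series.coords[t], series.box_at(t), params)
    return ClusterTimeSeries(
        times=series.times, labels=labels, params=params, species=series.species
    )


def _circular_center(points: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Translation-equivariant center of a periodic point set (per-axis
    circular mean: map each axis onto a circle, average the phase)."""
    theta = 2.0 * np.pi * points / box
    mean_angle = np.arctan2(np.sin(theta).mean(axis=0), np.cos(theta).mean(axis=0))
    return (box * mean_angle / (2.0 * np.pi)) % box


def swarm_radius_of_gyration(points, box) -> float:
    """PBC-aware radius of gyration of a point swarm (nm).

    The circular-mean center provides a translation-invariant reference;
    points are brought to their minimum images about it and the radius of
    gyration is taken about the mean of those images.  For a swarm compact
    relative to the cell this equals the radius of gyration of the unwrapped
    configuration; every molecule counts with equal weight.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("points must be (M, 3)")
    if x.shape[0] < 2:
        warnings.warn("swarm radius of gyration undefined for < 2 points; returning 0")
        return 0.0
    b = np.atleast_1d(np.asarray(box, dtype=float))
    if b.size == 1:
        b = np.repeat(b, 3)
    center = _circular_center(x, b)
    dev = min_image(x - center, b)
    dev = dev - dev.mean(axis=0)
    return float(np.sqrt((dev**2).sum(axis=1).mean()))


def swarm_series(series: ComSeries) -> pd.DataFrame:
    """Swarm radius of gyration per frame of a wrapped COM series."""
    if not series.wrapped:
        raise ValueError("swarm_series expects a wrapped COM series")
    rg = np.array(
        [
            swarm_radius_of_gyration(series.coords[t], series.box_at(t))
            for t in range(series.n_frames)
        ]
    )
    return pd.DataFrame({"time_ps": series.times, "rg_nm": rg})


def mean_neighbors_within(series: ComSeries, r_cut: float) -> np.ndarray:
    """Per-frame average number of other molecules within ``r_cut`` of each
    molecule (minimum-image distances)."""
    out = np.empty(series.n_frames)
    for t in range(series.n_frames):
        d = pairwise_min_image_distances(series.coords[t], series.box_at(t))
        np.fill_diagonal(d, np.inf)
        out[t] = (d <= r_cut).sum(axis=1).mean() if d.shape[0] else np.nan
    return out


def coordination_vs_cluster_check(
    series: ComSeries,
    coordination: float,
    r_cut: float,
    window: int = 10,
) -> pd.DataFrame:
    """Compare the direct neighbor count against the rdf coordination number.

    Averages the per-molecule neighbor count within ``r_cut`` over
    non-overlapping windows of ``window`` frames and tabulates it next to the
    rdf-integral coordination number computed on the same frames — the
    consistency check between cluster statistics and first-shell occupancy.
    """
    if series.n_frames == 0 or series.n_molecules == 0:
        return pd.DataFrame(
            columns=["t_start_ps", "t_end_ps", "mean_neighbors", "coordination_number"]
        )
    per_frame = mean_neighbors_within(series, r_cut)
    rows = []
    for start in range(0, series.n_frames, window):
        sl = slice(start, min(start + window, series.n_frames))
        rows.append(
            {
                "t_start_ps": series.times[sl][0],
                "t_end_ps": series.times[sl][-1],
                "mean_neighbors": float(np.mean(per_frame[sl])),
                "coordination_number": coordination,
            }
        )
    return pd.DataFrame(rows)
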