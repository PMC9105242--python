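"""Minimum-image arithmetic, molecule reassembly, centers of mass, and
trajectory unwrapping for orthorhombic periodic cells.

All coordinates are in nm and times in ps.  Boxes are orthorhombic edge
lengths ``(Lx, Ly, Lz)``; a scalar box is broadcast to a cube.  Wrapped
coordinates live in ``[0, L)`` per axis; minimum-image displacement
components live in ``[-L/2, L/2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np


def _as_box(box) -> np.ndarray:
    b = np.atleast_1d(np.asarray(box, dtype=float))
    if b.ndim == 1 and b.size == 1:
        b = np.repeat(b, 3)
    if b.shape[-1] != 3:
        raise ValueError(f"box must have 3 edge lengths, got shape {b.shape}")
    if np.any(b <= 0):
        raise ValueError("box edges must be positive")
    return b


def min_image(delta, box) -> np.ndarray:
    """Map displacement components into ``[-L/2, L/2)`` (minimum image)."""
    b = _as_box(box)
    d = np.asarray(delta, dtype=float)
    return d - b * np.floor(d / b + 0.5)


def min_image_vector(a, b, box) -> np.ndarray:
    """Minimum-image displacement from point ``a`` to point ``b``."""
    return min_image(np.asarray(b, dtype=float) - np.asarray(a, dtype=float), box)


def wrap_coordinates(coords, box) -> np.ndarray:
    """Wrap coordinates into the primary cell ``[0, L)`` per axis."""
    b = _as_box(box)
    x = np.asarray(coords, dtype=float)
    return x - b * np.floor(x / b)


def reassemble_molecule(coords, box) -> np.ndarray:
    """Make one molecule contiguous across periodic faces.

    The first atom anchors the molecule; each subsequent atom is placed at the
    minimum image relative to the previously placed atom (atoms of a molecule
    are stored contiguously, so chaining along storage order is the
    deterministic, bond-free reconstruction).  A consecutive pair separated by
    more than half a box edge *after* min-imaging indicates an unphysically
    stretched molecule and triggers a warning.
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("coords must be (n_atoms, 3)")
    if x.shape[0] == 1:
        return x.copy()
    b = _as_box(box)
    steps = min_image(np.diff(x, axis=0), b)
    if np.any(np.linalg.norm(steps, axis=1) > np.min(b) / 2):
        warnings.warn(
            "molecule spans more than half a box edge between consecutive "
            "atoms after reassembly; geometry may be unphysical",
            stacklevel=2,
        )
    out = np.empty_like(x)
    out[0] = x[0]
    out[1:] = x[0] + np.cumsum(steps, axis=0)
    return out


def center_of_mass(coords, masses) -> np.ndarray:
    """Mass-weighted mean position (no periodic handling)."""
    m = np.asarray(masses, dtype=float)
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    x = np.asarray(coords, dtype=float)
    return (m[:, None] * x).sum(axis=0) / m.sum()


@dataclass
class ComSeries:
    """Per-frame molecular centers of mass for one species.

    Attributes
    ----------
    times : (T,) float array, ps
    coords : (T, M, 3) float array, nm
    box : (3,) or (T, 3) float array, nm
    species : str
    wrapped : bool
        True if ``coords`` lie in ``[0, L)``; False for continuous
        (unwrapped) series suitable for displacement statistics.
    """

    times: np.ndarray
    coords: np.ndarray
    box: np.ndarray
    species: str = ""
    wrapped: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(_as_box(self.box), dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (T, M, 3)")
        if self.coords.shape[0] != self.times.shape[0]:
            raise ValueError("times and coords disagree on frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.coords.shape[1]

    def box_at(self, i: int) -> np.ndarray:
        return self.box if self.box.ndim == 1 else self.box[i]

    def mean_box(self) -> np.ndarray:
        return self.box if self.box.ndim == 1 else self.box.mean(axis=0)

    def sliced(self, sl) -> "ComSeries":
        box = self.box if self.box.ndim == 1 else self.box[sl]
        return replace(self, times=self.times[sl], coords=self.coords[sl], box=box)


def com_series(trajectory, species: str) -> ComSeries:
    """Wrapped center-of-mass series for every molecule of ``species``.

    Each molecule is reassembled across periodic faces first, then the
    mass-weighted center is taken and wrapped back into the primary cell.
    ``trajectory`` follows the container contract of
    :class:`oilcluster.io.Trajectory` (``times``, ``boxes``, ``coords``,
    ``topology``).
    """
    from .io import molecule_groups  # deferred: io imports pbc

    groups = molecule_groups(trajectory.topology, species)
    if not groups:
        raise ValueError(f"species {species!r} has no molecules")
    sizes = {len(g) for g in groups}
    masses = np.asarray(trajectory.topology.masses, dtype=float)
    T = len(trajectory.times)
    M = len(groups)
    out = np.empty((T, M, 3))
    if len(sizes) == 1:
        # homogeneous species: vectorize over molecules
        idx = np.asarray(groups)  # (M, n)
        m = masses[idx]  # (M, n)
        wsum = m.sum(axis=1)[:, None]
        for t in range(T):
            box = trajectory.boxes[t] if trajectory.boxes.ndim == 2 else trajectory.boxes
            x = trajectory.coords[t][idx]  # (M, n, 3)
            steps = min_image(np.diff(x, axis=1), box)
            xr = np.concatenate(
                [x[:, :1], x[:, :1] + np.cumsum(steps, axis=1)], axis=1
            )
            com = (m[..., None] * xr).sum(axis=1) / wsum
            out[t] = wrap_coordinates(com, box)
    else:
        for t in range(T):
            box = trajectory.boxes[t] if trajectory.boxes.ndim == 2 else trajectory.boxes
            for j, g in enumerate(groups):
                xr = reassemble_molecule(trajectory.coords[t][g], box)
                out[t, j] = wrap_coordinates(center_of_mass(xr, masses[g]), box)
    return ComSeries(
        times=np.asarray(trajectory.times, dtype=float),
        coords=out,
        box=np.asarray(trajectory.boxes, dtype=float),
        species=species,
        wrapped=True,
    )


def unwrap(series: ComSeries) -> ComSeries:
    """Remove periodic jumps from a wrapped COM series.

    Assumes no molecule truly moves half a box edge or more between saved
    frames, so the frame-to-frame displacement equals the minimum image of
    the wrapped difference.
    """
    if not series.wrapped:
        return series
    x = series.coords
    out = np.empty_like(x)
    out[0] = x[0]
    if series.n_frames > 1:
        if series.box.ndim == 1:
            steps = min_image(np.diff(x, axis=0), series.box)
        else:
            steps = np.stack(
                [
                    min_image(x[t + 1] - x[t], series.box[t + 1])
                    for t in range(series.n_frames - 1)
                ]
            )
        out[1:] = x[0] + np.cumsum(steps, axis=0)
    return replace(series, coords=out, wrapped=False)
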