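"""Center-of-mass radial distribution functions, coordination numbers,
first-shell detection, and the spherical-cap micelle surface model.

The rdf estimator normalizes per-bin pair counts by the ideal-gas
expectation.  Inside half the smallest box edge the spherical shell is
entirely contained in the minimum-image cell and the analytic volume
``4/3 pi (r2^3 - r1^3)`` applies; beyond, up to the maximal minimum-image
distance ``sqrt(3) L / 2`` of a cubic cell, the effective shell volume is
the intersection of the shell with the Wigner-Seitz cell.  That volume is
estimated once per (box, binning) by Monte-Carlo sampling of the
minimum-image displacement of uniform point pairs and cached, extending the
estimator beyond half the cell edge while keeping an ideal gas flat at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.signal import find_peaks

from .pbc import ComSeries, min_image

_SHELL_WEIGHT_CACHE: dict[tuple, np.ndarray] = {}


def shell_volumes(
    edges: np.ndarray,
    box,
    extended: bool = False,
    mc_samples: int = 10_000_000,
    mc_seed: int = 12345,
) -> np.ndarray:
    """Effective minimum-image shell volume per bin (nm^3).

    Analytic full-shell volumes are used for bins entirely inside the
    inscribed sphere of radius ``min(L)/2``; in extended mode the remaining
    bins use cached Monte-Carlo weights (uniform displacements over the
    Wigner-Seitz cell, a fixed-seed estimate shared across calls).
    """
    b = np.atleast_1d(np.asarray(box, dtype=float))
    if b.size == 1:
        b = np.repeat(b, 3)
    edges = np.asarray(edges, dtype=float)
    full = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    r_half = float(np.min(b)) / 2.0
    if not extended:
        return full
    inside = edges[1:] <= r_half
    if inside.all():
        return full
    key = (tuple(np.round(b, 9)), tuple(np.round(edges, 9)), mc_samples, mc_seed)
    if key not in _SHELL_WEIGHT_CACHE:
        # Direction-sampling estimator: for a direction u the Wigner-Seitz
        # cell bounds the radius at rho(u) = min_i (L_i/2) / |u_i|, so the
        # cumulative cell-limited volume is V(r) = (4pi/3) E[min(r, rho)^3].
        # Every sampled direction contributes its exact radial extent to
        # every bin, which beats naive point-in-shell counting by orders of
        # magnitude in variance near the cell corners.
        rng = np.random.default_rng(mc_seed)
        nbins = edges.size - 1
        counts = np.zeros(nbins + 1, dtype=np.int64)  # [+ overflow at r_max]
        sum3 = np.zeros(nbins + 1)
        chunk = 1_000_000
        done = 0
        half = b / 2.0
        while done < mc_samples:
            m = min(chunk, mc_samples - done)
            u = rng.normal(size=(m, 3))
            u /= np.linalg.norm(u, axis=1)[:, None]
            rho = np.min(half / np.abs(u), axis=1)
            idx = np.clip(np.searchsorted(edges, rho, side="right") - 1, 0, nbins)
            np.add.at(counts, idx, 1)
            np.add.at(sum3, idx, rho**3)
            done += m
        prefix_count = np.concatenate([[0], np.cumsum(counts)])
        prefix_sum3 = np.concatenate([[0.0], np.cumsum(sum3)])
        # V at each bin edge j: directions already clipped below edge_j keep
        # rho^3, the rest contribute edge_j^3
        v_edges = (
            (4.0 * np.pi / 3.0)
            / mc_samples
            * (prefix_sum3[: nbins + 1] + edges**3 * (mc_samples - prefix_count[: nbins + 1]))
        )
        _SHELL_WEIGHT_CACHE[key] = np.diff(v_edges)
    out = full.copy()
    mc = _SHELL_WEIGHT_CACHE[key]
    out[~inside] = mc[~inside]
    return out


def pair_distance_counts(
    xa: np.ndarray,
    xb: np.ndarray,
    box,
    edges: np.ndarray,
    exclude_diagonal: bool,
) -> np.ndarray:
    """Histogram of minimum-image distances between two point sets.

    Counts ordered pairs (one point from ``xa``, one from ``xb``).  With
    ``exclude_diagonal`` the pair ``(i, i)`` is skipped — used when both sets
    index the same molecules (self-pairs of a like-species rdf, or the
    ``i == j`` term of the distinct van Hove function).
    """
    delta = min_image(xa[:, None, :] - xb[None, :, :], box)
    r = np.linalg.norm(delta, axis=-1)
    if exclude_diagonal:
        np.fill_diagonal(r, -1.0)  # lands below the first edge
    return np.histogram(r, bins=edges)[0]


@dataclass
class RDFResult:
    """Binned center-of-mass pair distribution function g(r).

    ``n_r`` is the cumulative mean neighbor count at the right edge of each
    bin (raw counts per reference molecule); within half the box edge it is
    the binned equivalent of the coordination integral of
    ``4 pi s^2 rho g(s)``, and at the maximal minimum-image distance it
    exhausts all partner molecules.
    """

    pair: tuple[str, str]
    edges: np.ndarray
    g: np.ndarray
    counts: np.ndarray
    rho_partner: float
    n_frames: int
    n_reference: int
    extended: bool
    box: np.ndarray
    n_r: np.ndarray = None

    def __post_init__(self) -> None:
        if self.n_r is None:
            self.n_r = np.cumsum(self.counts) / (self.n_frames * self.n_reference)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def rdf_com(
    series_a: ComSeries,
    series_b: ComSeries | None = None,
    bin_width: float = 0.02,
    r_max: float | None = None,
    extended: bool = False,
    mc_samples: int = 10_000_000,
    mc_seed: int = 12345,
) -> RDFResult:
    """Radial distribution function of molecular centers of mass.

    Pass a single series for a like-species rdf (self-pairs excluded) or two
    series sharing the same frames for a distinct-species pair; the partner
    density ``rho_b`` normalizes the result.  ``r_max`` is bounded by half
    the smallest box edge, or ``sqrt(3)/2`` times it in extended mode.
    """
    same = series_b is None or series_b is series_a
    sb = series_a if same else series_b
    if not (series_a.wrapped and sb.wrapped):
        raise ValueError("rdf_com expects wrapped COM series")
    if not same and not np.array_equal(series_a.times, sb.times):
        raise ValueError("rdf pair series must share identical frames")
    box = series_a.mean_box()
    r_half = float(np.min(box)) / 2.0
    bound = np.sqrt(3.0) * r_half if extended else r_half
    if r_max is None:
        r_max = bound
    if r_max > bound * (1 + 1e-12):
        mode = "extended" if extended else "standard"
        raise ValueError(f"r_max={r_max} exceeds the {mode}-mode bound {bound:.6g}")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max * (1 + 1e-12)]
    if edges[-1] < r_max - 1e-12:
        edges = np.append(edges, r_max)
    T = series_a.n_frames
    counts = np.zeros(edges.size - 1, dtype=np.int64)
    for t in range(T):
        fb = series_a.box_at(t)
        counts += pair_distance_counts(
            series_a.coords[t], sb.coords[t], fb, edges, exclude_diagonal=same
        )
    n_a = series_a.n_molecules
    n_b = sb.n_molecules
    volume = float(np.prod(box))
    rho_b = (n_b - (1 if same else 0)) / volume
    vshell = shell_volumes(edges, box, extended=extended, mc_samples=mc_samples, mc_seed=mc_seed)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = counts / (T * n_a * rho_b * vshell)
    g = np.nan_to_num(g, nan=0.0, posinf=0.0)
    return RDFResult(
        pair=(series_a.species, sb.species),
        edges=edges,
        g=g,
        counts=counts,
        rho_partner=rho_b,
        n_frames=T,
        n_reference=n_a,
        extended=extended,
        box=np.asarray(box, dtype=float),
    )


def coordination_number(rdf: RDFResult, r_cut: float) -> float:
    """Average number of partner molecules within ``r_cut`` of a reference.

    The integral of the shell-weighted rdf, ``int 4 pi s^2 rho g(s) ds``,
    evaluated from the binned cumulative neighbor count (the two coincide
    inside half the box edge; the count form stays exact beyond, where
    shells are no longer full spheres).
    """
    if r_cut < 0:
        raise ValueError("r_cut must be non-negative")
    if r_cut > rdf.edges[-1] + 1e-12:
        raise ValueError(f"r_cut={r_cut} exceeds rdf range {rdf.edges[-1]}")
    grid = np.concatenate([[0.0], rdf.edges[1:]])
    vals = np.concatenate([[0.0], rdf.n_r])
    return float(np.interp(r_cut, grid, vals))


def first_shell_boundary(
    rdf: RDFResult,
    smooth_window: int = 5,
    prominence: float = 0.2,
) -> float | None:
    """Radius of the minimum between the first and second rdf peaks (nm).

    The curve is smoothed with a centered moving average before peak
    detection; a first peak must exceed the ``prominence`` threshold,
    otherwise the structure has no detectable shell and ``None`` is
    returned.  Flat valleys resolve to their leftmost point.
    """
    g = np.asarray(rdf.g, dtype=float)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        gp = np.pad(g, pad, mode="edge")
        g = np.convolve(gp, kernel, mode="valid")[: rdf.g.size]
    # a leading zero lets a maximum in the first bin count as a peak (a
    # condensed aggregate's COM rdf can decay monotonically from r = 0)
    peaks, _ = find_peaks(np.concatenate([[0.0], g]), prominence=prominence)
    peaks = peaks - 1
    if peaks.size == 0:
        return None
    p1 = peaks[0]
    centers = rdf.centers
    if peaks.size > 1:
        p2 = peaks[1]
        valley = p1 + int(np.argmin(g[p1 : p2 + 1]))  # argmin ties -> leftmost
        return float(centers[valley])
    seg = g[p1:]
    # first strict local minimum after the peak (flat stretches end at their
    # leftmost point because the right-hand comparison is strict)
    for i in range(1, seg.size - 1):
        if seg[i] <= seg[i - 1] and seg[i] < seg[i + 1]:
            return float(centers[p1 + i])
    # monotone decay past the peak (an isolated aggregate): the shell ends
    # where the curve first reaches its floor
    return float(centers[p1 + int(np.argmin(seg))])


def cap_area(x: float, R: float, extrapolate: bool = False) -> float:
    """Surface area of a spherical cap probed at distance ``x`` (nm^2).

    For a reference point on the surface of a sphere of radius ``R``, the
    locus of points of the sphere at distance ``x`` sweeps a cap of area
    ``A = 2 pi x^2 (1 - x / (2R))``, which vanishes at ``x = 0`` and
    ``x = 2R``.  ``extrapolate`` permits evaluating the polynomial outside
    ``[0, 2R]`` (e.g. for root bracketing).
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if not extrapolate and not (0.0 <= x <= 2.0 * R):
        raise ValueError(f"x={x} outside the cap domain [0, {2 * R}]")
    return 2.0 * np.pi * x**2 * (1.0 - x / (2.0 * R))


def cap_argmax(R: float) -> float:
    """Probe distance maximizing the cap area, found as the root of dA/dx."""
    if R <= 0:
        raise ValueError("R must be positive")
    # dA/dx = 4 pi x - 3 pi x^2 / R; positive near 0, negative at 2R
    return float(brentq(lambda x: 4.0 * np.pi * x - 3.0 * np.pi * x**2 / R, 1e-9 * R, 2.0 * R))


def cap_roots(R: float, upper: float | None = None, grid: int = 3000) -> np.ndarray:
    """Roots of the cap-area polynomial on ``(0, upper]`` (default 3R).

    Found by sign-change bracketing on a dense grid followed by bisection;
    grid points that are themselves (numerically) zero are kept as roots.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if upper is None:
        upper = 3.0 * R
    xs = np.linspace(1e-3 * R, upper, grid)
    vals = np.array([cap_area(x, R, extrapolate=True) for x in xs])
    roots: list[float] = []
    tol = 1e-12 * max(1.0, R**2)
    for i in range(xs.size - 1):
        if abs(vals[i]) < tol:
            roots.append(float(xs[i]))
        elif vals[i] * vals[i + 1] < 0:
            roots.append(
                float(brentq(lambda x: cap_area(x, R, extrapolate=True), xs[i], xs[i + 1]))
            )
    if abs(vals[-1]) < tol:
        roots.append(float(xs[-1]))
    dedup: list[float] = []
    for r in roots:
        if not dedup or abs(r - dedup[-1]) > 1e-9 * R:
            dedup.append(r)
    return np.asarray(dedup)
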