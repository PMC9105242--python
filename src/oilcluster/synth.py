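"""Seeded synthetic generators with known ground truth.

These generators emulate the statistical structure of terpenoid/polymer
solution trajectories at the molecular-center-of-mass level so that every
analysis stage can be validated without molecular dynamics data: uniform
ideal gases (flat g(r)), free Brownian walkers with known D, an overdamped
Langevin aggregation model of hydrophobic solutes plus amphiphilic
carriers (with an optional carrier-carrier screened repulsion emulating a
partially screened polyelectrolyte versus a neutral polymer), planted
cluster configurations, and stationary two-state (on/off) bond processes
with a closed-form autocorrelation.

All generators are pure functions of their parameters and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pbc import ComSeries, min_image, wrap_coordinates


def gen_ideal_gas(N: int, L: float, n_frames: int, seed: int, dt: float = 1.0) -> ComSeries:
    """Independent uniform points in a cubic box, re-drawn every frame."""
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    coords = rng.random((n_frames, N, 3)) * L
    return ComSeries(
        times=np.arange(n_frames) * dt,
        coords=coords,
        box=np.array([L, L, L]),
        species="ideal",
        wrapped=True,
    )


@dataclass
class BrownianResult:
    """Free Brownian walkers: the exact unwrapped series and, when a box is
    given, its wrapped twin (identical up to periodic wrapping)."""

    unwrapped: ComSeries
    wrapped: ComSeries | None
    D: float


def gen_brownian(
    N: int,
    D: float,
    dt: float,
    steps: int,
    seed: int,
    box: float | None = None,
) -> BrownianResult:
    """Isotropic Brownian motion: Gaussian increments of variance 2 D dt
    per axis.  Walkers start uniformly in the box (or at the origin region
    of a nominal cell when no box is given)."""
    if D < 0:
        raise ValueError("D must be >= 0")
    rng = np.random.default_rng(seed)
    L = box if box is not None else 1.0
    x0 = rng.random((N, 3)) * L
    steps_arr = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(steps, N, 3))
    coords = np.concatenate([x0[None], x0[None] + np.cumsum(steps_arr, axis=0)])
    times = np.arange(steps + 1) * dt
    # the unwrapped series needs a box only as metadata; use a cell large
    # enough that min-image arithmetic never clips a true displacement
    span = max(L, 4.0 * float(np.abs(coords).max()) + 1.0)
    unwrapped = ComSeries(
        times=times,
        coords=coords,
        box=np.array([span] * 3) if box is None else np.array([L] * 3),
        species="brownian",
        wrapped=False,
    )
    wrapped = None
    if box is not None:
        wrapped = ComSeries(
            times=times,
            coords=wrap_coordinates(coords, np.array([L] * 3)),
            box=np.array([L] * 3),
            species="brownian",
            wrapped=True,
        )
    return BrownianResult(unwrapped=unwrapped, wrapped=wrapped, D=D)


@dataclass(frozen=True)
class AggregationParams:
    """Overdamped Langevin aggregation model (energies in kT, lengths nm,
    times ps).

    ``n_oil`` hydrophobic solutes and ``n_polymer`` carriers interact through
    a smoothed square-well attraction (depth ``eps_attr``, range ``r_well``)
    acting on oil-oil and oil-polymer pairs, plus a bounded soft-core
    repulsion whose contact distance is pair-additive in the per-role core
    radii (``r_core_oil``/``r_core_polymer`` are the same-pair contact
    diameters).  The larger carrier core emulates the bulky amphiphile: it
    attaches to solute aggregates but cannot pack into their interior, so
    carriers accumulate at the aggregate surface.  With ``repulsion`` on,
    polymer-polymer pairs additionally feel a screened (Yukawa-like)
    repulsion ``A_rep * exp(-r / lam)`` — the partially screened
    polyelectrolyte scenario; off corresponds to a neutral carrier.
    """

    n_oil: int = 60
    n_polymer: int = 8
    L: float = 6.5
    D_oil: float = 0.1
    D_polymer: float = 0.05
    eps_attr: float = 6.0
    r_well: float = 1.2
    repulsion: bool = False
    A_rep: float = 12.0
    lam: float = 1.8
    eps_core: float = 10.0
    r_core_oil: float = 0.35
    r_core_polymer: float = 0.7
    dt: float = 0.02
    steps: int = 45000
    save_stride: int = 225
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L <= 2.0 * self.r_well:
            raise ValueError("box edge must exceed twice the well range")
        step_rms = np.sqrt(2.0 * max(self.D_oil, self.D_polymer) * self.dt)
        if step_rms >= self.r_well / 4.0:
            raise ValueError(
                f"diffusive step {step_rms:.3g} nm too large for well range "
                f"{self.r_well} nm; reduce dt (stability guard)"
            )


def hpg_like(seed: int, **overrides) -> AggregationParams:
    """Neutral-carrier preset: attraction only, no carrier-carrier repulsion
    (single-nanodroplet phenomenology)."""
    return replace(AggregationParams(seed=seed, repulsion=False), **overrides)


def hbpei_like(seed: int, **overrides) -> AggregationParams:
    """Charged-carrier preset: carrier-carrier screened repulsion on
    (dispersed small-cluster phenomenology)."""
    return replace(AggregationParams(seed=seed, repulsion=True), **overrides)


@dataclass
class AggregationResult:
    """Aggregation trajectory: wrapped and unwrapped COM series for the full
    system, a per-molecule role array, and the generating parameters."""

    wrapped: ComSeries
    unwrapped: ComSeries
    roles: np.ndarray  # 'oil' / 'polymer' per molecule
    params: AggregationParams

    def subset(self, role: str) -> ComSeries:
        idx = np.nonzero(self.roles == role)[0]
        return replace(
            self.wrapped, coords=self.wrapped.coords[:, idx], species=role
        )


def _pair_force_profile(r, eattr, arep, rcore, p: AggregationParams):
    """Scalar -dU/dr for every pair (positive = repulsive push apart)."""
    f = np.zeros_like(r)
    # soft core: U = eps_core (1 - r/r_core)^2, bounded force
    core = r < rcore
    f[core] += 2.0 * p.eps_core * (1.0 - r[core] / rcore[core]) / rcore[core]
    # smoothed square well: flat at -eps inside r_on, cubic switch to 0;
    # the switch spans half the well so forces stay overdamped-integrable
    r_on = 0.5 * p.r_well
    w = p.r_well - r_on
    rim = (r >= r_on) & (r < p.r_well)
    u = (r[rim] - r_on) / w
    f[rim] += -6.0 * eattr[rim] * u * (1.0 - u) / w  # attraction (pull together)
    # screened repulsion between charged carriers
    if np.any(arep):
        act = arep > 0
        f[act] += (arep[act] / p.lam) * np.exp(-r[act] / p.lam)
    return f


def gen_aggregation(params: AggregationParams) -> AggregationResult:
    """Integrate the overdamped Langevin aggregation model.

    Euler-Maruyama step ``x += D dt F + sqrt(2 D dt) xi`` (kT = 1) with
    minimum-image pair forces; positions are tracked unwrapped and saved
    every ``save_stride`` steps (frame 0 included).
    """
    p = params
    N = p.n_oil + p.n_polymer
    roles = np.array(["oil"] * p.n_oil + ["polymer"] * p.n_polymer)
    rng = np.random.default_rng(p.seed)
    box = np.array([p.L] * 3)
    x = rng.random((N, 3)) * p.L  # unwrapped running positions
    D = np.where(roles == "oil", p.D_oil, p.D_polymer)[:, None]
    is_poly = roles == "polymer"
    eattr = np.full((N, N), p.eps_attr)
    eattr[np.ix_(is_poly, is_poly)] = 0.0
    arep = np.zeros((N, N))
    if p.repulsion:
        arep[np.ix_(is_poly, is_poly)] = p.A_rep
    np.fill_diagonal(eattr, 0.0)
    np.fill_diagonal(arep, 0.0)
    radius = np.where(is_poly, p.r_core_polymer / 2.0, p.r_core_oil / 2.0)
    rcore = radius[:, None] + radius[None, :]

    frames = [x.copy()]
    save_at = set(range(p.save_stride, p.steps + 1, p.save_stride))
    noise_scale = np.sqrt(2.0 * D * p.dt)
    for step in range(1, p.steps + 1):
        delta = min_image(x[:, None, :] - x[None, :, :], box)
        r = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(r, np.inf)
        fmag = _pair_force_profile(r, eattr, arep, rcore, p)
        force = (fmag[:, :, None] * delta / r[:, :, None]).sum(axis=1)
        x = x + D * p.dt * force + noise_scale * rng.normal(size=(N, 3))
        if step in save_at:
            frames.append(x.copy())
    coords = np.stack(frames)
    times = np.arange(coords.shape[0]) * (p.save_stride * p.dt)
    unwrapped = ComSeries(
        times=times, coords=coords, box=box, species="aggregation", wrapped=False
    )
    wrapped = ComSeries(
        times=times,
        coords=wrap_coordinates(coords, box),
        box=box,
        species="aggregation",
        wrapped=True,
    )
    if not np.isfinite(coords).all():
        raise FloatingPointError("aggregation generator produced non-finite coordinates")
    return AggregationResult(wrapped=wrapped, unwrapped=unwrapped, roles=roles, params=p)


def gen_planted_clusters(
    k: int,
    sizes,
    spread: float,
    L: float,
    seed: int,
    eps_test: float = 0.65,
    max_tries: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Well-separated Gaussian blobs in a periodic cube with ground truth.

    Cluster centers keep pairwise minimum-image separations of at least
    ``5 * (spread + eps_test)`` so that an eps-graph with ``eps <= eps_test``
    can never merge blobs; the first center sits at the cell corner so at
    least one blob straddles periodic faces.  Returns ``(points, labels)``
    with points wrapped; a blob of size 1 is labeled -1 (noise under the
    default core threshold of 2).
    """
    sizes = np.asarray(sizes, dtype=int)
    if sizes.size != k:
        raise ValueError("sizes must list one size per cluster")
    min_sep = 5.0 * (spread + eps_test)
    if k > 1 and min_sep >= L / 2:
        raise ValueError("box too small for the requested separation guarantee")
    rng = np.random.default_rng(seed)
    centers = [np.zeros(3)]  # corner blob straddles all faces
    tries = 0
    while len(centers) < k:
        cand = rng.random(3) * L
        d = min_image(cand - np.array(centers), L)
        if np.all(np.linalg.norm(d, axis=-1) >= min_sep):
            centers.append(cand)
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place cluster centers; box too crowded")
    pts, labels = [], []
    for j, (c, n) in enumerate(zip(centers, sizes)):
        pts.append(c + rng.normal(0.0, spread, size=(n, 3)))
        labels.extend([j if n >= 2 else -1] * n)
    points = wrap_coordinates(np.concatenate(pts), np.array([L] * 3))
    return points, np.asarray(labels)


@dataclass
class MarkovBondSeries:
    """Independent stationary two-state (off/on) chains sampled on a grid.

    ``occupancy`` is the (T, n_chains) 0/1 matrix; the process has
    equilibrium occupancy ``p = k_on / (k_on + k_off)`` and autocorrelation
    ``C(t) = p + (1 - p) exp(-(k_on + k_off) t)``.
    """

    times: np.ndarray
    occupancy: np.ndarray
    k_on: float
    k_off: float

    @property
    def p(self) -> float:
        return self.k_on / (self.k_on + self.k_off)

    def analytic_acf(self, t) -> np.ndarray:
        k = self.k_on + self.k_off
        return self.p + (1.0 - self.p) * np.exp(-k * np.asarray(t, dtype=float))


def gen_markov_bonds(
    k_on: float,
    k_off: float,
    dt: float,
    steps: int,
    n_chains: int,
    seed: int,
) -> MarkovBondSeries:
    """Simulate stationary on/off bond indicator chains.

    Transition probabilities over one sampling interval are the exact
    two-state propagator, so the sampled chain is Markov at the grid spacing
    and its autocorrelation matches the closed form at the sampled lags.
    """
    if k_on < 0 or k_off < 0 or k_on + k_off <= 0:
        raise ValueError("rates must be non-negative with k_on + k_off > 0")
    rng = np.random.default_rng(seed)
    k = k_on + k_off
    p = k_on / k
    decay = np.exp(-k * dt)
    p_off_to_on = p * (1.0 - decay)
    p_on_to_off = (1.0 - p) * (1.0 - decay)
    state = (rng.random(n_chains) < p).astype(np.uint8)
    occ = np.empty((steps + 1, n_chains), dtype=np.uint8)
    occ[0] = state
    for t in range(1, steps + 1):
        u = rng.random(n_chains)
        flip = np.where(state == 1, u < p_on_to_off, u < p_off_to_on)
        state = np.where(flip, 1 - state, state).astype(np.uint8)
        occ[t] = state
    return MarkovBondSeries(
        times=np.arange(steps + 1) * dt, occupancy=occ, k_on=k_on, k_off=k_off
    )
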