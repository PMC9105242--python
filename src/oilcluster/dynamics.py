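"""Mean square displacement, Einstein-relation diffusion, and self/distinct
van Hove correlation functions.

The self part works on unwrapped center-of-mass series (true transport);
the distinct part works on wrapped coordinates with minimum-image distances
(local structure), so that its zero-lag limit reproduces the pair
distribution function bin for bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pbc import ComSeries
from .structure import RDFResult, first_shell_boundary, pair_distance_counts, shell_volumes


def _default_lags(n_frames: int, n_lags: int = 200) -> np.ndarray:
    """Zero plus ~n_lags distinct integer lags up to half the series length."""
    top = max(n_frames // 2, 1)
    lags = np.unique(np.round(np.linspace(0, top, min(n_lags, top) + 1)).astype(int))
    return lags


@dataclass
class MSDResult:
    """Multi-origin mean square displacement.

    ``lag_times`` in ps, ``msd`` in nm^2, ``n_samples`` = origins x molecules
    contributing at each lag.
    """

    lag_times: np.ndarray
    msd: np.ndarray
    n_samples: np.ndarray


def msd(
    series: ComSeries,
    lags: np.ndarray | None = None,
    origin_stride: int = 10,
) -> MSDResult:
    """Mean square displacement averaged over molecules and time origins.

    ``lags`` are integer frame separations (default: ~200 lags spanning half
    the series); origins are taken every ``origin_stride`` frames.
    """
    if series.wrapped:
        raise ValueError("msd requires an unwrapped COM series (see pbc.unwrap)")
    x = series.coords
    T = series.n_frames
    if lags is None:
        lags = _default_lags(T)
    lags = np.asarray(lags, dtype=int)
    if np.any(lags < 0) or np.any(lags >= T):
        raise ValueError("lags must lie in [0, n_frames)")
    dt_frame = series.times[1] - series.times[0] if T > 1 else 0.0
    out = np.empty(lags.size)
    ns = np.empty(lags.size, dtype=int)
    for k, lag in enumerate(lags):
        origins = np.arange(0, T - lag, origin_stride)
        d = x[origins + lag] - x[origins]
        out[k] = (d**2).sum(axis=-1).mean()
        ns[k] = origins.size * series.n_molecules
    return MSDResult(lag_times=lags * dt_frame, msd=out, n_samples=ns)


@dataclass
class DiffusionFit:
    """Linear Einstein-relation fit MSD = 6 D t over a lag window.

    ``D`` in nm^2/ps; ``D_cm2_s`` applies the exact conversion
    1 nm^2/ps = 1e-18 m^2 / 1e-12 s = 1e-6 m^2/s = 1e-2 cm^2/s.
    ``diffusive`` flags whether the log-log slope of the window is within
    0.1 of 1 (a ballistic or trapped regime fails this check).
    """

    D: float
    slope: float
    intercept: float
    r_squared: float
    window: tuple[float, float]
    alpha: float
    diffusive: bool

    @property
    def D_cm2_s(self) -> float:
        return self.D * 1e-2


def fit_diffusion(result: MSDResult, window: tuple[float, float] | None = None) -> DiffusionFit:
    """Least-squares line through MSD(t) on a lag window; D = slope / 6.

    The default window spans 10-50% of the maximum lag, past ballistic /
    short-time noise but before the poorly-sampled tail.
    """
    tmax = result.lag_times[-1]
    if window is None:
        window = (0.1 * tmax, 0.5 * tmax)
    lo, hi = window
    mask = (result.lag_times >= lo) & (result.lag_times <= hi)
    if mask.sum() < 3:
        raise ValueError(f"fit window {window} holds {int(mask.sum())} points; need >= 3")
    t = result.lag_times[mask]
    y = result.msd[mask]
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    pos = (t > 0) & (y > 0)
    alpha = float(np.polyfit(np.log(t[pos]), np.log(y[pos]), 1)[0]) if pos.sum() >= 2 else np.nan
    return DiffusionFit(
        D=float(slope) / 6.0,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        window=(float(lo), float(hi)),
        alpha=alpha,
        diffusive=bool(abs(alpha - 1.0) <= 0.1),
    )


@dataclass
class VanHoveSelf:
    """Self van Hove displacement distributions.

    ``p`` holds ``4 pi r^2 G_s(r; t)`` per lag, normalized so that
    ``sum(p * dr) == 1``; ``msd`` is the raw (unbinned) second moment of the
    displacement magnitudes at each lag.
    """

    lag_times: np.ndarray
    edges: np.ndarray
    p: np.ndarray  # (n_lags, n_bins)
    msd: np.ndarray
    n_samples: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def van_hove_self(
    series: ComSeries,
    lags: np.ndarray | None = None,
    bin_width: float = 0.02,
    r_max: float | None = None,
    origin_stride: int = 10,
) -> VanHoveSelf:
    """Distribution of single-molecule displacement magnitudes per lag."""
    if series.wrapped:
        raise ValueError("van_hove_self requires an unwrapped COM series")
    x = series.coords
    T = series.n_frames
    if lags is None:
        lags = _default_lags(T, n_lags=8)
    lags = np.asarray(lags, dtype=int)
    if np.any(lags < 0) or np.any(lags >= T):
        raise ValueError("lags must lie in [0, n_frames)")
    dt_frame = series.times[1] - series.times[0] if T > 1 else 0.0
    if r_max is None:
        # generous bound: largest displacement across the requested lags
        lag_max = int(lags.max())
        origins = np.arange(0, T - lag_max, origin_stride) if lag_max < T else np.array([0])
        if lag_max > 0 and origins.size:
            d = np.linalg.norm(x[origins + lag_max] - x[origins], axis=-1)
            r_max = max(float(d.max()) * 1.05, bin_width)
        else:
            r_max = bin_width
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    p = np.zeros((lags.size, edges.size - 1))
    m2 = np.zeros(lags.size)
    ns = np.zeros(lags.size, dtype=int)
    for k, lag in enumerate(lags):
        origins = np.arange(0, T - lag, origin_stride)
        r = np.linalg.norm(x[origins + lag] - x[origins], axis=-1).ravel()
        counts = np.histogram(r, bins=edges)[0]
        total = r.size
        p[k] = counts / (total * bin_width)
        m2[k] = float((r**2).mean())
        ns[k] = total
    return VanHoveSelf(lag_times=lags * dt_frame, edges=edges, p=p, msd=m2, n_samples=ns)


@dataclass
class VanHoveDistinct:
    """Distinct van Hove function normalized by the partner density.

    ``gd`` holds ``G_d(r; t) / rho`` per lag (dimensionless); the zero-lag
    row equals the like-species rdf ``g(r)`` computed on the same frames.
    """

    lag_times: np.ndarray
    edges: np.ndarray
    gd: np.ndarray  # (n_lags, n_bins)
    counts: np.ndarray
    rho: float
    n_reference: int
    n_origins: np.ndarray
    box: np.ndarray
    species: str = ""

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def as_rdf(self, lag_index: int = 0) -> RDFResult:
        """View one lag as an RDFResult (for shell detection, etc.)."""
        return RDFResult(
            pair=(self.species, self.species),
            edges=self.edges,
            g=self.gd[lag_index],
            counts=self.counts[lag_index],
            rho_partner=self.rho,
            n_frames=int(self.n_origins[lag_index]),
            n_reference=self.n_reference,
            extended=False,
            box=self.box,
        )


def van_hove_distinct(
    series: ComSeries,
    lags: np.ndarray | None = None,
    bin_width: float = 0.02,
    r_max: float | None = None,
    origin_stride: int = 1,
) -> VanHoveDistinct:
    """Density of *other* molecules at distance r after a time lag.

    For each lag t, histograms the minimum-image distance between molecule i
    at the origin frame and molecule j != i at the lagged frame, normalized
    exactly like an rdf (ideal-gas shell volume and partner density), so an
    uncorrelated system sits at 1 everywhere and the zero-lag curve is g(r).
    """
    if not series.wrapped:
        raise ValueError("van_hove_distinct requires a wrapped COM series")
    x = series.coords
    T, M = series.n_frames, series.n_molecules
    if lags is None:
        lags = _default_lags(T, n_lags=8)
    lags = np.asarray(lags, dtype=int)
    if np.any(lags < 0) or np.any(lags >= T):
        raise ValueError("lags must lie in [0, n_frames)")
    dt_frame = series.times[1] - series.times[0] if T > 1 else 0.0
    box = series.mean_box()
    r_half = float(np.min(box)) / 2.0
    if r_max is None:
        r_max = r_half
    elif r_max > r_half * (1 + 1e-12):
        warnings.warn(
            f"r_max={r_max} exceeds half the box edge; truncating to {r_half}"
        )
        r_max = r_half
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max * (1 + 1e-12)]
    if edges[-1] < r_max - 1e-12:
        edges = np.append(edges, r_max)
    vshell = shell_volumes(edges, box, extended=False)
    rho = (M - 1) / float(np.prod(box))
    gd = np.zeros((lags.size, edges.size - 1))
    counts_out = np.zeros((lags.size, edges.size - 1), dtype=np.int64)
    n_origins = np.zeros(lags.size, dtype=int)
    for k, lag in enumerate(lags):
        origins = np.arange(0, T - lag, origin_stride)
        counts = np.zeros(edges.size - 1, dtype=np.int64)
        for t0 in origins:
            fb = series.box_at(t0)
            counts += pair_distance_counts(
                x[t0], x[t0 + lag], fb, edges, exclude_diagonal=True
            )
        counts_out[k] = counts
        n_origins[k] = origins.size
        gd[k] = counts / (origins.size * M * rho * vshell)
    return VanHoveDistinct(
        lag_times=lags * dt_frame,
        edges=edges,
        gd=gd,
        counts=counts_out,
        rho=rho,
        n_reference=M,
        n_origins=n_origins,
        box=np.asarray(box, dtype=float),
        species=series.species,
    )


@dataclass
class PeakDecay:
    """First-shell peak height of the distinct van Hove function versus lag,
    relative to its zero-lag value (structural decorrelation curve)."""

    lag_times: np.ndarray
    ratio: np.ndarray
    heights: np.ndarray
    window_nm: float
    no_peak: bool


def peak_decay(
    vh: VanHoveDistinct,
    window: float | None = None,
    prominence: float = 0.2,
) -> PeakDecay:
    """Track the first-shell maximum of G_d/rho relative to zero lag.

    ``window`` bounds the search region (nm); by default the first-shell
    boundary detected on the zero-lag curve is used.  If the zero-lag curve
    shows no shell structure (e.g. an ideal gas) the result is flagged
    ``no_peak`` and the whole range is searched.
    """
    if window is None:
        window = first_shell_boundary(vh.as_rdf(0), prominence=prominence)
    no_peak = window is None
    if no_peak:
        window = float(vh.edges[-1])
    mask = vh.centers <= window
    if not mask.any():
        raise ValueError("empty peak-search window")
    heights = vh.gd[:, mask].max(axis=1)
    ratio = heights / heights[0]
    return PeakDecay(
        lag_times=vh.lag_times,
        ratio=ratio,
        heights=heights,
        window_nm=float(window),
        no_peak=no_peak,
    )
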