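"""Geometric hydrogen-bond detection, class-resolved counting, intermittent
autocorrelation, and integrated association timescales.

A hydrogen bond is the triple (donor, hydrogen, acceptor) satisfying a
donor-acceptor distance cutoff and a hydrogen-donor-acceptor angle cutoff
(vertex at the donor), both evaluated with minimum-image vectors.  Defaults
follow the common GROMACS convention of 0.35 nm and 30 degrees.  Bond
presence sampled at the saved frames defines the intermittent 0/1 process
h(t); its normalized autocorrelation C(t) = <h(t0+t) h(t0)> / <h(t0)^2>
starts at 1 and its time integral is the association timescale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pbc import min_image

BOND_CLASSES = ("polymer-polymer", "compound-compound", "polymer-compound", "other")


@dataclass(frozen=True)
class HBondCriterion:
    """Distance cutoff d(D, A) in nm and angle cutoff H-D-A in degrees."""

    d_max: float = 0.35
    angle_max: float = 30.0

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not (0.0 < self.angle_max < 90.0):
            raise ValueError("angle_max must lie in (0, 90) degrees")


@dataclass
class HBondTables:
    """Flattened donor/hydrogen/acceptor bookkeeping for fast detection.

    ``donor_atoms[i]`` pairs with ``donor_hydrogens[i]`` (a donor with two
    hydrogens occupies two rows).  ``atom_mol`` maps atoms to molecule
    indices and ``mol_role`` maps molecules to species roles.
    """

    donor_atoms: np.ndarray
    donor_hydrogens: np.ndarray
    acceptor_atoms: np.ndarray
    atom_mol: np.ndarray
    mol_role: np.ndarray  # array of role strings per molecule

    @classmethod
    def from_topology(cls, topology) -> "HBondTables":
        d_atoms, d_hyds, a_atoms = [], [], []
        names = topology.atom_names
        for m, sp in enumerate(topology.mol_species):
            hb = topology.hbond_spec.get(sp)
            if hb is None:
                continue
            atoms = topology.molecule_atoms(m)
            by_name: dict[str, list[int]] = {}
            for i in atoms:
                by_name.setdefault(names[i], []).append(i)
            for dname, hnames in hb.get("hydrogens", {}).items():
                if dname not in by_name:
                    raise ValueError(
                        f"species {sp!r}: donor atom {dname!r} not found in molecule"
                    )
                for d in by_name[dname]:
                    hs = []
                    for hname in hnames:
                        if hname not in by_name:
                            raise ValueError(
                                f"species {sp!r}: hydrogen {hname!r} of donor "
                                f"{dname!r} not found in molecule"
                            )
                        hs.extend(by_name[hname])
                    if not hs:
                        raise ValueError(
                            f"species {sp!r}: donor {dname!r} has no mapped hydrogens"
                        )
                    for h in hs:
                        d_atoms.append(d)
                        d_hyds.append(h)
            donors_wo_h = set(hb.get("donors", [])) - set(hb.get("hydrogens", {}))
            if donors_wo_h:
                raise ValueError(
                    f"species {sp!r}: donors {sorted(donors_wo_h)} have no mapped hydrogens"
                )
            for aname in hb.get("acceptors", []):
                if aname not in by_name:
                    raise ValueError(
                        f"species {sp!r}: acceptor atom {aname!r} not found in molecule"
                    )
                a_atoms.extend(by_name[aname])
        roles = np.array([topology.roles[sp] for sp in topology.mol_species])
        return cls(
            donor_atoms=np.asarray(d_atoms, dtype=int),
            donor_hydrogens=np.asarray(d_hyds, dtype=int),
            acceptor_atoms=np.asarray(a_atoms, dtype=int),
            atom_mol=np.asarray(topology.mol_index, dtype=int),
            mol_role=roles,
        )


def classify_pair(role_a: str, role_b: str) -> str:
    pair = {role_a, role_b}
    if pair == {"polymer"}:
        return "polymer-polymer"
    if pair == {"terpenoid"}:
        return "compound-compound"
    if pair == {"polymer", "terpenoid"}:
        return "polymer-compound"
    return "other"


def detect_hbonds(
    coords: np.ndarray,
    box,
    tables: HBondTables,
    criterion: HBondCriterion = HBondCriterion(),
) -> set[tuple[int, int, int]]:
    """Hydrogen bonds in one frame as (donor, hydrogen, acceptor) triples.

    A triple is included iff the minimum-image donor-acceptor distance is
    within ``d_max`` and the H-D-A angle is within ``angle_max``.
    Intramolecular pairs are excluded: the analysis targets association
    between molecules.
    """
    x = np.asarray(coords, dtype=float)
    if tables.donor_atoms.size == 0 or tables.acceptor_atoms.size == 0:
        return set()
    d_pos = x[tables.donor_atoms]
    a_pos = x[tables.acceptor_atoms]
    da = min_image(a_pos[None, :, :] - d_pos[:, None, :], box)
    dist = np.linalg.norm(da, axis=-1)
    same_mol = (
        tables.atom_mol[tables.donor_atoms][:, None]
        == tables.atom_mol[tables.acceptor_atoms][None, :]
    )
    cand = (dist <= criterion.d_max) & ~same_mol
    if not cand.any():
        return set()
    di, ai = np.nonzero(cand)
    h_pos = x[tables.donor_hydrogens[di]]
    dh = min_image(h_pos - d_pos[di], box)
    dav = da[di, ai]
    cosang = (dh * dav).sum(axis=1) / (
        np.linalg.norm(dh, axis=1) * np.linalg.norm(dav, axis=1)
    )
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ok = ang <= criterion.angle_max
    return {
        (
            int(tables.donor_atoms[d]),
            int(tables.donor_hydrogens[d]),
            int(tables.acceptor_atoms[a]),
        )
        for d, a in zip(di[ok], ai[ok])
    }


@dataclass
class HBondSeries:
    """Per-frame hydrogen-bond sets with class-resolved counts."""

    times: np.ndarray
    bonds: list  # list[set[(d, h, a)]]
    bond_class: dict  # triple -> class tag
    counts: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        data = {c: np.zeros(len(self.bonds), dtype=int) for c in BOND_CLASSES}
        for t, bset in enumerate(self.bonds):
            for triple in bset:
                data[self.bond_class[triple]][t] += 1
        self.counts = pd.DataFrame({"time_ps": self.times, **data})

    def occupancy(self, cls: str) -> tuple[np.ndarray, list]:
        """0/1 presence matrix (T, B) over every bond of ``cls`` ever seen,
        with identities ordered by first appearance then lexicographically."""
        ids = sorted({b for s in self.bonds for b in s if self.bond_class[b] == cls})
        h = np.zeros((len(self.bonds), len(ids)), dtype=np.uint8)
        index = {b: j for j, b in enumerate(ids)}
        for t, bset in enumerate(self.bonds):
            for b in bset:
                j = index.get(b)
                if j is not None:
                    h[t, j] = 1
        return h, ids


def hbond_counts(
    trajectory,
    criterion: HBondCriterion = HBondCriterion(),
    tables: HBondTables | None = None,
) -> HBondSeries:
    """Detect and classify hydrogen bonds in every frame of a trajectory."""
    if tables is None:
        tables = HBondTables.from_topology(trajectory.topology)
    bonds = []
    bond_class: dict[tuple[int, int, int], str] = {}
    for t in range(len(trajectory.times)):
        box = trajectory.boxes[t] if trajectory.boxes.ndim == 2 else trajectory.boxes
        bset = detect_hbonds(trajectory.coords[t], box, tables, criterion)
        for b in bset:
            if b not in bond_class:
                bond_class[b] = classify_pair(
                    tables.mol_role[tables.atom_mol[b[0]]],
                    tables.mol_role[tables.atom_mol[b[2]]],
                )
        bonds.append(bset)
    return HBondSeries(
        times=np.asarray(trajectory.times, dtype=float), bonds=bonds, bond_class=bond_class
    )


@dataclass
class HBondACF:
    """Intermittent bond autocorrelation C(t) on a lag grid (C(0) = 1)."""

    lag_times: np.ndarray
    c: np.ndarray
    n_bonds: int
    mean_occupancy: float


def acf_from_occupancy(
    h: np.ndarray,
    times: np.ndarray,
    lags: np.ndarray | None = None,
) -> HBondACF:
    """Normalized autocorrelation of a 0/1 presence matrix (T, B).

    Pooled averaging over bond identities and time origins:
    C(t) = <h(t0+t) h(t0)> / <h^2>, the denominator taken over all frames
    and identities (for an indicator process <h^2> = <h>).
    """
    h = np.asarray(h, dtype=float)
    if h.ndim != 2:
        raise ValueError("occupancy must be (T, B)")
    T, B = h.shape
    if T < 2:
        raise ValueError("need at least two frames")
    if B == 0:
        return HBondACF(
            lag_times=np.empty(0), c=np.empty(0), n_bonds=0, mean_occupancy=0.0
        )
    if lags is None:
        lags = np.arange(T // 2 + 1)
    lags = np.asarray(lags, dtype=int)
    if np.any(lags < 0) or np.any(lags >= T):
        raise ValueError("lags must lie in [0, n_frames)")
    denom = float((h**2).mean())
    c = np.empty(lags.size)
    for k, lag in enumerate(lags):
        c[k] = float((h[: T - lag] * h[lag:]).mean()) / denom
    times = np.asarray(times, dtype=float)
    dt = times[1] - times[0] if times.size > 1 else 1.0
    return HBondACF(
        lag_times=lags * dt, c=c, n_bonds=B, mean_occupancy=float(h.mean())
    )


def hbond_acf(
    series: HBondSeries,
    cls: str = "polymer-compound",
    lags: np.ndarray | None = None,
) -> HBondACF:
    """Intermittent autocorrelation over every bond of one class ever seen."""
    if cls not in BOND_CLASSES:
        raise ValueError(f"unknown bond class {cls!r}; choose from {BOND_CLASSES}")
    h, _ids = series.occupancy(cls)
    if h.shape[1] == 0:
        return HBondACF(
            lag_times=np.empty(0), c=np.empty(0), n_bonds=0, mean_occupancy=0.0
        )
    return acf_from_occupancy(h, series.times, lags)


@dataclass
class ACFIntegral:
    """Integrated association timescale (ps) with the cutoff bookkeeping."""

    tau: float
    cutoff: float
    t_cut: float
    truncated: bool  # True when C never dropped below the cutoff


def integrate_acf(acf: HBondACF, cutoff: float = 0.01) -> ACFIntegral:
    """Trapezoidal integral of C(t) up to its first drop below ``cutoff``.

    A plateauing C(t) never reaches the cutoff; the integral then covers the
    whole lag window and is flagged ``truncated``.
    """
    if acf.c.size == 0:
        return ACFIntegral(tau=0.0, cutoff=cutoff, t_cut=0.0, truncated=False)
    below = np.nonzero(acf.c < cutoff)[0]
    if below.size:
        end = int(below[0])
        truncated = False
    else:
        end = acf.c.size - 1
        truncated = True
    tau = float(np.trapezoid(acf.c[: end + 1], acf.lag_times[: end + 1]))
    return ACFIntegral(
        tau=tau, cutoff=cutoff, t_cut=float(acf.lag_times[end]), truncated=truncated
    )
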