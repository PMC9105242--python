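"""Structure/trajectory reading, atom selection, and table persistence.

GRO structures and XTC trajectories are read through MDAnalysis and
converted to the package's internal units (nm, ps; MDAnalysis reports
angstroms).  A species map — a small YAML file keyed by residue name —
assigns each species a role (polymer / terpenoid / water / ion) and,
where applicable, hydrogen-bond donor/acceptor designations and mass
overrides.  Multi-frame GRO files (not supported as trajectories by
MDAnalysis) are handled by a fixed-column block reader.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Topology",
    "Frame",
    "Trajectory",
    "TrajectoryIOError",
    "load_species_map",
    "read_structure",
    "read_trajectory",
    "select",
    "molecule_groups",
    "write_series",
    "read_series",
    "write_gro",
    "export_particles",
]


class TrajectoryIOError(RuntimeError):
    """Raised for unreadable or inconsistent structure/trajectory files."""


_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "NA": 22.990, "K": 39.098,
    "MG": 24.305, "CA": 40.078, "BR": 79.904, "I": 126.904, "M": 0.0,
}


def guess_mass(atom_name: str) -> float:
    """Guess an atomic mass (amu) from an atom name, GROMACS-style."""
    stripped = "".join(ch for ch in atom_name if ch.isalpha()).upper()
    if stripped in _ELEMENT_MASSES:
        return _ELEMENT_MASSES[stripped]
    for two in ("CL", "NA", "MG", "BR"):
        if stripped.startswith(two):
            return _ELEMENT_MASSES[two]
    if stripped and stripped[0] in _ELEMENT_MASSES:
        return _ELEMENT_MASSES[stripped[0]]
    raise ValueError(f"cannot guess a mass for atom name {atom_name!r}")


@dataclass
class Topology:
    """Per-atom and per-molecule bookkeeping bound to a trajectory.

    Atoms of a molecule are contiguous; every molecule belongs to exactly
    one species; ``hbond_spec`` maps species to donor/acceptor/hydrogen
    atom-name designations.
    """

    atom_names: np.ndarray
    mol_index: np.ndarray
    mol_species: np.ndarray
    roles: dict
    masses: np.ndarray
    hbond_spec: dict = field(default_factory=dict)
    source_path: str | None = None
    _mol_atoms: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names)
        self.mol_index = np.asarray(self.mol_index, dtype=int)
        self.mol_species = np.asarray(self.mol_species)
        self.masses = np.asarray(self.masses, dtype=float)
        if np.any(self.masses <= 0):
            raise ValueError("all atom masses must be positive")
        n_mol = self.mol_species.size
        if self.mol_index.max(initial=-1) != n_mol - 1:
            raise ValueError("mol_index and mol_species disagree on molecule count")
        if not self._mol_atoms:
            self._mol_atoms = [
                np.nonzero(self.mol_index == m)[0] for m in range(n_mol)
            ]

    @property
    def n_atoms(self) -> int:
        return self.atom_names.size

    @property
    def n_molecules(self) -> int:
        return self.mol_species.size

    def molecule_atoms(self, m: int) -> np.ndarray:
        return self._mol_atoms[m]

    @property
    def species_names(self) -> list[str]:
        seen: list[str] = []
        for s in self.mol_species:
            if s not in seen:
                seen.append(str(s))
        return seen


@dataclass
class Frame:
    """One snapshot: time (ps), orthorhombic box (nm), coordinates (nm)."""

    time: float
    box: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be 3 positive orthorhombic edge lengths")


@dataclass
class Trajectory:
    """In-memory frame sequence bound to a topology (times strictly
    increasing, constant atom count)."""

    times: np.ndarray
    boxes: np.ndarray
    coords: np.ndarray
    topology: Topology

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TrajectoryIOError(
                f"trajectory atom count {self.coords.shape[1]} does not match "
                f"topology ({self.topology.n_atoms})"
            )
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise TrajectoryIOError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.times.size

    def discard_equilibration(self, fraction: float) -> "Trajectory":
        """Drop the leading ``fraction`` of frames (e.g. 0.5 keeps the
        second half of the run for statistics)."""
        if not (0.0 <= fraction < 1.0):
            raise ValueError("discard fraction must lie in [0, 1)")
        start = int(np.floor(self.n_frames * fraction))
        return Trajectory(
            times=self.times[start:],
            boxes=self.boxes[start:] if self.boxes.ndim == 2 else self.boxes,
            coords=self.coords[start:],
            topology=self.topology,
        )


def load_species_map(path: str | Path) -> dict:
    """Load the per-residue species map (role, hbond designations, masses)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "species" not in raw:
        raise ValueError(f"{path}: species map must define a 'species' mapping")
    return raw


_DEFAULT_ROLES = {"SOL": "water", "WAT": "water", "HOH": "water", "TIP3": "water",
                  "CL": "ion", "NA": "ion", "K": "ion"}


def _build_topology(resnames, atom_names, resids, species_map: dict | None, path) -> Topology:
    resnames = np.asarray(resnames)
    atom_names = np.asarray(atom_names)
    resids = np.asarray(resids, dtype=int)
    # new molecule whenever resid or resname changes (resids wrap at 100000)
    breaks = np.nonzero((resids[1:] != resids[:-1]) | (resnames[1:] != resnames[:-1]))[0]
    mol_index = np.zeros(resnames.size, dtype=int)
    for b in breaks:
        mol_index[b + 1 :] += 1
    starts = np.concatenate([[0], breaks + 1])
    mol_species = resnames[starts]
    spec = (species_map or {}).get("species", {})
    roles: dict[str, str] = {}
    hbond_spec: dict[str, dict] = {}
    for sp in np.unique(mol_species):
        entry = spec.get(str(sp), {})
        role = entry.get("role") or _DEFAULT_ROLES.get(str(sp).upper())
        if role is None:
            role = "terpenoid"
            warnings.warn(
                f"{path}: residue {sp!r} not in species map; assuming role 'terpenoid'"
            )
        roles[str(sp)] = role
        if any(k in entry for k in ("donors", "acceptors", "hydrogens")):
            hbond_spec[str(sp)] = {
                "donors": entry.get("donors", list(entry.get("hydrogens", {}))),
                "acceptors": entry.get("acceptors", []),
                "hydrogens": entry.get("hydrogens", {}),
            }
    masses = np.empty(atom_names.size)
    for i, (rn, an) in enumerate(zip(resnames, atom_names)):
        override = spec.get(str(rn), {}).get("masses", {})
        masses[i] = override.get(str(an)) or guess_mass(str(an))
    return Topology(
        atom_names=atom_names,
        mol_index=mol_index,
        mol_species=mol_species,
        roles=roles,
        masses=masses,
        hbond_spec=hbond_spec,
        source_path=str(path) if path else None,
    )


def _mda_universe(*paths):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(*[str(p) for p in paths])


def read_structure(
    path: str | Path, species_map: dict | str | Path | None = None
) -> tuple[Topology, Frame]:
    """Read a GRO structure into a topology skeleton plus its frame.

    Species membership is inferred from residue names and refined by the
    optional species map (a dict or a YAML path).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    if isinstance(species_map, (str, Path)):
        species_map = load_species_map(species_map)
    try:
        u = _mda_universe(path)
        dims = u.dimensions
        if dims is None or np.any(dims[:3] <= 0):
            raise TrajectoryIOError(f"{path}: missing or invalid box")
        if not np.allclose(dims[3:6], 90.0):
            raise TrajectoryIOError(
                f"{path}: triclinic boxes are unsupported (angles {dims[3:6]})"
            )
        topo = _build_topology(
            u.atoms.resnames, u.atoms.names, u.atoms.resids, species_map, path
        )
        frame = Frame(
            time=float(getattr(u.trajectory.ts, "time", 0.0) or 0.0),
            box=dims[:3] / 10.0,  # angstrom -> nm
            coords=u.atoms.positions / 10.0,
        )
    except (TrajectoryIOError, FileNotFoundError):
        raise
    except Exception as exc:  # malformed file: surface the parser's complaint
        raise TrajectoryIOError(f"cannot parse structure {path}: {exc}") from exc
    return topo, frame


def _read_multiframe_gro(path: Path, n_atoms: int):
    """Fixed-column reader for concatenated GRO frames."""
    times, boxes, coords = [], [], []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        try:
            count = int(lines[i + 1])
        except (IndexError, ValueError) as exc:
            raise TrajectoryIOError(
                f"{path}:{i + 2}: expected an atom count"
            ) from exc
        if count != n_atoms:
            raise TrajectoryIOError(
                f"{path}:{i + 2}: frame {frame_no} has {count} atoms, topology "
                f"expects {n_atoms}"
            )
        if i + 2 + count >= len(lines):
            raise TrajectoryIOError(
                f"{path}: truncated after frame {frame_no - 1} (last complete frame)"
            )
        xyz = np.empty((count, 3))
        for j in range(count):
            ln = lines[i + 2 + j]
            try:
                xyz[j] = (float(ln[20:28]), float(ln[28:36]), float(ln[36:44]))
            except ValueError as exc:
                raise TrajectoryIOError(
                    f"{path}:{i + 3 + j}: malformed coordinate columns"
                ) from exc
        box_fields = lines[i + 2 + count].split()
        if len(box_fields) < 3:
            raise TrajectoryIOError(f"{path}:{i + 3 + count}: malformed box line")
        box = np.array([float(v) for v in box_fields[:3]])
        t = float(frame_no)
        if "t=" in title:
            try:
                t = float(title.split("t=")[1].split()[0])
            except (IndexError, ValueError):
                pass
        times.append(t)
        boxes.append(box)
        coords.append(xyz)
        i += count + 3
        frame_no += 1
    if not coords:
        raise TrajectoryIOError(f"{path}: no frames found")
    return np.array(times), np.array(boxes), np.array(coords)


def read_trajectory(
    path: str | Path,
    topology: Topology,
    structure: str | Path | None = None,
) -> Trajectory:
    """Read an XTC (or multi-frame GRO) trajectory bound to ``topology``.

    XTC needs a structure file for atom metadata; the one recorded by
    :func:`read_structure` is used unless ``structure`` overrides it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trajectory file not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".gro":
        times, boxes, coords = _read_multiframe_gro(path, topology.n_atoms)
    elif suffix in (".xtc", ".trr"):
        struct = structure or topology.source_path
        if struct is None:
            raise TrajectoryIOError("XTC reading needs a structure file")
        try:
            u = _mda_universe(struct, path)
            if len(u.atoms) != topology.n_atoms:
                raise TrajectoryIOError(
                    f"{path}: {len(u.atoms)} atoms, topology expects {topology.n_atoms}"
                )
            times, boxes, coords = [], [], []
            for ts in u.trajectory:
                times.append(float(ts.time))
                boxes.append(ts.dimensions[:3] / 10.0)
                coords.append(u.atoms.positions / 10.0)
            times, boxes, coords = np.array(times), np.array(boxes), np.array(coords)
        except TrajectoryIOError:
            raise
        except Exception as exc:
            raise TrajectoryIOError(f"cannot read trajectory {path}: {exc}") from exc
    else:
        raise TrajectoryIOError(f"unsupported trajectory format: {path.suffix}")
    return Trajectory(times=times, boxes=boxes, coords=coords, topology=topology)


def select(
    topology: Topology,
    species: str | None = None,
    role: str | None = None,
    atom_name: str | None = None,
) -> np.ndarray:
    """Deterministic, order-stable atom index selection.

    Criteria combine with AND; an empty result is a valid empty selection.
    """
    mask = np.ones(topology.n_atoms, dtype=bool)
    atom_species = topology.mol_species[topology.mol_index]
    if species is not None:
        mask &= atom_species == species
    if role is not None:
        atom_roles = np.array([topology.roles[str(s)] for s in atom_species])
        mask &= atom_roles == role
    if atom_name is not None:
        mask &= topology.atom_names == atom_name
    return np.nonzero(mask)[0]


def molecule_groups(topology: Topology, species: str) -> list[np.ndarray]:
    """Per-molecule atom index lists for one species, in molecule order."""
    return [
        topology.molecule_atoms(m)
        for m in range(topology.n_molecules)
        if topology.mol_species[m] == species
    ]


def write_series(table: pd.DataFrame, path: str | Path) -> None:
    """Persist a result table as CSV (.csv) or HDF5 (.h5/.hdf5)."""
    path = Path(path)
    if path.suffix == ".csv":
        table.to_csv(path, index=False)
    elif path.suffix in (".h5", ".hdf5"):
        table.to_hdf(path, key="table", mode="w")
    else:
        raise ValueError(f"unsupported output format: {path.suffix}")


def read_series(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".csv":
        return pd.read_csv(path)
    if path.suffix in (".h5", ".hdf5"):
        return pd.read_hdf(path, key="table")
    raise ValueError(f"unsupported input format: {path.suffix}")


def _particles_universe(n: int, resnames, box_nm, coords_nm):
    import MDAnalysis as mda

    u = mda.Universe.empty(
        n, n_residues=n, atom_resindex=np.arange(n), trajectory=True
    )
    u.add_TopologyAttr("name", ["P"] * n)
    u.add_TopologyAttr("resname", list(resnames))
    u.add_TopologyAttr("resid", (np.arange(n) % 99999) + 1)
    u.atoms.positions = np.asarray(coords_nm) * 10.0
    u.dimensions = np.array([*(np.asarray(box_nm) * 10.0), 90.0, 90.0, 90.0])
    return u


def write_gro(path: str | Path, coords_nm, box_nm, resnames=None) -> None:
    """Write single-particle molecules to a GRO file (nm coordinates)."""
    coords_nm = np.asarray(coords_nm, dtype=float)
    n = coords_nm.shape[0]
    if resnames is None:
        resnames = ["PRT"] * n
    u = _particles_universe(n, resnames, box_nm, coords_nm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def export_particles(
    series, out_dir: str | Path, name: str = "synth", resnames=None
) -> tuple[Path, Path]:
    """Write a ComSeries as GRO (first frame) + XTC (all frames).

    Each molecule becomes a one-atom residue; ``resnames`` (per molecule)
    default to the series' species label truncated to 3 characters.  This
    exercises the same I/O path used for MD data.
    """
    import MDAnalysis as mda

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = series.n_molecules
    if resnames is None:
        resnames = [((series.species or "PRT")[:3].upper() or "PRT")] * n
    box0 = series.box_at(0)
    u = _particles_universe(n, resnames, box0, series.coords[0])
    gro = out_dir / f"{name}.gro"
    xtc = out_dir / f"{name}.xtc"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(gro))
        with mda.Writer(str(xtc), n) as w:
            for t in range(series.n_frames):
                u.atoms.positions = series.coords[t] * 10.0
                bt = series.box_at(t)
                u.dimensions = np.array([*(bt * 10.0), 90.0, 90.0, 90.0])
                u.trajectory.ts.time = float(series.times[t])
                u.trajectory.ts.frame = t
                w.write(u.atoms)
    return gro, xtc
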