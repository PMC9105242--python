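"""Composition bookkeeping for terpenoid / hyperbranched-polymer solutions.

A :class:`SystemComposition` records, per species, how many molecules are in
the simulation cell and how many atoms each molecule carries, mirroring the
composition tables of the simulated systems (single terpenoids in water,
four-terpenoid mixtures, and HBPEI/HPG + terpenoid solutions with chloride
counterions).  Charged compositions must be electrically neutral overall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

VALID_ROLES = frozenset({"polymer", "terpenoid", "water", "ion"})


@dataclass(frozen=True)
class SpeciesSpec:
    """One molecular species of a solution.

    Parameters
    ----------
    name : str
        Species label, unique within a composition (e.g. ``"carvacrol"``).
    role : str
        One of ``polymer``, ``terpenoid``, ``water``, ``ion``.
    molecule_count : int
        Number of molecules of this species in the cell (>= 0).
    atoms_per_molecule : int
        Atoms per molecule (>= 1).
    charge_per_molecule : int
        Net charge per molecule in elementary charges (default 0).
    """

    name: str
    role: str
    molecule_count: int
    atoms_per_molecule: int
    charge_per_molecule: int = 0

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValueError(
                f"species {self.name!r}: role {self.role!r} not in {sorted(VALID_ROLES)}"
            )
        if self.molecule_count < 0:
            raise ValueError(f"species {self.name!r}: molecule_count must be >= 0")
        if self.atoms_per_molecule < 1:
            raise ValueError(f"species {self.name!r}: atoms_per_molecule must be >= 1")

    @property
    def atom_count(self) -> int:
        return self.molecule_count * self.atoms_per_molecule


@dataclass(frozen=True)
class SystemComposition:
    """An ordered collection of species making up one simulated system."""

    label: str
    species: tuple[SpeciesSpec, ...]
    notes: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError(f"composition {self.label!r}: duplicate species names")
        if any(s.charge_per_molecule != 0 for s in self.species):
            total = sum(s.charge_per_molecule * s.molecule_count for s in self.species)
            if total != 0:
                raise ValueError(
                    f"composition {self.label!r}: net charge {total:+d} e; "
                    "charged compositions must be neutral overall"
                )

    def __getitem__(self, name: str) -> SpeciesSpec:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)


def count_atoms(composition: SystemComposition) -> tuple[dict[str, int], int]:
    """Per-species atom counts and the system total.

    Returns ``(per_species, total)`` where ``per_species[name]`` is
    ``molecule_count * atoms_per_molecule``.  An empty composition yields
    ``({}, 0)``.
    """
    per_species = {s.name: s.atom_count for s in composition.species}
    return per_species, sum(per_species.values())


def molar_ratios(composition: SystemComposition) -> dict[str, tuple[int, int]]:
    """Reduced integer polymer : terpenoid molar ratios.

    For each terpenoid species the pair ``(a, b)`` satisfies
    ``a : b == polymer_count : terpenoid_count`` with ``gcd(a, b) == 1``.
    Raises ``ValueError`` if the composition holds no polymer species.
    """
    polymers = [s for s in composition.species if s.role == "polymer"]
    if not polymers:
        raise ValueError(
            f"composition {composition.label!r} contains no polymer species; "
            "molar ratios are defined relative to the polymer"
        )
    if len(polymers) > 1:
        raise ValueError("molar ratios defined for a single polymer species")
    npoly = polymers[0].molecule_count
    out: dict[str, tuple[int, int]] = {}
    for s in composition.species:
        if s.role == "terpenoid":
            g = math.gcd(npoly, s.molecule_count)
            out[s.name] = (npoly // g, s.molecule_count // g)
    return out


def _composition_from_dict(label: str, entry: dict) -> SystemComposition:
    species = tuple(
        SpeciesSpec(
            name=sp["name"],
            role=sp["role"],
            molecule_count=int(sp["molecules"]),
            atoms_per_molecule=int(sp["atoms_per_molecule"]),
            charge_per_molecule=int(sp.get("charge", 0)),
        )
        for sp in entry["species"]
    )
    return SystemComposition(label=label, species=species, notes=entry.get("notes", ""))


def load_composition(path: str | Path) -> SystemComposition:
    """Load a single composition from a YAML file.

    Expected layout::

        label: hpg8_10
        species:
          - {name: HPG, role: polymer, molecules: 8, atoms_per_molecule: 210}
          - {name: carvacrol, role: terpenoid, molecules: 80, atoms_per_molecule: 25}
          - {name: water, role: water, molecules: 17752, atoms_per_molecule: 3}
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "species" not in raw:
        raise ValueError(f"{path}: composition file must define a 'species' list")
    return _composition_from_dict(raw.get("label", path.stem), raw)


_REFERENCE_CACHE: dict[str, SystemComposition] | None = None


def reference_compositions() -> dict[str, SystemComposition]:
    """The packaged reference systems, keyed by label.

    Five terpenoid-in-water systems (``car``, ``thy``, ``ter``, ``cym``,
    ``mix``) and ten polymer-containing systems (``hbpei8_7`` ... ``hpg27_mix``)
    as tabulated for the simulated solutions.  Note that the tabulated
    atoms-per-molecule of gamma-terpinene differs between the two tables (22
    vs. 26); both are kept as printed so every tabulated total reproduces.
    """
    global _REFERENCE_CACHE
    if _REFERENCE_CACHE is None:
        text = (
            resources.files("oilcluster") / "data" / "reference_compositions.yaml"
        ).read_text()
        raw = yaml.safe_load(text)
        _REFERENCE_CACHE = {
            label: _composition_from_dict(label, entry) for label, entry in raw.items()
        }
    return dict(_REFERENCE_CACHE)
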