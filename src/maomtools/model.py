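"""Domain types and periodic-geometry utilities.

All lengths are Angstrom internally. The z axis is the surface normal and the
mineral slab occupies low z. Atom and molecule indices are 0-based; 1-based
numbering appears only at format boundaries (GRO/PDB records).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .data import atomic_weight, vdw_radius
from .errors import GeometryError

__all__ = [
    "Role",
    "Atom",
    "Box",
    "Frame",
    "SpeciesRecord",
    "Molecule",
    "Topology",
    "minimum_image_displacement",
    "minimum_image_distance",
    "validate_system",
]


class Role(Enum):
    """Coarse atom category used throughout classification and coverage."""

    MINERAL = "MINERAL"
    SOM = "SOM"
    WATER = "WATER"
    CATION = "CATION"


# Residue-name encoding of roles at GRO/PDB boundaries.
ROLE_TO_RESNAME = {
    Role.MINERAL: "MIN",
    Role.SOM: "SOM",
    Role.WATER: "SOL",
    Role.CATION: "ION",
}
RESNAME_TO_ROLE = {v: k for k, v in ROLE_TO_RESNAME.items()}


@dataclass(frozen=True)
class Atom:
    atom_id: int
    element: str
    role: Role
    molecule_id: int
    position: tuple[float, float, float]
    vdw_radius: float

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic cell. x and y are always periodic."""

    lx: float
    ly: float
    lz: float
    periodic_z: bool = False

    def __post_init__(self):
        for name in ("lx", "ly", "lz"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise GeometryError(f"box length {name}={v} must be finite and > 0")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz])

    @property
    def periodic(self) -> tuple[bool, bool, bool]:
        return (True, True, self.periodic_z)


@dataclass
class Frame:
    """One timestamped configuration, stored as structure-of-arrays.

    ``positions`` is (N, 3) float64 in Angstrom; ``roles`` holds
    :class:`Role` members; ``elements`` chemical symbols.
    """

    positions: np.ndarray
    elements: np.ndarray
    roles: np.ndarray
    molecule_ids: np.ndarray
    vdw_radii: np.ndarray
    box: Box
    temperature: float = 300.0
    frame_index: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.elements = np.asarray(self.elements, dtype=object)
        self.roles = np.asarray(self.roles, dtype=object)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=np.int64)
        self.vdw_radii = np.asarray(self.vdw_radii, dtype=float)
        for name in ("elements", "roles", "molecule_ids", "vdw_radii"):
            if len(getattr(self, name)) != n:
                raise GeometryError(f"frame field {name} has wrong length")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def is_heavy(self) -> np.ndarray:
        return self.elements != "H"

    def role_mask(self, role: Role) -> np.ndarray:
        return self.roles == role

    @property
    def atoms(self) -> list[Atom]:
        return [
            Atom(
                atom_id=i,
                element=str(self.elements[i]),
                role=self.roles[i],
                molecule_id=int(self.molecule_ids[i]),
                position=tuple(self.positions[i]),
                vdw_radius=float(self.vdw_radii[i]),
            )
            for i in range(self.n_atoms)
        ]

    @classmethod
    def from_atoms(
        cls,
        atoms: list[Atom],
        box: Box,
        temperature: float = 300.0,
        frame_index: int = 0,
    ) -> "Frame":
        return cls(
            positions=np.array([a.position for a in atoms], dtype=float).reshape(-1, 3),
            elements=np.array([a.element for a in atoms], dtype=object),
            roles=np.array([a.role for a in atoms], dtype=object),
            molecule_ids=np.array([a.molecule_id for a in atoms], dtype=np.int64),
            vdw_radii=np.array([a.vdw_radius for a in atoms], dtype=float),
            box=box,
            temperature=temperature,
            frame_index=frame_index,
        )

    def wrapped(self) -> "Frame":
        """Return a copy with coordinates wrapped into [0, L) on periodic axes."""
        pos = self.positions.copy()
        lengths = self.box.lengths
        for ax, per in enumerate(self.box.periodic):
            if per:
                w = np.mod(pos[:, ax], lengths[ax])
                # np.mod can round up to exactly L for tiny negative inputs
                w[w >= lengths[ax]] -= lengths[ax]
                pos[:, ax] = w
        out = replace(self)
        out.positions = pos
        return out

    def copy(self) -> "Frame":
        out = replace(self)
        out.positions = self.positions.copy()
        out.elements = self.elements.copy()
        out.roles = self.roles.copy()
        out.molecule_ids = self.molecule_ids.copy()
        out.vdw_radii = self.vdw_radii.copy()
        return out


@dataclass
class SpeciesRecord:
    """Per-species chemistry driving every descriptor.

    ``template_coords``/``template_elements`` hold the rigid placement
    geometry used by the synthetic-scene generator (centered on the origin);
    ``anchor_index`` points at a boundary O/N atom suitable for coordination
    placements. They are ``None`` for pseudo-species (water, ions, mineral).
    """

    species_id: str
    name: str
    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0
    s: int = 0
    p: int = 0
    formal_charge: int = 0
    aromatic_ring_count: int = 0
    carboxylic_acid_count: int = 0
    n_amine_count: int = 0
    logp: float | None = None
    is_peptide: bool = False
    role: Role = Role.SOM
    template_elements: list[str] | None = None
    template_coords: np.ndarray | None = None
    anchor_index: int | None = None

    @property
    def element_counts(self) -> dict[str, int]:
        return {"C": self.c, "H": self.h, "N": self.n, "O": self.o, "S": self.s, "P": self.p}

    @property
    def mass(self) -> float:
        return sum(cnt * atomic_weight(el) for el, cnt in self.element_counts.items())

    @property
    def n_heavy(self) -> int:
        return self.c + self.n + self.o + self.s + self.p


@dataclass
class Molecule:
    molecule_id: int
    species_id: str
    atom_ids: list[int]


@dataclass
class Topology:
    """Molecule membership, species records and role map for one system."""

    molecules: dict[int, Molecule] = field(default_factory=dict)
    species: dict[str, SpeciesRecord] = field(default_factory=dict)
    metal_ligand_pairs: dict[int, int] = field(default_factory=dict)
    radius_overrides: dict[int, float] = field(default_factory=dict)

    def species_of(self, molecule_id: int) -> SpeciesRecord:
        return self.species[self.molecules[molecule_id].species_id]

    def molecule_ids_with_role(self, role: Role) -> list[int]:
        return sorted(
            m.molecule_id
            for m in self.molecules.values()
            if self.species[m.species_id].role == role
        )

    @property
    def som_molecule_ids(self) -> list[int]:
        return self.molecule_ids_with_role(Role.SOM)

    def molecule_charge(self, molecule_id: int) -> int:
        return self.species_of(molecule_id).formal_charge

    def total_charge(self) -> int:
        return sum(self.molecule_charge(mid) for mid in self.molecules)


def minimum_image_displacement(a, b, box: Box) -> np.ndarray:
    """Displacement b - a under the minimum-image convention (vectorized)."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    lengths = box.lengths
    for ax, per in enumerate(box.periodic):
        if per:
            d[..., ax] -= lengths[ax] * np.round(d[..., ax] / lengths[ax])
    return d


def minimum_image_distance(a, b, box: Box) -> float:
    """Minimum distance between a and b over all periodic images."""
    d = minimum_image_displacement(a, b, box)
    return float(np.linalg.norm(d, axis=-1)) if d.ndim == 1 else np.linalg.norm(d, axis=-1)


def validate_system(frame: Frame, topology: Topology) -> list[str]:
    """Diagnostics report; empty list iff all invariants hold."""
    report: list[str] = []
    n = frame.n_atoms

    if not np.all(np.isfinite(frame.positions)):
        bad = np.where(~np.isfinite(frame.positions).all(axis=1))[0]
        report.append(f"non-finite positions for atoms {bad.tolist()}")

    nonpos = np.where(frame.vdw_radii <= 0)[0]
    for i in nonpos:
        report.append(f"non-positive radius on atom {int(i)}")

    seen: dict[int, int] = {}
    for mol in topology.molecules.values():
        if mol.species_id not in topology.species:
            report.append(f"molecule {mol.molecule_id} references unknown species {mol.species_id!r}")
        for aid in mol.atom_ids:
            if aid < 0 or aid >= n:
                report.append(f"molecule {mol.molecule_id} references out-of-range atom {aid}")
            elif aid in seen:
                report.append(
                    f"overlapping membership: atom {aid} in molecules {seen[aid]} and {mol.molecule_id}"
                )
            else:
                seen[aid] = mol.molecule_id

    orphans = sorted(set(range(n)) - set(seen))
    for aid in orphans:
        report.append(f"orphan atom {aid} belongs to no molecule")

    # membership must agree with the per-atom molecule ids
    for aid, mid in seen.items():
        if 0 <= aid < n and int(frame.molecule_ids[aid]) != mid:
            report.append(
                f"atom {aid} molecule_id {int(frame.molecule_ids[aid])} disagrees with topology ({mid})"
            )

    lengths = frame.box.lengths
    for ax, per in enumerate(frame.box.periodic):
        if per:
            out = np.where((frame.positions[:, ax] < 0) | (frame.positions[:, ax] >= lengths[ax]))[0]
            if out.size:
                report.append(
                    f"{out.size} atoms outside box on axis {'xyz'[ax]} before wrapping"
                )
    return report


def default_radii_for(elements) -> np.ndarray:
    return np.array([vdw_radius(str(e)) for e in elements], dtype=float)
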