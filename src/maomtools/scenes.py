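"""Labeled synthetic mineral–organic scenes with geometric margin guarantees.

Each scene is an orthorhombic box with a mineral slab at low z, organic
molecules planted to satisfy a chosen sorption label with margin, explicit
water on a jittered grid below a vapor gap, and charge-balancing counterions.
Because every binding distance is planted at least one margin away from the
corresponding classification cutoff, and jitter displacements are clipped
below half a margin, downstream classification recovers the planted ground
truth exactly rather than statistically.

Column layout: molecules and ion stacks occupy an xy grid of "columns" with
pitch wide enough that molecules in different columns can never interact
through any cutoff. Direct-contact anchors carry chains of stacked contact
partners (the planted aggregates); everything else is a singleton.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree

from .data import vdw_radius
from .errors import PlacementError
from .model import Box, Frame, Molecule, Role, SpeciesRecord, Topology
from .sorption import SorptionMode

__all__ = [
    "MineralKind",
    "CounterIon",
    "SceneSpec",
    "GroundTruth",
    "default_species_library",
    "default_composition",
    "build_mineral_slab",
    "build_scene",
    "jitter_trajectory",
    "temperature_ladder",
    "preset_spec",
    "small_scene_spec",
    "PRESETS",
]

# ---------------------------------------------------------------------------
# geometry constants (Angstrom)

SLAB_LATTICE = 2.6          # in-plane lattice spacing target
SLAB_PLANE_GAP = 2.0        # gap between atomic planes of the slab
SLAB_Z0 = 1.0               # z of the lowest slab plane
N_SLAB_PLANES = 3
COLUMN_PITCH = 12.0         # xy pitch between placement columns
TEMPLATE_SPACING = 1.7      # heavy-atom grid spacing inside a molecule blob
TEMPLATE_RADIUS_BOUND = 3.7
WATER_MIN_SPACING = 2.4
LIGAND_HEIGHT = 2.0         # ligand-water oxygen above its metal site
METAL_SITE_STRIDE = 3       # every 3rd lattice site on the top plane is a metal site


class MineralKind(Enum):
    SMECTITE_LIKE = "SMECTITE_LIKE"
    OXIDE_LIKE = "OXIDE_LIKE"


class CounterIon(Enum):
    NA = "NA"
    CA = "CA"


@dataclass(frozen=True)
class SceneSpec:
    lx: float
    ly: float
    lz: float
    mineral_kind: MineralKind = MineralKind.SMECTITE_LIKE
    counterion: CounterIon = CounterIon.NA
    n_direct: int = 0
    n_cation_bridged: int = 0
    n_som_bridged: int = 0
    n_free: int = 0
    n_interface: int = 0
    n_vapor: int = 0
    n_water: int | None = None
    water_density_target: float = 0.0334
    vapor_fraction: float = 0.35
    margin: float = 0.5
    seed: int = 0
    n_ligand_exchange: int = 0
    species_sequence: tuple[str, ...] | None = None
    #: explicit per-molecule labels (aligned with species_sequence); when set,
    #: the random label assignment is skipped. Counts must match the n_* fields.
    label_sequence: tuple[SorptionMode, ...] | None = None

    def __post_init__(self):
        counts = (self.n_direct, self.n_cation_bridged, self.n_som_bridged,
                  self.n_free, self.n_interface, self.n_vapor)
        if any(c < 0 for c in counts):
            raise ValueError("label counts must be >= 0")
        if self.margin <= 0:
            raise ValueError("placement margin must be > 0")
        if not (0.0 < self.vapor_fraction <= 0.5):
            raise ValueError("vapor_fraction must lie in (0, 0.5]")
        if self.species_sequence is not None and len(self.species_sequence) != self.n_som:
            raise ValueError("species_sequence length must equal the SOM molecule total")
        if self.label_sequence is not None:
            from collections import Counter

            counts = Counter(self.label_sequence)
            expected = {
                SorptionMode.DIRECT: self.n_direct,
                SorptionMode.CATION_BRIDGED: self.n_cation_bridged,
                SorptionMode.SOM_BRIDGED: self.n_som_bridged,
                SorptionMode.FREE: self.n_free,
                SorptionMode.INTERFACE: self.n_interface,
                SorptionMode.VAPOR: self.n_vapor,
            }
            if {k: counts.get(k, 0) for k in expected} != expected:
                raise ValueError("label_sequence counts disagree with the n_* fields")

    @property
    def n_som(self) -> int:
        return (self.n_direct + self.n_cation_bridged + self.n_som_bridged
                + self.n_free + self.n_interface + self.n_vapor)

    @property
    def z_surface(self) -> float:
        return (1.0 - self.vapor_fraction) * self.lz


@dataclass
class GroundTruth:
    """Planted labels and aggregate structure for one scene."""

    labels: dict[int, SorptionMode]
    cluster_of: dict[int, int]
    largest_cluster: set[int]
    bridging: set[int] = field(default_factory=set)
    ligand_exchanges: list[tuple[int, int]] = field(default_factory=list)
    z_surface: float = 0.0


# ---------------------------------------------------------------------------
# species library


def _template_blob(n_heavy: int, n_h: int, heavy_elements: list[str],
                   anchor_element: str | None, rng: np.random.Generator):
    """Self-avoiding blob on a jittered grid, one boundary anchor pushed out."""
    s = TEMPLATE_SPACING
    r = np.arange(-3, 4)
    grid = np.array([(x, y, z) for x in r for y in r for z in r], dtype=float) * s
    order = np.argsort(np.linalg.norm(grid, axis=1), kind="stable")
    pts = grid[order[:n_heavy]].copy()
    pts -= pts.mean(axis=0)

    radii = np.linalg.norm(pts, axis=1)
    anchor = int(np.argmax(radii))
    # push the anchor to the boundary so a rigid rotation can make it the
    # strictly lowest atom (needed for coordination placements)
    direction = pts[anchor] / (radii[anchor] or 1.0)
    push = 0.6
    while push <= 2.2:
        cand = direction * (radii.max() + push)
        others = np.delete(pts, anchor, axis=0)
        if len(others) == 0 or np.linalg.norm(others - cand, axis=1).min() >= s:
            break
        push += 0.2
    pts[anchor] = direction * (radii.max() + push)

    elements = [""] * n_heavy
    pool = list(heavy_elements)
    if anchor_element is not None:
        pool.remove(anchor_element)
        elements[anchor] = anchor_element
    slots = [i for i in range(n_heavy) if i != anchor] if anchor_element else list(range(n_heavy))
    for i, el in zip(slots, pool):
        elements[i] = el

    coords = [pts]
    h_elements = []
    if n_h:
        h_pos = np.empty((n_h, 3))
        for k in range(n_h):
            parent = pts[k % n_heavy]
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            h_pos[k] = parent + 1.0 * v
        coords.append(h_pos)
        h_elements = ["H"] * n_h
    all_coords = np.vstack(coords)
    all_elements = elements + h_elements
    return all_coords, all_elements, anchor


def _species(sid, name, formula, charge, rings, cooh, amine, logp, peptide=False):
    c, h, n, o, s, p = formula
    return SpeciesRecord(
        species_id=sid, name=name, c=c, h=h, n=n, o=o, s=s, p=p,
        formal_charge=charge, aromatic_ring_count=rings,
        carboxylic_acid_count=cooh, n_amine_count=amine,
        logp=logp, is_peptide=peptide,
    )


# (C, H, N, O, S, P) element counts; charges restricted to {0, -1, -2};
# masses span ~73-292 Da. One peptide species (net-0 zwitterion).
_LIBRARY_ROWS = [
    _species("propanoate",    "propanoate-like anion",   (3, 5, 0, 2, 0, 0), -1, 0, 1, 0, 0.3),
    _species("pyruvate",      "pyruvate-like anion",     (3, 3, 0, 3, 0, 0), -1, 0, 1, 0, -0.5),
    _species("glycerol",      "glycerol-like polyol",    (3, 8, 0, 3, 0, 0),  0, 0, 0, 0, -1.8),
    _species("phenol",        "phenol-like aromatic",    (6, 6, 0, 1, 0, 0),  0, 1, 0, 0, 1.5),
    _species("benzoate",      "benzoate-like anion",     (7, 5, 0, 2, 0, 0), -1, 1, 1, 0, 1.9),
    _species("salicylate",    "salicylate-like anion",   (7, 5, 0, 3, 0, 0), -1, 1, 1, 0, 2.3),
    _species("glucose",       "hexose-like sugar",       (6, 12, 0, 6, 0, 0), 0, 0, 0, 0, -3.2),
    _species("citrate",       "citrate-like dianion",    (6, 6, 0, 7, 0, 0), -2, 0, 3, 0, -1.7),
    _species("malate",        "malate-like dianion",     (4, 4, 0, 5, 0, 0), -2, 0, 2, 0, -1.3),
    _species("succinate",     "succinate-like dianion",  (4, 4, 0, 4, 0, 0), -2, 0, 2, 0, -0.6),
    _species("vanillin",      "vanillin-like aromatic",  (8, 8, 0, 3, 0, 0),  0, 1, 0, 0, 1.2),
    _species("ferulate",      "ferulate-like anion",     (10, 9, 0, 4, 0, 0), -1, 1, 1, 0, 1.5),
    _species("methylpyridine", "methylpyridine-like base", (6, 7, 1, 0, 0, 0), 0, 1, 0, 0, 1.2),
    _species("indole",        "indole-like heteroarene", (8, 7, 1, 0, 0, 0),  0, 2, 0, 0, 2.1),
    _species("naphthol",      "naphthol-like aromatic",  (10, 8, 0, 1, 0, 0), 0, 2, 0, 0, 2.7),
    _species("syringol",      "syringol-like phenolic",  (8, 10, 0, 3, 0, 0), 0, 1, 0, 0, 1.1),
    _species("gallate",       "gallate-like anion",      (7, 5, 0, 5, 0, 0), -1, 1, 1, 0, 0.7),
    _species("coumarate",     "coumarate-like anion",    (9, 7, 0, 3, 0, 0), -1, 1, 1, 0, 1.5),
    _species("ligdimer",      "guaiacyl-dimer-like phenolic", (15, 16, 0, 6, 0, 0), 0, 2, 0, 0, None),
    _species("glycys",        "glycylcysteine-like peptide", (5, 10, 2, 3, 1, 0), 0, 0, 1, 1, -2.8,
             peptide=True),
]


def default_species_library() -> list[SpeciesRecord]:
    """The 20-species organic library with per-species template geometry."""
    library = []
    for row in _LIBRARY_ROWS:
        sp = replace(row)
        rng = np.random.default_rng(zlib.crc32(sp.species_id.encode()))
        heavies = (["C"] * sp.c + ["N"] * sp.n + ["O"] * sp.o
                   + ["S"] * sp.s + ["P"] * sp.p)
        anchor_el = "O" if sp.o else ("N" if sp.n else None)
        coords, elements, anchor = _template_blob(
            sp.n_heavy, sp.h, heavies, anchor_el, rng
        )
        sp.template_coords = coords
        sp.template_elements = elements
        sp.anchor_index = anchor
        library.append(sp)
    return library


def default_composition(library: list[SpeciesRecord]) -> list[str]:
    """4 copies of each non-peptide species + 8 of the peptide (84 total)."""
    seq: list[str] = []
    for sp in library:
        seq.extend([sp.species_id] * (8 if sp.is_peptide else 4))
    return seq


# ---------------------------------------------------------------------------
# mineral slab


def _slab_lattice(spec: SceneSpec):
    nx_ = int(round(spec.lx / SLAB_LATTICE))
    ny_ = int(round(spec.ly / SLAB_LATTICE))
    if nx_ < 4 or ny_ < 4:
        raise PlacementError("box too small for a 4x4 mineral lattice")
    ax, ay = spec.lx / nx_, spec.ly / ny_
    return nx_, ny_, ax, ay


def slab_top_z() -> float:
    return SLAB_Z0 + (N_SLAB_PLANES - 1) * SLAB_PLANE_GAP


def build_mineral_slab(spec: SceneSpec, slab_charge_sites: int = 0):
    """Lattice slab atoms; returns (positions, elements, metal_ligand_local).

    SMECTITE_LIKE marks ``slab_charge_sites`` middle-plane sites as charged
    (element Mg; slab net charge = -sites). OXIDE_LIKE is neutral; every
    METAL_SITE_STRIDE-th top-plane site is a metal (Fe) paired with one
    ligand-water oxygen placed LIGAND_HEIGHT above it.
    """
    nx_, ny_, ax, ay = _slab_lattice(spec)
    positions, elements = [], []
    metal_ligand: dict[int, int] = {}
    charged_left = slab_charge_sites
    for k in range(N_SLAB_PLANES):
        z = SLAB_Z0 + k * SLAB_PLANE_GAP
        top = k == N_SLAB_PLANES - 1
        middle = k == N_SLAB_PLANES // 2
        for i in range(nx_):
            for j in range(ny_):
                x, y = (i + 0.5) * ax, (j + 0.5) * ay
                is_metal = (
                    spec.mineral_kind == MineralKind.OXIDE_LIKE
                    and top
                    and i % METAL_SITE_STRIDE == 0
                    and j % METAL_SITE_STRIDE == 0
                )
                if spec.mineral_kind == MineralKind.SMECTITE_LIKE and middle and charged_left > 0:
                    elements.append("Mg")
                    charged_left -= 1
                elif is_metal:
                    elements.append("Fe")
                else:
                    elements.append("Si" if spec.mineral_kind == MineralKind.SMECTITE_LIKE else "O")
                positions.append((x, y, z))
                if is_metal:
                    metal_idx = len(positions) - 1
                    positions.append((x, y, z + LIGAND_HEIGHT))
                    elements.append("O")
                    metal_ligand[metal_idx] = len(positions) - 1
    if charged_left > 0:
        raise PlacementError("slab too small for the requested charged-site count")
    return np.array(positions, dtype=float), elements, metal_ligand


# ---------------------------------------------------------------------------
# rigid placement helpers


def _rotation_to_minus_z(u: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector u to (0, 0, -1)."""
    v = np.array([0.0, 0.0, -1.0])
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    axis /= s
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + k * s + k @ k * (1 - c)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _place_anchor_down(sp: SpeciesRecord, anchor_target: np.ndarray) -> np.ndarray:
    """Rigidly place the template with its anchor atom lowest, at the target."""
    coords = sp.template_coords.copy()
    a = coords[sp.anchor_index]
    u = a / np.linalg.norm(a)
    rot = _rotation_to_minus_z(u)
    coords = coords @ rot.T
    coords += anchor_target - coords[sp.anchor_index]
    return coords


def _place_centered(sp: SpeciesRecord, center: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    coords = sp.template_coords @ _random_rotation(rng).T
    heavy = [i for i, el in enumerate(sp.template_elements) if el != "H"]
    coords += center - coords[heavy].mean(axis=0)
    return coords


# ---------------------------------------------------------------------------
# scene assembly


def _assign_labels_to_species(spec: SceneSpec, library_by_id: dict[str, SpeciesRecord],
                              sequence: list[str], rng: np.random.Generator):
    """Pair every molecule index with a label, honoring neutrality of VAPOR
    molecules and the oxygen requirement of ligand-exchange plants."""
    if spec.label_sequence is not None:
        assignment = dict(enumerate(spec.label_sequence))
        for idx, label in assignment.items():
            sp = library_by_id[sequence[idx]]
            if label == SorptionMode.VAPOR and sp.formal_charge != 0:
                raise PlacementError(
                    f"molecule {idx} ({sp.species_id}) planted VAPOR but is not neutral"
                )
        return assignment
    n = len(sequence)
    order = list(rng.permutation(n))
    labels_needed = (
        [SorptionMode.VAPOR] * spec.n_vapor
        + [SorptionMode.DIRECT] * spec.n_direct
        + [SorptionMode.CATION_BRIDGED] * spec.n_cation_bridged
        + [SorptionMode.SOM_BRIDGED] * spec.n_som_bridged
        + [SorptionMode.INTERFACE] * spec.n_interface
        + [SorptionMode.FREE] * spec.n_free
    )
    if len(labels_needed) != n:
        raise PlacementError("label counts do not sum to the composition total")

    assignment: dict[int, SorptionMode] = {}
    remaining = list(order)

    def take(predicate, label, what):
        for k, idx in enumerate(remaining):
            if predicate(library_by_id[sequence[idx]]):
                assignment[idx] = label
                return remaining.pop(k)
        raise PlacementError(f"no feasible molecule left for label {label.value} ({what})")

    n_exchange_left = spec.n_ligand_exchange
    for label in labels_needed:
        if label == SorptionMode.VAPOR:
            take(lambda sp: sp.formal_charge == 0, label, "needs a neutral species")
        elif label == SorptionMode.DIRECT and n_exchange_left > 0:
            take(lambda sp: sp.o >= 1, label, "ligand exchange needs an oxygen anchor")
            n_exchange_left -= 1
        else:
            assignment[remaining.pop(0)] = label
    return assignment


def _chain_distribution(n_som_bridged: int, n_direct: int) -> list[int]:
    """Chain length per direct anchor; anchor 0 strictly longest when possible."""
    if n_som_bridged == 0:
        return [0] * n_direct
    if n_direct == 0:
        raise PlacementError("SOM_BRIDGED molecules need at least one DIRECT anchor")
    counts = [0] * n_direct
    for k in range(n_som_bridged):
        counts[k % n_direct] += 1
    if n_direct > 1 and counts[0] == counts[1]:
        # break the tie so the planted largest cluster is unique
        for j in range(n_direct - 1, 0, -1):
            if counts[j] > 0:
                counts[j] -= 1
                counts[0] += 1
                break
    return counts


def build_scene(spec: SceneSpec):
    """Generate one labeled frame; returns (Frame, Topology, GroundTruth)."""
    rng = np.random.default_rng(spec.seed)
    m = spec.margin
    clearance = 2.0 * TEMPLATE_RADIUS_BOUND  # blob diameter bound

    library = default_species_library()
    lib = {sp.species_id: sp for sp in library}
    sequence = list(spec.species_sequence) if spec.species_sequence is not None else None
    if sequence is None:
        if spec.n_som == 84:
            sequence = default_composition(library)
        else:
            ids = [sp.species_id for sp in library]
            sequence = [ids[i % len(ids)] for i in range(spec.n_som)]

    if spec.n_ligand_exchange and spec.mineral_kind != MineralKind.OXIDE_LIKE:
        raise PlacementError("ligand-exchange plants require an OXIDE_LIKE slab")
    if spec.n_ligand_exchange > spec.n_direct:
        raise PlacementError("ligand-exchange plants must be DIRECT molecules")

    # --- charges and slab
    som_charge = sum(lib[sid].formal_charge for sid in sequence)
    ion_valence = 1 if spec.counterion == CounterIon.NA else 2
    if spec.mineral_kind == MineralKind.SMECTITE_LIKE:
        nx_, ny_, _, _ = _slab_lattice(spec)
        slab_sites = max(2, round(0.04 * nx_ * ny_))
        while (slab_sites + abs(som_charge)) % ion_valence != 0:
            slab_sites += 1
        slab_charge = -slab_sites
    else:
        slab_sites = 0
        slab_charge = 0
        if abs(som_charge) % ion_valence != 0:
            raise PlacementError(
                "total organic charge not divisible by the counterion valence on a neutral slab"
            )
    n_cations = (abs(som_charge) + abs(slab_charge)) // ion_valence
    if n_cations < spec.n_cation_bridged:
        raise PlacementError("not enough counterions to plant all cation bridges")

    slab_pos, slab_elements, metal_ligand_local = build_mineral_slab(spec, slab_sites)
    z_top = slab_top_z()
    z_surf = spec.z_surface
    if spec.lz - z_surf < 14.5 + TEMPLATE_RADIUS_BOUND:
        raise PlacementError("vapor gap too small for VAPOR placements")

    # --- column grid
    ncx = int(spec.lx // COLUMN_PITCH)
    ncy = int(spec.ly // COLUMN_PITCH)
    if ncx < 1 or ncy < 1:
        raise PlacementError("box too small for a single placement column")
    col_centers = [
        np.array([(i + 0.5) * spec.lx / ncx, (j + 0.5) * spec.ly / ncy])
        for i in range(ncx)
        for j in range(ncy)
    ]

    z_chain_max = z_surf - 10.0
    z_free_min = z_top + 12.0
    z_free_max = z_surf - 6.5
    if z_free_max <= z_free_min and spec.n_free > 0:
        raise PlacementError("liquid region too shallow for FREE placements")
    n_free_layers = max(1, int((z_free_max - z_free_min) // COLUMN_PITCH) + 1)
    free_cols = -(-spec.n_free // n_free_layers) if spec.n_free else 0

    z_ion_min, z_ion_max = z_top + 12.0, z_surf - 6.0
    ion_capacity = max(1, int((z_ion_max - z_ion_min) // 4.0) + 1)
    n_spectators = n_cations - spec.n_cation_bridged
    ion_cols = -(-n_spectators // ion_capacity) if n_spectators else 0

    needed = (spec.n_direct + spec.n_cation_bridged + spec.n_interface
              + spec.n_vapor + free_cols + ion_cols)
    if needed > len(col_centers):
        raise PlacementError(
            f"need {needed} placement columns but the box only fits {len(col_centers)}"
        )
    col_iter = iter(col_centers)

    # --- slab site snapping helpers
    nx_, ny_, ax, ay = _slab_lattice(spec)

    def snap_site(center, want_metal: bool):
        i = int(round(center[0] / ax - 0.5))
        j = int(round(center[1] / ay - 0.5))
        if spec.mineral_kind == MineralKind.OXIDE_LIKE:
            stride = METAL_SITE_STRIDE
            if want_metal:
                i = (i // stride) * stride
                j = (j // stride) * stride
            else:
                if i % stride == 0:
                    i += 1
                if j % stride == 0:
                    j += 1
        return np.array([((i % nx_) + 0.5) * ax, ((j % ny_) + 0.5) * ay])

    # --- organic molecule placement
    assignment = _assign_labels_to_species(spec, lib, sequence, rng)
    by_label: dict[SorptionMode, list[int]] = {mode: [] for mode in SorptionMode}
    for idx in sorted(assignment):
        by_label[assignment[idx]].append(idx)

    mol_coords: dict[int, np.ndarray] = {}
    gt_labels: dict[int, SorptionMode] = {}
    cluster_of: dict[int, int] = {}
    bridging: set[int] = set()
    ligand_exchanges: list[tuple[int, int]] = []
    bridge_cation_positions: list[np.ndarray] = []
    ligand_displacements: dict[int, np.ndarray] = {}  # local slab index -> new pos

    next_cluster = 0
    chain_lengths = _chain_distribution(spec.n_som_bridged, spec.n_direct)
    chain_pool = list(by_label[SorptionMode.SOM_BRIDGED])

    exchange_left = spec.n_ligand_exchange
    metal_locals = sorted(metal_ligand_local)
    used_metals: set[int] = set()

    for a_i, mid in enumerate(by_label[SorptionMode.DIRECT]):
        sp = lib[sequence[mid]]
        center = next(col_iter)
        if exchange_left > 0 and sp.o >= 1:
            # plant a ligand-exchange event: anchor O right above a metal site
            site = snap_site(center, want_metal=True)
            metal_local = None
            for ml in metal_locals:
                p = slab_pos[ml]
                if abs(p[0] - site[0]) < 1e-6 and abs(p[1] - site[1]) < 1e-6 and ml not in used_metals:
                    metal_local = ml
                    break
            if metal_local is None:
                raise PlacementError("could not snap a ligand-exchange column to a metal site")
            used_metals.add(metal_local)
            anchor_target = np.array([site[0], site[1], slab_pos[metal_local][2] + 2.1])
            coords = _place_anchor_down(sp, anchor_target)
            ligand_local = metal_ligand_local[metal_local]
            ligand_displacements[ligand_local] = slab_pos[ligand_local] + np.array([6.0, 0.0, 0.0])
            ligand_exchanges.append((metal_local, mid))  # local ids fixed up later
            exchange_left -= 1
        else:
            site = snap_site(center, want_metal=False)
            anchor_target = np.array([site[0], site[1], z_top + 2.8])
            coords = _place_anchor_down(sp, anchor_target)
        mol_coords[mid] = coords
        gt_labels[mid] = SorptionMode.DIRECT
        cluster_of[mid] = next_cluster

        # stack the planted chain on this anchor (heavy-heavy contact at 2.5 A)
        prev = coords
        prev_sp = sp
        for _ in range(chain_lengths[a_i]):
            cid = chain_pool.pop(0)
            csp = lib[sequence[cid]]
            heavy_rows = [r for r, el in enumerate(prev_sp.template_elements) if el != "H"]
            top_idx = heavy_rows[int(np.argmax(prev[heavy_rows, 2]))]
            target = prev[top_idx] + np.array([0.0, 0.0, 2.5])
            ccoords = _place_anchor_down(csp, target)
            if ccoords[:, 2].max() > z_chain_max:
                raise PlacementError(
                    f"SOM_BRIDGED chain for molecule {cid} exceeds the liquid region"
                )
            mol_coords[cid] = ccoords
            gt_labels[cid] = SorptionMode.SOM_BRIDGED
            cluster_of[cid] = next_cluster
            prev = ccoords
            prev_sp = csp
        if chain_lengths[a_i] > 0:
            bridging.add(mid)
        next_cluster += 1

    if exchange_left:
        raise PlacementError("not enough oxygen-bearing DIRECT molecules for ligand exchange")

    for mid in by_label[SorptionMode.CATION_BRIDGED]:
        sp = lib[sequence[mid]]
        center = next(col_iter)
        site = snap_site(center, want_metal=False)
        cation = np.array([site[0], site[1], z_top + 2.4])
        bridge_cation_positions.append(cation)
        anchor_target = cation + np.array([0.0, 0.0, 2.3])
        mol_coords[mid] = _place_anchor_down(sp, anchor_target)
        gt_labels[mid] = SorptionMode.CATION_BRIDGED
        cluster_of[mid] = next_cluster
        next_cluster += 1

    for mid in by_label[SorptionMode.INTERFACE]:
        center = next(col_iter)
        mol_coords[mid] = _place_centered(
            lib[sequence[mid]], np.array([center[0], center[1], z_surf]), rng
        )
        gt_labels[mid] = SorptionMode.INTERFACE
        cluster_of[mid] = next_cluster
        next_cluster += 1

    for mid in by_label[SorptionMode.VAPOR]:
        center = next(col_iter)
        mol_coords[mid] = _place_centered(
            lib[sequence[mid]], np.array([center[0], center[1], z_surf + 11.0]), rng
        )
        gt_labels[mid] = SorptionMode.VAPOR
        cluster_of[mid] = next_cluster
        next_cluster += 1

    free_ids = list(by_label[SorptionMode.FREE])
    for c in range(free_cols):
        center = next(col_iter)
        for layer in range(n_free_layers):
            if not free_ids:
                break
            mid = free_ids.pop(0)
            z = z_free_min + layer * COLUMN_PITCH
            mol_coords[mid] = _place_centered(
                lib[sequence[mid]], np.array([center[0], center[1], z]), rng
            )
            gt_labels[mid] = SorptionMode.FREE
            cluster_of[mid] = next_cluster
            next_cluster += 1

    # --- spectator cations
    spectator_positions: list[np.ndarray] = []
    left = n_spectators
    for c in range(ion_cols):
        center = next(col_iter)
        for k in range(ion_capacity):
            if left == 0:
                break
            spectator_positions.append(
                np.array([center[0], center[1], z_ion_min + 4.0 * k])
            )
            left -= 1

    # --- assemble atoms: slab, organics, cations, water
    for local, newpos in ligand_displacements.items():
        slab_pos[local] = newpos

    positions = [slab_pos]
    elements: list[str] = list(slab_elements)
    roles: list[Role] = [Role.MINERAL] * len(slab_pos)
    atom_mol: list[int] = []

    n_som = len(sequence)
    mineral_mol_id = n_som
    atom_mol.extend([mineral_mol_id] * len(slab_pos))

    molecules: dict[int, Molecule] = {}
    species: dict[str, SpeciesRecord] = {sp.species_id: sp for sp in library}

    metal_ligand_pairs = {int(k): int(v) for k, v in metal_ligand_local.items()}
    ligand_exchanges = [(int(metal_local), mid) for metal_local, mid in ligand_exchanges]

    molecules[mineral_mol_id] = Molecule(
        mineral_mol_id,
        "MINERAL_SMECTITE" if spec.mineral_kind == MineralKind.SMECTITE_LIKE else "MINERAL_OXIDE",
        list(range(len(slab_pos))),
    )
    species["MINERAL_SMECTITE"] = SpeciesRecord(
        "MINERAL_SMECTITE", "charged smectite-like slab", role=Role.MINERAL,
        formal_charge=slab_charge if spec.mineral_kind == MineralKind.SMECTITE_LIKE else 0,
    )
    species["MINERAL_OXIDE"] = SpeciesRecord(
        "MINERAL_OXIDE", "neutral oxide-like slab", role=Role.MINERAL, formal_charge=0,
    )

    cursor = len(slab_pos)
    exchange_anchor_atoms: dict[int, int] = {}
    for mid in range(n_som):
        sp = lib[sequence[mid]]
        coords = mol_coords[mid]
        n_at = len(coords)
        molecules[mid] = Molecule(mid, sp.species_id, list(range(cursor, cursor + n_at)))
        positions.append(coords)
        elements.extend(sp.template_elements)
        roles.extend([Role.SOM] * n_at)
        atom_mol.extend([mid] * n_at)
        exchange_anchor_atoms[mid] = cursor + sp.anchor_index
        cursor += n_at

    ion_sid = spec.counterion.value
    species["NA"] = SpeciesRecord("NA", "sodium ion", formal_charge=1, role=Role.CATION)
    species["CA"] = SpeciesRecord("CA", "calcium ion", formal_charge=2, role=Role.CATION)
    # SpeciesRecord charge invariant {-2,-1,0} applies to organic species only.
    ion_element = "Na" if spec.counterion == CounterIon.NA else "Ca"
    next_mol = mineral_mol_id + 1
    for p in bridge_cation_positions + spectator_positions:
        molecules[next_mol] = Molecule(next_mol, ion_sid, [cursor])
        positions.append(p.reshape(1, 3))
        elements.append(ion_element)
        roles.append(Role.CATION)
        atom_mol.append(next_mol)
        cursor += 1
        next_mol += 1

    # --- water on a jittered grid, filtered against everything placed so far
    species["WAT"] = SpeciesRecord("WAT", "water", h=2, o=1, role=Role.WATER)
    solute = np.vstack(positions)
    spacing = (1.0 / spec.water_density_target) ** (1.0 / 3.0)
    gx = max(1, int(spec.lx // spacing))
    gy = max(1, int(spec.ly // spacing))
    z_lo, z_hi = z_top + 2.6, z_surf
    gz = max(1, int((z_hi - z_lo) // spacing))
    xs = (np.arange(gx) + 0.5) * spec.lx / gx
    ys = (np.arange(gy) + 0.5) * spec.ly / gy
    # plane ladder anchored at the nominal surface so the detected z* tracks it
    zs = z_surf - 0.3 - np.arange(gz) * spacing
    zs = zs[zs >= z_lo]
    cand = np.array(np.meshgrid(xs, ys, zs, indexing="ij")).reshape(3, -1).T
    cand = cand + rng.uniform(-0.25, 0.25, size=cand.shape)

    # filter against all solute atoms with xy periodicity (3x3 images)
    images = [
        solute + np.array([dx * spec.lx, dy * spec.ly, 0.0])
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
    ]
    d3tree = cKDTree(np.vstack(images))
    dists, _ = d3tree.query(cand, k=1)
    keep = cand[dists >= WATER_MIN_SPACING]
    if spec.n_water is not None:
        keep = keep[: spec.n_water]
    h1 = np.array([0.76, 0.0, 0.59])
    h2 = np.array([-0.76, 0.0, 0.59])
    for w in keep:
        rot = _random_rotation(rng)
        molecules[next_mol] = Molecule(next_mol, "WAT", [cursor, cursor + 1, cursor + 2])
        positions.append(np.vstack([w, w + rot @ h1, w + rot @ h2]))
        elements.extend(["O", "H", "H"])
        roles.extend([Role.WATER] * 3)
        atom_mol.extend([next_mol] * 3)
        cursor += 3
        next_mol += 1

    frame = Frame(
        positions=np.vstack(positions),
        elements=np.array(elements, dtype=object),
        roles=np.array(roles, dtype=object),
        molecule_ids=np.array(atom_mol, dtype=np.int64),
        vdw_radii=np.array([vdw_radius(e) for e in elements]),
        box=Box(spec.lx, spec.ly, spec.lz),
        temperature=300.0,
    ).wrapped()

    topology = Topology(
        molecules=molecules,
        species=species,
        metal_ligand_pairs=metal_ligand_pairs,
    )

    # planted largest cluster: the strictly longest chain, or the deterministic
    # tie-break (smallest molecule id) when everything is a singleton
    sizes: dict[int, int] = {}
    for mid, cid in cluster_of.items():
        sizes[cid] = sizes.get(cid, 0) + 1
    best = min(sizes, key=lambda cid: (-sizes[cid], min(m for m in cluster_of if cluster_of[m] == cid)))
    largest = {mid for mid, cid in cluster_of.items() if cid == best}

    ground_truth = GroundTruth(
        labels=gt_labels,
        cluster_of=cluster_of,
        largest_cluster=largest,
        bridging=bridging,
        ligand_exchanges=sorted(
            (metal_local, exchange_anchor_atoms[mid]) for metal_local, mid in ligand_exchanges
        ),
        z_surface=z_surf,
    )
    return frame, topology, ground_truth


# ---------------------------------------------------------------------------
# trajectories and ladders


def jitter_trajectory(
    frame: Frame,
    n_frames: int,
    sigma: float,
    seed: int,
    margin: float = 0.5,
) -> list[Frame]:
    """Frames with per-atom Gaussian displacement, norm-clipped to keep labels.

    Displacement norms are clipped to min(3*sigma, 0.45*margin) so that no
    planted pair distance can drift by a full margin; requires 3*sigma < margin.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if 3.0 * sigma >= margin:
        raise ValueError(f"jitter sigma={sigma} too large for margin {margin} (need 3*sigma < margin)")
    rng = np.random.default_rng(seed)
    clip = min(3.0 * sigma, 0.45 * margin)
    frames = []
    for k in range(n_frames):
        out = frame.copy()
        if sigma > 0:
            disp = rng.normal(0.0, sigma, size=out.positions.shape)
            norms = np.linalg.norm(disp, axis=1)
            scale = np.where(norms > clip, clip / np.maximum(norms, 1e-300), 1.0)
            out.positions = out.positions + disp * scale[:, None]
        out = out.wrapped()
        out.frame_index = k
        frames.append(out)
    return frames


def temperature_ladder(t_min: float, t_max: float, dt: float) -> list[float]:
    """Inclusive arithmetic temperature ladder."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_max < t_min:
        raise ValueError("t_max must be >= t_min")
    steps = (t_max - t_min) / dt
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError(f"range {t_min}..{t_max} not divisible by dt={dt}")
    return [t_min + k * dt for k in range(int(round(steps)) + 1)]


# ---------------------------------------------------------------------------
# presets


def preset_spec(name: str, seed: int = 0) -> SceneSpec:
    """Full-composition (84-molecule) preset scenes."""
    try:
        mineral, ion = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; expected one of {sorted(PRESETS)}")
    return SceneSpec(
        lx=96.0, ly=84.0, lz=110.0,
        mineral_kind=mineral, counterion=ion,
        n_direct=12, n_cation_bridged=8, n_som_bridged=24,
        n_free=24, n_interface=8, n_vapor=8,
        water_density_target=0.015,
        vapor_fraction=0.35,
        seed=seed,
    )


PRESETS = {
    "na-smectite": (MineralKind.SMECTITE_LIKE, CounterIon.NA),
    "ca-smectite": (MineralKind.SMECTITE_LIKE, CounterIon.CA),
    "na-oxide": (MineralKind.OXIDE_LIKE, CounterIon.NA),
    "ca-oxide": (MineralKind.OXIDE_LIKE, CounterIon.CA),
}

_SMALL_SEQUENCE = (
    "glucose", "phenol", "benzoate", "salicylate", "succinate", "malate",
    "glycys", "indole", "vanillin", "naphthol", "coumarate", "gallate",
    "glycerol", "methylpyridine", "citrate", "syringol",
)


def small_scene_spec(mineral: MineralKind, counterion: CounterIon, seed: int = 0) -> SceneSpec:
    """Reduced 16-molecule scene used for fast exact-recovery testing."""
    return SceneSpec(
        lx=48.0, ly=48.0, lz=76.0,
        mineral_kind=mineral, counterion=counterion,
        n_direct=3, n_cation_bridged=2, n_som_bridged=4,
        n_free=3, n_interface=2, n_vapor=2,
        water_density_target=0.0334,
        vapor_fraction=0.35,
        seed=seed,
        species_sequence=_SMALL_SEQUENCE,
    )
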