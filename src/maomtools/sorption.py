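"""Per-molecule sorption-mode classification.

Every organic molecule in a frame is assigned exactly one mode per the
priority chain VAPOR > DIRECT > CATION_BRIDGED > SOM_BRIDGED > INTERFACE >
FREE, plus a separate *bridging* tag for surface-bound molecules that anchor
non-bound neighbors. Ligand-exchange-like coordination events at annotated
metal sites are detected geometrically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree

from .errors import SurfaceError
from .model import Box, Frame, Role, Topology

__all__ = [
    "SorptionMode",
    "SorptionParams",
    "locate_liquid_surface",
    "classify_sorption",
    "tag_bridging",
    "adsorbed_percentage",
    "detect_ligand_exchange",
]


class SorptionMode(Enum):
    DIRECT = "DIRECT"
    CATION_BRIDGED = "CATION_BRIDGED"
    SOM_BRIDGED = "SOM_BRIDGED"
    FREE = "FREE"
    INTERFACE = "INTERFACE"
    VAPOR = "VAPOR"


ADSORBED_MODES = (SorptionMode.DIRECT, SorptionMode.CATION_BRIDGED, SorptionMode.SOM_BRIDGED)
DESORBED_MODES = (SorptionMode.FREE, SorptionMode.INTERFACE, SorptionMode.VAPOR)


@dataclass(frozen=True)
class SorptionParams:
    """Cutoffs for the classification rules (Angstrom)."""

    d_direct: float = 3.5
    d_cat_surf: float = 3.0
    d_cat_som: float = 3.0
    interface_shell: float = 3.0
    density_bin: float = 0.2
    d_fe_o: float = 2.6
    #: moving-average window (Angstrom) applied to the water density profile;
    #: must exceed any granularity of the water structure along z
    smooth_window: float = 4.0

    def __post_init__(self):
        for name in ("d_direct", "d_cat_surf", "d_cat_som", "interface_shell",
                     "density_bin", "d_fe_o"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _query_near(points_a: np.ndarray, points_b: np.ndarray, box: Box, cutoff: float):
    """Pairs (i, j) with periodic-xy minimum-image distance <= cutoff."""
    if len(points_a) == 0 or len(points_b) == 0:
        return []
    zmin = min(points_a[:, 2].min(), points_b[:, 2].min())
    zmax = max(points_a[:, 2].max(), points_b[:, 2].max())
    lengths = box.lengths
    if box.periodic_z:
        bs = lengths
        shift = np.zeros(3)
    else:
        bs = np.array([lengths[0], lengths[1], 2.0 * (zmax - zmin) + 2 * cutoff + 2.0])
        shift = np.array([0.0, 0.0, -zmin + cutoff + 0.5])
    wa = points_a + shift
    wb = points_b + shift
    wa[:, 0] = np.mod(wa[:, 0], lengths[0])
    wa[:, 1] = np.mod(wa[:, 1], lengths[1])
    wb[:, 0] = np.mod(wb[:, 0], lengths[0])
    wb[:, 1] = np.mod(wb[:, 1], lengths[1])
    if box.periodic_z:
        wa[:, 2] = np.mod(wa[:, 2], lengths[2])
        wb[:, 2] = np.mod(wb[:, 2], lengths[2])
    ta = cKDTree(wa, boxsize=bs)
    tb = cKDTree(wb, boxsize=bs)
    return ta.query_ball_tree(tb, cutoff)


def locate_liquid_surface(frame: Frame, params: SorptionParams = SorptionParams()) -> float:
    """Locate the liquid surface z* from the water-oxygen density profile.

    z* is the highest z at which the (smoothed) binned profile first falls
    below 50% of its bulk plateau, the plateau being the median of the bins
    in the central occupied region.
    """
    mask = (frame.roles == Role.WATER) & (frame.elements == "O")
    z = frame.positions[mask, 2]
    if z.size < 50:
        raise SurfaceError(f"need >= 50 water molecules to locate the surface (got {z.size})")
    bin_w = params.density_bin
    lo = np.floor(z.min() / bin_w) * bin_w
    hi = np.ceil(z.max() / bin_w) * bin_w + bin_w
    edges = np.arange(lo, hi + bin_w / 2, bin_w)
    counts, edges = np.histogram(z, bins=edges)
    win = max(1, int(round(params.smooth_window / bin_w)))
    kernel = np.ones(win) / win
    smooth = np.convolve(counts.astype(float), kernel, mode="same")

    occupied = np.where(smooth > 0)[0]
    if occupied.size < 3:
        raise SurfaceError("water density profile has no resolvable plateau")
    span = occupied[-1] - occupied[0] + 1
    c0 = occupied[0] + span // 4
    c1 = occupied[0] + (3 * span) // 4
    plateau = float(np.median(smooth[c0 : c1 + 1]))
    if plateau <= 0:
        raise SurfaceError("water density profile has no resolvable plateau")

    threshold = 0.5 * plateau
    # scan upward from the plateau region; first bin below threshold marks z*
    for i in range(c1, len(smooth)):
        if smooth[i] < threshold:
            return float(edges[i])
    return float(edges[-1])


def _molecule_atom_index(frame: Frame, topology: Topology):
    out: dict[int, np.ndarray] = {}
    for mid, mol in topology.molecules.items():
        out[mid] = np.asarray(mol.atom_ids, dtype=int)
    return out


def classify_sorption(
    frame: Frame,
    topology: Topology,
    clusters,
    graph,
    params: SorptionParams = SorptionParams(),
    z_star: float | None = None,
) -> dict[int, SorptionMode]:
    """Assign one sorption mode to every SOM molecule of the frame.

    ``clusters``/``graph`` must come from :mod:`maomtools.aggregation` run on
    the same frame. ``z_star`` overrides liquid-surface detection (useful for
    waterless test frames); otherwise the surface is located from the water
    density profile and its absence is an error.
    """
    som_ids = topology.som_molecule_ids
    if z_star is None:
        try:
            z_star = locate_liquid_surface(frame, params)
        except SurfaceError as exc:
            raise SurfaceError(
                "cannot classify without a liquid surface; pass z_star explicitly"
            ) from exc

    atom_idx = _molecule_atom_index(frame, topology)
    heavy = frame.is_heavy
    pos = frame.positions
    box = frame.box

    mineral_pos = pos[frame.roles == Role.MINERAL]
    cation_atom_ids = np.where(frame.roles == Role.CATION)[0]
    cation_pos = pos[cation_atom_ids]

    # cations complexed with the surface
    surf_cation_mask = np.zeros(len(cation_pos), dtype=bool)
    if len(cation_pos) and len(mineral_pos):
        hits = _query_near(cation_pos, mineral_pos, box, params.d_cat_surf)
        surf_cation_mask = np.array([len(h) > 0 for h in hits])
    surf_cation_pos = cation_pos[surf_cation_mask]

    labels: dict[int, SorptionMode] = {}
    direct_or_bridged: set[int] = set()

    # pass 1: VAPOR / DIRECT / CATION_BRIDGED
    for mid in som_ids:
        ids = atom_idx[mid]
        mol_pos = pos[ids]
        centroid_z = float(mol_pos[:, 2].mean())
        if centroid_z > z_star + 2.0 * params.interface_shell:
            labels[mid] = SorptionMode.VAPOR
            continue
        hmask = heavy[ids]
        hpos = mol_pos[hmask]
        if len(mineral_pos):
            hits = _query_near(hpos, mineral_pos, box, params.d_direct)
            if any(len(h) for h in hits):
                labels[mid] = SorptionMode.DIRECT
                direct_or_bridged.add(mid)
                continue
        on_mask = np.isin(frame.elements[ids], ("O", "N")) & heavy[ids]
        on_pos = mol_pos[on_mask]
        if len(surf_cation_pos) and len(on_pos):
            hits = _query_near(on_pos, surf_cation_pos, box, params.d_cat_som)
            if any(len(h) for h in hits):
                labels[mid] = SorptionMode.CATION_BRIDGED
                direct_or_bridged.add(mid)
                continue

    # pass 2: SOM_BRIDGED via component reachability, then INTERFACE / FREE
    anchored_components = {clusters.component_of[m] for m in direct_or_bridged}
    for mid in som_ids:
        if mid in labels:
            continue
        if clusters.component_of[mid] in anchored_components:
            labels[mid] = SorptionMode.SOM_BRIDGED
            continue
        ids = atom_idx[mid]
        centroid_z = float(pos[ids, 2].mean())
        if abs(centroid_z - z_star) <= params.interface_shell:
            labels[mid] = SorptionMode.INTERFACE
        else:
            labels[mid] = SorptionMode.FREE
    return labels


def tag_bridging(labels: dict[int, SorptionMode], graph) -> set[int]:
    """Surface-bound molecules with at least one edge to a non-bound molecule."""
    bound = {m for m, lab in labels.items()
             if lab in (SorptionMode.DIRECT, SorptionMode.CATION_BRIDGED)}
    tagged = set()
    for m in bound:
        for nbr in graph.neighbors(m):
            if nbr not in bound:
                tagged.add(m)
                break
    return tagged


@dataclass
class AdsorbedResult:
    adsorbed_pct: float
    desorbed_pct: float
    mode_pct: dict[SorptionMode, float] = field(default_factory=dict)


def adsorbed_percentage(
    frames_labels: list[dict[int, SorptionMode]],
    interface_is_adsorbed: bool = False,
) -> AdsorbedResult:
    """Average adsorbed/desorbed percentages over frames, with mode breakdown."""
    if not frames_labels:
        raise ValueError("need at least one frame of labels")
    mode_fracs = {mode: 0.0 for mode in SorptionMode}
    for labels in frames_labels:
        n = len(labels)
        if n == 0:
            raise ValueError("empty label map in frame")
        for lab in labels.values():
            mode_fracs[lab] += 1.0 / n
    nf = len(frames_labels)
    mode_pct = {mode: 100.0 * v / nf for mode, v in mode_fracs.items()}
    adsorbed = sum(mode_pct[m] for m in ADSORBED_MODES)
    if interface_is_adsorbed:
        adsorbed += mode_pct[SorptionMode.INTERFACE]
    return AdsorbedResult(
        adsorbed_pct=adsorbed,
        desorbed_pct=100.0 - adsorbed,
        mode_pct=mode_pct,
    )


def detect_ligand_exchange(
    frame: Frame, topology: Topology, params: SorptionParams = SorptionParams()
) -> list[tuple[int, int]]:
    """Geometric ligand-exchange events at annotated metal sites.

    An event is a metal-site atom with an organic oxygen within ``d_fe_o``
    while its paired ligand-water oxygen sits farther than ``d_fe_o``.
    Returns (metal_atom_id, som_oxygen_atom_id) pairs.
    """
    if not topology.metal_ligand_pairs:
        raise ValueError("frame's slab carries no metal-site/ligand-water annotation")
    pos = frame.positions
    box = frame.box
    som_o_ids = np.where((frame.roles == Role.SOM) & (frame.elements == "O"))[0]
    events: list[tuple[int, int]] = []
    if len(som_o_ids) == 0:
        return events
    metal_ids = sorted(topology.metal_ligand_pairs)
    hits = _query_near(pos[metal_ids], pos[som_o_ids], box, params.d_fe_o)
    from .model import minimum_image_distance

    for k, metal_id in enumerate(metal_ids):
        if not hits[k]:
            continue
        ligand_id = topology.metal_ligand_pairs[metal_id]
        d_lig = minimum_image_distance(pos[metal_id], pos[ligand_id], box)
        if d_lig > params.d_fe_o:
            for j in hits[k]:
                events.append((int(metal_id), int(som_o_ids[j])))
    return sorted(events)
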