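"""Molecule-level contact graph, aggregate detection and cluster statistics.

Contacts are heavy-atom pairs within a cutoff under the minimum-image
convention; optional divalent-cation bridge edges connect molecules whose
O/N atoms share a +2 cation within an ion cutoff. Neighbor search uses a
periodic KD-tree and is oracle-checked against brute force in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .errors import GeometryError
from .model import Box, Frame, Role, Topology

__all__ = [
    "ContactParams",
    "EdgeKind",
    "contact_graph",
    "find_clusters",
    "ClusterAssignment",
    "largest_cluster_probability",
]


@dataclass(frozen=True)
class ContactParams:
    """Cutoffs for aggregate detection (Angstrom)."""

    r_c: float = 3.5
    include_divalent_bridges: bool = False
    r_ion: float = 3.0

    def validate_for(self, box: Box) -> None:
        limit = min(box.lx, box.ly, box.lz if box.periodic_z else np.inf) / 2.0
        for name, value in (("r_c", self.r_c), ("r_ion", self.r_ion)):
            if value <= 0:
                raise GeometryError(f"{name} must be > 0")
            if value >= limit:
                raise GeometryError(
                    f"{name}={value} must be below half the smallest periodic box length ({limit})"
                )


class EdgeKind:
    CONTACT = "CONTACT"
    DIVALENT_BRIDGE = "DIVALENT_BRIDGE"


def _periodic_tree(points: np.ndarray, box: Box, cutoff: float) -> tuple[cKDTree, np.ndarray]:
    """KD-tree periodic in x/y (and z when the box is); z padded otherwise."""
    lengths = box.lengths
    pts = points.copy()
    pts[:, 0] = np.mod(pts[:, 0], lengths[0])
    pts[:, 1] = np.mod(pts[:, 1], lengths[1])
    if box.periodic_z:
        pts[:, 2] = np.mod(pts[:, 2], lengths[2])
        boxsize = lengths.copy()
    else:
        zmin = pts[:, 2].min()
        pts[:, 2] += -zmin + cutoff + 1.0
        boxsize = np.array(
            [lengths[0], lengths[1], 2.0 * (pts[:, 2].max() + cutoff + 1.0)]
        )
    return cKDTree(pts, boxsize=boxsize), pts


def contact_graph(
    frame: Frame, topology: Topology, params: ContactParams = ContactParams()
) -> nx.Graph:
    """Build the undirected molecule graph of SOM–SOM contacts.

    Nodes are all SOM molecule ids (isolated molecules included). An edge of
    kind CONTACT joins molecules with any heavy-atom pair within ``r_c``;
    with ``include_divalent_bridges``, a DIVALENT_BRIDGE edge joins molecules
    whose O/N atoms both lie within ``r_ion`` of one +2 cation.
    """
    params.validate_for(frame.box)
    graph = nx.Graph()
    som_ids = topology.som_molecule_ids
    graph.add_nodes_from(som_ids)

    heavy_ids = []
    heavy_mol = []
    for mid in som_ids:
        for aid in topology.molecules[mid].atom_ids:
            if frame.elements[aid] != "H":
                heavy_ids.append(aid)
                heavy_mol.append(mid)
    if not heavy_ids:
        return graph
    heavy_ids = np.asarray(heavy_ids)
    heavy_mol = np.asarray(heavy_mol)

    tree, _ = _periodic_tree(frame.positions[heavy_ids], frame.box, params.r_c)
    for i, j in tree.query_pairs(params.r_c):
        mi, mj = int(heavy_mol[i]), int(heavy_mol[j])
        if mi != mj and not graph.has_edge(mi, mj):
            graph.add_edge(mi, mj, kind=EdgeKind.CONTACT)

    if params.include_divalent_bridges:
        divalent_pos = []
        for mid in topology.molecule_ids_with_role(Role.CATION):
            if topology.species_of(mid).formal_charge == 2:
                divalent_pos.extend(
                    frame.positions[aid] for aid in topology.molecules[mid].atom_ids
                )
        on_mask = np.isin(frame.elements[heavy_ids], ("O", "N"))
        on_ids = heavy_ids[on_mask]
        on_mol = heavy_mol[on_mask]
        if divalent_pos and len(on_ids):
            divalent_pos = np.asarray(divalent_pos, dtype=float)
            all_pts = np.vstack([divalent_pos, frame.positions[on_ids]])
            tree, pts = _periodic_tree(all_pts, frame.box, params.r_ion)
            n_cat = len(divalent_pos)
            cat_tree = cKDTree(pts[:n_cat], boxsize=tree.boxsize)
            on_tree = cKDTree(pts[n_cat:], boxsize=tree.boxsize)
            for hits in cat_tree.query_ball_tree(on_tree, params.r_ion):
                mols = sorted({int(on_mol[h]) for h in hits})
                for a in range(len(mols)):
                    for b in range(a + 1, len(mols)):
                        if not graph.has_edge(mols[a], mols[b]):
                            graph.add_edge(mols[a], mols[b], kind=EdgeKind.DIVALENT_BRIDGE)
    return graph


@dataclass
class ClusterAssignment:
    """Connected components of the molecule graph."""

    component_of: dict[int, int]
    component_sizes: dict[int, int]
    largest_component: int
    members: dict[int, list[int]] = field(default_factory=dict)

    @property
    def largest_members(self) -> set[int]:
        return set(self.members[self.largest_component])

    def in_largest(self, molecule_id: int) -> bool:
        return self.component_of[molecule_id] == self.largest_component


def find_clusters(graph: nx.Graph) -> ClusterAssignment:
    """Connected components; largest by size, ties to smallest molecule id.

    Component ids are assigned deterministically in order of each
    component's smallest molecule id.
    """
    comps = sorted(nx.connected_components(graph), key=min)
    component_of: dict[int, int] = {}
    members: dict[int, list[int]] = {}
    sizes: dict[int, int] = {}
    for cid, comp in enumerate(comps):
        members[cid] = sorted(comp)
        sizes[cid] = len(comp)
        for m in comp:
            component_of[m] = cid
    if comps:
        largest = min(sizes, key=lambda cid: (-sizes[cid], min(members[cid])))
    else:
        largest = -1
    return ClusterAssignment(
        component_of=component_of,
        component_sizes=sizes,
        largest_component=largest,
        members=members,
    )


def largest_cluster_probability(
    assignments: list[ClusterAssignment],
    topology: Topology,
    per_copy: bool = False,
):
    """Probability of largest-cluster membership, pooled per species.

    Counts (copy, frame) pairs found in the largest cluster over
    copies x frames. With ``per_copy`` the probability is returned per
    molecule id instead of pooled per species.
    """
    if not assignments:
        raise ValueError("need at least one frame of cluster assignments")
    som_ids = topology.som_molecule_ids
    nf = len(assignments)
    if per_copy:
        return {
            mid: sum(a.in_largest(mid) for a in assignments) / nf for mid in som_ids
        }
    hits: dict[str, int] = {}
    copies: dict[str, int] = {}
    for mid in som_ids:
        sid = topology.molecules[mid].species_id
        copies[sid] = copies.get(sid, 0) + 1
        hits[sid] = hits.get(sid, 0) + sum(a.in_largest(mid) for a in assignments)
    return {sid: hits[sid] / (copies[sid] * nf) for sid in sorted(copies)}
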