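import numpy as np
import pytest

from maomtools.data import vdw_radius
from maomtools.model import Box, Frame, Molecule, Role, SpeciesRecord, Topology


def make_system(molecules, box, temperature=300.0):
    """Assemble a Frame + Topology from simple molecule dicts.

    Each dict: positions (n, 3); optional elements (default all C), role
    (default SOM), charge (default 0), species_id.
    """
    positions, elements, roles, mol_ids = [], [], [], []
    topo_mols, species = {}, {}
    cursor = 0
    for mid, mol in enumerate(molecules):
        pos = np.asarray(mol["positions"], dtype=float).reshape(-1, 3)
        els = mol.get("elements", ["C"] * len(pos))
        role = mol.get("role", Role.SOM)
        sid = mol.get("species_id", f"TOY{mid}")
        if sid not in species:
            species[sid] = SpeciesRecord(
                species_id=sid,
                name=sid,
                c=sum(1 for e in els if e == "C") or 1,
                h=sum(1 for e in els if e == "H"),
                o=sum(1 for e in els if e == "O"),
                n=sum(1 for e in els if e == "N"),
                formal_charge=mol.get("charge", 0),
                role=role,
            )
        topo_mols[mid] = Molecule(mid, sid, list(range(cursor, cursor + len(pos))))
        positions.append(pos)
        elements.extend(els)
        roles.extend([role] * len(pos))
        mol_ids.extend([mid] * len(pos))
        cursor += len(pos)
    frame = Frame(
        positions=np.vstack(positions),
        elements=np.array(elements, dtype=object),
        roles=np.array(roles, dtype=object),
        molecule_ids=np.array(mol_ids, dtype=np.int64),
        vdw_radii=np.array([vdw_radius(e) for e in elements]),
        box=box,
        temperature=temperature,
    )
    return frame, Topology(molecules=topo_mols, species=species)


def brute_force_min_image(a, b, box):
    """Minimum distance by explicit enumeration of neighbor images."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    shifts = []
    zr = (-1, 0, 1) if box.periodic_z else (0,)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in zr:
                shifts.append((dx * box.lx, dy * box.ly, dz * box.lz))
    return min(np.linalg.norm(b + s - a) for s in np.array(shifts))


def brute_force_edges(frame, topology, r_c):
    """O(N^2) heavy-atom contact edges between SOM molecules."""
    from maomtools.model import minimum_image_displacement

    som = topology.som_molecule_ids
    heavy = {}
    for mid in som:
        ids = [i for i in topology.molecules[mid].atom_ids if frame.elements[i] != "H"]
        heavy[mid] = frame.positions[ids]
    edges = set()
    for i, mi in enumerate(som):
        for mj in som[i + 1 :]:
            d = minimum_image_displacement(
                heavy[mi][:, None, :], heavy[mj][None, :, :], frame.box
            )
            if (np.linalg.norm(d, axis=-1) <= r_c).any():
                edges.add((mi, mj))
    return edges


def bfs_components(nodes, edges):
    """Connected components by BFS from every node (oracle)."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, comps = set(), []
    for n in sorted(nodes):
        if n in seen:
            continue
        comp, queue = {n}, [n]
        while queue:
            cur = queue.pop()
            for nbr in adj[cur]:
                if nbr not in comp:
                    comp.add(nbr)
                    queue.append(nbr)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


def naive_spearman(x, y):
    """Rank-then-Pearson with average ranks for ties (independent oracle)."""
    def ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v))
        sv = v[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def two_sphere_sasa_analytic(r1, r2, d, probe):
    """Closed-form SASA of two overlapping spheres (spherical caps removed)."""
    R1, R2 = r1 + probe, r2 + probe
    full = 4.0 * np.pi * (R1**2 + R2**2)
    if d >= R1 + R2:
        return full
    h1 = R1 - (d**2 + R1**2 - R2**2) / (2.0 * d)
    h2 = R2 - (d**2 + R2**2 - R1**2) / (2.0 * d)
    return full - 2.0 * np.pi * (R1 * h1 + R2 * h2)


def mc_coverage_fractions(frame, layer_ids, box, n_points, seed):
    """Monte-Carlo nearest-atom area fractions (periodic xy), by role."""
    from scipy.spatial import cKDTree

    from maomtools.model import Role

    ids = np.asarray(sorted(layer_ids), dtype=int)
    ids = ids[frame.is_heavy[ids]]
    pts = frame.positions[ids, :2].copy()
    pts[:, 0] = np.mod(pts[:, 0], box.lx)
    pts[:, 1] = np.mod(pts[:, 1], box.ly)
    tree = cKDTree(pts, boxsize=[box.lx, box.ly])
    rng = np.random.default_rng(seed)
    samples = rng.uniform(0, 1, size=(n_points, 2)) * [box.lx, box.ly]
    _, owner = tree.query(samples, k=1)
    roles = frame.roles[ids]
    out = {}
    for role in (Role.WATER, Role.CATION, Role.SOM):
        out[role] = float((roles[owner] == role).mean())
    return out


@pytest.fixture(scope="session")
def library():
    from maomtools.scenes import default_species_library

    return default_species_library()


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic small scene shared by read-only tests."""
    from maomtools.scenes import CounterIon, MineralKind, build_scene, small_scene_spec

    spec = small_scene_spec(MineralKind.SMECTITE_LIKE, CounterIon.NA, seed=11)
    frame, topology, gt = build_scene(spec)
    return spec, frame, topology, gt
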