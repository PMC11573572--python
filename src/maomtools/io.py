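"""Coordinate and topology I/O.

Supported coordinate dialects: GRO (nm, converted to/from Angstrom on the
boundary), XYZ (Angstrom, box carried on the comment line) and a PDB subset
(ATOM/CRYST1/REMARK). Roles and molecule membership round-trip through
residue names/ids in GRO/PDB; XYZ carries coordinates only and needs the
topology sidecar to recover them.

The topology sidecar is JSON; schema documented in the README.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np

from .data import vdw_radius
from .errors import FormatError, GeometryError, ParseError
from .model import (
    RESNAME_TO_ROLE,
    ROLE_TO_RESNAME,
    Box,
    Frame,
    Molecule,
    Role,
    SpeciesRecord,
    Topology,
)

FORMATS = ("GRO", "XYZ", "PDB")


def _infer_format(path) -> str:
    suffix = Path(path).suffix.lower().lstrip(".")
    fmt = suffix.upper()
    if fmt not in FORMATS:
        raise FormatError(f"cannot infer format from suffix {suffix!r}; pass format=")
    return fmt


def _radii_for(elements, topology: Topology | None) -> np.ndarray:
    radii = np.array([vdw_radius(str(e)) for e in elements], dtype=float)
    if topology is not None:
        for aid, r in topology.radius_overrides.items():
            if 0 <= aid < len(radii):
                radii[aid] = r
    return radii


def _apply_topology(elements, roles, molecule_ids, topology: Topology | None):
    """Override per-atom roles/molecule ids from the sidecar when present."""
    if topology is None:
        return roles, molecule_ids
    roles = list(roles)
    molecule_ids = list(molecule_ids)
    for mol in topology.molecules.values():
        role = topology.species[mol.species_id].role
        for aid in mol.atom_ids:
            roles[aid] = role
            molecule_ids[aid] = mol.molecule_id
    return roles, molecule_ids


# --------------------------------------------------------------------------
# GRO

_TEMP_RE = re.compile(r"t=\s*([0-9.eE+-]+)")
_FRAME_RE = re.compile(r"frame=\s*(\d+)")


def _read_gro(path) -> Frame:
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ParseError("GRO file needs title, count and box lines", line=len(lines) or 1)
    title = lines[0]
    try:
        n = int(lines[1].strip())
    except ValueError:
        raise ParseError(f"bad atom count {lines[1]!r}", line=2)
    if len(lines) < n + 3:
        raise ParseError(f"expected {n} atom records", line=len(lines))

    positions = np.empty((n, 3))
    elements, roles, mol_ids = [], [], []
    for i in range(n):
        ln = lines[2 + i]
        try:
            resid = int(ln[0:5])
            resname = ln[5:10].strip()
            name = ln[10:15].strip()
            x = float(ln[20:28])
            y = float(ln[28:36])
            z = float(ln[36:44])
        except (ValueError, IndexError):
            raise ParseError(f"malformed GRO atom record {ln!r}", line=3 + i)
        positions[i] = (x * 10.0, y * 10.0, z * 10.0)  # nm -> Angstrom
        elements.append(name.rstrip("0123456789") or name)
        roles.append(RESNAME_TO_ROLE.get(resname, Role.SOM))
        mol_ids.append(resid - 1)

    box_fields = lines[2 + n].split()
    if len(box_fields) not in (3, 9):
        raise ParseError(f"malformed GRO box line {lines[2 + n]!r}", line=3 + n)
    vals = [float(v) for v in box_fields]
    if len(vals) == 9 and any(abs(v) > 1e-12 for v in vals[3:]):
        raise GeometryError("triclinic boxes are not supported (orthorhombic only)")
    if any(v <= 0 for v in vals[:3]):
        raise ParseError("GRO box lengths must be positive", line=3 + n)
    box = Box(vals[0] * 10.0, vals[1] * 10.0, vals[2] * 10.0, periodic_z="pz=1" in title)

    m = _TEMP_RE.search(title)
    temperature = float(m.group(1)) if m else 300.0
    m = _FRAME_RE.search(title)
    frame_index = int(m.group(1)) if m else 0
    return Frame(
        positions=positions,
        elements=np.array(elements, dtype=object),
        roles=np.array(roles, dtype=object),
        molecule_ids=np.array(mol_ids, dtype=np.int64),
        vdw_radii=_radii_for(elements, None),
        box=box,
        temperature=temperature,
        frame_index=frame_index,
    )


def _write_gro(frame: Frame, path) -> None:
    box = frame.box
    with open(path, "w") as fh:
        pz = 1 if box.periodic_z else 0
        fh.write(f"maomtools t= {frame.temperature:.4f} frame= {frame.frame_index} pz={pz}\n")
        fh.write(f"{frame.n_atoms:5d}\n")
        for i in range(frame.n_atoms):
            resid = (int(frame.molecule_ids[i]) + 1) % 100000
            resname = ROLE_TO_RESNAME[frame.roles[i]]
            name = str(frame.elements[i])
            x, y, z = frame.positions[i] / 10.0  # Angstrom -> nm
            fh.write(
                f"{resid:5d}{resname:<5s}{name:>5s}{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        fh.write(f"{box.lx / 10:10.5f}{box.ly / 10:10.5f}{box.lz / 10:10.5f}\n")


# --------------------------------------------------------------------------
# XYZ

_BOX_RE = re.compile(r"box=\s*([0-9.eE+-]+)\s+([0-9.eE+-]+)\s+([0-9.eE+-]+)")


def _read_xyz(path) -> Frame:
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise ParseError("XYZ file needs count and comment lines", line=1)
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise ParseError(f"bad atom count {lines[0]!r}", line=1)
    comment = lines[1]
    m = _BOX_RE.search(comment)
    if not m:
        raise ParseError("XYZ comment line carries no box= record (periodicity required)", line=2)
    box = Box(
        float(m.group(1)), float(m.group(2)), float(m.group(3)), periodic_z="pz=1" in comment
    )
    if len(lines) < n + 2:
        raise ParseError(f"expected {n} atom records", line=len(lines))

    positions = np.empty((n, 3))
    elements = []
    for i in range(n):
        parts = lines[2 + i].split()
        if len(parts) < 4:
            raise ParseError(f"malformed XYZ record {lines[2 + i]!r}", line=3 + i)
        try:
            positions[i] = [float(v) for v in parts[1:4]]
        except ValueError:
            raise ParseError(f"malformed XYZ record {lines[2 + i]!r}", line=3 + i)
        elements.append(parts[0])

    tm = _TEMP_RE.search(comment)
    fm = _FRAME_RE.search(comment)
    return Frame(
        positions=positions,
        elements=np.array(elements, dtype=object),
        roles=np.array([Role.SOM] * n, dtype=object),
        molecule_ids=np.zeros(n, dtype=np.int64),
        vdw_radii=_radii_for(elements, None),
        box=box,
        temperature=float(tm.group(1)) if tm else 300.0,
        frame_index=int(fm.group(1)) if fm else 0,
    )


def _write_xyz(frame: Frame, path) -> None:
    box = frame.box
    pz = 1 if box.periodic_z else 0
    with open(path, "w") as fh:
        fh.write(f"{frame.n_atoms}\n")
        fh.write(
            f"box= {box.lx:.6f} {box.ly:.6f} {box.lz:.6f} pz={pz} "
            f"t= {frame.temperature:.4f} frame= {frame.frame_index}\n"
        )
        for i in range(frame.n_atoms):
            x, y, z = frame.positions[i]
            fh.write(f"{str(frame.elements[i]):<3s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


# --------------------------------------------------------------------------
# PDB (ATOM/CRYST1/REMARK subset)


def _read_pdb(path) -> Frame:
    positions, elements, roles, mol_ids = [], [], [], []
    box = None
    temperature, frame_index = 300.0, 0
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        rec = ln[:6].strip()
        if rec == "CRYST1":
            try:
                a, b, c = float(ln[6:15]), float(ln[15:24]), float(ln[24:33])
                alpha, beta, gamma = float(ln[33:40]), float(ln[40:47]), float(ln[47:54])
            except ValueError:
                raise ParseError(f"malformed CRYST1 record {ln!r}", line=lineno)
            if any(abs(ang - 90.0) > 1e-6 for ang in (alpha, beta, gamma)):
                raise GeometryError("triclinic boxes are not supported (orthorhombic only)")
            box = Box(a, b, c)
        elif rec == "REMARK":
            tm = _TEMP_RE.search(ln)
            if tm:
                temperature = float(tm.group(1))
            fm = _FRAME_RE.search(ln)
            if fm:
                frame_index = int(fm.group(1))
            if "pz=1" in ln and box is not None:
                box = Box(box.lx, box.ly, box.lz, periodic_z=True)
        elif rec in ("ATOM", "HETATM"):
            try:
                resname = ln[17:20].strip()
                resseq = int(ln[22:26])
                x, y, z = float(ln[30:38]), float(ln[38:46]), float(ln[46:54])
                element = ln[76:78].strip() or ln[12:16].strip().rstrip("0123456789")
            except (ValueError, IndexError):
                raise ParseError(f"malformed ATOM record {ln!r}", line=lineno)
            positions.append((x, y, z))
            elements.append(element)
            roles.append(RESNAME_TO_ROLE.get(resname, Role.SOM))
            mol_ids.append(resseq - 1)
    if not positions:
        raise ParseError("no ATOM records found", line=1)
    if box is None:
        raise ParseError("no CRYST1 record found (periodicity required)", line=1)
    return Frame(
        positions=np.array(positions),
        elements=np.array(elements, dtype=object),
        roles=np.array(roles, dtype=object),
        molecule_ids=np.array(mol_ids, dtype=np.int64),
        vdw_radii=_radii_for(elements, None),
        box=box,
        temperature=temperature,
        frame_index=frame_index,
    )


def _write_pdb(frame: Frame, path) -> None:
    box = frame.box
    pz = 1 if box.periodic_z else 0
    with open(path, "w") as fh:
        fh.write(f"REMARK 100 t= {frame.temperature:.4f} frame= {frame.frame_index} pz={pz}\n")
        fh.write(
            f"CRYST1{box.lx:9.3f}{box.ly:9.3f}{box.lz:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
        )
        for i in range(frame.n_atoms):
            el = str(frame.elements[i])
            resname = ROLE_TO_RESNAME[frame.roles[i]]
            resseq = (int(frame.molecule_ids[i]) + 1) % 10000
            x, y, z = frame.positions[i]
            fh.write(
                f"ATOM  {(i + 1) % 100000:5d} {el:<4s}{resname:>3s}  {resseq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {el:>2s}\n"
            )
        fh.write("END\n")


# --------------------------------------------------------------------------
# public API

_READERS = {"GRO": _read_gro, "XYZ": _read_xyz, "PDB": _read_pdb}
_WRITERS = {"GRO": _write_gro, "XYZ": _write_xyz, "PDB": _write_pdb}


def read_configuration(path, format: str | None = None, topology: Topology | None = None) -> Frame:
    """Read one configuration; positions returned in Angstrom.

    When ``topology`` is given, per-atom roles, molecule ids and radius
    overrides are taken from the sidecar instead of the file's residue fields.
    """
    fmt = (format or _infer_format(path)).upper()
    if fmt not in _READERS:
        raise FormatError(f"unsupported format {fmt!r}; expected one of {FORMATS}")
    frame = _READERS[fmt](path)
    if topology is not None:
        roles, mids = _apply_topology(frame.elements, frame.roles, frame.molecule_ids, topology)
        frame.roles = np.array(roles, dtype=object)
        frame.molecule_ids = np.array(mids, dtype=np.int64)
        frame.vdw_radii = _radii_for(frame.elements, topology)
    return frame


def write_configuration(frame: Frame, topology: Topology | None, path, format: str | None = None) -> None:
    """Write ``frame`` to ``path``; re-readable by :func:`read_configuration`."""
    fmt = (format or _infer_format(path)).upper()
    if fmt not in _WRITERS:
        raise FormatError(f"unsupported format {fmt!r}; expected one of {FORMATS}")
    _WRITERS[fmt](frame, path)


# --------------------------------------------------------------------------
# topology sidecar (JSON)


def topology_to_dict(topology: Topology) -> dict:
    return {
        "species": [
            {
                "species_id": sp.species_id,
                "name": sp.name,
                "c": sp.c, "h": sp.h, "n": sp.n, "o": sp.o, "s": sp.s, "p": sp.p,
                "formal_charge": sp.formal_charge,
                "aromatic_ring_count": sp.aromatic_ring_count,
                "carboxylic_acid_count": sp.carboxylic_acid_count,
                "n_amine_count": sp.n_amine_count,
                "logp": sp.logp,
                "is_peptide": sp.is_peptide,
                "role": sp.role.value,
            }
            for sp in sorted(topology.species.values(), key=lambda s: s.species_id)
        ],
        "molecules": [
            {"molecule_id": m.molecule_id, "species_id": m.species_id, "atom_ids": list(m.atom_ids)}
            for m in sorted(topology.molecules.values(), key=lambda m: m.molecule_id)
        ],
        "metal_ligand_pairs": {str(k): v for k, v in sorted(topology.metal_ligand_pairs.items())},
        "radius_overrides": {str(k): v for k, v in sorted(topology.radius_overrides.items())},
    }


def topology_from_dict(data: dict) -> Topology:
    species = {}
    for sp in data["species"]:
        species[sp["species_id"]] = SpeciesRecord(
            species_id=sp["species_id"],
            name=sp["name"],
            c=sp["c"], h=sp["h"], n=sp["n"], o=sp["o"], s=sp["s"], p=sp["p"],
            formal_charge=sp["formal_charge"],
            aromatic_ring_count=sp["aromatic_ring_count"],
            carboxylic_acid_count=sp["carboxylic_acid_count"],
            n_amine_count=sp["n_amine_count"],
            logp=sp["logp"],
            is_peptide=sp["is_peptide"],
            role=Role(sp["role"]),
        )
    molecules = {
        m["molecule_id"]: Molecule(m["molecule_id"], m["species_id"], list(m["atom_ids"]))
        for m in data["molecules"]
    }
    return Topology(
        molecules=molecules,
        species=species,
        metal_ligand_pairs={int(k): int(v) for k, v in data.get("metal_ligand_pairs", {}).items()},
        radius_overrides={int(k): float(v) for k, v in data.get("radius_overrides", {}).items()},
    )


def write_topology(topology: Topology, path) -> None:
    Path(path).write_text(json.dumps(topology_to_dict(topology), indent=1, sort_keys=True) + "\n")


def read_topology(path) -> Topology:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid topology JSON: {exc}", line=exc.lineno)
    return topology_from_dict(data)
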