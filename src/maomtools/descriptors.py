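"""Per-species chemical descriptors and polar/apolar solvent-accessible area.

Polarity follows the element rule: polar area belongs to O and N atoms,
apolar to every other heavy atom; hydrogens contribute neither area nor
occlusion. Sphere sampling uses a deterministic Fibonacci lattice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import SpeciesRecord

__all__ = [
    "SasaParams",
    "SasaResult",
    "molecular_mass",
    "dbe",
    "van_krevelen",
    "fibonacci_sphere",
    "shrake_rupley_sasa",
    "species_descriptor_table",
]


def molecular_mass(species: SpeciesRecord) -> float:
    """Molecular mass (Da) from element counts and standard atomic weights."""
    return species.mass


def dbe(species: SpeciesRecord) -> float:
    """Double bond equivalents: C - H/2 + N/2 + 1 (S, P valence-neutral)."""
    if species.c < 1:
        raise ValueError("DBE requires at least one carbon")
    return species.c - species.h / 2.0 + species.n / 2.0 + 1.0


def van_krevelen(species: SpeciesRecord) -> tuple[float, float]:
    """(O/C, H/C) atomic ratios."""
    if species.c < 1:
        raise ValueError("van Krevelen ratios require at least one carbon")
    return species.o / species.c, species.h / species.c


@dataclass(frozen=True)
class SasaParams:
    probe_radius: float = 1.4
    n_sphere_points: int = 960

    def __post_init__(self):
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.n_sphere_points < 32:
            raise ValueError("n_sphere_points must be >= 32")


@dataclass
class SasaResult:
    total: float
    polar: float
    apolar: float
    per_atom: np.ndarray


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform points on the unit sphere (deterministic)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    positions: np.ndarray,
    radii: np.ndarray,
    elements,
    params: SasaParams = SasaParams(),
) -> SasaResult:
    """Shrake–Rupley SASA of one molecule in isolation, split polar/apolar.

    Per heavy atom: the fraction of sphere points at radius (r + probe) not
    inside any other heavy atom's expanded sphere, times 4*pi*(r + probe)^2.
    Polar area is the O/N share; hydrogens are excluded entirely.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float)
    elements = np.asarray(elements, dtype=object)
    heavy = elements != "H"
    if not heavy.any():
        raise ValueError("SASA requires at least one heavy atom")
    pos = positions[heavy]
    rad = radii[heavy]
    els = elements[heavy]
    n = len(pos)
    sphere = fibonacci_sphere(params.n_sphere_points)
    expanded = rad + params.probe_radius

    per_atom = np.zeros(n)
    for i in range(n):
        pts = pos[i] + expanded[i] * sphere
        exposed = np.ones(len(pts), dtype=bool)
        buried_whole = False
        for j in range(n):
            if j == i:
                continue
            d_ij = np.linalg.norm(pos[j] - pos[i])
            # neighbor can only occlude if the expanded spheres intersect
            if d_ij >= expanded[i] + expanded[j]:
                continue
            if d_ij < 1e-9:
                # coincident atoms: the larger sphere (or the lower index on a
                # tie) keeps the surface, the other is fully buried
                if expanded[j] > expanded[i] or (expanded[j] == expanded[i] and j < i):
                    buried_whole = True
                    break
                continue
            d2 = np.einsum("ij,ij->i", pts - pos[j], pts - pos[j])
            exposed &= d2 > expanded[j] ** 2
        if buried_whole:
            continue
        per_atom[i] = exposed.mean() * 4.0 * np.pi * expanded[i] ** 2

    polar_mask = np.isin(els, ("O", "N"))
    polar = float(per_atom[polar_mask].sum())
    apolar = float(per_atom[~polar_mask].sum())
    full = np.zeros(len(positions))
    full[heavy] = per_atom
    return SasaResult(total=polar + apolar, polar=polar, apolar=apolar, per_atom=full)


def species_sasa(species: SpeciesRecord, params: SasaParams = SasaParams()) -> SasaResult:
    """SASA of a species' template geometry with the built-in radius table."""
    from .data import vdw_radius

    if species.template_coords is None:
        raise ValueError(f"species {species.species_id!r} has no template geometry")
    radii = np.array([vdw_radius(el) for el in species.template_elements])
    return shrake_rupley_sasa(species.template_coords, radii, species.template_elements, params)


def species_descriptor_table(
    library: list[SpeciesRecord], sasa_params: SasaParams = SasaParams()
) -> pd.DataFrame:
    """One descriptor row per species, indexed by species_id."""
    rows = []
    for sp in library:
        o_to_c, h_to_c = van_krevelen(sp)
        sasa = species_sasa(sp, sasa_params)
        rows.append(
            {
                "species_id": sp.species_id,
                "mass": sp.mass,
                "formal_charge": sp.formal_charge,
                "dbe": dbe(sp),
                "aromatic_ring_count": sp.aromatic_ring_count,
                "carboxylic_acid_count": sp.carboxylic_acid_count,
                "n_amine_count": sp.n_amine_count,
                "o_to_c": o_to_c,
                "h_to_c": h_to_c,
                "polar_sasa": sasa.polar,
                "apolar_sasa": sasa.apolar,
                "total_sasa": sasa.total,
                "logp": sp.logp if sp.logp is not None else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("species_id").sort_index()
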