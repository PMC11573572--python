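"""Built-in element tables: standard atomic weights and van der Waals radii.

The radius table follows Bondi-style values and is the package default for
solvent-accessible surface area and overlap checks; individual atoms may
override it through the topology sidecar.
"""

# Standard atomic weights (Da), CIAAW conventional values.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "Na": 22.990,
    "Ca": 40.078,
    "Mg": 24.305,
    "Al": 26.982,
    "Si": 28.085,
    "Fe": 55.845,
}

# Bondi-style van der Waals radii (Angstrom). Metals use common
# crystallographic-ish defaults; only consistency matters for the contracts.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "Na": 2.27,
    "Ca": 2.31,
    "Mg": 1.73,
    "Al": 1.84,
    "Si": 2.10,
    "Fe": 2.00,
}

DEFAULT_VDW_RADIUS = 1.70


def atomic_weight(element: str) -> float:
    try:
        return ATOMIC_WEIGHTS[element]
    except KeyError:
        raise KeyError(f"no standard atomic weight for element {element!r}")


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element, DEFAULT_VDW_RADIUS)
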