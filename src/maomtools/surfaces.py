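"""Discrete atomic layers above the slab and per-layer Voronoi area coverage.

Layers are disjoint z-bands of non-mineral heavy atoms found from the
z-density profile (empty-gap separation), with a flagged fallback to fixed
3.0 A bands when the profile does not resolve. Coverage partitions the full
lx*ly cross-section among the layer's atoms by periodic 2D Voronoi
tessellation (3x3 image replication, central-copy extraction) and sums cell
areas by role.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi

from .errors import GeometryError, SurfaceError
from .model import Box, Frame, Role, Topology

__all__ = ["LayerAssignment", "CoverageResult", "assign_layers", "layer_coverage"]

FALLBACK_BAND_WIDTH = 3.0


@dataclass
class LayerAssignment:
    """First-N z-bands above the mineral surface (1-based layer keys)."""

    layers: dict[int, np.ndarray]
    bounds: dict[int, tuple[float, float]]
    z_top: float
    fallback: bool = False


def assign_layers(
    frame: Frame,
    topology: Topology,
    n_layers: int = 4,
    bin_width: float = 0.2,
) -> LayerAssignment:
    """Assign non-mineral heavy atoms to the first ``n_layers`` z-bands.

    Band boundaries are the empty gaps of the binned z-density profile above
    the top mineral plane; when fewer than ``n_layers`` bands resolve, fixed
    3.0 A bands are used and ``fallback`` is set.
    """
    mineral = frame.roles == Role.MINERAL
    if not mineral.any():
        raise SurfaceError("no mineral slab present")
    z_top = float(frame.positions[mineral, 2].max())

    candidate = (~mineral) & frame.is_heavy & (frame.positions[:, 2] > z_top)
    ids = np.where(candidate)[0]
    if ids.size == 0:
        raise SurfaceError("no atoms above the mineral surface")
    z = frame.positions[ids, 2] - z_top

    zmax = z.max()
    edges = np.arange(0.0, zmax + 2 * bin_width, bin_width)
    counts, edges = np.histogram(z, bins=edges)

    # contiguous occupied runs of the profile
    occupied = counts > 0
    bands: list[tuple[float, float]] = []
    start = None
    for i, occ in enumerate(occupied):
        if occ and start is None:
            start = i
        elif not occ and start is not None:
            bands.append((edges[start], edges[i]))
            start = None
    if start is not None:
        bands.append((edges[start], edges[len(occupied)]))

    fallback = len(bands) < n_layers
    if fallback:
        bands = [
            (k * FALLBACK_BAND_WIDTH, (k + 1) * FALLBACK_BAND_WIDTH) for k in range(n_layers)
        ]
    layers: dict[int, np.ndarray] = {}
    bounds: dict[int, tuple[float, float]] = {}
    for k in range(n_layers):
        lo, hi = bands[k]
        in_band = (z >= lo) & (z < hi)
        layers[k + 1] = ids[in_band]
        bounds[k + 1] = (z_top + lo, z_top + hi)
    return LayerAssignment(layers=layers, bounds=bounds, z_top=z_top, fallback=fallback)


@dataclass
class CoverageResult:
    """Area fractions of one layer; area-weighted primary, count-weighted aside."""

    fraction_water: float
    fraction_ion: float
    fraction_som: float
    count_fraction_water: float = 0.0
    count_fraction_ion: float = 0.0
    count_fraction_som: float = 0.0
    total_area: float = 0.0
    empty: bool = False
    areas_by_atom: dict[int, float] = field(default_factory=dict)


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))


def layer_coverage(frame: Frame, topology: Topology, layer_atom_ids, box: Box | None = None) -> CoverageResult:
    """Voronoi area coverage of one layer over the xy cross-section.

    Layer atoms (heavy, non-mineral) are projected to xy, replicated in the
    3x3 periodic images, tessellated, and the central-copy cell areas summed
    by role. Fractions are cell area / (lx*ly).
    """
    box = box or frame.box
    ids = np.asarray(sorted(int(i) for i in np.asarray(layer_atom_ids).ravel()), dtype=int)
    ids = ids[frame.is_heavy[ids]]
    total_area = box.lx * box.ly
    if ids.size == 0:
        return CoverageResult(0.0, 0.0, 0.0, total_area=total_area, empty=True)
    roles = frame.roles[ids]
    if (roles == Role.MINERAL).any():
        raise ValueError("layer contains mineral atoms; coverage is defined for non-mineral layers")

    pts = frame.positions[ids, :2].copy()
    pts[:, 0] = np.mod(pts[:, 0], box.lx)
    pts[:, 1] = np.mod(pts[:, 1], box.ly)
    offsets = [(0, 0)] + [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]
    tiled = np.vstack([pts + np.array([dx * box.lx, dy * box.ly]) for dx, dy in offsets])

    if ids.size == 1:
        # a single atom owns the whole cross-section
        areas = np.array([total_area])
    else:
        vor = Voronoi(tiled)
        areas = np.empty(ids.size)
        for i in range(ids.size):
            region = vor.regions[vor.point_region[i]]
            if -1 in region or len(region) == 0:
                raise GeometryError(
                    "unbounded central Voronoi cell; 3x3 replication insufficient for this layer"
                )
            areas[i] = _polygon_area(vor.vertices[region])
        if abs(areas.sum() - total_area) > 1e-9 * total_area:
            raise GeometryError(
                f"Voronoi area not conserved: {areas.sum():.6f} vs {total_area:.6f}"
            )

    def frac(role: Role) -> float:
        return float(areas[roles == role].sum() / total_area)

    n = ids.size
    return CoverageResult(
        fraction_water=frac(Role.WATER),
        fraction_ion=frac(Role.CATION),
        fraction_som=frac(Role.SOM),
        count_fraction_water=float((roles == Role.WATER).sum() / n),
        count_fraction_ion=float((roles == Role.CATION).sum() / n),
        count_fraction_som=float((roles == Role.SOM).sum() / n),
        total_area=total_area,
        empty=False,
        areas_by_atom={int(a): float(ar) for a, ar in zip(ids, areas)},
    )
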