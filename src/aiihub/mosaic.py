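"""Spatial statistics of cell mosaics.

Density, nearest-neighbor spacing with a boundary guard zone, Voronoi tile
jitter, coverage factor, and the square-grid connectivity predicted by a
given coverage factor.  Tile spacing follows the square-measure convention
``1/sqrt(density)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Polygon

__all__ = [
    "MosaicStats",
    "planar_density",
    "tile_spacing_um",
    "nn_spacing",
    "voronoi_jitter",
    "coverage_factor",
    "predicted_grid_connectivity",
    "mosaic_stats",
]


@dataclass
class MosaicStats:
    n_cells: int
    density_per_mm2: float
    tile_spacing_um: float
    nn_mean_um: float
    nn_sd_um: float
    nn_n: int
    jitter: float
    coverage_factor: float


def planar_density(points_um: np.ndarray, field_diameter_mm: float) -> float:
    """Cell density (cells/mm^2) of points in a circular field."""
    points_um = np.asarray(points_um, dtype=float)
    if len(points_um) < 1:
        raise ValueError("need at least one point")
    if field_diameter_mm <= 0:
        raise ValueError("field diameter must be positive")
    area_mm2 = math.pi * (field_diameter_mm / 2.0) ** 2
    return len(points_um) / area_mm2


def tile_spacing_um(density_per_mm2: float) -> float:
    """Center-to-center tile spacing (um), square-measure convention."""
    return 1000.0 / math.sqrt(density_per_mm2)


def _interior_mask(
    points_um: np.ndarray, field_diameter_mm: float, guard_um: float
) -> np.ndarray:
    center = points_um.mean(axis=0) if len(points_um) else np.zeros(2)
    r = np.linalg.norm(points_um - center, axis=1)
    return r <= field_diameter_mm * 500.0 - guard_um  # mm/2 -> um


def nn_spacing(
    points_um: np.ndarray,
    field_diameter_mm: float | None = None,
    edge_guard_um: float = 0.0,
) -> tuple[float, float, int]:
    """Nearest-neighbor distance statistics: (mean, sample SD, n focal points).

    Points within ``edge_guard_um`` of the circular field boundary are
    excluded as focal points (their true nearest neighbor may fall outside
    the field) but still serve as neighbors.
    """
    points_um = np.asarray(points_um, dtype=float)
    if len(points_um) < 2:
        raise ValueError("need at least two points")
    tree = cKDTree(points_um)
    d, _ = tree.query(points_um, k=2)
    nn = d[:, 1]
    if field_diameter_mm is not None and edge_guard_um > 0:
        mask = _interior_mask(points_um, field_diameter_mm, edge_guard_um)
        nn = nn[mask]
    if len(nn) == 0:
        raise ValueError("edge guard excluded every focal point")
    sd = float(np.std(nn, ddof=1)) if len(nn) > 1 else 0.0
    return float(np.mean(nn)), sd, int(len(nn))


def voronoi_jitter(
    points_um: np.ndarray,
    field_diameter_mm: float,
    edge_guard_um: float | None = None,
) -> float:
    """Mean soma-to-Voronoi-tile-centroid offset, normalized by tile spacing.

    Only interior tiles are used: bounded tiles whose generating point lies
    more than one guard distance (default: one tile spacing) from the field
    boundary.  Raises if no interior tile remains.
    """
    points_um = np.asarray(points_um, dtype=float)
    if len(points_um) < 3:
        raise ValueError("need at least three points")
    density = planar_density(points_um, field_diameter_mm)
    spacing = tile_spacing_um(density)
    guard = spacing if edge_guard_um is None else edge_guard_um
    vor = Voronoi(points_um)
    interior = _interior_mask(points_um, field_diameter_mm, guard)
    offsets = []
    for i, region_idx in enumerate(vor.point_region):
        if not interior[i]:
            continue
        region = vor.regions[region_idx]
        if not region or -1 in region:
            continue  # unbounded tile
        poly = Polygon(vor.vertices[region])
        if poly.area <= 0:
            continue
        c = poly.centroid
        offsets.append(math.hypot(points_um[i, 0] - c.x,
                                  points_um[i, 1] - c.y))
    if not offsets:
        raise ValueError("no interior Voronoi tiles; field too small")
    return float(np.mean(offsets)) / spacing


def coverage_factor(arbor_diameter_um: float, tile_spacing: float) -> float:
    """Coverage factor C = (arbor diameter / tile spacing)^2."""
    if arbor_diameter_um <= 0 or tile_spacing <= 0:
        raise ValueError("arbor diameter and spacing must be positive")
    return (arbor_diameter_um / tile_spacing) ** 2


def predicted_grid_connectivity(C: float) -> int:
    """Number of square-lattice neighbors whose arbors strictly overlap a
    focal cell's arbor at coverage factor ``C``.

    With arbor diameter sqrt(C) x spacing, two arbors of lattice offset
    (dx, dy) overlap iff dx^2 + dy^2 < C (tangency excluded).  C = 4 gives
    the 8-connected prediction.
    """
    if C <= 0:
        raise ValueError("coverage factor must be positive")
    m = math.isqrt(math.ceil(C))
    count = 0
    for dx in range(-m, m + 1):
        for dy in range(-m, m + 1):
            if (dx, dy) != (0, 0) and dx * dx + dy * dy < C:
                count += 1
    return count


def mosaic_stats(
    points_um: np.ndarray,
    field_diameter_mm: float,
    arbor_diameter_um: float,
    edge_guard_um: float | None = None,
) -> MosaicStats:
    """Full mosaic report for one cell class."""
    points_um = np.asarray(points_um, dtype=float)
    density = planar_density(points_um, field_diameter_mm)
    spacing = tile_spacing_um(density)
    guard = spacing if edge_guard_um is None else edge_guard_um
    nn_mean, nn_sd, nn_n = nn_spacing(points_um, field_diameter_mm, guard)
    jitter = voronoi_jitter(points_um, field_diameter_mm, guard)
    return MosaicStats(
        n_cells=len(points_um),
        density_per_mm2=density,
        tile_spacing_um=spacing,
        nn_mean_um=nn_mean,
        nn_sd_um=nn_sd,
        nn_n=nn_n,
        jitter=jitter,
        coverage_factor=coverage_factor(arbor_diameter_um, spacing),
    )
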