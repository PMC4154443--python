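"""Disc-stack geometry: Feret diameters, contact areas, IPL depth,
compartments, contact resolution, depth profiles, lateral spreads and
convex-hull fields.

Conventions
-----------
A child structure annotated as per-slice Feret-diameter discs is measured as

- Feret diameter = max over slices of the disc diameter, and
- contact area   = sum over slices of (diameter x section thickness),

which treats the annotation as a profile through a roughly planar junction.
Depth through the inner plexiform layer is the normalized 0-25 scale of
:class:`~aiihub.model.VolumeMeta` (0 = amacrine cell layer side, 25 =
ganglion cell layer side); somas and necks may sit above 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from shapely.geometry import Polygon

from .model import (
    AnnotationDB,
    CATEGORIES,
    ContactPair,
    StructureRecord,
    VolumeMeta,
    in_group,
)

__all__ = [
    "feret_diameter",
    "structure_area",
    "ipl_depth",
    "assign_compartment",
    "classify_contact",
    "resolve_contacts",
    "DepthProfile",
    "depth_profile",
    "lateral_spread",
    "convex_hull_field",
    "MalformedLinkError",
    "DEPTH_BIN_LO",
    "DEPTH_BIN_HI",
    "OFF_ON_BOUNDARY",
]

#: depth range covered by profile bins; contacts outside [0, 25] (e.g. on
#: the neck, above the IPL) still land in a bin so area is conserved
DEPTH_BIN_LO = -5
DEPTH_BIN_HI = 30

#: OFF/ON sublamina boundary on the 0-25 depth scale (40% depth)
OFF_ON_BOUNDARY = 10.0


class MalformedLinkError(ValueError):
    """A structure link that cannot be resolved into a contact."""


def feret_diameter(s: StructureRecord) -> float:
    """Maximum Feret diameter (nm) of a child structure across its slices."""
    if s.kind == "cell":
        raise ValueError("Feret diameter is undefined for whole-cell traces")
    if not s.discs:
        raise ValueError(f"structure {s.structure_id} has no discs")
    return max(2.0 * d.radius_nm for d in s.discs)


def structure_area(s: StructureRecord, meta: VolumeMeta) -> float:
    """Contact area (um^2) of a child structure: sum over slices of
    Feret diameter x section thickness."""
    if not s.discs:
        raise ValueError(f"structure {s.structure_id} has no discs")
    total_nm2 = 0.0
    for d in s.discs:
        if d.radius_nm <= 0:
            raise ValueError(
                f"zero-radius disc on structure {s.structure_id}"
            )
        total_nm2 += 2.0 * d.radius_nm * meta.section_thickness_nm
    return total_nm2 * 1e-6  # nm^2 -> um^2


def ipl_depth(z: float, meta: VolumeMeta) -> float:
    """Normalized IPL depth of section index ``z`` (0 at top, 25 at bottom;
    values outside [0, 25] are permitted for somas and necks)."""
    return 25.0 * (z - meta.ipl_top_z) / (meta.ipl_bottom_z - meta.ipl_top_z)


def assign_compartment(depth: float) -> str:
    """AII compartment at a normalized depth: neck above the IPL, lobules in
    the OFF sublamina, waist at the sublamina border zone, arboreal below."""
    if depth < 0:
        return "neck"
    if depth < 10:
        return "lobule"
    if depth < 15:
        return "waist"
    return "arboreal"


def _structure_depth_stats(
    s: StructureRecord, meta: VolumeMeta
) -> tuple[float, float]:
    """(area-weighted mean depth, total area um^2) over a structure's discs."""
    wsum = 0.0
    dsum = 0.0
    for d in s.discs:
        w = 2.0 * d.radius_nm * meta.section_thickness_nm
        wsum += w
        dsum += w * ipl_depth(d.z, meta)
    return dsum / wsum, wsum * 1e-6


def classify_contact(
    kind: str,
    pre_class: str,
    post_class: str,
    depth: float,
) -> str | None:
    """Functional category of a resolved contact, or None if it falls outside
    the tracked AII-focal categories (adherens, touches, non-AII contacts)."""
    if kind == "gap_junction":
        classes = {pre_class, post_class}
        if classes == {"AII"}:
            return "coupling_AII_AII"
        if "AII" in classes and any(in_group(c, "CBb") for c in classes):
            return "coupling_AII_CBb"
        return None
    if kind == "ribbon_input" and post_class == "AII":
        if pre_class == "RodBC":
            return "rodBC_input"
        if in_group(pre_class, "CBa"):
            return "OFF_BC_input"
        if pre_class == "CBb7":
            return "CBb7_ribbon_input"
        return None
    if kind == "conventional_synapse":
        if post_class == "AII":
            if pre_class == "TH1":
                return "TH1_input"
            if in_group(pre_class, "AC"):
                return ("AC_input_ON" if depth >= OFF_ON_BOUNDARY
                        else "AC_input_OFF")
            return None
        if pre_class == "AII":
            if in_group(post_class, "BC"):
                return "output_BC"
            if in_group(post_class, "AC"):
                return "output_AC"
            if in_group(post_class, "GC"):
                return "output_GC"
        return None
    return None


_PRESYN_KINDS = ("ribbon_presyn", "conventional_presyn")


def resolve_contacts(db: AnnotationDB) -> list[ContactPair]:
    """Resolve every structure link into a :class:`ContactPair`.

    Presynapse<->PSD links become directed synaptic contacts; gap-junction,
    adherens and touch links become unordered contacts in canonical order.
    Contact area, diameter and depth are measured on the presynaptic (or
    smaller-id) side.  A link joining two presynaptic structures raises
    :class:`MalformedLinkError`.
    """
    meta = db.meta
    contacts: list[ContactPair] = []
    seen: set[tuple[int, int]] = set()
    for s in db.structures.values():
        for lid in s.link_ids:
            key = (min(s.structure_id, lid), max(s.structure_id, lid))
            if key in seen:
                continue
            seen.add(key)
            a, b = db.structures[key[0]], db.structures[key[1]]
            if a.kind in _PRESYN_KINDS and b.kind in _PRESYN_KINDS:
                raise MalformedLinkError(
                    f"link ({a.structure_id}, {b.structure_id}) joins two "
                    "presynaptic structures"
                )
            if a.kind in _PRESYN_KINDS or b.kind in _PRESYN_KINDS:
                pre, post = (a, b) if a.kind in _PRESYN_KINDS else (b, a)
                if post.kind != "psd":
                    raise MalformedLinkError(
                        f"link ({a.structure_id}, {b.structure_id}): "
                        f"presynapse linked to {post.kind!r}, expected psd"
                    )
                kind = ("ribbon_input" if pre.kind == "ribbon_presyn"
                        else "conventional_synapse")
                ref = pre
            elif a.kind == b.kind and a.kind in ("gap_junction", "adherens",
                                                 "touch"):
                pre, post = a, b  # canonical order by id
                kind = a.kind
                ref = a
            else:
                raise MalformedLinkError(
                    f"link ({a.structure_id}, {b.structure_id}) joins "
                    f"incompatible kinds {a.kind!r} and {b.kind!r}"
                )
            depth, area = _structure_depth_stats(ref, meta)
            diameter = feret_diameter(ref)
            pre_class = db.cell_class(pre.parent_cell)
            post_class = db.cell_class(post.parent_cell)
            contacts.append(
                ContactPair(
                    pre_cell=pre.parent_cell,
                    post_cell=post.parent_cell,
                    kind=kind,
                    category=classify_contact(kind, pre_class, post_class,
                                              depth),
                    pre_compartment=assign_compartment(
                        _structure_depth_stats(pre, meta)[0]
                    ),
                    post_compartment=assign_compartment(
                        _structure_depth_stats(post, meta)[0]
                    ),
                    area_um2=area,
                    diameter_nm=diameter,
                    depth=depth,
                    pre_structure=pre.structure_id,
                    post_structure=post.structure_id,
                )
            )
    return contacts


@dataclass
class DepthProfile:
    """Contact area per unit-depth bin for one category."""

    category: str
    bin_edges: np.ndarray  # len n_bins + 1, unit-width, half-open [i, i+1)
    area_per_bin: np.ndarray

    @property
    def total_area(self) -> float:
        return float(self.area_per_bin.sum())

    def occupied_bins(self) -> set[int]:
        """Indices of the lower bin edges with non-zero area."""
        lo = self.bin_edges[:-1]
        return {int(lo[i]) for i in np.nonzero(self.area_per_bin)[0]}


def depth_profile(
    contacts: list[ContactPair], category: str
) -> DepthProfile:
    """Bin contact areas of one category into unit-depth bins.

    Bins span [DEPTH_BIN_LO, DEPTH_BIN_HI) so the sum over bins equals the
    sum of contributing contact areas exactly (conservation).
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    edges = np.arange(DEPTH_BIN_LO, DEPTH_BIN_HI + 1, dtype=float)
    areas = np.zeros(len(edges) - 1)
    for c in contacts:
        if c.category != category:
            continue
        i = int(np.clip(math.floor(c.depth) - DEPTH_BIN_LO, 0,
                        len(areas) - 1))
        areas[i] += c.area_um2
    return DepthProfile(category=category, bin_edges=edges,
                        area_per_bin=areas)


def _zone_points_um(
    db: AnnotationDB, cell_id: int, zone: str
) -> np.ndarray:
    s = next(
        (
            st
            for st in db.structures.values()
            if st.kind == "cell" and st.parent_cell == cell_id
        ),
        None,
    )
    if s is None:
        raise ValueError(f"cell {cell_id} has no cell-kind structure")
    pts = [
        (d.x_nm * 1e-3, d.y_nm * 1e-3)
        for d in s.discs
        if assign_compartment(ipl_depth(d.z, db.meta)) == zone
    ]
    return np.asarray(pts, dtype=float)


def lateral_spread(
    db: AnnotationDB, cell_ids: list[int], zone: str
) -> dict:
    """Mean +/- sample SD of per-cell lateral extent (um) in one zone.

    Per-cell extent is the maximum pairwise XY distance between the cell's
    zone discs after centering on the zone centroid; single-cell input
    reports SD 0 with an ``n=1`` flag.
    """
    if not cell_ids:
        raise ValueError("need at least one cell")
    extents = []
    for cid in cell_ids:
        pts = _zone_points_um(db, cid, zone)
        if len(pts) < 2:
            extents.append(0.0)
            continue
        pts = pts - pts.mean(axis=0)
        extents.append(float(pdist(pts).max()))
    extents_arr = np.asarray(extents)
    n = len(extents_arr)
    return {
        "zone": zone,
        "n": n,
        "mean_um": float(extents_arr.mean()),
        "sd_um": float(extents_arr.std(ddof=1)) if n > 1 else 0.0,
        "single_cell": n == 1,
    }


def convex_hull_field(
    db: AnnotationDB, cell_id: int, zone: str
) -> tuple[Polygon, float]:
    """2D convex hull (XY, um) of a cell's zone disc centers and its area
    (um^2).  Fewer than 3 points, or collinear points, raise ValueError."""
    pts = _zone_points_um(db, cell_id, zone)
    if len(pts) < 3:
        raise ValueError(
            f"cell {cell_id}: need >=3 points in zone {zone!r} for a hull"
        )
    try:
        hull = ConvexHull(pts)
    except Exception as e:
        raise ValueError(
            f"cell {cell_id}: degenerate (collinear) hull in zone {zone!r}"
        ) from e
    poly = Polygon(pts[hull.vertices])
    return poly, float(poly.area)
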