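"""Domain types for disc-annotation connectome volumes.

The data model mirrors the export of a serial-section annotation database:
each cell is traced as a stack of per-slice inscribed discs, and child
structures (ribbon and conventional presynapses, postsynaptic densities,
gap junctions, adherens junctions, and non-synaptic touches) are annotated
as per-slice discs of the structure's Feret diameter, linked across cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "VolumeMeta",
    "CellRecord",
    "DiscAnnotation",
    "StructureRecord",
    "AnnotationDB",
    "ContactPair",
    "CELL_CLASSES",
    "CLASS_GROUPS",
    "CHILD_KINDS",
    "CONTACT_KINDS",
    "COMPARTMENTS",
    "CATEGORIES",
    "class_polarity",
    "class_transmitter",
    "in_group",
]

#: child-structure kinds; ``cell`` is reserved for the parent trace itself
CHILD_KINDS = (
    "ribbon_presyn",
    "conventional_presyn",
    "psd",
    "gap_junction",
    "adherens",
    "touch",
)

#: resolved contact kinds
CONTACT_KINDS = (
    "ribbon_input",
    "conventional_synapse",
    "gap_junction",
    "adherens",
    "touch",
)

COMPARTMENTS = ("neck", "lobule", "waist", "arboreal")

#: functional contact categories used for depth profiles and weighting
CATEGORIES = (
    "rodBC_input",
    "OFF_BC_input",
    "CBb7_ribbon_input",
    "TH1_input",
    "AC_input_ON",
    "AC_input_OFF",
    "coupling_AII_AII",
    "coupling_AII_CBb",
    "output_BC",
    "output_AC",
    "output_GC",
)

# class -> (polarity, transmitter).  AII cells are glycinergic; TH1 axonal
# cells are dual glutamate/dopamine neurons; ganglion cells are glutamatergic.
_CLASS_INFO: dict[str, tuple[str, str]] = {
    "AII": ("ON-OFF", "glycine"),
    "RodBC": ("ON", "glutamate"),
    "CBa1": ("OFF", "glutamate"),
    "CBa2": ("OFF", "glutamate"),
    "CBa3": ("OFF", "glutamate"),
    "CBa4": ("OFF", "glutamate"),
    "CBa5": ("OFF", "glutamate"),
    "CBa6": ("OFF", "glutamate"),
    "CBb3": ("ON", "glutamate"),
    "CBb4w": ("ON", "glutamate"),
    "CBb5w": ("ON", "glutamate"),
    "CBb4-5i": ("ON", "glutamate"),
    "CBb5-6i": ("ON", "glutamate"),
    "CBb6": ("ON", "glutamate"),
    "CBb7": ("ON", "glutamate"),
    "TH1": ("ON", "glutamate+dopamine"),
    "AI": ("ON", "GABA"),
    "GAC": ("ON", "glycine"),
    "gammaAC": ("ON-OFF", "GABA"),
    "OFF-alpha-GC": ("OFF", "glutamate"),
    "OFF-delta-GC": ("OFF", "glutamate"),
    "other": ("n/a", "n/a"),
}

CELL_CLASSES = tuple(_CLASS_INFO)

#: superclass groups used by connectivity rules and contact categories
CLASS_GROUPS: dict[str, tuple[str, ...]] = {
    "CBa": ("CBa1", "CBa2", "CBa3", "CBa4", "CBa5", "CBa6"),
    "CBb": ("CBb3", "CBb4w", "CBb5w", "CBb4-5i", "CBb5-6i", "CBb6", "CBb7"),
    "CBb_non7": ("CBb3", "CBb4w", "CBb5w", "CBb4-5i", "CBb5-6i", "CBb6"),
    "AC": ("AI", "GAC", "gammaAC"),
    "GC": ("OFF-alpha-GC", "OFF-delta-GC"),
    "BC": ("RodBC", "CBa1", "CBa2", "CBa3", "CBa4", "CBa5", "CBa6",
           "CBb3", "CBb4w", "CBb5w", "CBb4-5i", "CBb5-6i", "CBb6", "CBb7"),
}


def class_polarity(cell_class: str) -> str:
    return _CLASS_INFO[cell_class][0]


def class_transmitter(cell_class: str) -> str:
    return _CLASS_INFO[cell_class][1]


def in_group(cell_class: str, group: str) -> bool:
    """True if ``cell_class`` matches ``group`` (a class name, a group name,
    or the wildcard ``"any"``)."""
    if group == "any":
        return True
    if group in CLASS_GROUPS:
        return cell_class in CLASS_GROUPS[group]
    return cell_class == group


@dataclass(frozen=True)
class VolumeMeta:
    """Calibration of one annotation volume.

    Depth through the inner plexiform layer (IPL) is a normalized 0-25 scale:
    0 at the amacrine cell layer side, 25 at the ganglion cell layer side,
    linear in section index between ``ipl_top_z`` and ``ipl_bottom_z``.
    """

    field_diameter_mm: float = 0.243
    section_thickness_nm: float = 80.0
    n_sections: int = 401
    ipl_top_z: int = 80
    ipl_bottom_z: int = 392
    pixel_size_nm: float = 2.18

    def __post_init__(self) -> None:
        if self.field_diameter_mm <= 0:
            raise ValueError("field_diameter_mm must be positive")
        if not (70.0 <= self.section_thickness_nm <= 90.0):
            raise ValueError("section_thickness_nm must be in [70, 90] nm")
        if self.ipl_top_z >= self.ipl_bottom_z:
            raise ValueError("ipl_top_z must be below ipl_bottom_z")


@dataclass(frozen=True)
class CellRecord:
    cell_id: int
    cell_class: str
    soma_x_nm: float
    soma_y_nm: float

    def __post_init__(self) -> None:
        if self.cell_class not in _CLASS_INFO:
            raise ValueError(f"unknown cell class {self.cell_class!r}")

    @property
    def polarity(self) -> str:
        return class_polarity(self.cell_class)

    @property
    def transmitter(self) -> str:
        return class_transmitter(self.cell_class)


@dataclass(frozen=True)
class DiscAnnotation:
    structure_id: int
    z: int
    x_nm: float
    y_nm: float
    radius_nm: float

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise ValueError(
                f"disc on structure {self.structure_id} has non-positive radius"
            )


@dataclass
class StructureRecord:
    structure_id: int
    kind: str  # 'cell' or one of CHILD_KINDS
    parent_cell: int
    discs: list[DiscAnnotation] = field(default_factory=list)
    link_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind != "cell" and self.kind not in CHILD_KINDS:
            raise ValueError(f"unknown structure kind {self.kind!r}")


@dataclass
class AnnotationDB:
    """Relational bundle of cells, structures, discs and links."""

    meta: VolumeMeta
    cells: dict[int, CellRecord] = field(default_factory=dict)
    structures: dict[int, StructureRecord] = field(default_factory=dict)

    def add_cell(self, cell: CellRecord) -> None:
        if cell.cell_id in self.cells:
            raise ValueError(f"duplicate cell_id {cell.cell_id}")
        self.cells[cell.cell_id] = cell

    def add_structure(self, s: StructureRecord) -> None:
        if s.structure_id in self.structures:
            raise ValueError(f"duplicate structure_id {s.structure_id}")
        self.structures[s.structure_id] = s

    def cell_class(self, cell_id: int) -> str:
        return self.cells[cell_id].cell_class

    def structures_of_kind(self, kind: str) -> Iterable[StructureRecord]:
        return (s for s in self.structures.values() if s.kind == kind)

    def class_census(self) -> dict[str, int]:
        census: dict[str, int] = {}
        for c in self.cells.values():
            census[c.cell_class] = census.get(c.cell_class, 0) + 1
        return census

    def validate_refs(self) -> None:
        """Raise if any parent_cell or link_id dangles, or a disc is orphaned."""
        for s in self.structures.values():
            if s.parent_cell not in self.cells:
                raise ValueError(
                    f"structure {s.structure_id} references missing cell "
                    f"{s.parent_cell}"
                )
            for lid in s.link_ids:
                if lid not in self.structures:
                    raise ValueError(
                        f"structure {s.structure_id} links to missing "
                        f"structure {lid}"
                    )
            for d in s.discs:
                if d.structure_id != s.structure_id:
                    raise ValueError(
                        f"disc attached to structure {s.structure_id} carries "
                        f"id {d.structure_id}"
                    )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationDB):
            return NotImplemented
        if self.meta != other.meta or self.cells != other.cells:
            return False
        if set(self.structures) != set(other.structures):
            return False
        for sid, s in self.structures.items():
            o = other.structures[sid]
            if (s.kind, s.parent_cell) != (o.kind, o.parent_cell):
                return False
            if sorted(s.discs, key=lambda d: (d.z, d.x_nm, d.y_nm)) != sorted(
                o.discs, key=lambda d: (d.z, d.x_nm, d.y_nm)
            ):
                return False
            if sorted(s.link_ids) != sorted(o.link_ids):
                return False
        return True


@dataclass(frozen=True)
class ContactPair:
    """A resolved pre/post (or coupled) cell pair.

    For gap junctions the pair is unordered; ``pre_cell``/``post_cell`` hold
    the two coupled cells in canonical (smaller id first) order.
    """

    pre_cell: int
    post_cell: int
    kind: str  # one of CONTACT_KINDS
    category: str | None
    pre_compartment: str
    post_compartment: str
    area_um2: float
    diameter_nm: float
    depth: float
    pre_structure: int
    post_structure: int
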