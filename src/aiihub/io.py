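"""Readers and writers for the on-disk annotation tables and graph exports.

The on-disk representation is five tab-separated tables:

- ``meta.tsv``       (key, value)
- ``cells.tsv``      (cell_id, cell_class, polarity, transmitter, soma_x_nm, soma_y_nm)
- ``structures.tsv`` (structure_id, kind, parent_cell)
- ``discs.tsv``      (structure_id, z, x_nm, y_nm, radius_nm)
- ``links.tsv``      (structure_id, linked_id)

Rows are sorted by id so a write is byte-stable; links are stored once in
canonical order (smaller id first) and re-symmetrized on load.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .model import (
    AnnotationDB,
    CellRecord,
    ContactPair,
    DiscAnnotation,
    StructureRecord,
    VolumeMeta,
)

__all__ = ["LoadError", "load_db", "write_db", "export_graph"]

_TABLES = {
    "meta": ["key", "value"],
    "cells": ["cell_id", "cell_class", "polarity", "transmitter",
              "soma_x_nm", "soma_y_nm"],
    "structures": ["structure_id", "kind", "parent_cell"],
    "discs": ["structure_id", "z", "x_nm", "y_nm", "radius_nm"],
    "links": ["structure_id", "linked_id"],
}

_META_FIELDS = [f.name for f in dataclasses.fields(VolumeMeta)]


class LoadError(ValueError):
    """A table failed schema or referential-integrity checks."""


def _read_table(dirpath: Path, name: str) -> pd.DataFrame:
    path = dirpath / f"{name}.tsv"
    if not path.exists():
        raise LoadError(f"missing table {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TABLES[name] if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing column(s) {missing}")
    return df


def load_db(dirpath: str | Path) -> AnnotationDB:
    """Load an :class:`AnnotationDB` from a directory of TSV tables.

    Raises :class:`LoadError` naming the offending row on missing columns,
    duplicate ids, or dangling references.
    """
    dirpath = Path(dirpath)
    meta_df = _read_table(dirpath, "meta")
    kv = dict(zip(meta_df["key"], meta_df["value"]))
    try:
        meta = VolumeMeta(
            field_diameter_mm=float(kv["field_diameter_mm"]),
            section_thickness_nm=float(kv["section_thickness_nm"]),
            n_sections=int(float(kv["n_sections"])),
            ipl_top_z=int(float(kv["ipl_top_z"])),
            ipl_bottom_z=int(float(kv["ipl_bottom_z"])),
            pixel_size_nm=float(kv.get("pixel_size_nm", 2.18)),
        )
    except KeyError as e:  # pragma: no cover - defensive
        raise LoadError(f"meta.tsv: missing key {e}") from e

    db = AnnotationDB(meta=meta)

    cells_df = _read_table(dirpath, "cells")
    for i, row in enumerate(cells_df.itertuples(index=False)):
        cid = int(row.cell_id)
        if cid in db.cells:
            raise LoadError(f"cells.tsv row {i}: duplicate cell_id {cid}")
        db.cells[cid] = CellRecord(
            cell_id=cid,
            cell_class=row.cell_class,
            soma_x_nm=float(row.soma_x_nm),
            soma_y_nm=float(row.soma_y_nm),
        )

    struct_df = _read_table(dirpath, "structures")
    for i, row in enumerate(struct_df.itertuples(index=False)):
        sid = int(row.structure_id)
        if sid in db.structures:
            raise LoadError(
                f"structures.tsv row {i}: duplicate structure_id {sid}"
            )
        parent = int(row.parent_cell)
        if parent not in db.cells:
            raise LoadError(
                f"structures.tsv row {i}: structure {sid} references missing "
                f"cell {parent}"
            )
        db.structures[sid] = StructureRecord(
            structure_id=sid, kind=row.kind, parent_cell=parent
        )

    discs_df = _read_table(dirpath, "discs")
    for i, row in enumerate(discs_df.itertuples(index=False)):
        sid = int(row.structure_id)
        if sid not in db.structures:
            raise LoadError(
                f"discs.tsv row {i}: disc references missing structure {sid}"
            )
        db.structures[sid].discs.append(
            DiscAnnotation(
                structure_id=sid,
                z=int(row.z),
                x_nm=float(row.x_nm),
                y_nm=float(row.y_nm),
                radius_nm=float(row.radius_nm),
            )
        )

    links_df = _read_table(dirpath, "links")
    for i, row in enumerate(links_df.itertuples(index=False)):
        a, b = int(row.structure_id), int(row.linked_id)
        for sid in (a, b):
            if sid not in db.structures:
                raise LoadError(
                    f"links.tsv row {i}: link ({a}, {b}) references missing "
                    f"structure {sid}"
                )
        db.structures[a].link_ids.append(b)
        db.structures[b].link_ids.append(a)

    db.validate_refs()
    return db


def write_db(db: AnnotationDB, dirpath: str | Path) -> None:
    """Write ``db`` as the five TSV tables under ``dirpath`` (created if
    needed).  Output is deterministic: rows sorted by id, links canonical."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)

    meta_rows = [(name, getattr(db.meta, name)) for name in _META_FIELDS]
    pd.DataFrame(meta_rows, columns=["key", "value"]).to_csv(
        dirpath / "meta.tsv", sep="\t", index=False
    )

    cells = sorted(db.cells.values(), key=lambda c: c.cell_id)
    pd.DataFrame(
        [
            (c.cell_id, c.cell_class, c.polarity, c.transmitter,
             c.soma_x_nm, c.soma_y_nm)
            for c in cells
        ],
        columns=_TABLES["cells"],
    ).to_csv(dirpath / "cells.tsv", sep="\t", index=False)

    structs = sorted(db.structures.values(), key=lambda s: s.structure_id)
    pd.DataFrame(
        [(s.structure_id, s.kind, s.parent_cell) for s in structs],
        columns=_TABLES["structures"],
    ).to_csv(dirpath / "structures.tsv", sep="\t", index=False)

    disc_rows = []
    for s in structs:
        for d in sorted(s.discs, key=lambda d: (d.z, d.x_nm, d.y_nm)):
            disc_rows.append((s.structure_id, d.z, d.x_nm, d.y_nm, d.radius_nm))
    pd.DataFrame(disc_rows, columns=_TABLES["discs"]).to_csv(
        dirpath / "discs.tsv", sep="\t", index=False
    )

    link_rows = sorted(
        {
            (min(s.structure_id, lid), max(s.structure_id, lid))
            for s in structs
            for lid in s.link_ids
        }
    )
    pd.DataFrame(link_rows, columns=_TABLES["links"]).to_csv(
        dirpath / "links.tsv", sep="\t", index=False
    )


def export_graph(
    contacts: Sequence[ContactPair],
    path: str | Path,
    fmt: str = "graphml",
    cells: Iterable[CellRecord] | None = None,
) -> None:
    """Export resolved contacts as a graph file.

    ``fmt='graphml'`` writes a GraphML multigraph with one edge per contact;
    ``fmt='edgelist'`` writes a CSV edge list with the same attributes.
    """
    if fmt not in ("graphml", "edgelist"):
        raise ValueError(f"unknown export format {fmt!r}")
    rows = [
        {
            "pre_cell": c.pre_cell,
            "post_cell": c.post_cell,
            "kind": c.kind,
            "category": c.category or "",
            "area_um2": c.area_um2,
            "diameter_nm": c.diameter_nm,
            "depth": c.depth,
        }
        for c in contacts
    ]
    if fmt == "edgelist":
        pd.DataFrame(
            rows,
            columns=["pre_cell", "post_cell", "kind", "category",
                     "area_um2", "diameter_nm", "depth"],
        ).to_csv(path, index=False)
        return
    g = nx.MultiDiGraph()
    if cells is not None:
        for cell in cells:
            g.add_node(cell.cell_id, cell_class=cell.cell_class,
                       polarity=cell.polarity, transmitter=cell.transmitter)
    for r in rows:
        g.add_edge(r.pop("pre_cell"), r.pop("post_cell"), **r)
    nx.write_graphml(g, path)
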