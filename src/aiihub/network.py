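"""Partner summaries, the weighted signed multigraph, class contact
matrices, hub hop distances and category weight ratios.

Sign convention: directed synaptic edges carry the presynaptic cell's
transmitter sign (glutamate +, GABA/glycine -); gap junctions are
undirected, sign-conserving (+) edges.  Dopamine co-release (TH1) is an
edge attribute, not a sign.  Parallel edges are kept (one edge per contact)
so both counts and areas are conserved; collapsed views are derived.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .model import AnnotationDB, CellRecord, ContactPair

__all__ = [
    "PartnerSummary",
    "ClassContactMatrix",
    "aggregate_partners",
    "build_graph",
    "hop_distances",
    "class_contact_matrix",
    "weight_report",
]

_NEGATIVE = ("GABA", "glycine")


def _edge_sign(kind: str, transmitter: str) -> int:
    if kind == "gap_junction":
        return +1
    return -1 if transmitter in _NEGATIVE else +1


@dataclass
class PartnerSummary:
    focal_cell: int
    table: pd.DataFrame  # partner_cell, partner_class, kind, n_contacts,
    #                      total_area_um2, compartments

    @property
    def n_contacts(self) -> int:
        return int(self.table["n_contacts"].sum()) if len(self.table) else 0

    def total_for_kind(self, kind: str) -> int:
        t = self.table
        return int(t.loc[t["kind"] == kind, "n_contacts"].sum())


def aggregate_partners(
    contacts: list[ContactPair],
    focal: int,
    db: AnnotationDB | None = None,
) -> PartnerSummary:
    """Group a focal cell's contacts by (partner, kind) with counts, total
    areas and the focal compartments involved."""
    rows = []
    for c in contacts:
        if c.pre_cell == focal:
            partner, comp = c.post_cell, c.pre_compartment
        elif c.post_cell == focal:
            partner, comp = c.pre_cell, c.post_compartment
        else:
            continue
        rows.append({
            "partner_cell": partner,
            "partner_class": db.cell_class(partner) if db else "",
            "kind": c.kind,
            "area_um2": c.area_um2,
            "compartment": comp,
        })
    if not rows:
        return PartnerSummary(
            focal_cell=focal,
            table=pd.DataFrame(columns=[
                "partner_cell", "partner_class", "kind", "n_contacts",
                "total_area_um2", "compartments",
            ]),
        )
    df = pd.DataFrame(rows)
    grouped = (
        df.groupby(["partner_cell", "partner_class", "kind"], as_index=False)
        .agg(
            n_contacts=("area_um2", "size"),
            total_area_um2=("area_um2", "sum"),
            compartments=("compartment",
                          lambda s: ",".join(sorted(set(s)))),
        )
        .sort_values(["partner_cell", "kind"], ignore_index=True)
    )
    return PartnerSummary(focal_cell=focal, table=grouped)


def build_graph(
    contacts: list[ContactPair], cells: dict[int, CellRecord]
) -> nx.MultiDiGraph:
    """Weighted signed multigraph of all synaptic and coupling contacts.

    Gap junctions appear as a pair of reciprocal directed edges flagged
    ``undirected=True`` so the container stays a single MultiDiGraph;
    adherens and touches are excluded (non-synaptic).
    """
    g = nx.MultiDiGraph()
    involved = {c.pre_cell for c in contacts} | {c.post_cell for c in contacts}
    for cid in sorted(involved):
        cell = cells[cid]
        g.add_node(cid, cell_class=cell.cell_class, polarity=cell.polarity,
                   transmitter=cell.transmitter)
    for c in contacts:
        if c.kind in ("adherens", "touch"):
            continue
        if c.kind == "gap_junction":
            attrs = dict(kind=c.kind, sign=+1, weight=c.area_um2,
                         area_um2=c.area_um2, category=c.category or "",
                         undirected=True)
            g.add_edge(c.pre_cell, c.post_cell, **attrs)
            g.add_edge(c.post_cell, c.pre_cell, **attrs)
        else:
            transmitter = cells[c.pre_cell].transmitter
            g.add_edge(
                c.pre_cell, c.post_cell,
                kind=c.kind,
                sign=_edge_sign(c.kind, transmitter),
                weight=c.area_um2,
                area_um2=c.area_um2,
                category=c.category or "",
                modulatory="dopamine" in transmitter,
                undirected=False,
            )
    return g


def hop_distances(
    graph: nx.MultiDiGraph, source_class: str = "AII"
) -> dict:
    """Minimum hop count from any source-class node, ignoring edge
    direction (synapses and gap junctions both count as one hop).

    Returns per-node distances, a hop histogram, and the fraction of
    non-source nodes at hop <= 1.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    sources = [n for n, d in graph.nodes(data=True)
               if d.get("cell_class") == source_class]
    if not sources:
        raise ValueError(f"no node of class {source_class!r}")
    und = graph.to_undirected(as_view=True)
    dist = {n: 0 for n in sources}
    queue = deque(sources)
    while queue:
        u = queue.popleft()
        for v in und.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    hist: dict[int, int] = {}
    for n in graph.nodes:
        d = dist.get(n, -1)  # -1: unreachable
        hist[d] = hist.get(d, 0) + 1
    non_source = [n for n in graph.nodes if n not in sources]
    at_most_1 = sum(1 for n in non_source if dist.get(n, 99) <= 1)
    return {
        "distances": dist,
        "histogram": dict(sorted(hist.items())),
        "fraction_direct": at_most_1 / len(non_source) if non_source else 0.0,
        "max_hop": max((d for d in dist.values()), default=0),
    }


@dataclass
class ClassContactMatrix:
    counts: pd.DataFrame  # partner classes x contact kinds
    areas: pd.DataFrame

    @property
    def n_partner_classes(self) -> int:
        return int((self.counts.sum(axis=1) > 0).sum())

    @property
    def n_contact_kinds(self) -> int:
        """Number of (partner class, kind) combinations observed."""
        return int((self.counts > 0).sum().sum())


def class_contact_matrix(
    contacts: list[ContactPair], db: AnnotationDB, focal_class: str = "AII"
) -> ClassContactMatrix:
    """Partner-class x contact-kind table of counts and total areas for all
    contacts involving the focal class.  Marginals equal contact totals."""
    rows = []
    for c in contacts:
        pre_class = db.cell_class(c.pre_cell)
        post_class = db.cell_class(c.post_cell)
        if focal_class not in (pre_class, post_class):
            continue
        partner = post_class if pre_class == focal_class else pre_class
        if pre_class == post_class == focal_class:
            partner = focal_class
        rows.append({"partner_class": partner, "kind": c.kind,
                     "area_um2": c.area_um2})
    if not rows:
        empty = pd.DataFrame()
        return ClassContactMatrix(counts=empty, areas=empty.copy())
    df = pd.DataFrame(rows)
    counts = df.pivot_table(index="partner_class", columns="kind",
                            values="area_um2", aggfunc="size", fill_value=0)
    areas = df.pivot_table(index="partner_class", columns="kind",
                           values="area_um2", aggfunc="sum", fill_value=0.0)
    return ClassContactMatrix(counts=counts, areas=areas)


def _category_totals(contacts: list[ContactPair]) -> pd.DataFrame:
    rows = [
        {"category": c.category, "area_um2": c.area_um2}
        for c in contacts
        if c.category is not None
    ]
    if not rows:
        return pd.DataFrame(columns=["n", "total_area_um2"])
    df = pd.DataFrame(rows)
    return df.groupby("category").agg(
        n=("area_um2", "size"), total_area_um2=("area_um2", "sum")
    )


def weight_report(contacts: list[ContactPair]) -> dict:
    """Per-category totals and the headline weight ratios.

    Coupling areas are attributed per cell: a homocellular AII::AII junction
    sits on two AII membranes so its area counts twice in per-cell coupling
    weight, a heterocellular junction once.  Ratios over empty categories
    are reported as None (undefined).
    """
    totals = _category_totals(contacts)

    def area(cat: str) -> float:
        return float(totals.loc[cat, "total_area_um2"]) \
            if cat in totals.index else 0.0

    def count(cat: str) -> int:
        return int(totals.loc[cat, "n"]) if cat in totals.index else 0

    def ratio(num: float, den: float) -> float | None:
        return num / den if den > 0 else None

    homo, het = area("coupling_AII_AII"), area("coupling_AII_CBb")
    coupling_per_cell = 2.0 * homo + het
    return {
        "category_totals": totals.reset_index().to_dict(orient="records"),
        "on_ac_to_rod_ribbon_area": ratio(area("AC_input_ON"),
                                          area("rodBC_input")),
        "ac_to_off_bc_lobule_count": ratio(count("AC_input_OFF"),
                                           count("OFF_BC_input")),
        "homo_to_hetero_coupling_area": ratio(2.0 * homo, het),
        "th1_to_coupling_area": ratio(area("TH1_input"), coupling_per_cell),
    }
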