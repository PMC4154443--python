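"""Partner aggregation, the signed multigraph, hop distances and weight
ratios."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from aiihub.model import AnnotationDB, CellRecord, ContactPair, VolumeMeta
from aiihub.network import (
    aggregate_partners,
    build_graph,
    class_contact_matrix,
    hop_distances,
    weight_report,
)
from aiihub.pipeline import WORKED_COUPLING_PARTNERS, worked_partner_example


def _contact(pre, post, kind="gap_junction", category=None, area=1.0,
             depth=20.0):
    return ContactPair(pre, post, kind, category, "arboreal", "arboreal",
                       area, 200.0, depth, 0, 0)


def _cells(spec: dict[int, str]) -> dict[int, CellRecord]:
    return {cid: CellRecord(cid, cls, 0.0, 0.0) for cid, cls in spec.items()}


# ----------------------------------------------------------- aggregation

def test_worked_coupling_example_sums_to_28_sites():
    """The eight ON cone bipolar partners of the exemplar AII cell couple
    at 1+9+2+1+2+2+8+3 = 28 gap junction sites."""
    summary = worked_partner_example()
    assert summary.total_for_kind("gap_junction") == 28
    assert len(summary.table) == len(WORKED_COUPLING_PARTNERS) == 8
    counts = dict(zip(summary.table["partner_cell"],
                      summary.table["n_contacts"]))
    assert counts[4569] == 9 and counts[419] == 8 and counts[324] == 1


def test_aggregate_empty_contacts():
    s = aggregate_partners([], focal=1)
    assert s.n_contacts == 0
    assert len(s.table) == 0


def test_aggregate_matches_group_by_oracle():
    rng = np.random.default_rng(12)
    for _ in range(100):
        contacts = []
        for _ in range(rng.integers(1, 60)):
            pre, post = rng.choice(range(1, 8), 2, replace=False)
            kind = ("gap_junction", "conventional_synapse",
                    "ribbon_input")[rng.integers(3)]
            contacts.append(_contact(int(pre), int(post), kind,
                                     area=float(rng.uniform(0.01, 2))))
        focal = int(rng.integers(1, 8))
        summary = aggregate_partners(contacts, focal)
        oracle: dict[tuple, list[float]] = {}
        for c in contacts:
            if focal == c.pre_cell:
                key = (c.post_cell, c.kind)
            elif focal == c.post_cell:
                key = (c.pre_cell, c.kind)
            else:
                continue
            oracle.setdefault(key, []).append(c.area_um2)
        got = {
            (r.partner_cell, r.kind): (r.n_contacts, r.total_area_um2)
            for r in summary.table.itertuples()
        }
        assert set(got) == set(oracle)
        for key, areas in oracle.items():
            assert got[key][0] == len(areas)
            assert got[key][1] == pytest.approx(sum(areas), rel=1e-9)


# ----------------------------------------------------------------- graph

def test_single_glycinergic_synapse_is_one_negative_edge():
    cells = _cells({1: "AII", 2: "CBa1"})
    g = build_graph([_contact(1, 2, "conventional_synapse",
                              "output_BC", depth=5.0)], cells)
    assert g.number_of_edges() == 1
    (_, _, data), = g.edges(data=True)
    assert data["sign"] == -1
    assert data["undirected"] is False


def test_gap_junction_is_reciprocal_positive_edge():
    cells = _cells({1: "AII", 2: "AII"})
    g = build_graph([_contact(1, 2, "gap_junction", "coupling_AII_AII")],
                    cells)
    assert g.number_of_edges() == 2  # one undirected junction, both arcs
    assert all(d["sign"] == +1 and d["undirected"]
               for _, _, d in g.edges(data=True))


def test_glutamatergic_ribbon_is_positive_and_th1_is_modulatory():
    cells = _cells({1: "RodBC", 2: "AII", 3: "TH1"})
    g = build_graph([
        _contact(1, 2, "ribbon_input", "rodBC_input"),
        _contact(3, 2, "conventional_synapse", "TH1_input", depth=-1.0),
    ], cells)
    signs = {d["kind"]: d["sign"] for _, _, d in g.edges(data=True)}
    assert signs["ribbon_input"] == +1
    assert signs["conventional_synapse"] == +1  # glutamate+dopamine
    mods = [d["modulatory"] for _, _, d in g.edges(data=True)
            if d["kind"] == "conventional_synapse"]
    assert mods == [True]


def test_graph_weights_conserve_contact_areas(default_bundle, default_volume):
    db, _ = default_volume
    g = build_graph(default_bundle.contacts, db.cells)
    per_kind_graph: dict[str, float] = {}
    for _, _, d in g.edges(data=True):
        w = d["area_um2"] / (2.0 if d["undirected"] else 1.0)
        per_kind_graph[d["kind"]] = per_kind_graph.get(d["kind"], 0.0) + w
    per_kind_contacts: dict[str, float] = {}
    for c in default_bundle.contacts:
        if c.kind in ("adherens", "touch"):
            continue
        per_kind_contacts[c.kind] = \
            per_kind_contacts.get(c.kind, 0.0) + c.area_um2
    for kind, total in per_kind_contacts.items():
        assert per_kind_graph[kind] == pytest.approx(total, rel=1e-9)


# ------------------------------------------------------------------ hops

def test_hop_distances_star_and_chain():
    cells = _cells({1: "AII", 2: "RodBC", 3: "CBa1", 4: "gammaAC"})
    star = build_graph([
        _contact(2, 1, "ribbon_input"),
        _contact(1, 3, "conventional_synapse", depth=5.0),
        _contact(4, 1, "conventional_synapse", depth=5.0),
    ], cells)
    out = hop_distances(star, "AII")
    assert all(out["distances"][n] == 1 for n in (2, 3, 4))

    cells = _cells({1: "AII", 2: "gammaAC", 3: "CBa1"})
    chain = build_graph([
        _contact(1, 2, "conventional_synapse", depth=5.0),
        _contact(2, 3, "conventional_synapse", depth=5.0),
    ], cells)
    out = hop_distances(chain, "AII")
    assert out["distances"][3] == 2
    assert out["max_hop"] == 2


def test_hop_distances_match_bfs_oracle():
    rng = np.random.default_rng(13)
    for _ in range(50):
        n = int(rng.integers(5, 25))
        classes = {i: ("AII" if i <= 2 else "gammaAC") for i in range(1, n)}
        cells = _cells(classes)
        contacts = []
        for _ in range(rng.integers(n, 3 * n)):
            a, b = rng.choice(range(1, n), 2, replace=False)
            contacts.append(_contact(int(a), int(b), "conventional_synapse",
                                     depth=5.0))
        g = build_graph(contacts, cells)
        out = hop_distances(g, "AII")
        und = nx.Graph(g.to_undirected())
        sources = [i for i in und if classes[i] == "AII"]
        oracle = {}
        for node in und:
            best = min(
                (nx.shortest_path_length(und, s, node)
                 for s in sources if nx.has_path(und, s, node)),
                default=None,
            )
            if best is not None:
                oracle[node] = best
        assert out["distances"] == oracle


def test_every_neuron_within_two_hops_of_aii(default_bundle, default_volume):
    """Hub property of the default volume: all connected neurons sit at
    hop distance <= 2 from the AII cohort, most directly."""
    out = default_bundle.hop_report
    assert out["max_hop"] <= 2
    assert out["fraction_direct"] >= 0.5


def test_hop_distances_rejects_empty_graph():
    with pytest.raises(ValueError):
        hop_distances(nx.MultiDiGraph(), "AII")


# ---------------------------------------------------------- class matrix

def _tiny_db(spec):
    db = AnnotationDB(meta=VolumeMeta())
    for cid, cls in spec.items():
        db.add_cell(CellRecord(cid, cls, 0.0, 0.0))
    return db


def test_class_matrix_single_contact():
    db = _tiny_db({1: "AII", 2: "RodBC"})
    m = class_contact_matrix([_contact(2, 1, "ribbon_input",
                                       "rodBC_input")], db)
    assert m.counts.shape == (1, 1)
    assert m.counts.loc["RodBC", "ribbon_input"] == 1
    assert m.n_partner_classes == 1
    assert m.n_contact_kinds == 1


def test_class_matrix_marginals_match_totals(default_bundle, default_volume):
    db, _ = default_volume
    m = class_contact_matrix(default_bundle.contacts, db)
    n_aii_contacts = sum(
        1 for c in default_bundle.contacts
        if "AII" in (db.cell_class(c.pre_cell), db.cell_class(c.post_cell))
    )
    assert int(m.counts.values.sum()) == n_aii_contacts


def test_all_touch_volume_has_no_synapse_columns():
    db = _tiny_db({1: "AII", 2: "OFF-alpha-GC"})
    m = class_contact_matrix([_contact(1, 2, "touch"),
                              _contact(1, 2, "touch")], db)
    assert list(m.counts.columns) == ["touch"]


# --------------------------------------------------------------- weights

def test_weight_report_equal_areas_give_unit_ratios():
    contacts = [
        _contact(1, 2, "conventional_synapse", "AC_input_ON", area=2.0),
        _contact(3, 2, "ribbon_input", "rodBC_input", area=2.0),
        _contact(4, 2, "conventional_synapse", "AC_input_OFF", area=1.0,
                 depth=5.0),
        _contact(5, 2, "ribbon_input", "OFF_BC_input", area=1.0, depth=5.0),
    ]
    w = weight_report(contacts)
    assert w["on_ac_to_rod_ribbon_area"] == pytest.approx(1.0)
    assert w["ac_to_off_bc_lobule_count"] == pytest.approx(1.0)


def test_weight_report_undefined_ratio_is_none():
    w = weight_report([_contact(1, 2, "conventional_synapse",
                                "AC_input_ON")])
    assert w["homo_to_hetero_coupling_area"] is None


def test_weight_report_per_cell_coupling_convention():
    # one homocellular (counts twice) + one heterocellular junction
    contacts = [
        _contact(1, 2, "gap_junction", "coupling_AII_AII", area=3.0),
        _contact(1, 3, "gap_junction", "coupling_AII_CBb", area=2.0),
    ]
    w = weight_report(contacts)
    assert w["homo_to_hetero_coupling_area"] == pytest.approx(3.0)
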