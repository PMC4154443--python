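"""Disc-stack geometry: measurement conventions, contact resolution,
depth profiles, spreads and hulls."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aiihub import geometry
from aiihub.model import (
    DiscAnnotation,
    StructureRecord,
    VolumeMeta,
)

META = VolumeMeta()


def _stack(radii, kind="gap_junction", sid=1, parent=1):
    discs = [DiscAnnotation(sid, 100 + i, 0.0, 0.0, r)
             for i, r in enumerate(radii)]
    return StructureRecord(sid, kind, parent, discs)


# ---------------------------------------------------------------- feret/area

@pytest.mark.parametrize("radii, expected", [
    ([133.5], 267.0),
    ([100.0, 250.0, 180.0], 500.0),
])
def test_feret_diameter_is_max_disc_diameter(radii, expected):
    assert geometry.feret_diameter(_stack(radii)) == expected


def test_feret_rejects_cells_and_empty_stacks():
    with pytest.raises(ValueError, match="cell"):
        geometry.feret_diameter(_stack([100.0], kind="cell"))
    with pytest.raises(ValueError, match="no discs"):
        geometry.feret_diameter(StructureRecord(1, "psd", 1, []))


@pytest.mark.parametrize("radii, thickness, expected", [
    ([250.0], 80.0, 0.04),            # one disc, diameter 500 nm
    ([125.0] * 5, 80.0, 0.10),        # five discs, diameter 250 nm each
])
def test_structure_area_sums_diameter_times_thickness(radii, thickness,
                                                      expected):
    meta = VolumeMeta(section_thickness_nm=thickness)
    assert geometry.structure_area(_stack(radii), meta) == \
        pytest.approx(expected, rel=1e-12)


def test_feret_and_area_match_brute_force_oracle():
    """1000 random stacks against exhaustive-scan / exact-rational oracles."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        radii = rng.uniform(1.0, 1000.0, size=rng.integers(1, 9))
        s = _stack(list(radii))
        # brute-force max scan
        best = -1.0
        for r in radii:
            if 2 * r > best:
                best = 2 * r
        assert geometry.feret_diameter(s) == best
        # exact rational re-summation
        exact = sum(
            Fraction(2 * r) * Fraction(META.section_thickness_nm)
            for r in map(float, radii)
        ) / Fraction(10 ** 6)
        assert geometry.structure_area(s, META) == \
            pytest.approx(float(exact), rel=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    radii=st.lists(st.floats(1, 1e4, allow_nan=False), min_size=1,
                   max_size=6),
    dx=st.floats(-1e6, 1e6, allow_nan=False),
    dy=st.floats(-1e6, 1e6, allow_nan=False),
)
def test_measurements_invariant_to_translation_and_order(radii, dx, dy):
    s1 = _stack(radii)
    shifted = [DiscAnnotation(1, d.z, d.x_nm + dx, d.y_nm + dy, d.radius_nm)
               for d in reversed(s1.discs)]
    s2 = StructureRecord(1, "gap_junction", 1, shifted)
    assert geometry.feret_diameter(s1) == geometry.feret_diameter(s2)
    assert geometry.structure_area(s1, META) == \
        pytest.approx(geometry.structure_area(s2, META), rel=1e-12)


# ------------------------------------------------------- depth / compartment

def test_ipl_depth_is_linear_in_section_index():
    assert geometry.ipl_depth(META.ipl_top_z, META) == 0.0
    assert geometry.ipl_depth(META.ipl_bottom_z, META) == 25.0
    mid = (META.ipl_top_z + META.ipl_bottom_z) / 2
    assert geometry.ipl_depth(mid, META) == pytest.approx(12.5)


@pytest.mark.parametrize("depth, comp", [
    (-2.0, "neck"), (0.0, "lobule"), (5.0, "lobule"), (9.99, "lobule"),
    (10.0, "waist"), (14.9, "waist"), (15.0, "arboreal"), (20.0, "arboreal"),
])
def test_compartment_boundaries(depth, comp):
    assert geometry.assign_compartment(depth) == comp


# ----------------------------------------------------------------- contacts

def test_resolve_rod_ribbon_contact(tiny):
    tiny.cell(1, "RodBC")
    tiny.cell(2, "AII")
    z = tiny.depth_z(20.0)
    pre = tiny.structure("ribbon_presyn", 1, [(z, 0.0, 0.0, 125.0)])
    tiny.structure("psd", 2, [(z, 0.0, 0.0, 125.0)], links=[pre])
    (c,) = geometry.resolve_contacts(tiny.db)
    assert c.kind == "ribbon_input"
    assert c.category == "rodBC_input"
    assert c.post_compartment == "arboreal"
    assert c.depth == pytest.approx(20.0, abs=0.05)


def test_resolve_heterocellular_coupling(tiny):
    """A gap junction between an AII cell and an ON cone bipolar cell is a
    heterocellular coupling contact (e.g. pairing 476 with CBb5-6i 419)."""
    tiny.cell(476, "AII")
    tiny.cell(419, "CBb5-6i")
    z = tiny.depth_z(18.0)
    a = tiny.structure("gap_junction", 476, [(z, 0.0, 0.0, 120.0)])
    tiny.structure("gap_junction", 419, [(z, 0.0, 0.0, 120.0)], links=[a])
    (c,) = geometry.resolve_contacts(tiny.db)
    assert c.category == "coupling_AII_CBb"
    assert {c.pre_cell, c.post_cell} == {476, 419}


def test_malformed_link_raises(tiny):
    tiny.cell(1, "RodBC")
    tiny.cell(2, "RodBC")
    a = tiny.structure("ribbon_presyn", 1, [(100, 0.0, 0.0, 100.0)])
    tiny.structure("ribbon_presyn", 2, [(100, 0.0, 0.0, 100.0)], links=[a])
    with pytest.raises(geometry.MalformedLinkError):
        geometry.resolve_contacts(tiny.db)


def test_resolved_contacts_match_planted_ledger(default_volume):
    """The resolved ContactPair multiset equals the generator's ledger:
    same counts per (cells, kind), identical diameters and areas."""
    db, ledger = default_volume
    contacts = geometry.resolve_contacts(db)
    assert len(contacts) == len(ledger.contacts)

    got = sorted(
        (min(c.pre_cell, c.post_cell), max(c.pre_cell, c.post_cell),
         c.kind, round(c.diameter_nm, 6))
        for c in contacts
    )
    want = sorted(
        (min(r.pre_cell, r.post_cell), max(r.pre_cell, r.post_cell),
         r.kind, round(r.diameter_nm, 6))
        for r in ledger.contacts.itertuples()
    )
    assert got == want

    total_got = sum(c.area_um2 for c in contacts)
    assert total_got == pytest.approx(ledger.contacts["area_um2"].sum(),
                                      rel=1e-9)


# ------------------------------------------------------------ depth profiles

def test_depth_profile_trivials(default_bundle):
    from aiihub.model import ContactPair

    empty = geometry.depth_profile([], "TH1_input")
    assert empty.total_area == 0.0

    c = ContactPair(1, 2, "ribbon_input", "rodBC_input", "arboreal",
                    "arboreal", 3.5, 250.0, 7.3, 0, 0)
    prof = geometry.depth_profile([c], "rodBC_input")
    lo = prof.bin_edges[:-1]
    idx = np.nonzero(prof.area_per_bin)[0]
    assert len(idx) == 1
    assert lo[idx[0]] == 7.0
    assert prof.area_per_bin[idx[0]] == 3.5

    with pytest.raises(ValueError, match="category"):
        geometry.depth_profile([], "nonsense")


def test_depth_profile_conserves_area_per_category(default_bundle):
    for cat, prof in default_bundle.depth_profiles.items():
        direct = sum(c.area_um2 for c in default_bundle.contacts
                     if c.category == cat)
        assert prof.total_area == pytest.approx(direct, rel=1e-9)


def test_outputs_and_coupling_are_segregated(default_bundle):
    """Output contacts stratify in the OFF sublamina, coupling in the ON
    sublamina; their occupied depth bins never overlap."""
    out_bins: set[int] = set()
    for cat in ("output_BC", "output_AC", "output_GC"):
        out_bins |= default_bundle.depth_profiles[cat].occupied_bins()
    coupling_bins: set[int] = set()
    for cat in ("coupling_AII_AII", "coupling_AII_CBb"):
        coupling_bins |= default_bundle.depth_profiles[cat].occupied_bins()
    assert out_bins and coupling_bins
    assert not (out_bins & coupling_bins)
    assert max(out_bins) < geometry.OFF_ON_BOUNDARY
    assert min(coupling_bins) >= geometry.OFF_ON_BOUNDARY


# ------------------------------------------------------------ spreads/hulls

def test_lateral_spread_single_cell(tiny):
    tiny.cell(1, "AII")
    z = tiny.depth_z(20.0)
    tiny.structure("cell", 1, [(z, 0.0, 0.0, 500.0),
                               (z, 10_000.0, 0.0, 500.0)])
    out = geometry.lateral_spread(tiny.db, [1], "arboreal")
    assert out["mean_um"] == pytest.approx(10.0)
    assert out["sd_um"] == 0.0
    assert out["single_cell"] is True


def test_lateral_spread_identical_cells_have_zero_sd(tiny):
    z = tiny.depth_z(20.0)
    for cid in (1, 2, 3):
        tiny.cell(cid, "AII")
        tiny.structure("cell", cid, [(z, 0.0, 0.0, 500.0),
                                     (z, 7_000.0, 7_000.0, 500.0)])
    out = geometry.lateral_spread(tiny.db, [1, 2, 3], "arboreal")
    assert out["sd_um"] == 0.0
    assert out["n"] == 3


def test_lateral_spread_matches_pairwise_oracle(tiny):
    rng = np.random.default_rng(3)
    z = tiny.depth_z(20.0)
    cells = []
    for cid in range(1, 6):
        tiny.cell(cid, "AII")
        pts = rng.uniform(0, 50_000, size=(8, 2))
        tiny.structure("cell", cid,
                       [(z, x, y, 500.0) for x, y in pts])
        cells.append(pts)
    out = geometry.lateral_spread(tiny.db, list(range(1, 6)), "arboreal")
    extents = []
    for pts in cells:
        best = 0.0
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                best = max(best, math.dist(pts[i], pts[j]))
        extents.append(best * 1e-3)
    assert out["mean_um"] == pytest.approx(np.mean(extents), rel=1e-9)
    assert out["sd_um"] == pytest.approx(np.std(extents, ddof=1), rel=1e-9)


def _gift_wrap_area(pts: np.ndarray) -> float:
    """Independent convex-hull oracle (gift wrapping + shoelace)."""
    pts = [tuple(p) for p in pts]
    start = min(pts)
    hull = [start]
    current = start
    while True:
        candidate = pts[0] if pts[0] != current else pts[1]
        for p in pts:
            if p == current:
                continue
            cross = ((candidate[0] - current[0]) * (p[1] - current[1])
                     - (candidate[1] - current[1]) * (p[0] - current[0]))
            if cross < 0 or (cross == 0 and
                             math.dist(current, p) >
                             math.dist(current, candidate)):
                candidate = p
        current = candidate
        if current == start:
            break
        hull.append(current)
    area = 0.0
    for i in range(len(hull)):
        x1, y1 = hull[i]
        x2, y2 = hull[(i + 1) % len(hull)]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


def test_convex_hull_known_shapes(tiny):
    tiny.cell(1, "AII")
    z = tiny.depth_z(20.0)
    square = [(z, 0.0, 0.0, 500.0), (z, 1000.0, 0.0, 500.0),
              (z, 1000.0, 1000.0, 500.0), (z, 0.0, 1000.0, 500.0)]
    tiny.structure("cell", 1, square)
    _, area = geometry.convex_hull_field(tiny.db, 1, "arboreal")
    assert area == pytest.approx(1.0)

    tiny.cell(2, "AII")
    tri = [(z, 0.0, 0.0, 500.0), (z, 4000.0, 0.0, 500.0),
           (z, 0.0, 3000.0, 500.0)]
    tiny.structure("cell", 2, tri)
    _, area = geometry.convex_hull_field(tiny.db, 2, "arboreal")
    assert area == pytest.approx(6.0)


def test_convex_hull_degenerate_inputs(tiny):
    tiny.cell(1, "AII")
    z = tiny.depth_z(20.0)
    tiny.structure("cell", 1, [(z, 0.0, 0.0, 500.0), (z, 1.0, 1.0, 500.0)])
    with pytest.raises(ValueError, match=">=3"):
        geometry.convex_hull_field(tiny.db, 1, "arboreal")
    tiny.cell(2, "AII")
    tiny.structure("cell", 2, [(z, 0.0, 0.0, 500.0),
                               (z, 1000.0, 1000.0, 500.0),
                               (z, 2000.0, 2000.0, 500.0)])
    with pytest.raises(ValueError, match="collinear"):
        geometry.convex_hull_field(tiny.db, 2, "arboreal")


def test_convex_hull_matches_gift_wrap_oracle(tiny):
    rng = np.random.default_rng(9)
    z = tiny.depth_z(20.0)
    for cid in range(1, 201):
        tiny.cell(cid, "AII")
        pts = rng.uniform(0, 60_000, size=(rng.integers(4, 12), 2))
        tiny.structure("cell", cid, [(z, x, y, 500.0) for x, y in pts])
        _, area = geometry.convex_hull_field(tiny.db, cid, "arboreal")
        oracle = _gift_wrap_area(pts * 1e-3)
        assert area == pytest.approx(oracle, rel=1e-9)
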