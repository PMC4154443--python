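"""Rule-compliant synthetic connectome generator with a planted-truth ledger.

Emulates the annotation export of a retinal connectome volume: a jittered
square-lattice AII mosaic in a circular field, the companion bipolar /
amacrine / ganglion cell census, per-slice disc annotations for every cell
and child structure, and contact populations drawn from configured
distributions (rod ribbon intake, gap-junction diameters, category area
ratios).  Every generated contact respects the default contact-rule table
by construction, and the ledger records the planted truth the analysis
pipeline must recover.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    AnnotationDB,
    CellRecord,
    DiscAnnotation,
    StructureRecord,
    VolumeMeta,
)

__all__ = [
    "GeneratorConfig",
    "PlantedLedger",
    "generate_mosaic",
    "generate_db",
    "inject_violations",
]

_UM = 1000.0  # nm per um


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic volume.

    Distances in um unless suffixed; diameters in nm.  The configuration
    plus the seed fully determine the output.
    """

    seed: int = 1
    field_diameter_mm: float = 0.243
    section_thickness_nm: float = 80.0
    n_sections: int = 401
    ipl_top_z: int = 80
    ipl_bottom_z: int = 392

    # mosaic
    aii_density_per_mm2: float = 841.0
    mosaic_jitter_frac: float = 0.10

    # class census (AII count is emergent from the mosaic)
    n_rodbc: int = 104
    n_cba: int = 180
    n_cbb: int = 200  # includes CBb7
    n_cbb7: int = 7
    n_th1: int = 4
    n_ai: int = 20
    n_gac: int = 20
    n_gamma_ac: int = 30
    n_off_alpha_gc: int = 1
    n_off_delta_gc: int = 1

    # morphology (um)
    soma_diameter: float = 9.0
    neck_diameter: float = 6.0
    lobule_reach: tuple[float, float] = (10.0, 17.0)
    arboreal_span: float = 70.0
    rod_input_field: float = 60.0
    rodbc_terminal_span: tuple[float, float] = (20.0, 30.0)

    # contact counts
    ribbons_per_rodbc: tuple[float, float] = (31.0, 3.9)  # truncated >= 1
    aii_ribbon_intake: tuple[float, float] = (75.6, 3.0)
    cbb7_ribbons: tuple[int, int] = (1, 3)
    cbb7_gap_junctions: tuple[int, int] = (2, 7)
    offbc_ribbons_per_aii: tuple[int, int] = (2, 5)
    n_homocellular_gj: int = 525
    n_heterocellular_gj: int = 172  # includes CBb7 junctions
    off_ac_per_aii: tuple[int, int] = (15, 25)
    on_ac_per_aii: tuple[int, int] = (25, 35)
    th1_syn_per_aii: tuple[int, int] = (4, 6)
    outputs_to_cba_per_aii: tuple[int, int] = (8, 16)
    outputs_to_ac_per_aii: tuple[int, int] = (6, 12)
    n_gc_coupled_aii: int = 12
    gc_lobules_per_aii: tuple[int, int] = (1, 3)

    # touches / adherens
    n_arboreal_gc_touches: int = 11
    n_rodbc_lobule_touches: int = 6
    n_lobule_lobule_touches: int = 6
    n_ai_lobule_touches: int = 12
    ai_adherens_per_aii: tuple[int, int] = (1, 3)

    # size distributions (mean, sd) nm, truncated to bounds
    gj_diam_homo: tuple[float, float] = (267.0, 95.0)
    gj_diam_het: tuple[float, float] = (238.0, 95.0)
    gj_diam_bounds: tuple[float, float] = (50.0, 800.0)
    ribbon_diam: tuple[float, float] = (250.0, 50.0)
    ribbon_diam_bounds: tuple[float, float] = (100.0, 600.0)
    conv_diam: tuple[float, float] = (300.0, 60.0)
    conv_diam_bounds: tuple[float, float] = (100.0, 800.0)

    # category weight targets
    on_ac_to_rod_area_ratio: float = 8.0
    th1_to_coupling_area_frac: float = 1.0 / 3.0

    def meta(self) -> VolumeMeta:
        return VolumeMeta(
            field_diameter_mm=self.field_diameter_mm,
            section_thickness_nm=self.section_thickness_nm,
            n_sections=self.n_sections,
            ipl_top_z=self.ipl_top_z,
            ipl_bottom_z=self.ipl_bottom_z,
        )

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        data = json.loads(Path(path).read_text())
        for f_ in ("lobule_reach", "rodbc_terminal_span", "ribbons_per_rodbc",
                   "aii_ribbon_intake", "cbb7_ribbons", "cbb7_gap_junctions",
                   "offbc_ribbons_per_aii", "off_ac_per_aii", "on_ac_per_aii",
                   "th1_syn_per_aii", "outputs_to_cba_per_aii",
                   "outputs_to_ac_per_aii", "gc_lobules_per_aii",
                   "ai_adherens_per_aii", "gj_diam_homo", "gj_diam_het",
                   "gj_diam_bounds", "ribbon_diam", "ribbon_diam_bounds",
                   "conv_diam", "conv_diam_bounds"):
            if f_ in data:
                data[f_] = tuple(data[f_])
        return cls(**data)


@dataclass
class PlantedLedger:
    """Ground truth of one generated volume."""

    census: dict[str, int]
    mosaic_points_um: np.ndarray  # AII soma XY relative to field center
    contacts: pd.DataFrame  # one row per planted contact
    aii_ribbon_intake: dict[int, int]  # realized rod-ribbon totals per AII
    rodbc_ribbon_counts: dict[int, int]  # realized ribbons per rod BC

    def category_counts(self) -> pd.Series:
        return self.contacts["category"].value_counts()

    def category_areas(self) -> pd.Series:
        return self.contacts.groupby("category")["area_um2"].sum()


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float, size: int) -> np.ndarray:
    """Truncated normal by resampling (simple and exact in distribution)."""
    out = np.empty(size)
    need = np.arange(size)
    while len(need):
        draw = rng.normal(mean, sd, size=len(need))
        ok = (draw >= lo) & (draw <= hi)
        out[need[ok]] = draw[ok]
        need = need[~ok]
    return out


def _planned_slices(diameter_nm: float, thickness_nm: float
                    ) -> tuple[int, np.ndarray]:
    """Odd slice count and per-slice chord diameters for a circular junction
    profile; the central slice carries the full Feret diameter exactly."""
    m = int(round(diameter_nm / thickness_nm))
    if m < 1:
        m = 1
    if m % 2 == 0:
        m -= 1 if m > 1 else 0
        m = max(m, 1)
    k = np.arange(m)
    x = (2 * k - m + 1) / (m + 1)
    chords = diameter_nm * np.sqrt(1.0 - x * x)
    return m, chords


def _planned_area_um2(diameter_nm: float, thickness_nm: float) -> float:
    _, chords = _planned_slices(diameter_nm, thickness_nm)
    return float(chords.sum() * thickness_nm * 1e-6)


def generate_mosaic(config: GeneratorConfig,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Jittered square-lattice soma positions (um, field center at origin)
    clipped to the circular field.  Expected count = density x field area."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    spacing = 1000.0 / math.sqrt(config.aii_density_per_mm2)  # um
    radius = config.field_diameter_mm * 500.0  # um
    n_half = int(math.ceil((radius + spacing) / spacing))
    coords = np.arange(-n_half, n_half + 1) * spacing
    gx, gy = np.meshgrid(coords, coords)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    # random phase so the lattice is not registered to the field center
    pts = pts + rng.uniform(0, spacing, size=2)
    pts = pts + rng.normal(0.0, config.mosaic_jitter_frac * spacing,
                           size=pts.shape)
    keep = np.hypot(pts[:, 0], pts[:, 1]) <= radius
    return pts[keep]


def _exact_count_points(rng: np.random.Generator, n: int, radius_um: float,
                        density_like_spacing: float | None = None
                        ) -> np.ndarray:
    """Exactly n points in a circle: jittered lattice trimmed or padded."""
    if n == 0:
        return np.empty((0, 2))
    spacing = (density_like_spacing
               if density_like_spacing is not None
               else math.sqrt(math.pi * radius_um ** 2 / n))
    n_half = int(math.ceil((radius_um + spacing) / spacing))
    coords = np.arange(-n_half, n_half + 1) * spacing
    gx, gy = np.meshgrid(coords, coords)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pts = pts + rng.uniform(0, spacing, size=2)
    pts = pts + rng.normal(0.0, 0.15 * spacing, size=pts.shape)
    pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= radius_um]
    while len(pts) < n:
        extra = rng.uniform(-radius_um, radius_um, size=(n, 2))
        extra = extra[np.hypot(extra[:, 0], extra[:, 1]) <= radius_um]
        pts = np.vstack([pts, extra])
    if len(pts) > n:
        idx = rng.choice(len(pts), size=n, replace=False)
        pts = pts[np.sort(idx)]
    return pts


class _Builder:
    """Accumulates cells, structures and the contact ledger."""

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        self.meta = config.meta()
        self.db = AnnotationDB(meta=self.meta)
        self.next_cell_id = 1
        self.next_structure_id = 100_000
        self.ledger_rows: list[dict] = []
        self.positions: dict[str, np.ndarray] = {}  # class -> (n, 2) um
        self.ids: dict[str, list[int]] = {}  # class -> cell ids
        self.aii_lobules: dict[int, list[tuple[float, float, float]]] = {}
        self.rodbc_radius: dict[int, float] = {}

    # -- coordinate helpers -------------------------------------------------
    @property
    def field_radius_um(self) -> float:
        return self.cfg.field_diameter_mm * 500.0

    def to_nm(self, x_um: float, y_um: float) -> tuple[float, float]:
        # origin at field top-left corner
        r = self.field_radius_um * _UM
        return x_um * _UM + r, y_um * _UM + r

    def depth_to_z(self, depth: float) -> int:
        m = self.meta
        z = m.ipl_top_z + depth / 25.0 * (m.ipl_bottom_z - m.ipl_top_z)
        return int(np.clip(round(z), 0, m.n_sections - 1))

    # -- structure creation -------------------------------------------------
    def new_cell(self, cell_class: str, x_um: float, y_um: float) -> int:
        cid = self.next_cell_id
        self.next_cell_id += 1
        x_nm, y_nm = self.to_nm(x_um, y_um)
        self.db.add_cell(CellRecord(cid, cell_class, x_nm, y_nm))
        self.ids.setdefault(cell_class, []).append(cid)
        return cid

    def new_structure(self, kind: str, parent: int,
                      discs: list[DiscAnnotation]) -> int:
        sid = self.next_structure_id
        self.next_structure_id += 1
        discs = [replace(d, structure_id=sid) for d in discs]
        self.db.add_structure(
            StructureRecord(structure_id=sid, kind=kind, parent_cell=parent,
                            discs=discs)
        )
        return sid

    def disc(self, x_um: float, y_um: float, depth: float,
             radius_nm: float, dz: int = 0) -> DiscAnnotation:
        x_nm, y_nm = self.to_nm(x_um, y_um)
        z = int(np.clip(self.depth_to_z(depth) + dz, 0,
                        self.meta.n_sections - 1))
        return DiscAnnotation(structure_id=0, z=z, x_nm=x_nm, y_nm=y_nm,
                              radius_nm=radius_nm)

    def child_discs(self, x_um: float, y_um: float, depth: float,
                    diameter_nm: float) -> list[DiscAnnotation]:
        m, chords = _planned_slices(diameter_nm,
                                    self.cfg.section_thickness_nm)
        return [
            self.disc(x_um, y_um, depth, c / 2.0, dz=k - (m - 1) // 2)
            for k, c in enumerate(chords)
        ]

    def link(self, a: int, b: int) -> None:
        self.db.structures[a].link_ids.append(b)
        self.db.structures[b].link_ids.append(a)

    def add_contact(self, pre_cell: int, post_cell: int, pre_kind: str,
                    post_kind: str, x_um: float, y_um: float, depth: float,
                    diameter_nm: float, kind: str, category: str | None
                    ) -> tuple[int, int]:
        """Two mirrored child structures (one per cell) plus their link."""
        discs = self.child_discs(x_um, y_um, depth, diameter_nm)
        pre_sid = self.new_structure(pre_kind, pre_cell, discs)
        post_sid = self.new_structure(post_kind, post_cell, discs)
        self.link(pre_sid, post_sid)
        area = _planned_area_um2(diameter_nm, self.cfg.section_thickness_nm)
        self.ledger_rows.append({
            "pre_cell": pre_cell, "post_cell": post_cell, "kind": kind,
            "category": category, "diameter_nm": diameter_nm,
            "area_um2": area, "depth": depth,
            "pre_structure": pre_sid, "post_structure": post_sid,
        })
        return pre_sid, post_sid

    def add_touch(self, cell_a: int, cell_b: int, x_um: float, y_um: float,
                  depth: float) -> None:
        self.add_contact(min(cell_a, cell_b), max(cell_a, cell_b),
                         "touch", "touch", x_um, y_um, depth,
                         150.0, "touch", None)

    # -- placement helpers --------------------------------------------------
    def nearest(self, cls: str, x_um: float, y_um: float,
                max_dist_um: float | None = None,
                exclude: int | None = None) -> list[int]:
        """Cell ids of class ``cls`` ordered by distance from (x, y),
        optionally restricted to ``max_dist_um``; falls back to the single
        nearest cell if none is in range."""
        pos = self.positions[cls]
        ids = self.ids[cls]
        d = np.hypot(pos[:, 0] - x_um, pos[:, 1] - y_um)
        order = np.argsort(d, kind="stable")
        out = [ids[i] for i in order
               if ids[i] != exclude
               and (max_dist_um is None or d[i] <= max_dist_um)]
        if not out:
            out = [ids[i] for i in order if ids[i] != exclude][:1]
        return out


# ---------------------------------------------------------------------------


def _place_cells(b: _Builder) -> None:
    cfg, rng = b.cfg, b.rng
    R = b.field_radius_um

    aii_pts = generate_mosaic(cfg, rng)
    b.positions["AII"] = aii_pts
    for x, y in aii_pts:
        cid = b.new_cell("AII", x, y)
        _aii_scaffold(b, cid, x, y)

    rod_pts = _exact_count_points(rng, cfg.n_rodbc, R)
    b.positions["RodBC"] = rod_pts
    for x, y in rod_pts:
        cid = b.new_cell("RodBC", x, y)
        r_term = rng.uniform(*cfg.rodbc_terminal_span) / 2.0
        b.rodbc_radius[cid] = r_term
        _rodbc_scaffold(b, cid, x, y, r_term)

    def plain(cls: str, n: int) -> None:
        pts = _exact_count_points(rng, n, R)
        b.positions[cls] = pts
        for x, y in pts:
            cid = b.new_cell(cls, x, y)
            b.new_structure("cell", cid, [b.disc(x, y, -4.0, 2500.0)])

    n_cba_sub = cfg.n_cba // 6
    cba_all = []
    for i in range(1, 7):
        n_sub = n_cba_sub + (1 if i <= cfg.n_cba - 6 * n_cba_sub else 0)
        plain(f"CBa{i}", n_sub)
        cba_all.extend(b.ids[f"CBa{i}"])
    b.ids["CBa*"] = cba_all
    b.positions["CBa*"] = np.vstack(
        [b.positions[f"CBa{i}"] for i in range(1, 7)
         if len(b.positions[f"CBa{i}"])]
    )

    cbb_classes = ("CBb3", "CBb4w", "CBb5w", "CBb4-5i", "CBb5-6i", "CBb6")
    n_rest = cfg.n_cbb - cfg.n_cbb7
    n_each = n_rest // len(cbb_classes)
    cbb_all = []
    for i, cls in enumerate(cbb_classes):
        n_sub = n_each + (1 if i < n_rest - len(cbb_classes) * n_each else 0)
        plain(cls, n_sub)
        cbb_all.extend(b.ids[cls])
    b.ids["CBb*"] = cbb_all
    b.positions["CBb*"] = np.vstack(
        [b.positions[c] for c in cbb_classes if len(b.positions[c])]
    )
    plain("CBb7", cfg.n_cbb7)
    plain("TH1", cfg.n_th1)
    plain("AI", cfg.n_ai)
    plain("GAC", cfg.n_gac)
    plain("gammaAC", cfg.n_gamma_ac)
    plain("OFF-alpha-GC", cfg.n_off_alpha_gc)
    plain("OFF-delta-GC", cfg.n_off_delta_gc)
    b.ids["GC*"] = b.ids["OFF-alpha-GC"] + b.ids["OFF-delta-GC"]


def _aii_scaffold(b: _Builder, cid: int, x: float, y: float) -> None:
    """Cell-kind disc stack for one AII: soma/neck column, lobule stalks,
    waist cone and arboreal field."""
    cfg, rng = b.cfg, b.rng
    discs = []
    # soma + neck column (above the IPL)
    for depth, r_um in ((-4.0, cfg.soma_diameter / 2),
                        (-2.5, cfg.neck_diameter / 2),
                        (-1.0, cfg.neck_diameter / 2)):
        discs.append(b.disc(x, y, depth, r_um * _UM))
    # lobules: 5-6 stalks reaching into the OFF sublamina
    lobules = []
    n_lob = int(rng.integers(5, 7))
    for i in range(n_lob):
        ang = 2 * math.pi * (i + rng.uniform(-0.2, 0.2)) / n_lob
        reach = rng.uniform(*cfg.lobule_reach)
        lx, ly = x + reach * math.cos(ang), y + reach * math.sin(ang)
        depth = rng.uniform(2.0, 8.0)
        lobules.append((lx, ly, depth))
        discs.append(b.disc(lx, ly, depth, 1250.0))
    b.aii_lobules[cid] = lobules
    # waist cone
    for _ in range(5):
        ang = rng.uniform(0, 2 * math.pi)
        r = rng.uniform(0, 15.0)
        discs.append(b.disc(x + r * math.cos(ang), y + r * math.sin(ang),
                            rng.uniform(10.0, 15.0), 1000.0))
    # arboreal field spanning the configured diameter
    half = cfg.arboreal_span / 2.0
    for i in range(8):
        ang = 2 * math.pi * (i + rng.uniform(-0.3, 0.3)) / 8
        r = rng.uniform(0.9, 1.0) * half
        discs.append(b.disc(x + r * math.cos(ang), y + r * math.sin(ang),
                            rng.uniform(15.5, 24.5), 600.0))
    for _ in range(4):
        ang = rng.uniform(0, 2 * math.pi)
        r = rng.uniform(0.1, 0.8) * half
        discs.append(b.disc(x + r * math.cos(ang), y + r * math.sin(ang),
                            rng.uniform(15.5, 24.5), 600.0))
    b.new_structure("cell", cid, discs)


def _rodbc_scaffold(b: _Builder, cid: int, x: float, y: float,
                    r_term: float) -> None:
    rng = b.rng
    discs = [b.disc(x, y, -4.0, 3000.0)]
    for i in range(6):
        ang = 2 * math.pi * i / 6 + rng.uniform(-0.3, 0.3)
        r = rng.uniform(0.7, 1.0) * r_term
        discs.append(b.disc(x + r * math.cos(ang), y + r * math.sin(ang),
                            rng.uniform(18.0, 24.0), 800.0))
    b.new_structure("cell", cid, discs)


def _rod_ribbons(b: _Builder) -> tuple[dict[int, int], dict[int, int]]:
    """Rod bipolar ribbon synapses onto AII arboreal dendrites.

    Each AII draws a regulated ribbon intake target; ribbons are allocated
    to the rod bipolar cells whose terminal fields overlap the AII's rod
    input field, weighted by proximity (cell-count variance is geometric,
    ribbon totals are regulated).  Rod BCs short of their own ribbon budget
    direct the remainder onto AI amacrine cells.
    """
    cfg, rng = b.cfg, b.rng
    rod_ids = b.ids["RodBC"]
    rod_pos = b.positions["RodBC"]
    aii_ids = b.ids["AII"]
    aii_pos = b.positions["AII"]
    mean_t, sd_t = cfg.aii_ribbon_intake
    intake: dict[int, int] = {}
    alloc: dict[int, int] = {rid: 0 for rid in rod_ids}

    rib_mean, rib_sd = cfg.ribbon_diam
    rib_lo, rib_hi = cfg.ribbon_diam_bounds

    for idx, aid in enumerate(aii_ids):
        ax, ay = aii_pos[idx]
        target = max(1, int(round(rng.normal(mean_t, sd_t))))
        intake[aid] = target
        cover_r = cfg.rod_input_field / 2.0
        d = np.hypot(rod_pos[:, 0] - ax, rod_pos[:, 1] - ay)
        radii = np.array([b.rodbc_radius[r] for r in rod_ids])
        in_range = np.nonzero(d <= cover_r + radii)[0]
        if len(in_range) == 0:
            in_range = np.array([int(np.argmin(d))])
        w = np.maximum(0.05, 1.0 - d[in_range] / (cover_r + radii[in_range]))
        counts = rng.multinomial(target, w / w.sum())
        diams = _trunc_normal(rng, rib_mean, rib_sd, rib_lo, rib_hi, target)
        di = 0
        for j, cnt in zip(in_range, counts):
            rid = rod_ids[j]
            alloc[rid] += int(cnt)
            rx, ry = rod_pos[j]
            # contact sites scatter inside the terminal-arbor overlap
            mx, my = (ax + rx) / 2.0, (ay + ry) / 2.0
            for _ in range(int(cnt)):
                sx = mx + rng.normal(0, 3.0)
                sy = my + rng.normal(0, 3.0)
                b.add_contact(rid, aid, "ribbon_presyn", "psd", sx, sy,
                              rng.uniform(18.0, 24.0), diams[di],
                              "ribbon_input", "rodBC_input")
                di += 1

    # top up rod BCs to their own ribbon budget with AI-cell dyad partners
    rod_counts: dict[int, int] = {}
    for j, rid in enumerate(rod_ids):
        budget = max(1, int(round(rng.normal(*cfg.ribbons_per_rodbc))))
        extra = budget - alloc[rid]
        rx, ry = rod_pos[j]
        for _ in range(max(0, extra)):
            ai = b.nearest("AI", rx, ry)[0]
            diam = _trunc_normal(rng, rib_mean, rib_sd, rib_lo, rib_hi, 1)[0]
            b.add_contact(rid, ai, "ribbon_presyn", "psd",
                          rx + rng.normal(0, 3.0), ry + rng.normal(0, 3.0),
                          rng.uniform(18.0, 24.0), diam,
                          "ribbon_input", None)
        rod_counts[rid] = max(alloc[rid], budget)
    return intake, rod_counts


def _gap_junctions(b: _Builder) -> None:
    """Homocellular AII::AII and heterocellular AII::CBb coupling.

    Exactly ``n_homocellular_gj`` junctions are spread over adjacent AII
    pairs (every arboreal-overlap pair couples); the heterocellular budget
    covers the CBb7 junctions first, with the remainder over nearby non-CBb7
    ON cone bipolar cells.  CBb7 ribbon partners are a subset of their
    coupling partners so every arboreal encounter is coupled.
    """
    cfg, rng = b.cfg, b.rng
    aii_ids = b.ids["AII"]
    pos = b.positions["AII"]
    lo, hi = cfg.gj_diam_bounds

    pairs = []
    for i in range(len(aii_ids)):
        for j in range(i + 1, len(aii_ids)):
            if np.hypot(*(pos[i] - pos[j])) < cfg.arboreal_span:
                pairs.append((i, j))
    if not pairs:
        pairs = [(0, 1)] if len(aii_ids) > 1 else []

    n_homo = cfg.n_homocellular_gj
    counts = np.zeros(len(pairs), dtype=int)
    if pairs:
        base = min(1, n_homo // len(pairs))
        counts += base
        rest = n_homo - counts.sum()
        if rest > 0:
            counts += rng.multinomial(rest, np.full(len(pairs),
                                                    1.0 / len(pairs)))
        elif rest < 0:
            drop = rng.choice(len(pairs), size=-rest, replace=False)
            counts[drop] -= 1
    diams = _trunc_normal(rng, *cfg.gj_diam_homo, lo, hi, int(counts.sum()))
    di = 0
    for (i, j), cnt in zip(pairs, counts):
        a, bb = aii_ids[i], aii_ids[j]
        mx, my = (pos[i] + pos[j]) / 2.0
        for _ in range(cnt):
            b.add_contact(min(a, bb), max(a, bb), "gap_junction",
                          "gap_junction",
                          mx + rng.normal(0, 5.0), my + rng.normal(0, 5.0),
                          rng.uniform(15.5, 24.5), diams[di],
                          "gap_junction", "coupling_AII_AII")
            di += 1

    # CBb7: 1-3 ribbons and 2-7 gap junctions with neighboring AII cells
    n_het_used = 0
    for k, cid in enumerate(b.ids["CBb7"]):
        cx, cy = b.positions["CBb7"][k]
        partners = b.nearest("AII", cx, cy, max_dist_um=70.0)[:3]
        n_gj = int(rng.integers(cfg.cbb7_gap_junctions[0],
                                cfg.cbb7_gap_junctions[1] + 1))
        n_rib = int(rng.integers(cfg.cbb7_ribbons[0],
                                 cfg.cbb7_ribbons[1] + 1))
        gj_partners = [partners[i % len(partners)] for i in range(n_gj)]
        diams = _trunc_normal(rng, *cfg.gj_diam_het, lo, hi, n_gj)
        for aid, diam in zip(gj_partners, diams):
            ax, ay = pos[aii_ids.index(aid)]
            b.add_contact(min(cid, aid), max(cid, aid), "gap_junction",
                          "gap_junction",
                          (cx + ax) / 2 + rng.normal(0, 4.0),
                          (cy + ay) / 2 + rng.normal(0, 4.0),
                          rng.uniform(15.5, 24.5), diam,
                          "gap_junction", "coupling_AII_CBb")
            n_het_used += 1
        rib_d = _trunc_normal(rng, *cfg.ribbon_diam, *cfg.ribbon_diam_bounds,
                              size=n_rib)
        for i in range(n_rib):
            aid = gj_partners[i % len(gj_partners)]
            ax, ay = pos[aii_ids.index(aid)]
            b.add_contact(cid, aid, "ribbon_presyn", "psd",
                          (cx + ax) / 2 + rng.normal(0, 4.0),
                          (cy + ay) / 2 + rng.normal(0, 4.0),
                          rng.uniform(15.5, 24.5), rib_d[i],
                          "ribbon_input", "CBb7_ribbon_input")

    # remaining heterocellular junctions over non-CBb7 ON cone bipolar cells
    n_rest = max(0, cfg.n_heterocellular_gj - n_het_used)
    diams = _trunc_normal(rng, *cfg.gj_diam_het, lo, hi, n_rest)
    for i in range(n_rest):
        ai = int(rng.integers(len(aii_ids)))
        aid = aii_ids[ai]
        ax, ay = pos[ai]
        cbb = b.nearest("CBb*", ax, ay, max_dist_um=60.0)
        cid = cbb[int(rng.integers(min(len(cbb), 8)))]
        b.add_contact(min(cid, aid), max(cid, aid), "gap_junction",
                      "gap_junction",
                      ax + rng.normal(0, 8.0), ay + rng.normal(0, 8.0),
                      rng.uniform(15.5, 24.5), diams[i],
                      "gap_junction", "coupling_AII_CBb")


def _lobule_contacts(b: _Builder) -> None:
    """OFF-sublamina contacts: OFF bipolar ribbon input, GABAergic input,
    and the AII's synaptic outputs (all from lobules)."""
    cfg, rng = b.cfg, b.rng
    for idx, aid in enumerate(b.ids["AII"]):
        ax, ay = b.positions["AII"][idx]
        lobules = b.aii_lobules[aid]

        def site() -> tuple[float, float, float]:
            lx, ly, dep = lobules[int(rng.integers(len(lobules)))]
            return (lx + rng.normal(0, 1.0), ly + rng.normal(0, 1.0), dep)

        # sparse OFF cone bipolar ribbon input onto lobules
        for _ in range(int(rng.integers(cfg.offbc_ribbons_per_aii[0],
                                        cfg.offbc_ribbons_per_aii[1] + 1))):
            cba = b.nearest("CBa*", ax, ay, max_dist_um=40.0)
            pre = cba[int(rng.integers(min(len(cba), 6)))]
            x, y, dep = site()
            diam = _trunc_normal(rng, *cfg.ribbon_diam,
                                 *cfg.ribbon_diam_bounds, size=1)[0]
            b.add_contact(pre, aid, "ribbon_presyn", "psd", x, y, dep, diam,
                          "ribbon_input", "OFF_BC_input")

        # dominant GABAergic OFF amacrine input onto lobules
        for _ in range(int(rng.integers(cfg.off_ac_per_aii[0],
                                        cfg.off_ac_per_aii[1] + 1))):
            pre = b.nearest("gammaAC", ax, ay)[
                int(rng.integers(min(len(b.ids["gammaAC"]), 6)))]
            x, y, dep = site()
            diam = _trunc_normal(rng, *cfg.conv_diam, *cfg.conv_diam_bounds,
                                 size=1)[0]
            b.add_contact(pre, aid, "conventional_presyn", "psd", x, y, dep,
                          diam, "conventional_synapse", "AC_input_OFF")

        # glycinergic outputs: OFF cone bipolar cells and amacrine cells
        for _ in range(int(rng.integers(cfg.outputs_to_cba_per_aii[0],
                                        cfg.outputs_to_cba_per_aii[1] + 1))):
            cba = b.nearest("CBa*", ax, ay, max_dist_um=40.0)
            post = cba[int(rng.integers(min(len(cba), 6)))]
            x, y, dep = site()
            diam = _trunc_normal(rng, *cfg.conv_diam, *cfg.conv_diam_bounds,
                                 size=1)[0]
            b.add_contact(aid, post, "conventional_presyn", "psd", x, y, dep,
                          diam, "conventional_synapse", "output_BC")
        for _ in range(int(rng.integers(cfg.outputs_to_ac_per_aii[0],
                                        cfg.outputs_to_ac_per_aii[1] + 1))):
            cls = "gammaAC" if rng.random() < 0.6 else "GAC"
            post = b.nearest(cls, ax, ay)[
                int(rng.integers(min(len(b.ids[cls]), 6)))]
            x, y, dep = site()
            diam = _trunc_normal(rng, *cfg.conv_diam, *cfg.conv_diam_bounds,
                                 size=1)[0]
            b.add_contact(aid, post, "conventional_presyn", "psd", x, y, dep,
                          diam, "conventional_synapse", "output_AC")


def _gc_outputs(b: _Builder) -> None:
    """An OFF alpha (and delta) ganglion cell dendrite crossing the volume:
    every lobule it encounters receives a synapse (touch + synapse pairs)."""
    cfg, rng = b.cfg, b.rng
    aii_ids = b.ids["AII"]
    for gc_cls, n_aii in (("OFF-alpha-GC", cfg.n_gc_coupled_aii),
                          ("OFF-delta-GC", max(1, cfg.n_gc_coupled_aii // 3))):
        gc = b.ids[gc_cls][0]
        chosen = rng.choice(len(aii_ids), size=min(n_aii, len(aii_ids)),
                            replace=False)
        for ai in chosen:
            aid = aii_ids[ai]
            lobules = b.aii_lobules[aid]
            n_lob = int(rng.integers(cfg.gc_lobules_per_aii[0],
                                     cfg.gc_lobules_per_aii[1] + 1))
            for li in rng.choice(len(lobules), size=min(n_lob, len(lobules)),
                                 replace=False):
                lx, ly, dep = lobules[li]
                b.add_touch(aid, gc, lx + rng.normal(0, 1.0),
                            ly + rng.normal(0, 1.0), dep)
                diam = _trunc_normal(rng, *cfg.conv_diam,
                                     *cfg.conv_diam_bounds, size=1)[0]
                b.add_contact(aid, gc, "conventional_presyn", "psd",
                              lx + rng.normal(0, 1.0),
                              ly + rng.normal(0, 1.0),
                              dep, diam, "conventional_synapse", "output_GC")


def _touches_and_adherens(b: _Builder) -> None:
    """Declined connections (touches without specializations) and AII-AI
    adherens junctions."""
    cfg, rng = b.cfg, b.rng
    aii_ids = b.ids["AII"]
    pos = b.positions["AII"]

    def random_aii() -> tuple[int, float, float]:
        i = int(rng.integers(len(aii_ids)))
        return aii_ids[i], pos[i, 0], pos[i, 1]

    gc_all = b.ids["GC*"]
    for _ in range(cfg.n_arboreal_gc_touches):
        aid, ax, ay = random_aii()
        gc = gc_all[int(rng.integers(len(gc_all)))]
        b.add_touch(aid, gc, ax + rng.normal(0, 15.0),
                    ay + rng.normal(0, 15.0), rng.uniform(16.0, 24.0))

    for _ in range(cfg.n_rodbc_lobule_touches):
        aid, ax, ay = random_aii()
        lx, ly, dep = b.aii_lobules[aid][0]
        rod = b.nearest("RodBC", ax, ay)[0]
        b.add_touch(aid, rod, lx, ly, dep)

    for _ in range(cfg.n_lobule_lobule_touches):
        i = int(rng.integers(len(aii_ids)))
        aid = aii_ids[i]
        d = np.hypot(pos[:, 0] - pos[i, 0], pos[:, 1] - pos[i, 1])
        d[i] = np.inf
        other = aii_ids[int(np.argmin(d))]
        lx, ly, dep = b.aii_lobules[aid][int(rng.integers(
            len(b.aii_lobules[aid])))]
        b.add_touch(aid, other, lx, ly, dep)

    for _ in range(cfg.n_ai_lobule_touches):
        aid, ax, ay = random_aii()
        lx, ly, dep = b.aii_lobules[aid][int(rng.integers(
            len(b.aii_lobules[aid])))]
        ai = b.nearest("AI", ax, ay)[0]
        b.add_touch(aid, ai, lx, ly, dep)

    for idx, aid in enumerate(aii_ids):
        ax, ay = pos[idx]
        for _ in range(int(rng.integers(cfg.ai_adherens_per_aii[0],
                                        cfg.ai_adherens_per_aii[1] + 1))):
            ai = b.nearest("AI", ax, ay)[0]
            b.add_contact(min(aid, ai), max(aid, ai), "adherens", "adherens",
                          ax + rng.normal(0, 10.0), ay + rng.normal(0, 10.0),
                          rng.uniform(16.0, 24.0), 300.0, "adherens", None)


def _calibrated_inputs(b: _Builder) -> None:
    """ON amacrine and TH1 inputs with diameters calibrated so the planted
    area ratios (ON-AC : rod ribbon, TH1 : per-cell coupling) hit their
    configured targets."""
    cfg, rng = b.cfg, b.rng
    led = pd.DataFrame(b.ledger_rows)
    t = cfg.section_thickness_nm

    rod_area = led.loc[led["category"] == "rodBC_input", "area_um2"].sum()
    homo = led.loc[led["category"] == "coupling_AII_AII", "area_um2"].sum()
    het = led.loc[led["category"] == "coupling_AII_CBb", "area_um2"].sum()

    def calibrate(diams: np.ndarray, target_total: float) -> np.ndarray:
        """Rescale a diameter sample so its sliced-area total hits target."""
        d = diams.copy()
        for _ in range(4):
            total = sum(_planned_area_um2(x, t) for x in d)
            d = d * math.sqrt(target_total / total)
        return d

    # ON amacrine input (GABAergic + glycinergic, waist/arboreal levels)
    plans = []  # (aii, pre, x, y, depth)
    for idx, aid in enumerate(b.ids["AII"]):
        ax, ay = b.positions["AII"][idx]
        for _ in range(int(rng.integers(cfg.on_ac_per_aii[0],
                                        cfg.on_ac_per_aii[1] + 1))):
            cls = ("gammaAC", "GAC", "AI")[int(rng.integers(3))]
            pre = b.nearest(cls, ax, ay)[
                int(rng.integers(min(len(b.ids[cls]), 6)))]
            plans.append((aid, pre,
                          ax + rng.normal(0, 12.0), ay + rng.normal(0, 12.0),
                          rng.uniform(12.0, 24.0)))
    diams = _trunc_normal(rng, *cfg.conv_diam, *cfg.conv_diam_bounds,
                          size=len(plans))
    diams = calibrate(diams, cfg.on_ac_to_rod_area_ratio * rod_area)
    for (aid, pre, x, y, dep), diam in zip(plans, diams):
        b.add_contact(pre, aid, "conventional_presyn", "psd", x, y, dep,
                      diam, "conventional_synapse",
                      "AC_input_ON" if dep >= 10 else "AC_input_OFF")

    # TH1 dopaminergic/glutamatergic synapses onto the neck
    plans = []
    for idx, aid in enumerate(b.ids["AII"]):
        ax, ay = b.positions["AII"][idx]
        th1 = b.nearest("TH1", ax, ay)[0]
        for _ in range(int(rng.integers(cfg.th1_syn_per_aii[0],
                                        cfg.th1_syn_per_aii[1] + 1))):
            plans.append((aid, th1, ax + rng.normal(0, 2.0),
                          ay + rng.normal(0, 2.0), rng.uniform(-2.5, -0.5)))
    # per-cell coupling weight: homocellular junctions sit on two AII
    # membranes, heterocellular on one
    coupling_weight = 2.0 * homo + het
    diams = _trunc_normal(rng, *cfg.conv_diam, *cfg.conv_diam_bounds,
                          size=len(plans))
    diams = calibrate(diams,
                      cfg.th1_to_coupling_area_frac * coupling_weight)
    for (aid, pre, x, y, dep), diam in zip(plans, diams):
        b.add_contact(pre, aid, "conventional_presyn", "psd", x, y, dep,
                      diam, "conventional_synapse", "TH1_input")


def generate_db(config: GeneratorConfig | None = None
                ) -> tuple[AnnotationDB, PlantedLedger]:
    """Generate a full rule-compliant synthetic volume and its ledger."""
    if config is None:
        config = GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    b = _Builder(config, rng)
    _place_cells(b)
    if len(b.ids.get("AII", [])) < 2:
        raise ValueError("mosaic produced fewer than two AII cells; "
                         "enlarge the field or density")
    intake, rod_counts = _rod_ribbons(b)
    _gap_junctions(b)
    _lobule_contacts(b)
    _gc_outputs(b)
    _touches_and_adherens(b)
    _calibrated_inputs(b)
    b.db.validate_refs()
    ledger = PlantedLedger(
        census=b.db.class_census(),
        mosaic_points_um=b.positions["AII"],
        contacts=pd.DataFrame(b.ledger_rows),
        aii_ribbon_intake=intake,
        rodbc_ribbon_counts=rod_counts,
    )
    return b.db, ledger


# ---------------------------------------------------------------------------
# config-implied expectations (for parameter-recovery tests)


def _truncnorm_grid(mean: float, sd: float, lo: float, hi: float,
                    n: int = 4001) -> tuple[np.ndarray, np.ndarray]:
    x = np.linspace(lo, hi, n)
    pdf = np.exp(-0.5 * ((x - mean) / sd) ** 2)
    pdf /= np.trapezoid(pdf, x)
    return x, pdf


def expected_gj_mean_nm(config: GeneratorConfig, pairing: str) -> float:
    """Mean of the configured truncated-normal junction diameter
    distribution (the value the measured sample mean should recover)."""
    mean, sd = (config.gj_diam_homo if pairing == "homo"
                else config.gj_diam_het)
    x, pdf = _truncnorm_grid(mean, sd, *config.gj_diam_bounds)
    return float(np.trapezoid(x * pdf, x))


def expected_coupling_ratio(config: GeneratorConfig) -> float:
    """Config-implied homocellular : heterocellular per-cell coupling area
    ratio: 2 x n_homo x E[area] over n_het x E[area], with junction area
    integrated over the truncated diameter distributions through the same
    slicing rule the generator uses.  Approximately 7 under the defaults.
    """
    t = config.section_thickness_nm

    def e_area(mean: float, sd: float) -> float:
        x, pdf = _truncnorm_grid(mean, sd, *config.gj_diam_bounds)
        areas = np.array([_planned_area_um2(d, t) for d in x])
        return float(np.trapezoid(areas * pdf, x))

    homo = config.n_homocellular_gj * e_area(*config.gj_diam_homo)
    het = config.n_heterocellular_gj * e_area(*config.gj_diam_het)
    return 2.0 * homo / het


# ---------------------------------------------------------------------------

_VIOLATION_TEMPLATES = ("rod_gj", "ai_lobule_synapse", "cba_gj",
                        "output_from_arboreal")


def inject_violations(db: AnnotationDB, ledger: PlantedLedger, k: int,
                      seed: int = 0) -> list[dict]:
    """Inject ``k`` rule-violating contacts into a generated volume.

    Each injection is constructed to trip exactly one rule (partners are
    chosen so no encounter-level rule fires as a side effect).  Returns the
    injection ledger; the volume is modified in place.
    """
    rng = np.random.default_rng(seed)
    meta = db.meta
    next_sid = max(db.structures) + 1
    contacts = ledger.contacts
    injected = []

    def add_pair(kind_a: str, kind_b: str, cell_a: int, cell_b: int,
                 x_nm: float, y_nm: float, z: int, radius: float) -> tuple:
        nonlocal next_sid
        sids = []
        for kind, cell in ((kind_a, cell_a), (kind_b, cell_b)):
            sid = next_sid
            next_sid += 1
            db.add_structure(StructureRecord(
                structure_id=sid, kind=kind, parent_cell=cell,
                discs=[DiscAnnotation(sid, z, x_nm, y_nm, radius)],
            ))
            sids.append(sid)
        db.structures[sids[0]].link_ids.append(sids[1])
        db.structures[sids[1]].link_ids.append(sids[0])
        return tuple(sids)

    z_arboreal = int(meta.ipl_top_z
                     + 0.8 * (meta.ipl_bottom_z - meta.ipl_top_z))
    z_lobule = int(meta.ipl_top_z
                   + 0.2 * (meta.ipl_bottom_z - meta.ipl_top_z))

    rod_rows = contacts[contacts["category"] == "rodBC_input"]
    ac_rows = contacts[contacts["category"] == "AC_input_OFF"]
    cba_rows = contacts[contacts["category"] == "OFF_BC_input"]
    on_ac_rows = contacts[contacts["category"] == "AC_input_ON"]

    for i in range(k):
        template = _VIOLATION_TEMPLATES[i % len(_VIOLATION_TEMPLATES)]
        if template == "rod_gj":
            # gap junction with a rod BC that already ribbons onto this AII
            row = rod_rows.iloc[int(rng.integers(len(rod_rows)))]
            ref = db.structures[int(row["pre_structure"])].discs[0]
            sids = add_pair("gap_junction", "gap_junction",
                            int(row["pre_cell"]), int(row["post_cell"]),
                            ref.x_nm + 200.0, ref.y_nm, z_arboreal, 150.0)
        elif template == "ai_lobule_synapse":
            row = ac_rows.iloc[int(rng.integers(len(ac_rows)))]
            aii = int(row["post_cell"])
            ai = next(c.cell_id for c in db.cells.values()
                      if c.cell_class == "AI")
            ref = db.structures[int(row["post_structure"])].discs[0]
            sids = add_pair("conventional_presyn", "psd", ai, aii,
                            ref.x_nm + 300.0, ref.y_nm, z_lobule, 150.0)
        elif template == "cba_gj":
            row = cba_rows.iloc[int(rng.integers(len(cba_rows)))]
            ref = db.structures[int(row["pre_structure"])].discs[0]
            sids = add_pair("gap_junction", "gap_junction",
                            int(row["pre_cell"]), int(row["post_cell"]),
                            ref.x_nm - 200.0, ref.y_nm, z_lobule, 150.0)
        else:  # output_from_arboreal
            row = on_ac_rows.iloc[int(rng.integers(len(on_ac_rows)))]
            aii, ac = int(row["post_cell"]), int(row["pre_cell"])
            ref = db.structures[int(row["post_structure"])].discs[0]
            sids = add_pair("conventional_presyn", "psd", aii, ac,
                            ref.x_nm, ref.y_nm + 300.0, z_arboreal, 150.0)
        injected.append({"template": template, "structures": sids})
    return injected
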