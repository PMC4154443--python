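"""End-to-end orchestration: generate -> load -> resolve -> analyze -> report.

A single :func:`run` produces a :class:`ReportBundle` holding the mosaic
statistics, precision report, gap-junction size statistics, depth profiles,
partner summaries, class contact matrix, rule audit and weight ratios, with
provenance (config hash, seed) attached, and writes everything as CSV/JSON
under an output directory.  :func:`paper_check` evaluates the bundle
against the reference values the analysis is expected to reproduce.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, mosaic, network, stats
from .io import export_graph, write_db
from .model import AnnotationDB, CATEGORIES, ContactPair
from .rules import RuleSet, ValidationReport, default_ruleset, validate
from .synthetic import GeneratorConfig, PlantedLedger, generate_db

__all__ = ["ReportBundle", "run", "analyze", "paper_check"]

log = logging.getLogger("aiihub")


@dataclass
class ReportBundle:
    config: GeneratorConfig
    config_hash: str
    mosaic_stats: mosaic.MosaicStats
    precision_cells: stats.PrecisionReport
    precision_ribbons: stats.PrecisionReport
    gj_homo: stats.GJSizeStats
    gj_het: stats.GJSizeStats
    gj_t_test: tuple[float, int, float]
    gj_ks_test: tuple[float, float]
    depth_profiles: dict[str, geometry.DepthProfile]
    partner_summary: network.PartnerSummary
    class_matrix: network.ClassContactMatrix
    hop_report: dict
    weight_ratios: dict
    validation: ValidationReport
    contacts: list[ContactPair]
    ledger: PlantedLedger | None = None

    def summary(self) -> dict:
        ms = self.mosaic_stats
        return {
            "seed": self.config.seed,
            "config_hash": self.config_hash,
            "n_cells": sum(1 for _ in self.class_census()),
            "mosaic": dataclasses.asdict(ms),
            "precision": {
                "cells": {"n": self.precision_cells.n,
                          "mean": self.precision_cells.mean,
                          "sd": self.precision_cells.sd,
                          "cv": self.precision_cells.cv},
                "ribbons": {"n": self.precision_ribbons.n,
                            "mean": self.precision_ribbons.mean,
                            "sd": self.precision_ribbons.sd,
                            "cv": self.precision_ribbons.cv},
                "fold": stats.precision_ratio(self.precision_cells.cv,
                                              self.precision_ribbons.cv)[0],
            },
            "gap_junctions": {
                "homo": {"n": self.gj_homo.n, "mean_nm": self.gj_homo.mean_nm,
                         "sd_nm": self.gj_homo.sd_nm,
                         "max_nm": self.gj_homo.max_nm},
                "het": {"n": self.gj_het.n, "mean_nm": self.gj_het.mean_nm,
                        "sd_nm": self.gj_het.sd_nm,
                        "max_nm": self.gj_het.max_nm},
                "percent_difference": stats.percent_difference(
                    self.gj_homo.mean_nm, self.gj_het.mean_nm),
                "t_test": dict(zip(("t", "df", "p"), self.gj_t_test)),
                "ks_test": dict(zip(("D", "p"), self.gj_ks_test)),
            },
            "weight_ratios": {k: v for k, v in self.weight_ratios.items()
                              if k != "category_totals"},
            "hops": {"max_hop": self.hop_report["max_hop"],
                     "fraction_direct": self.hop_report["fraction_direct"]},
            "rule_audit": {
                "n_proper": self.validation.n_proper,
                "n_violations": self.validation.n_violations,
                "n_touches": self.validation.n_touches,
            },
        }

    def class_census(self):
        seen = set()
        for c in self.contacts:
            for cid in (c.pre_cell, c.post_cell):
                if cid not in seen:
                    seen.add(cid)
                    yield cid


def _config_hash(config: GeneratorConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def analyze(
    db: AnnotationDB,
    config: GeneratorConfig,
    ledger: PlantedLedger | None = None,
    ruleset: RuleSet | None = None,
) -> ReportBundle:
    """Run the full analysis battery on a loaded volume."""
    t0 = time.time()
    contacts = geometry.resolve_contacts(db)
    log.info("resolved %d contacts in %.1fs", len(contacts),
             time.time() - t0)

    aii_ids = sorted(c.cell_id for c in db.cells.values()
                     if c.cell_class == "AII")
    aii_pts = np.array([
        [db.cells[i].soma_x_nm * 1e-3, db.cells[i].soma_y_nm * 1e-3]
        for i in aii_ids
    ])
    aii_pts -= aii_pts.mean(axis=0)
    ms = mosaic.mosaic_stats(aii_pts, db.meta.field_diameter_mm,
                             arbor_diameter_um=config.arboreal_span)

    # sampling precision: rod BC partner counts vs ribbon counts per AII
    partners: dict[int, set[int]] = {i: set() for i in aii_ids}
    ribbons: dict[int, int] = {i: 0 for i in aii_ids}
    for c in contacts:
        if c.category == "rodBC_input":
            partners[c.post_cell].add(c.pre_cell)
            ribbons[c.post_cell] += 1
    with_input = [i for i in aii_ids if ribbons[i] > 0]
    precision_cells = stats.precision_report(
        "rod BC partners per AII", [len(partners[i]) for i in with_input])
    precision_ribbons = stats.precision_report(
        "rod ribbons per AII", [ribbons[i] for i in with_input])

    homo_d = [c.diameter_nm for c in contacts
              if c.category == "coupling_AII_AII"]
    het_d = [c.diameter_nm for c in contacts
             if c.category == "coupling_AII_CBb"]
    gj_homo = stats.size_histogram(homo_d, pairing="AII::AII")
    gj_het = stats.size_histogram(het_d, pairing="AII::CBb")
    gj_t = stats.t_from_summary(gj_homo.mean_nm, gj_homo.sd_nm, gj_homo.n,
                                gj_het.mean_nm, gj_het.sd_nm, gj_het.n)
    gj_ks = stats.ks_two_sample(homo_d, het_d)

    profiles = {cat: geometry.depth_profile(contacts, cat)
                for cat in CATEGORIES}

    # partner map for the most heavily coupled AII cell
    coupling_counts: dict[int, int] = {}
    for c in contacts:
        if c.category == "coupling_AII_CBb":
            aii = c.pre_cell if db.cell_class(c.pre_cell) == "AII" \
                else c.post_cell
            coupling_counts[aii] = coupling_counts.get(aii, 0) + 1
    focal = max(coupling_counts, key=coupling_counts.get) \
        if coupling_counts else aii_ids[0]
    partner_summary = network.aggregate_partners(contacts, focal, db)

    class_matrix = network.class_contact_matrix(contacts, db)
    graph = network.build_graph(contacts, db.cells)
    hop_report = network.hop_distances(graph, "AII")
    weights = network.weight_report(contacts)
    report = validate(db, ruleset or default_ruleset(), contacts)

    return ReportBundle(
        config=config,
        config_hash=_config_hash(config),
        mosaic_stats=ms,
        precision_cells=precision_cells,
        precision_ribbons=precision_ribbons,
        gj_homo=gj_homo,
        gj_het=gj_het,
        gj_t_test=gj_t,
        gj_ks_test=gj_ks,
        depth_profiles=profiles,
        partner_summary=partner_summary,
        class_matrix=class_matrix,
        hop_report=hop_report,
        weight_ratios=weights,
        validation=report,
        contacts=contacts,
        ledger=ledger,
    )


def run(
    config: GeneratorConfig | None = None,
    out_dir: str | Path | None = None,
    allow_violations: bool = False,
    write_volume: bool = True,
) -> ReportBundle:
    """Generate a synthetic volume, analyze it, and write all reports.

    Raises ``RuntimeError`` if the rule audit finds violations, unless
    ``allow_violations`` is set.
    """
    config = config or GeneratorConfig()
    db, ledger = generate_db(config)
    bundle = analyze(db, config, ledger=ledger)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if write_volume:
            write_db(db, out_dir / "volume")
        _write_reports(bundle, out_dir)
    if bundle.validation.n_violations and not allow_violations:
        raise RuntimeError(
            f"rule audit found {bundle.validation.n_violations} violations"
        )
    return bundle


def _write_reports(bundle: ReportBundle, out_dir: Path) -> None:
    (out_dir / "summary.json").write_text(
        json.dumps(bundle.summary(), indent=1, default=str))
    rows = []
    for cat, prof in bundle.depth_profiles.items():
        for lo, area in zip(prof.bin_edges[:-1], prof.area_per_bin):
            rows.append({"category": cat, "bin_lo": lo, "bin_hi": lo + 1,
                         "area_um2": area})
    pd.DataFrame(rows).to_csv(out_dir / "depth_profiles.csv", index=False)
    bundle.partner_summary.table.to_csv(
        out_dir / f"partners_aii_{bundle.partner_summary.focal_cell}.csv",
        index=False)
    if len(bundle.class_matrix.counts):
        bundle.class_matrix.counts.to_csv(out_dir / "class_matrix_counts.csv")
        bundle.class_matrix.areas.to_csv(out_dir / "class_matrix_areas.csv")
    bundle.validation.encounter_table.to_csv(
        out_dir / "encounter_audit.csv", index=False)
    pd.DataFrame([dataclasses.asdict(v)
                  for v in bundle.validation.violations]).to_csv(
        out_dir / "violations.csv", index=False)
    export_graph(bundle.contacts, out_dir / "network.graphml")


#: the worked coupling example: per-partner gap-junction counts of the eight
#: ON cone bipolar cells coupled to one exemplar AII cell (cell 476)
WORKED_COUPLING_PARTNERS = {
    6155: ("CBb3", 1), 4569: ("CBb3", 9), 170: ("CBb4w", 2),
    324: ("CBb4w", 1), 483: ("CBb5w", 2), 6156: ("CBb4-5i", 2),
    419: ("CBb5-6i", 8), 4570: ("CBb5-6i", 3),
}


def worked_partner_example(focal: int = 476) -> network.PartnerSummary:
    """Partner summary of the exemplar AII cell's coupling cohort, built
    from the per-partner gap-junction counts of the worked example."""
    contacts = []
    for partner, (_cls, n) in WORKED_COUPLING_PARTNERS.items():
        for _ in range(n):
            contacts.append(ContactPair(
                pre_cell=min(focal, partner), post_cell=max(focal, partner),
                kind="gap_junction", category="coupling_AII_CBb",
                pre_compartment="arboreal", post_compartment="arboreal",
                area_um2=0.0, diameter_nm=0.0, depth=20.0,
                pre_structure=0, post_structure=0,
            ))
    return network.aggregate_partners(contacts, focal)


#: reference values for :func:`paper_check`: id -> (description, expected,
#: relative tolerance)
_CHECKS = {
    "t1": ("AII planar density (cells/mm^2)", 841.0, 0.10),
    "t2": ("CV of rod BC cell sampling (printed summary)", 0.28, 0.0),
    "t3": ("CV of ribbon sampling (printed summary)", 0.04, 0.0),
    "t4": ("cell vs ribbon precision fold", 7.0, 0.0),
    "t5": ("outlier SDs to equalize CVs", 20.0, 0.0),
    "t6": ("percent difference of GJ mean diameters", 11.0, 0.5 / 11.0),
    "t7": ("grid connectivity at coverage factor 4", 8.0, 0.0),
    "t8": ("rule violations on compliant volume", 0.0, 0.0),
    "t9": ("coupling sites of the worked partner example", 28.0, 0.0),
    "t10": ("measured AII::AII GJ mean diameter (nm)", 267.0, None),
}


def paper_check(bundle: ReportBundle) -> pd.DataFrame:
    """Evaluate the bundle against the reference quantities.

    Desk-scale rows are computed from the printed summary inputs via the
    statistics module; data-scale rows come from the bundle.  Returns one
    row per check with value, expected, tolerance and verdict.
    """
    fold, _ = stats.precision_ratio(stats.cv(11.8, 3.3), stats.cv(75.6, 3.0))
    homo_mean = bundle.gj_homo.mean_nm
    se2 = 2.0 * bundle.config.gj_diam_homo[1] / math.sqrt(max(bundle.gj_homo.n, 1))
    values = {
        "t1": round(bundle.mosaic_stats.density_per_mm2),
        "t2": round(stats.cv(11.8, 3.3), 2),
        "t3": round(stats.cv(75.6, 3.0), 2),
        "t4": fold,
        "t5": stats.outlier_sds_to_reach_cv(5, 75.6, 3.0, 0.28)["k"],
        "t6": round(stats.percent_difference(267.0, 238.0)),
        "t7": mosaic.predicted_grid_connectivity(4.0),
        "t8": bundle.validation.n_violations,
        "t9": worked_partner_example().total_for_kind("gap_junction"),
        "t10": homo_mean,
    }
    rows = []
    for tid, (desc, expected, rtol) in _CHECKS.items():
        value = values[tid]
        if value is None:
            verdict = "not computed"
        elif tid == "t10":
            verdict = "pass" if abs(value - expected) <= se2 else "fail"
        elif rtol == 0.0:
            verdict = "pass" if value == expected else "fail"
        else:
            verdict = ("pass"
                       if abs(value - expected) <= rtol * abs(expected)
                       else "fail")
        rows.append({"id": tid, "description": desc, "value": value,
                     "expected": expected, "verdict": verdict})
    return pd.DataFrame(rows)
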