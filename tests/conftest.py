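"""Shared fixtures: generated volumes, analysis bundles, and tiny
hand-built annotation databases."""

from __future__ import annotations

import pytest

from aiihub.model import (
    AnnotationDB,
    CellRecord,
    DiscAnnotation,
    StructureRecord,
    VolumeMeta,
)
from aiihub.pipeline import analyze
from aiihub.synthetic import GeneratorConfig, generate_db


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def default_volume(default_config):
    """The default synthetic volume (seed 1) and its planted ledger."""
    return generate_db(default_config)


@pytest.fixture(scope="session")
def default_bundle(default_config, default_volume):
    db, ledger = default_volume
    return analyze(db, default_config, ledger=ledger)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A scaled-down volume for fast end-to-end tests."""
    return GeneratorConfig(
        seed=11,
        n_rodbc=30, n_cba=30, n_cbb=40, n_cbb7=3,
        n_ai=8, n_gac=8, n_gamma_ac=10,
        n_homocellular_gj=120, n_heterocellular_gj=40,
        n_gc_coupled_aii=5,
        n_arboreal_gc_touches=4, n_rodbc_lobule_touches=2,
        n_lobule_lobule_touches=2, n_ai_lobule_touches=4,
    )


class TinyDB:
    """Builder for small hand-crafted databases in unit tests."""

    def __init__(self, meta: VolumeMeta | None = None):
        self.db = AnnotationDB(meta=meta or VolumeMeta())
        self._next_sid = 1000

    def cell(self, cid: int, cls: str, x_nm: float = 0.0, y_nm: float = 0.0):
        self.db.add_cell(CellRecord(cid, cls, x_nm, y_nm))
        return cid

    def structure(self, kind: str, parent: int, discs, links=()):
        sid = self._next_sid
        self._next_sid += 1
        d = [DiscAnnotation(sid, z, x, y, r) for (z, x, y, r) in discs]
        self.db.add_structure(
            StructureRecord(sid, kind, parent, d, list(links))
        )
        for lid in links:
            self.db.structures[lid].link_ids.append(sid)
        return sid

    def depth_z(self, depth: float) -> int:
        m = self.db.meta
        return round(m.ipl_top_z + depth / 25 * (m.ipl_bottom_z - m.ipl_top_z))


@pytest.fixture()
def tiny() -> TinyDB:
    return TinyDB()
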