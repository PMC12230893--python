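"""Community assembly: classification, filters, socio-economic covariates.

Atlas grid cells become analysis communities through a fixed, logged filter
sequence: (1) keep cells with at least half their area inside a functional
urban area (FUA); (2) optionally drop species below a per-country occurrence
fraction (a rare-species sensitivity variant, off by default); (3) classify
each cell as invaded (at least one non-native species present) or
non-invaded; (4) drop cells with fewer than three species; (5) join the
area-weighted, per-country-standardized median household income.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import shape
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .containers import CommunityMatrix, IncomeGrid

__all__ = [
    "classify_communities",
    "derive_no_alien",
    "occurrence_filter",
    "min_richness_filter",
    "fua_overlap_filter",
    "cell_income",
    "standardize_income",
    "assemble",
    "AssemblyLog",
]

logger = logging.getLogger(__name__)

INVADED = "invaded"
NON_INVADED = "non-invaded"


def classify_communities(m: CommunityMatrix) -> pd.Series:
    """Label each cell invaded/non-invaded by presence of non-native species.

    Empty cells are labelled non-invaded; they fall to the minimum-richness
    filter downstream.
    """
    alien_cols = m.presence.columns[m.nonnative.to_numpy()]
    n_alien = m.presence[alien_cols].sum(axis=1)
    labels = pd.Series(
        np.where(n_alien > 0, INVADED, NON_INVADED), index=m.presence.index, name="type"
    )
    return labels


def derive_no_alien(m: CommunityMatrix) -> CommunityMatrix:
    """Native component of the invaded communities.

    Returns the invaded cells (same cell ids, enabling pairing) with every
    non-native presence zeroed.  Raises if applied to a matrix containing
    non-invaded cells only.
    """
    labels = classify_communities(m)
    invaded_cells = labels.index[labels == INVADED]
    if len(invaded_cells) == 0:
        raise ValueError("no invaded communities to derive a no-alien set from")
    sub = m.subset_cells(invaded_cells)
    pres = sub.presence.copy()
    pres.loc[:, pres.columns[sub.nonnative.to_numpy()]] = 0
    return CommunityMatrix(presence=pres, cell_meta=sub.cell_meta, nonnative=sub.nonnative)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def occurrence_filter(m: CommunityMatrix, fraction: float = 0.01) -> CommunityMatrix:
    """Drop rare species per country: fewer than round(fraction * n_cells).

    The threshold is rounded half away from zero and species occurring in
    exactly the threshold number of cells are retained ("at least").  A
    species is kept overall if it passes in at least one country; cells are
    untouched.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    keep = pd.Series(False, index=m.presence.columns)
    for country, cells in m.cell_meta.groupby("country").groups.items():
        n_cells = len(cells)
        threshold = max(_round_half_away(fraction * n_cells), 1)
        occ = m.presence.loc[list(cells)].sum(axis=0)
        keep |= occ >= threshold
        logger.info("occurrence filter: country=%s cells=%d threshold=%d", country, n_cells, threshold)
    return m.subset_species(m.presence.columns[keep])


def occurrence_threshold(n_cells: int, fraction: float = 0.01) -> int:
    """The per-country occurrence threshold implied by ``fraction``."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    return max(_round_half_away(fraction * n_cells), 1)


def min_richness_filter(m: CommunityMatrix, k: int = 3) -> CommunityMatrix:
    """Remove communities with fewer than ``k`` species (dispersion is
    unreliable below three members)."""
    rich = m.richness()
    return m.subset_cells(rich.index[rich >= k])


def _as_geom(g):
    return g if hasattr(g, "geom_type") else shape(g)


def fua_overlap_filter(cells: dict, fuas: list, min_frac: float = 0.5) -> list:
    """Keep cell ids whose intersection with the FUA union covers at least
    ``min_frac`` of the cell's area (boundary-inclusive: exactly 50% passes).

    Parameters
    ----------
    cells
        Mapping cell id -> polygon (shapely geometry or GeoJSON-like dict).
    fuas
        Iterable of FUA polygons.
    """
    union = unary_union([_as_geom(f) for f in fuas])
    kept = []
    for cid, geom in cells.items():
        g = _as_geom(geom)
        if not g.is_valid:
            raise ValueError(f"invalid cell geometry: {cid}")
        if g.area <= 0:
            continue
        frac = g.intersection(union).area / g.area
        if frac >= min_frac - 1e-12:
            kept.append(cid)
    return kept


def cell_income(cells: dict, neighbourhoods: list[tuple[object, float]]) -> pd.Series:
    """Area-weighted mean of neighbourhood median incomes per grid cell.

    income_cell = sum_k area(overlap_k) * income_k / sum_k area(overlap_k).
    Weighting by overlap area prevents a neighbourhood that straddles
    several cells from being over-represented.  Cells with no overlapping
    income polygon are NaN (missing, never zero) and are dropped from models.

    Parameters
    ----------
    cells
        Mapping cell id -> polygon.
    neighbourhoods
        Iterable of ``(polygon, income)`` pairs; incomes must be positive.
    """
    nb = [(_as_geom(g), float(v)) for g, v in neighbourhoods]
    for _, v in nb:
        if v <= 0:
            raise ValueError("incomes must be positive")
    tree = STRtree([g for g, _ in nb])
    out = {}
    for cid, geom in cells.items():
        g = _as_geom(geom)
        wsum = vsum = 0.0
        for k in tree.query(g):
            poly, inc = nb[int(k)]
            a = g.intersection(poly).area
            if a > 0:
                wsum += a
                vsum += a * inc
        out[cid] = vsum / wsum if wsum > 0 else np.nan
    return pd.Series(out, name="income")


def standardize_income(g: IncomeGrid) -> IncomeGrid:
    """Per-country z-scores of cell income (sample sd), NaN rows excluded.

    Separate standardization per country puts the two national income
    distributions on a common scale despite different costs of living.
    """
    t = g.table.copy()
    z = pd.Series(np.nan, index=t.index, dtype=float)
    for country, idx in t.groupby("country").groups.items():
        x = t.loc[idx, "income"]
        valid = x.dropna()
        if len(valid) < 2:
            raise ValueError(f"country {country!r} has < 2 cells with income")
        z.loc[valid.index] = (valid - valid.mean()) / valid.std(ddof=1)
    t["z_income"] = z
    return IncomeGrid(table=t, standardized=True)


@dataclass
class AssemblyLog:
    """Cell/species counts at each pipeline stage, in applied order."""

    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, n_cells: int, n_species: int) -> None:
        self.stages.append({"stage": stage, "n_cells": n_cells, "n_species": n_species})
        logger.info("assembly %s: %d cells, %d species", stage, n_cells, n_species)


def assemble(
    m: CommunityMatrix,
    income: IncomeGrid,
    *,
    cells_geom: dict | None = None,
    fuas_geom: list | None = None,
    occurrence_fraction: float | None = None,
    min_richness: int = 3,
) -> tuple[CommunityMatrix, IncomeGrid, pd.Series, AssemblyLog]:
    """Run the fixed filter pipeline and return analysis-ready objects.

    Order: FUA-overlap filter -> occurrence filter (only when a fraction is
    given; rare-species screening is a sensitivity variant) -> invasion
    classification -> minimum-richness filter -> income join (cells with
    missing income dropped).  Returns the filtered matrix, the matching
    standardized income grid, per-cell invasion labels, and the stage log.
    """
    log = AssemblyLog()
    log.record("input", len(m.cells), len(m.species))

    if cells_geom is not None and fuas_geom is not None:
        kept = fua_overlap_filter(cells_geom, fuas_geom)
        m = m.subset_cells([c for c in m.cells if c in set(kept)])
        log.record("fua_overlap", len(m.cells), len(m.species))

    if occurrence_fraction is not None:
        m = occurrence_filter(m, occurrence_fraction)
        log.record("occurrence", len(m.cells), len(m.species))

    labels = classify_communities(m)

    m = min_richness_filter(m, k=min_richness)
    labels = labels.loc[m.cells]
    log.record("min_richness", len(m.cells), len(m.species))

    if not income.standardized:
        income = standardize_income(income)
    inc = income.table.loc[[c for c in m.cells if c in income.table.index]]
    inc = inc[inc["income"].notna()]
    m = m.subset_cells(inc.index)
    labels = labels.loc[m.cells]
    log.record("income_join", len(m.cells), len(m.species))

    return m, IncomeGrid(table=inc, standardized=True), labels, log
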