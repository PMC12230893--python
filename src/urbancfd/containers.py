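"""Shared tabular containers for the analysis pipeline.

Traits, communities and incomes all travel as thin wrappers around pandas
objects so every module reads and writes the same plain-text formats
(CSV/TSV, Newick, GeoJSON).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TraitTable", "CommunityMatrix", "IncomeGrid", "CULTURAL", "REGULATING"]

CULTURAL = "cultural"
REGULATING = "regulating"


@dataclass
class TraitTable:
    """Species-by-trait values plus per-trait metadata.

    Attributes
    ----------
    values
        DataFrame indexed by species id; one column per trait.  Continuous
        traits are real-valued, binary traits are 0/1.
    meta
        DataFrame indexed by trait name with columns ``group`` (one of the
        nine trait groups), ``service`` (``cultural`` or ``regulating``) and
        ``kind`` (``continuous`` or ``binary``).
    nonnative
        Boolean Series indexed by species id.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    nonnative: pd.Series

    def __post_init__(self) -> None:
        missing = set(self.meta.index) - set(self.values.columns)
        if missing:
            raise ValueError(f"traits in meta but not in values: {sorted(missing)}")
        self.nonnative = self.nonnative.reindex(self.values.index).fillna(False).astype(bool)

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    def service_columns(self, service: str) -> list[str]:
        if service not in (CULTURAL, REGULATING):
            raise ValueError(f"unknown service {service!r}")
        cols = self.meta.index[self.meta["service"] == service]
        return [c for c in cols if c in self.values.columns]

    def subset(self, columns: list[str]) -> "TraitTable":
        return TraitTable(
            values=self.values[columns].copy(),
            meta=self.meta.loc[[c for c in columns if c in self.meta.index]].copy(),
            nonnative=self.nonnative.copy(),
        )

    # -- I/O ---------------------------------------------------------------
    def write(self, values_path: str | Path, meta_path: str | Path | None = None) -> None:
        out = self.values.copy()
        out.insert(0, "nonnative", self.nonnative.astype(int))
        out.to_csv(values_path, index_label="species")
        if meta_path is not None:
            self.meta.to_csv(meta_path, index_label="trait")

    @classmethod
    def read(cls, values_path: str | Path, meta_path: str | Path) -> "TraitTable":
        values = pd.read_csv(values_path, index_col="species")
        nonnative = values.pop("nonnative").astype(bool)
        meta = pd.read_csv(meta_path, index_col="trait")
        return cls(values=values, meta=meta, nonnative=nonnative)


@dataclass
class CommunityMatrix:
    """Grid-cell-by-species presence/absence with cell and species metadata."""

    presence: pd.DataFrame  # cells x species, 0/1
    cell_meta: pd.DataFrame  # index cell id; columns fua, country
    nonnative: pd.Series  # bool by species

    def __post_init__(self) -> None:
        if not set(self.presence.index) <= set(self.cell_meta.index):
            raise ValueError("presence rows without cell metadata")
        self.cell_meta = self.cell_meta.loc[self.presence.index]
        vals = self.presence.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("presence values must be 0/1")
        self.presence = self.presence.astype(np.int8)
        self.nonnative = self.nonnative.reindex(self.presence.columns).fillna(False).astype(bool)

    @property
    def cells(self) -> list:
        return list(self.presence.index)

    @property
    def species(self) -> list[str]:
        return list(self.presence.columns)

    def richness(self) -> pd.Series:
        return self.presence.sum(axis=1).rename("richness")

    def community(self, cell) -> list[str]:
        row = self.presence.loc[cell]
        return list(row.index[row > 0])

    def subset_cells(self, cells) -> "CommunityMatrix":
        return CommunityMatrix(
            presence=self.presence.loc[list(cells)].copy(),
            cell_meta=self.cell_meta.loc[list(cells)].copy(),
            nonnative=self.nonnative.copy(),
        )

    def subset_species(self, species) -> "CommunityMatrix":
        return CommunityMatrix(
            presence=self.presence[list(species)].copy(),
            cell_meta=self.cell_meta.copy(),
            nonnative=self.nonnative.loc[list(species)].copy(),
        )

    # -- I/O ---------------------------------------------------------------
    def write(self, path: str | Path) -> None:
        out = pd.concat([self.cell_meta, self.presence], axis=1)
        out.to_csv(path, index_label="cell")

    @classmethod
    def read(cls, path: str | Path, nonnative: pd.Series) -> "CommunityMatrix":
        df = pd.read_csv(path, index_col="cell")
        meta = df[["fua", "country"]]
        pres = df.drop(columns=["fua", "country"])
        return cls(presence=pres, cell_meta=meta, nonnative=nonnative)


@dataclass
class IncomeGrid:
    """Per-cell area-weighted median household income, raw and standardized.

    ``table`` is indexed by cell id with columns ``income`` (currency/year,
    NaN where no income polygon overlaps the cell), ``z_income`` (per-country
    standardized, filled by :func:`urbancfd.assembly.standardize_income`),
    ``fua`` and ``country``.
    """

    table: pd.DataFrame
    standardized: bool = field(default=False)

    def __post_init__(self) -> None:
        required = {"income", "fua", "country"}
        if not required <= set(self.table.columns):
            raise ValueError(f"income table needs columns {sorted(required)}")

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="cell")

    @classmethod
    def read(cls, path: str | Path) -> "IncomeGrid":
        t = pd.read_csv(path, index_col="cell")
        return cls(table=t, standardized="z_income" in t.columns)
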