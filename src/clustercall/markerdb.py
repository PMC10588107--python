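"""Marker-gene database: loading, validation, QC and the indicator matrix.

A marker database is a catalogue of (tissue, cell type, gene, species)
records: gene *g* is listed as a marker of cell type *c* in tissue *t*.
Annotation never touches expression data directly — it only asks, for each
differentially expressed gene of a cluster, which cell types list that gene
as a marker. That membership question is answered by a binary indicator
matrix ``d`` with ``d[i, c] = 1`` iff gene *i* is a marker of cell type *c*.

Two on-disk layouts are accepted:

* long form (canonical): one record per row with columns
  ``tissue, cell_type, gene[, species]``;
* wide binary form: rows are genes, columns are ``tissue:cell_type`` labels,
  entries are 0/1 membership flags.

Gene symbols are matched case-insensitively (human ``INS1`` vs mouse
``Ins1``) through an upper-cased matching key, optionally after resolving
aliases through a user-supplied synonym table; display casing is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "EmptyDatabaseError",
    "MarkerDatabase",
    "IndicatorMatrix",
    "DatabaseQC",
    "normalize_gene_symbol",
    "load_database",
    "load_synonyms",
    "to_indicator",
    "qc_summary",
    "spreadsheet_to_tsv",
]

LONG_COLUMNS = ("tissue", "cell_type", "gene")
SPECIES_VALUES = ("human", "mouse", "both")


class SchemaError(ValueError):
    """A required column or field is missing or malformed."""


class EmptyDatabaseError(ValueError):
    """The database file contains no marker records."""


def normalize_gene_symbol(symbol: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Return the canonical matching key for a gene symbol.

    Trims whitespace, resolves the alias through ``synonyms`` (keys matched
    case-insensitively) and upper-cases the result so that human/mouse
    casing variants collapse onto one key. Idempotent.
    """
    key = symbol.strip()
    if not key:
        raise ValueError("empty gene symbol")
    key = key.upper()
    if synonyms:
        key = _fold_synonyms(synonyms).get(key, key)
    return key


def _fold_synonyms(synonyms: Mapping[str, str]) -> dict[str, str]:
    return {a.strip().upper(): c.strip().upper() for a, c in synonyms.items()}


def load_synonyms(path: str | Path) -> dict[str, str]:
    """Read a two-column (alias, canonical) TSV into a synonym mapping."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise SchemaError(f"synonym table {path} needs two columns (alias, canonical)")
    # tolerate an optional header line
    if df.iloc[0, 0].strip().lower() in {"alias", "symbol"}:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))


@dataclass(frozen=True)
class MarkerDatabase:
    """A validated catalogue of marker records.

    ``records`` holds one row per (tissue, cell_type, gene, species) with an
    additional ``gene_key`` column (the canonical matching key). The
    cell-type universe is the set of distinct (tissue, cell_type) pairs:
    identical names in different tissues are distinct cell types.
    """

    records: pd.DataFrame
    gene_synonyms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in LONG_COLUMNS if c not in self.records.columns]
        if missing:
            raise SchemaError(f"marker records missing column(s): {', '.join(missing)}")
        if self.records.empty:
            raise EmptyDatabaseError("marker database has no records")

    @property
    def tissues(self) -> list[str]:
        return sorted(self.records["tissue"].unique())

    @property
    def cell_types(self) -> list[tuple[str, str]]:
        pairs = self.records[["tissue", "cell_type"]].drop_duplicates()
        return sorted(map(tuple, pairs.itertuples(index=False)))

    @property
    def n_records(self) -> int:
        return len(self.records)

    def subset(self, tissue: str | None = None, species: str | None = None) -> "MarkerDatabase":
        """Restrict to one tissue and/or species track (case-insensitive tissue match)."""
        rec = self.records
        if tissue is not None:
            key = tissue.strip().lower()
            mask = rec["tissue"].str.strip().str.lower() == key
            if not mask.any():
                raise ValueError(
                    f"unknown tissue {tissue!r}; available: {', '.join(self.tissues)}"
                )
            rec = rec[mask]
        if species is not None:
            if species not in SPECIES_VALUES:
                raise ValueError(f"species must be one of {SPECIES_VALUES}, got {species!r}")
            if species != "both":
                rec = rec[rec["species"].isin([species, "both"])]
            if rec.empty:
                raise EmptyDatabaseError(f"no records for species {species!r}")
        return MarkerDatabase(rec.reset_index(drop=True), self.gene_synonyms)

    def to_tsv(self, path: str | Path) -> None:
        """Write the validated long-form layout (tissue, cell_type, gene, species)."""
        cols = ["tissue", "cell_type", "gene", "species"]
        self.records[cols].to_csv(path, sep="\t", index=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerDatabase):
            return NotImplemented
        cols = ["tissue", "cell_type", "gene_key", "species"]
        a = self.records[cols].sort_values(cols).reset_index(drop=True)
        b = other.records[cols].sort_values(cols).reset_index(drop=True)
        return a.equals(b)


def _read_table(path: Path) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _is_wide_layout(df: pd.DataFrame) -> bool:
    header = {c.strip().lower() for c in df.columns}
    if {"tissue", "cell_type", "gene"} <= header:
        return False
    return any(":" in c for c in df.columns[1:])


def _long_from_wide(df: pd.DataFrame) -> pd.DataFrame:
    gene_col = df.columns[0]
    rows = []
    for col in df.columns[1:]:
        if ":" not in col:
            raise SchemaError(
                f"wide-layout column {col!r} is not of the form 'tissue:cell_type'"
            )
        tissue, cell_type = col.split(":", 1)
        vals = df[col].str.strip()
        bad = ~vals.isin(["0", "1", "0.0", "1.0", ""])
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-binary entry {vals.iloc[i]!r} at row {i} (gene "
                f"{df[gene_col].iloc[i]!r}), column {col!r}"
            )
        hit = vals.isin(["1", "1.0"])
        for g in df.loc[hit, gene_col]:
            rows.append((tissue.strip(), cell_type.strip(), g.strip(), "both"))
    return pd.DataFrame(rows, columns=["tissue", "cell_type", "gene", "species"])


def load_database(
    path: str | Path,
    species_filter: str | None = None,
    synonyms: Mapping[str, str] | None = None,
) -> MarkerDatabase:
    """Load and validate a marker database from a long-form or wide binary file.

    The layout is auto-detected from the header: a ``tissue/cell_type/gene``
    header selects long form, ``tissue:cell_type`` columns select the wide
    binary layout. Exact duplicate records are dropped (count logged). Gene
    symbols keep their display casing; a ``gene_key`` column carries the
    canonical matching key.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_table(path)
    if df.empty:
        raise EmptyDatabaseError(f"{path} contains no marker records")

    if _is_wide_layout(df):
        rec = _long_from_wide(df)
    else:
        df.columns = [c.strip().lower() for c in df.columns]
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"{path} is missing required column(s): {', '.join(missing)}")
        rec = df.copy()
        if "species" not in rec.columns:
            rec["species"] = "both"
        rec = rec[["tissue", "cell_type", "gene", "species"]]

    for col in ("tissue", "cell_type", "gene"):
        rec[col] = rec[col].str.strip()
        if (rec[col] == "").any():
            i = int(np.flatnonzero((rec[col] == "").to_numpy())[0])
            raise ValueError(f"empty {col!r} value at record {i} in {path}")
    rec["species"] = rec["species"].str.strip().str.lower().replace("", "both")
    bad_sp = ~rec["species"].isin(SPECIES_VALUES)
    if bad_sp.any():
        raise ValueError(
            f"invalid species value(s) {sorted(rec.loc[bad_sp, 'species'].unique())}; "
            f"expected one of {SPECIES_VALUES}"
        )

    syn = dict(synonyms) if synonyms else {}
    rec["gene_key"] = [normalize_gene_symbol(g, syn) for g in rec["gene"]]

    before = len(rec)
    rec = rec.drop_duplicates(subset=["tissue", "cell_type", "gene_key", "species"])
    if len(rec) < before:
        logger.info("dropped %d duplicate marker record(s)", before - len(rec))
    if rec.empty:
        raise EmptyDatabaseError(f"{path} contains no marker records after deduplication")

    db = MarkerDatabase(rec.reset_index(drop=True), syn)
    if species_filter is not None:
        db = db.subset(species=species_filter)
    return db


@dataclass(frozen=True)
class IndicatorMatrix:
    """Binary genes x cell-types membership matrix.

    ``genes`` are canonical matching keys (axis 0), ``cell_types`` are
    (tissue, cell_type) pairs (axis 1); ``d[i, c] = 1`` iff gene i marks
    cell type c. Every row and column has at least one 1 by construction.
    """

    genes: tuple[str, ...]
    cell_types: tuple[tuple[str, str], ...]
    d: np.ndarray

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def to_records(self) -> set[tuple[str, str, str]]:
        """Reconstruct the (tissue, cell_type, gene_key) membership set."""
        ii, cc = np.nonzero(self.d)
        return {(*self.cell_types[c], self.genes[i]) for i, c in zip(ii, cc)}


def to_indicator(db: MarkerDatabase, tissue: str | None = None) -> IndicatorMatrix:
    """Derive the binary indicator matrix, optionally restricted to one tissue.

    Cell-type labels retain the tissue so identical names in different
    tissues stay distinct columns. Axes are sorted for determinism.
    """
    sub = db.subset(tissue=tissue) if tissue is not None else db
    rec = sub.records
    genes = tuple(sorted(rec["gene_key"].unique()))
    cell_types = tuple(sub.cell_types)
    gi = {g: i for i, g in enumerate(genes)}
    ci = {ct: j for j, ct in enumerate(cell_types)}
    d = np.zeros((len(genes), len(cell_types)), dtype=np.int8)
    for t, c, g in rec[["tissue", "cell_type", "gene_key"]].itertuples(index=False):
        d[gi[g], ci[(t, c)]] = 1
    return IndicatorMatrix(genes, cell_types, d)


@dataclass(frozen=True)
class DatabaseQC:
    """Summary statistics and quality flags for a marker database.

    ``n_marker_entries`` counts species tracks: a record listed for both
    species contributes one human and one mouse entry; ``markers_per_celltype``
    counts distinct genes per (tissue, cell_type) regardless of species.
    """

    n_tissues: int
    n_cell_types: int
    n_marker_entries: int
    n_marker_rows: int
    markers_per_celltype: pd.Series
    celltypes_per_tissue: pd.Series
    markers_min: int
    markers_max: int
    markers_mean: float
    markers_mean_1dp: float
    frac_tissues_gt6_celltypes: float
    frac_celltypes_gt4_markers: float

    def oneliner(self) -> str:
        return (
            f"{self.n_tissues} tissues, {self.n_cell_types} cell types, "
            f"{self.n_marker_entries} marker entries "
            f"(markers/cell type: min {self.markers_min}, "
            f"mean {self.markers_mean_1dp}, max {self.markers_max})"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "n_tissues",
                    "n_cell_types",
                    "n_marker_entries",
                    "n_marker_rows",
                    "markers_per_celltype_min",
                    "markers_per_celltype_mean",
                    "markers_per_celltype_max",
                    "frac_tissues_gt6_celltypes",
                    "frac_celltypes_gt4_markers",
                ],
                "value": [
                    self.n_tissues,
                    self.n_cell_types,
                    self.n_marker_entries,
                    self.n_marker_rows,
                    self.markers_min,
                    self.markers_mean_1dp,
                    self.markers_max,
                    round(self.frac_tissues_gt6_celltypes, 3),
                    round(self.frac_celltypes_gt4_markers, 3),
                ],
            }
        )


def qc_summary(db: MarkerDatabase) -> DatabaseQC:
    """Compute database QC counts and quality flags.

    Quality flags follow the catalogue-quality convention of flagging
    tissues with more than 6 cell types and cell types with more than 4
    marker genes; the fractions report how much of the database passes.
    """
    rec = db.records
    unified = rec[["tissue", "cell_type", "gene_key"]].drop_duplicates()
    per_ct = unified.groupby(["tissue", "cell_type"]).size().sort_index()
    per_tissue = (
        rec[["tissue", "cell_type"]].drop_duplicates().groupby("tissue").size().sort_index()
    )
    # species tracks: 'both' covers human and mouse, hence counts twice
    entries = int((rec["species"].map({"human": 1, "mouse": 1, "both": 2})).sum())
    mean = float(per_ct.mean())
    return DatabaseQC(
        n_tissues=int(per_tissue.size),
        n_cell_types=int(per_ct.size),
        n_marker_entries=entries,
        n_marker_rows=int(len(unified)),
        markers_per_celltype=per_ct,
        celltypes_per_tissue=per_tissue,
        markers_min=int(per_ct.min()),
        markers_max=int(per_ct.max()),
        markers_mean=mean,
        markers_mean_1dp=round(mean, 1),
        frac_tissues_gt6_celltypes=float((per_tissue > 6).mean()),
        frac_celltypes_gt4_markers=float((per_ct > 4).mean()),
    )


def spreadsheet_to_tsv(
    xlsx_path: str | Path, out_path: str | Path, sheet: int | str = 0
) -> Path:
    """Convert one sheet of a spreadsheet (e.g. a supplementary table) to TSV."""
    df = pd.read_excel(xlsx_path, sheet_name=sheet, dtype=str)
    out_path = Path(out_path)
    df.to_csv(out_path, sep="\t", index=False)
    return out_path
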