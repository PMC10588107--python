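"""Synthetic marker databases and cluster marker tables with planted truth.

Simulation starts at the tool's input boundary — the differential-expression
marker table — rather than at count matrices: each synthetic cluster is
generated *from* one database cell type (the planted truth), with its signal
genes drawn from that type's marker set at strong effect sizes and its noise
genes drawn from other cell types' markers or from genes the database has
never seen. Effect-size defaults mimic strong curated markers (log2 fold
change in [1, 3], out-of-cluster detection below 0.1); noise rows use weak
background ranges and adjusted p-values straddling the 0.05 filter boundary
so the filtering step always has real work to do.

Everything is a pure function of the config (same seed, same bytes out).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .markerdb import MarkerDatabase

__all__ = [
    "SyntheticConfig",
    "PlantedTruth",
    "make_database",
    "make_truth",
    "make_marker_table",
    "make_reference_like_database",
    "write_fixture_scenario",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic scenario generator.

    Ranges are inclusive (low, high) bounds of uniform draws. ``noise_fraction``
    is the fraction of each cluster's rows that are noise genes — half drawn
    from other cell types' marker sets, half novel symbols absent from the
    database. ``shared_marker_rate`` injects marker overlap between cell
    types (0 = disjoint marker sets).
    """

    n_tissues: int = 1
    n_celltypes_per_tissue: int = 8
    markers_per_celltype: tuple[int, int] = (5, 15)
    n_clusters: int = 8
    genes_per_cluster: int = 20
    signal_log2fc: tuple[float, float] = (1.0, 3.0)
    background_log2fc: tuple[float, float] = (-0.5, 0.5)
    pct_in: tuple[float, float] = (0.4, 0.9)
    pct_out_signal: tuple[float, float] = (0.01, 0.1)
    pct_out_background: tuple[float, float] = (0.2, 0.6)
    noise_fraction: float = 0.2
    shared_marker_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tissues", "n_celltypes_per_tissue", "n_clusters", "genes_per_cluster"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in (
            "markers_per_celltype",
            "signal_log2fc",
            "background_log2fc",
            "pct_in",
            "pct_out_signal",
            "pct_out_background",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range ({lo}, {hi}) is inverted")
        if not 0.0 <= self.noise_fraction < 1.0:
            raise ValueError("noise_fraction must lie in [0, 1)")
        if not 0.0 <= self.shared_marker_rate <= 1.0:
            raise ValueError("shared_marker_rate must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth: which cell type each synthetic cluster was generated from."""

    table: pd.DataFrame  # columns: cluster, tissue, cell_type, n_cells

    def reference_labels(self) -> pd.DataFrame:
        return self.table[["cluster", "cell_type", "n_cells"]].copy()


def _rng(config: SyntheticConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), salt]))


def make_database(config: SyntheticConfig) -> MarkerDatabase:
    """Synthetic marker catalogue with disjoint-by-default marker sets.

    Gene symbols are 'G000001'-style; with ``shared_marker_rate`` r > 0,
    each cell type replaces round(r * size) of its private markers with
    markers of the preceding cell type, injecting controlled overlap.
    """
    rng = _rng(config, 1)
    lo, hi = config.markers_per_celltype
    n_ct = config.n_tissues * config.n_celltypes_per_tissue
    sizes = rng.integers(lo, hi + 1, size=n_ct)
    universe = sizes.sum()
    pool = [f"G{i + 1:06d}" for i in range(int(universe))]
    if len(pool) < sizes.sum():
        raise ValueError("requested more markers than the gene universe holds")
    rows = []
    cursor = 0
    prev: list[str] = []
    for j in range(n_ct):
        tissue = f"tissue{j // config.n_celltypes_per_tissue + 1:02d}"
        ct = f"celltype{j + 1:02d}"
        size = int(sizes[j])
        genes = pool[cursor : cursor + size]
        cursor += size
        n_shared = round(config.shared_marker_rate * size)
        if n_shared and prev:
            borrowed = list(rng.choice(prev, size=min(n_shared, len(prev)), replace=False))
            genes = genes[: size - len(borrowed)] + borrowed
        for g in genes:
            rows.append((tissue, ct, g, "both"))
        prev = genes
    rec = pd.DataFrame(rows, columns=["tissue", "cell_type", "gene", "species"])
    rec["gene_key"] = rec["gene"].str.upper()
    rec = rec.drop_duplicates(subset=["tissue", "cell_type", "gene_key", "species"])
    return MarkerDatabase(rec.reset_index(drop=True))


def make_truth(db: MarkerDatabase, config: SyntheticConfig) -> PlantedTruth:
    """Assign each cluster a planted cell type (cycling) and a cell count."""
    rng = _rng(config, 2)
    cell_types = db.cell_types
    rows = []
    for k in range(config.n_clusters):
        tissue, ct = cell_types[k % len(cell_types)]
        rows.append((str(k), tissue, ct, int(rng.integers(50, 501))))
    return PlantedTruth(pd.DataFrame(rows, columns=["cluster", "tissue", "cell_type", "n_cells"]))


def make_marker_table(
    db: MarkerDatabase, truth: PlantedTruth, config: SyntheticConfig
) -> pd.DataFrame:
    """Generate the per-cluster DE table implied by the planted truth.

    Signal rows (fraction 1 - noise_fraction) are markers of the cluster's
    planted type with log2 fold change and detection fractions from the
    signal ranges and adjusted p-values log-uniform in [1e-50, 1e-3]. Noise
    rows alternate between other cell types' markers and novel genes, use
    the background ranges, and cycle through three fates — fail the
    detection filter, fail the significance filter, pass both — so both
    filter branches are exercised whenever noise rows exist.
    """
    rng = _rng(config, 3)
    markers_by_ct = {
        (t, c): list(g["gene"]) for (t, c), g in db.records.groupby(["tissue", "cell_type"])
    }
    all_cts = list(markers_by_ct)
    novel_counter = 0
    noise_counter = 0  # global, so filter-failing fates appear even at 1 noise row/cluster
    rows = []
    for cluster, tissue, ct, _n in truth.table.itertuples(index=False):
        planted = (tissue, ct)
        n_noise = round(config.noise_fraction * config.genes_per_cluster)
        n_signal = config.genes_per_cluster - n_noise
        own = markers_by_ct[planted]
        take = min(n_signal, len(own))
        signal_genes = list(rng.choice(own, size=take, replace=False))
        n_noise += n_signal - take  # shift shortfall into noise
        used = set(signal_genes)
        for g in signal_genes:
            rows.append(
                (
                    cluster,
                    g,
                    rng.uniform(*config.signal_log2fc),
                    rng.uniform(*config.pct_in),
                    rng.uniform(*config.pct_out_signal),
                    10 ** rng.uniform(-50, -3),
                )
            )
        for j in range(n_noise):
            if j % 2 == 0 and len(all_cts) > 1:
                # marker of some other cell type
                others = [p for p in all_cts if p != planted]
                src = others[int(rng.integers(len(others)))]
                candidates = [g for g in markers_by_ct[src] if g not in used]
                if candidates:
                    gene = candidates[int(rng.integers(len(candidates)))]
                else:
                    novel_counter += 1
                    gene = f"NOV{novel_counter:05d}"
            else:
                novel_counter += 1
                gene = f"NOV{novel_counter:05d}"
            used.add(gene)
            fate = noise_counter % 3
            noise_counter += 1
            if fate == 0:  # fails the detection-fraction filter
                pct_in = rng.uniform(0.02, 0.25)
                p_adj = 10 ** rng.uniform(-6, -2)
            elif fate == 1:  # fails the significance filter
                pct_in = rng.uniform(0.3, 0.9)
                p_adj = rng.uniform(0.05, 0.8)
            else:  # passes both
                pct_in = rng.uniform(0.3, 0.9)
                p_adj = 10 ** rng.uniform(-4, np.log10(0.049))
            rows.append(
                (
                    cluster,
                    gene,
                    rng.uniform(*config.background_log2fc),
                    pct_in,
                    rng.uniform(*config.pct_out_background),
                    p_adj,
                )
            )
    return pd.DataFrame(
        rows, columns=["cluster", "gene", "avg_log2fc", "pct_in", "pct_out", "p_adj"]
    )


def write_fixture_scenario(outdir: str | Path, config: SyntheticConfig) -> dict[str, Path]:
    """Materialize a full test scenario directory (database, markers, reference).

    Marker tables are written with Seurat-style headers so the files also
    exercise the header-alias reader.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    db = make_database(config)
    truth = make_truth(db, config)
    table = make_marker_table(db, truth, config)
    paths = {
        "database": outdir / "database.tsv",
        "markers": outdir / "markers.tsv",
        "reference": outdir / "reference.tsv",
    }
    db.to_tsv(paths["database"])
    seurat = table.rename(
        columns={"avg_log2fc": "avg_log2FC", "pct_in": "pct.1", "pct_out": "pct.2", "p_adj": "p_val_adj"}
    )[["gene", "cluster", "avg_log2FC", "pct.1", "pct.2", "p_val_adj"]]
    seurat.to_csv(paths["markers"], sep="\t", index=False)
    truth.reference_labels().to_csv(paths["reference"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Reference-catalogue stand-in

#: 28 tissue names used by the synthetic reference-like catalogue
_CATALOG_TISSUES = (
    "skin", "bone", "muscle", "brain", "heart", "blood", "lung", "tooth",
    "esophagus", "liver", "pancreas", "stomach", "small intestine",
    "large intestine", "bladder", "kidney", "ovary", "placenta", "uterus",
    "mammary gland", "embryo", "testis", "prostate", "bone marrow", "thymus",
    "spleen", "adipose tissue", "eye",
)


def make_reference_like_database(seed: int = 0) -> MarkerDatabase:
    """SYNTHETIC stand-in for a curated human/mouse marker catalogue.

    Generates a database with the summary shape of a large published
    catalogue: 28 tissues, 340 cell types, 14,892 distinct
    (tissue, cell type, gene) marker rows (per-type counts between 4 and
    300 with mean 43.8), of which 11,595 are shared human/mouse entries —
    26,487 marker entries when each species track is counted separately.
    Gene symbols and cell-type names are synthetic; only the marginal
    counts are meaningful. Intended for exercising QC and scale, not for
    annotating real data.
    """
    rng = np.random.default_rng(seed)
    n_types, total_rows, n_both = 340, 14_892, 11_595

    counts = np.clip(
        np.round(rng.lognormal(mean=np.log(28.0), sigma=0.9, size=n_types)), 4, 300
    ).astype(int)
    counts[0], counts[1] = 4, 300  # pin the published extremes
    diff = total_rows - int(counts.sum())
    while diff != 0:
        j = int(rng.integers(2, n_types))
        if diff > 0 and counts[j] < 300:
            counts[j] += 1
            diff -= 1
        elif diff < 0 and counts[j] > 4:
            counts[j] -= 1
            diff += 1

    # 28 tissues covering 340 cell types: four tissues hold 13, the rest 12
    sizes = [13] * 4 + [12] * 24
    assert sum(sizes) == n_types
    tissue_of = np.repeat(np.arange(28), sizes)

    pool = np.array([f"G{i + 1:05d}" for i in range(25_000)])
    rows = []
    for j in range(n_types):
        tissue = _CATALOG_TISSUES[tissue_of[j]]
        ct = f"{tissue} cell type {j + 1:03d}"
        genes = rng.choice(pool, size=int(counts[j]), replace=False)
        rows.extend((tissue, ct, g) for g in genes)
    rec = pd.DataFrame(rows, columns=["tissue", "cell_type", "gene"])

    species = np.empty(total_rows, dtype=object)
    both_idx = rng.choice(total_rows, size=n_both, replace=False)
    species[:] = ""
    species[both_idx] = "both"
    rest = np.flatnonzero(species == "")
    species[rest[: len(rest) // 2]] = "human"
    species[rest[len(rest) // 2 :]] = "mouse"
    rec["species"] = species
    rec["gene_key"] = rec["gene"].str.upper()
    return MarkerDatabase(rec.reset_index(drop=True))
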