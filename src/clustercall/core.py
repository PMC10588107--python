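"""Cluster annotation engine: marker filtering, composite scores, selection.

The method assumes a good marker gene is highly expressed in its cell type
and rarely detected elsewhere. Starting from a per-cluster differential
expression table (one row per cluster/gene, the layout produced by Seurat's
``FindAllMarkers``), annotation proceeds in four steps:

1. **Filter.** Keep genes detected in more than ``pct_threshold`` (default
   0.25) of the cluster's cells with adjusted p-value below ``alpha``
   (default 0.05); both inequalities strict.
2. **Gene score.** Each retained gene i of cluster k gets a composite
   expression score ``S_i = 2**l * p_in / p_out`` where l is the average
   log2 fold change, p_in the detection fraction in the cluster and p_out
   the detection fraction in all other clusters. On the log scale this is
   the log fold change plus the log prevalence ratio. A ``zero_floor``
   (default 0.001) replaces p_out = 0 so genes detected nowhere else rank
   finitely high instead of producing infinities.
3. **Cell-type score.** For each candidate cell type c,
   ``S_c = (1 / I_k) * sum_i S_i * d_ic`` where d_ic is database membership
   and I_k counts *all* retained genes of cluster k, matched or not —
   clusters dominated by genes the database does not know are penalized.
4. **Selection.** Cell types are ranked by S_c; the number of co-assigned
   types n is the jump point of the score sequence, operationalized as the
   position of the largest gap between consecutive sorted scores within the
   positive-score prefix (ties toward smaller n), capped at ``max_n``.

The statsmodels-style surface is :class:`CellTypeAnnotator` (model) whose
``fit()`` returns an :class:`AnnotationResult` (ranked candidates, selected
types, matched-marker evidence, ``summary()``, ``to_tsv()``, ``plot()``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .markerdb import (
    IndicatorMatrix,
    MarkerDatabase,
    SchemaError,
    load_database,
    normalize_gene_symbol,
    to_indicator,
)

__all__ = [
    "REQUIRED_COLUMNS",
    "read_marker_table",
    "validate_marker_table",
    "filter_markers",
    "gene_score",
    "celltype_scores",
    "CellTypeScoreMatrix",
    "select_top_n",
    "annotate",
    "CellTypeAnnotator",
    "AnnotationResult",
    "UNASSIGNED",
]

#: canonical internal column names of a cluster marker table
REQUIRED_COLUMNS = ("cluster", "gene", "avg_log2fc", "pct_in", "pct_out", "p_adj")

#: sentinel label for clusters that could not be annotated
UNASSIGNED = "unassigned"

# Seurat FindAllMarkers headers and common variants -> canonical names
_HEADER_ALIASES = {
    "cluster": "cluster",
    "gene": "gene",
    "avg_log2fc": "avg_log2fc",
    "avg_logfc": "avg_logfc_natural",  # natural-log fold change, rescaled below
    "pct.1": "pct_in",
    "pct_1": "pct_in",
    "pct_in": "pct_in",
    "pct.2": "pct_out",
    "pct_2": "pct_out",
    "pct_out": "pct_out",
    "p_val_adj": "p_adj",
    "p_adj": "p_adj",
    "padj": "p_adj",
}


def read_marker_table(path: str | Path, logfc_units: str = "log2") -> pd.DataFrame:
    """Read a cluster marker table from CSV/TSV into the canonical layout.

    Accepts the Seurat ``FindAllMarkers`` header (gene, cluster, avg_log2FC,
    pct.1, pct.2, p_val_adj) and canonical names. ``avg_logFC`` columns in
    natural-log units (``logfc_units='ln'`` or an ``avg_logFC`` header) are
    converted to log2 via the log2(e) scale factor.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep)
    cols = {}
    for c in raw.columns:
        canon = _HEADER_ALIASES.get(c.strip().lower())
        if canon:
            cols[c] = canon
    df = raw.rename(columns=cols)
    if "avg_logfc_natural" in df.columns and "avg_log2fc" not in df.columns:
        df["avg_log2fc"] = df["avg_logfc_natural"] * np.log2(np.e)
        df = df.drop(columns=["avg_logfc_natural"])
    elif logfc_units == "ln" and "avg_log2fc" in df.columns:
        df["avg_log2fc"] = df["avg_log2fc"] * np.log2(np.e)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path} is missing required column(s): {', '.join(missing)} "
            f"(accepted aliases: {sorted(set(_HEADER_ALIASES))})"
        )
    df = df[list(REQUIRED_COLUMNS)].copy()
    df["cluster"] = df["cluster"].astype(str)
    df["gene"] = df["gene"].astype(str)
    return validate_marker_table(df)


def validate_marker_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check ranges and uniqueness of a canonical-layout marker table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"marker table missing column(s): {', '.join(missing)}")
    t = table.copy()
    t["cluster"] = t["cluster"].astype(str)
    t["gene"] = t["gene"].astype(str).str.strip()
    for col in ("avg_log2fc", "pct_in", "pct_out", "p_adj"):
        t[col] = pd.to_numeric(t[col], errors="coerce")
    bad = ~np.isfinite(t["avg_log2fc"])
    for col in ("pct_in", "pct_out", "p_adj"):
        bad |= ~t[col].between(0.0, 1.0)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        row = t.iloc[i]
        raise ValueError(
            f"invalid marker-table row {i} (cluster {row['cluster']!r}, gene "
            f"{row['gene']!r}): avg_log2fc must be finite and pct_in/pct_out/"
            "p_adj within [0, 1]"
        )
    dup = t.duplicated(subset=["cluster", "gene"])
    if dup.any():
        pairs = t.loc[dup, ["cluster", "gene"]].drop_duplicates()
        raise ValueError(
            "duplicate (cluster, gene) rows in marker table: "
            + "; ".join(f"({c}, {g})" for c, g in pairs.itertuples(index=False))
        )
    return t.reset_index(drop=True)


def filter_markers(
    table: pd.DataFrame, pct_threshold: float = 0.25, alpha: float = 0.05
) -> pd.DataFrame:
    """Retain rows with ``pct_in > pct_threshold`` and ``p_adj < alpha``.

    Both inequalities are strict: rows exactly at the thresholds are
    dropped. Input row order is preserved. Per-cluster retained counts
    (the denominator I_k, including zero counts for clusters losing every
    row) are attached as ``result.attrs['i_k']``.
    """
    table = validate_marker_table(table)
    keep = (table["pct_in"] > pct_threshold) & (table["p_adj"] < alpha)
    out = table[keep].reset_index(drop=True)
    clusters = table["cluster"].unique()
    i_k = out["cluster"].value_counts().reindex(clusters, fill_value=0)
    out.attrs["i_k"] = i_k.to_dict()
    return out


def gene_score(
    avg_log2fc: float | np.ndarray,
    pct_in: float | np.ndarray,
    pct_out: float | np.ndarray,
    zero_floor: float = 0.001,
) -> float | np.ndarray:
    """Composite expression score ``2**avg_log2fc * pct_in / max(pct_out, zero_floor)``.

    Vectorized; scalar inputs return a scalar. ``pct_in`` must be positive
    on retained rows (a zero cannot have passed the detection filter).
    """
    l = np.asarray(avg_log2fc, dtype=float)
    p_in = np.asarray(pct_in, dtype=float)
    p_out = np.asarray(pct_out, dtype=float)
    if np.any(p_in <= 0.0):
        raise ValueError("pct_in must be > 0 on retained rows")
    # scalar pow per element: bit-identical to a plain evaluation of the
    # formula (numpy's SIMD pow can differ in the last ulp)
    pow2 = np.fromiter((2.0**v for v in l.ravel()), dtype=float, count=l.size).reshape(l.shape)
    s = pow2 * p_in / np.maximum(p_out, zero_floor)
    if np.isscalar(avg_log2fc) and np.isscalar(pct_in) and np.isscalar(pct_out):
        return float(s)
    return s


@dataclass(frozen=True)
class CellTypeScoreMatrix:
    """Per-(cluster, cell type) scores S_c with the per-cluster denominators I_k."""

    clusters: tuple[str, ...]
    cell_types: tuple[tuple[str, str], ...]
    s: np.ndarray  # shape (n_clusters, n_cell_types), nonnegative
    i_k: np.ndarray  # retained-gene counts per cluster

    def to_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(self.cell_types, names=["tissue", "cell_type"])
        return pd.DataFrame(self.s, index=list(self.clusters), columns=cols)


def celltype_scores(
    scores: pd.DataFrame,
    indicator: IndicatorMatrix,
    clusters: Sequence[str] | None = None,
) -> CellTypeScoreMatrix:
    """Average the matched gene scores into per-cell-type scores.

    ``scores`` holds the retained rows with columns ``cluster``, ``gene``
    (or a pre-normalized ``gene_key``) and ``s_gene``. For each cluster k,
    ``S_c = sum(s_gene over retained genes that mark c) / I_k`` with I_k the
    count of all retained genes of the cluster; genes absent from the
    database add nothing to any cell type but still inflate I_k. ``clusters``
    may list extra cluster labels (e.g. filtered to emptiness) which come
    out as all-zero rows with I_k = 0.
    """
    if "gene_key" in scores.columns:
        keys = scores["gene_key"]
    else:
        keys = scores["gene"].map(normalize_gene_symbol)
    order = list(dict.fromkeys(scores["cluster"])) if clusters is None else list(clusters)
    gi = indicator.gene_index()
    n_c = len(indicator.cell_types)
    s = np.zeros((len(order), n_c), dtype=float)
    i_k = np.zeros(len(order), dtype=int)
    pos = {k: i for i, k in enumerate(order)}
    for cl, grp in scores.groupby("cluster", sort=False):
        if cl not in pos:
            raise ValueError(f"score table contains unknown cluster {cl!r}")
        r = pos[cl]
        i_k[r] = len(grp)
        rows = keys.loc[grp.index].map(gi)
        hit = rows.notna()
        if hit.any():
            idx = rows[hit].astype(int).to_numpy()
            w = grp.loc[hit, "s_gene"].to_numpy(dtype=float)
            s[r] = w @ indicator.d[idx] / len(grp)
    return CellTypeScoreMatrix(tuple(order), indicator.cell_types, s, i_k)


def select_top_n(scores_for_cluster: Sequence[float], max_n: int = 3) -> int:
    """Number of cell types to co-assign, by the largest-gap jump rule.

    ``scores_for_cluster`` must be sorted descending. Over positions m in
    the positive-score prefix, the gap ``s[m-1] - s[m]`` is computed; n is
    the position of the largest gap (first occurrence on ties, i.e. ties
    break toward smaller n), capped at ``max_n``. Returns 0 when every
    score is zero (no assignment possible).
    """
    s = np.asarray(scores_for_cluster, dtype=float)
    if s.size and np.any(np.diff(s) > 0):
        raise ValueError("scores must be sorted in descending order")
    n_pos = int((s > 0).sum())
    if n_pos == 0:
        return 0
    m_max = min(n_pos, s.size - 1)
    if m_max < 1:
        return 1
    gaps = s[:m_max] - s[1 : m_max + 1]
    n = int(np.argmax(gaps)) + 1
    return min(n, max_n)


@dataclass
class AnnotationResult:
    """Ranked cell-type predictions per cluster with matched-marker evidence.

    Attributes
    ----------
    ranked : DataFrame
        One row per (cluster, candidate cell type) with positive score:
        columns cluster, rank, tissue, cell_type, score, normalized_score
        (score divided by the cluster's maximum), selected (jump-point
        choice). Within a cluster, ties in score are broken by
        (tissue, cell_type) lexicographic order.
    evidence : DataFrame
        For every selected cell type, the retained marker genes that
        matched it and their composite scores (cluster, tissue, cell_type,
        gene, s_gene).
    assignments : Series
        Cluster -> top-ranked cell-type name, ``'unassigned'`` where no
        candidate scored above zero.
    i_k : Series
        Retained-gene count per cluster (the score denominator).
    unassigned : dict
        Cluster -> reason, for clusters without an assignment.
    params : dict
        Effective thresholds of the run.
    """

    ranked: pd.DataFrame
    evidence: pd.DataFrame
    assignments: pd.Series
    i_k: pd.Series
    unassigned: dict[str, str]
    params: dict
    cell_types: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    @property
    def clusters(self) -> list[str]:
        return list(self.assignments.index)

    def selected(self) -> pd.DataFrame:
        return self.ranked[self.ranked["selected"]].reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            "Cluster annotation summary",
            f"  clusters: {len(self.assignments)}   "
            f"unassigned: {len(self.unassigned)}   "
            f"candidate cell types: {len(self.cell_types)}",
            f"  thresholds: pct_in > {self.params['pct_threshold']}, "
            f"p_adj < {self.params['alpha']}, zero_floor {self.params['zero_floor']}, "
            f"max_n {self.params['max_n']}",
            "",
            f"  {'cluster':<12} {'I_k':>4}  {'predicted cell type(s)':<44} {'top score':>10}",
        ]
        for cl in self.clusters:
            if cl in self.unassigned:
                lines.append(
                    f"  {cl:<12} {self.i_k.get(cl, 0):>4}  "
                    f"{UNASSIGNED + ' (' + self.unassigned[cl] + ')':<44} {'-':>10}"
                )
                continue
            sel = self.ranked[(self.ranked["cluster"] == cl) & self.ranked["selected"]]
            names = "; ".join(sel["cell_type"])
            top = sel["score"].iloc[0]
            lines.append(f"  {cl:<12} {self.i_k[cl]:>4}  {names:<44} {top:>10.4g}")
        return "\n".join(lines)

    def to_tsv(self, outdir: str | Path) -> tuple[Path, Path]:
        """Write the prediction and evidence tables; returns their paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pred = outdir / "predictions.tsv"
        evid = outdir / "evidence.tsv"
        out = self.ranked.copy()
        out["score"] = out["score"].map(lambda v: f"{v:.10g}")
        out["normalized_score"] = out["normalized_score"].map(lambda v: f"{v:.10g}")
        out.to_csv(pred, sep="\t", index=False)
        ev = self.evidence.copy()
        if len(ev):
            ev["s_gene"] = ev["s_gene"].map(lambda v: f"{v:.10g}")
        ev.to_csv(evid, sep="\t", index=False)
        return pred, evid

    def plot(self, path: str | Path | None = None, **kwargs):
        from .plotting import render_dotplot

        return render_dotplot(self, path=path, **kwargs)


class CellTypeAnnotator:
    """Model object: a cluster marker table scored against a marker database.

    Parameters
    ----------
    table : DataFrame
        Cluster marker table in canonical layout (see
        :func:`read_marker_table`); one row per (cluster, gene) with
        avg_log2fc, pct_in, pct_out and p_adj.
    database : MarkerDatabase
        The marker catalogue to score against.
    tissue : str, optional
        Restrict candidates to one tissue of the database.
    pct_threshold, alpha : float
        Marker filter: detection fraction strictly above ``pct_threshold``
        and adjusted p-value strictly below ``alpha``.
    zero_floor : float
        Floor for a zero out-of-cluster detection fraction.
    max_n : int
        Cap on the number of co-assigned cell types per cluster.

    ``fit()`` runs the filter/score/select pipeline and returns an
    :class:`AnnotationResult`.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        database: MarkerDatabase,
        tissue: str | None = None,
        pct_threshold: float = 0.25,
        alpha: float = 0.05,
        zero_floor: float = 0.001,
        max_n: int = 3,
    ) -> None:
        for name, v in (("pct_threshold", pct_threshold), ("alpha", alpha)):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if zero_floor <= 0:
            raise ValueError(f"zero_floor must be positive, got {zero_floor}")
        if max_n < 1:
            raise ValueError(f"max_n must be >= 1, got {max_n}")
        self.table = validate_marker_table(table)
        self.database = database
        self.tissue = tissue
        self.pct_threshold = pct_threshold
        self.alpha = alpha
        self.zero_floor = zero_floor
        self.max_n = max_n

    @classmethod
    def from_files(
        cls,
        markers_path: str | Path,
        db_path: str | Path,
        species_filter: str | None = None,
        synonyms: Mapping[str, str] | None = None,
        logfc_units: str = "log2",
        **kwargs,
    ) -> "CellTypeAnnotator":
        table = read_marker_table(markers_path, logfc_units=logfc_units)
        db = load_database(db_path, species_filter=species_filter, synonyms=synonyms)
        return cls(table, db, **kwargs)

    def fit(self) -> AnnotationResult:
        params = {
            "tissue": self.tissue,
            "pct_threshold": self.pct_threshold,
            "alpha": self.alpha,
            "zero_floor": self.zero_floor,
            "max_n": self.max_n,
        }
        clusters = list(dict.fromkeys(self.table["cluster"]))
        retained = filter_markers(self.table, self.pct_threshold, self.alpha)
        retained = retained.copy()
        retained["s_gene"] = gene_score(
            retained["avg_log2fc"].to_numpy(),
            retained["pct_in"].to_numpy(),
            retained["pct_out"].to_numpy(),
            self.zero_floor,
        )
        syn = self.database.gene_synonyms
        retained["gene_key"] = [normalize_gene_symbol(g, syn) for g in retained["gene"]]

        indicator = to_indicator(self.database, tissue=self.tissue)
        if not set(retained["gene_key"]) & set(indicator.genes):
            warnings.warn(
                "no overlap between marker-table genes and database genes; "
                "every cluster will be unassigned",
                stacklevel=2,
            )
        mat = celltype_scores(retained, indicator, clusters=clusters)

        gi = indicator.gene_index()
        tissues = np.array([t for t, _ in mat.cell_types])
        names = np.array([c for _, c in mat.cell_types])
        lex = np.lexsort((names, tissues))  # tie-break order

        ranked_rows, evid_rows = [], []
        assign, unassigned = {}, {}
        for r, cl in enumerate(mat.clusters):
            if mat.i_k[r] == 0:
                assign[cl] = UNASSIGNED
                unassigned[cl] = "no marker genes passed filtering"
                continue
            row = mat.s[r]
            # sort by descending score, ties lexicographic on (tissue, cell_type)
            order = lex[np.argsort(-row[lex], kind="stable")]
            order = order[row[order] > 0]
            if order.size == 0:
                assign[cl] = UNASSIGNED
                unassigned[cl] = "no retained gene matched the database"
                continue
            top = row[order[0]]
            n_sel = select_top_n(row[order], max_n=self.max_n)
            grp = retained[retained["cluster"] == cl]
            for rank, j in enumerate(order, start=1):
                sel = rank <= n_sel
                ranked_rows.append(
                    (cl, rank, tissues[j], names[j], row[j], row[j] / top, sel)
                )
                if sel:
                    for g in grp.index:
                        i = gi.get(grp.at[g, "gene_key"])
                        if i is not None and indicator.d[i, j]:
                            evid_rows.append(
                                (cl, tissues[j], names[j], grp.at[g, "gene"], grp.at[g, "s_gene"])
                            )
            assign[cl] = names[order[0]]

        ranked = pd.DataFrame(
            ranked_rows,
            columns=[
                "cluster",
                "rank",
                "tissue",
                "cell_type",
                "score",
                "normalized_score",
                "selected",
            ],
        )
        evidence = pd.DataFrame(
            evid_rows, columns=["cluster", "tissue", "cell_type", "gene", "s_gene"]
        )
        i_k = pd.Series(
            {cl: int(mat.i_k[r]) for r, cl in enumerate(mat.clusters)}, name="i_k"
        )
        return AnnotationResult(
            ranked=ranked,
            evidence=evidence,
            assignments=pd.Series(assign, name="cell_type").reindex(clusters),
            i_k=i_k.reindex(clusters, fill_value=0),
            unassigned=unassigned,
            params=params,
            cell_types=mat.cell_types,
        )


def annotate(
    table: pd.DataFrame,
    db: MarkerDatabase,
    tissue: str | None = None,
    pct_threshold: float = 0.25,
    alpha: float = 0.05,
    zero_floor: float = 0.001,
    max_n: int = 3,
) -> AnnotationResult:
    """One-call annotation: build a :class:`CellTypeAnnotator` and fit it."""
    return CellTypeAnnotator(
        table,
        db,
        tissue=tissue,
        pct_threshold=pct_threshold,
        alpha=alpha,
        zero_floor=zero_floor,
        max_n=max_n,
    ).fit()
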