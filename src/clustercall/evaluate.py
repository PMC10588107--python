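"""Benchmarking of cluster annotations against reference labels.

The protocol scores cluster-level predictions against the cell-type labels
published with a dataset. Because label vocabularies differ between tools
and atlases ("NK cell" vs "natural killer cell", islet "b" vs "beta cell"),
both sides are first canonicalized through an editable synonym table; known
ambiguous reference names (e.g. "pp", "MHC class II", "PSC") are excluded
from the evaluation entirely. Metrics:

* **accuracy** — proportion of cells (cluster sizes as weights) whose
  cluster was labelled with its reference cell type;
* **cluster_accuracy** — unweighted fraction of clusters correct;
* **f1** — per reference cell type, precision/recall over cell-weighted
  cluster assignments (a correct cluster is a TP for its type; a wrong one
  is an FN for its reference type and an FP for its predicted type), with
  the per-type F1 scores averaged weighted by reference cell counts;
* **per_celltype** — per-reference-type accuracy.

Unassigned predictions always count as wrong; they are never excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .core import UNASSIGNED, AnnotationResult

__all__ = [
    "LabelSynonyms",
    "BenchmarkReport",
    "read_reference_labels",
    "resolve_prediction",
    "score_benchmark",
]


def _canon_key(label: str) -> str:
    """Whitespace-collapsed, case-folded label with a plural 'cells' singularized."""
    key = " ".join(str(label).strip().split()).casefold()
    if key.endswith(" cells"):
        key = key[: -len(" cells")] + " cell"
    return key


@dataclass(frozen=True)
class LabelSynonyms:
    """Cell-type name harmonization: alias -> canonical map plus exclusions.

    The mapping is applied once after basic normalization (trim, case-fold,
    'cells' -> 'cell') and must be idempotent: a canonical name never
    appears as an alias of something else.
    """

    mapping: dict[str, str] = field(default_factory=dict)
    exclusions: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        folded = {_canon_key(a): _canon_key(c) for a, c in self.mapping.items()}
        for alias, canon in folded.items():
            if canon in folded and folded[canon] != canon:
                raise ValueError(
                    f"synonym map is not idempotent: {alias!r} -> {canon!r} -> {folded[canon]!r}"
                )
        object.__setattr__(self, "mapping", folded)
        object.__setattr__(
            self, "exclusions", frozenset(_canon_key(e) for e in self.exclusions)
        )

    def canonical(self, label: str) -> str:
        key = _canon_key(label)
        return self.mapping.get(key, key)

    def is_excluded(self, label: str) -> bool:
        return self.canonical(label) in self.exclusions or _canon_key(label) in self.exclusions

    @classmethod
    def from_files(
        cls, mapping_path: str | Path | None = None, exclusions_path: str | Path | None = None
    ) -> "LabelSynonyms":
        """Load from a two-column alias/canonical TSV and a one-column exclusion list."""
        mapping: dict[str, str] = {}
        exclusions: set[str] = set()
        if mapping_path is not None:
            df = pd.read_csv(mapping_path, sep="\t", header=None, comment="#", dtype=str)
            if df.shape[1] < 2:
                raise ValueError(f"{mapping_path}: expected two columns (alias, canonical)")
            if df.iloc[0, 0].strip().lower() == "alias":
                df = df.iloc[1:]
            mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
        if exclusions_path is not None:
            text = Path(exclusions_path).read_text()
            exclusions = {
                ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")
            }
        return cls(mapping, frozenset(exclusions))

    @classmethod
    def default(cls) -> "LabelSynonyms":
        """The synonym/exclusion tables shipped with the package."""
        data = resources.files("clustercall.data")
        with resources.as_file(data / "label_synonyms.tsv") as m, resources.as_file(
            data / "label_exclusions.txt"
        ) as e:
            return cls.from_files(m, e)


def read_reference_labels(path: str | Path) -> pd.DataFrame:
    """Read reference labels: TSV with columns cluster, cell_type, n_cells."""
    df = pd.read_csv(path, sep="\t", dtype={"cluster": str})
    missing = [c for c in ("cluster", "cell_type", "n_cells") if c not in df.columns]
    if missing:
        raise ValueError(f"{path} missing column(s): {', '.join(missing)}")
    df["cluster"] = df["cluster"].astype(str)
    if df["cluster"].duplicated().any():
        raise ValueError(f"{path}: duplicate cluster labels")
    if (df["n_cells"] < 1).any():
        raise ValueError(f"{path}: n_cells must be >= 1")
    return df


def resolve_prediction(result: AnnotationResult) -> pd.Series:
    """Collapse a multi-assignment result to one label per cluster.

    The final call is the rank-1 (maximum-score) cell type; clusters with
    no positive-scoring candidate map to the ``'unassigned'`` sentinel.
    """
    return result.assignments.copy()


@dataclass(frozen=True)
class BenchmarkReport:
    """Benchmark metrics; all values in [0, 1]."""

    accuracy: float
    cluster_accuracy: float
    f1: float
    per_celltype: pd.DataFrame
    n_clusters_evaluated: int
    n_clusters_excluded: int
    n_cells_evaluated: int

    def summary(self) -> str:
        lines = [
            "Benchmark report",
            f"  clusters evaluated: {self.n_clusters_evaluated} "
            f"(excluded: {self.n_clusters_excluded}); cells: {self.n_cells_evaluated}",
            f"  accuracy (cell-weighted): {self.accuracy:.4f}",
            f"  accuracy (per cluster):   {self.cluster_accuracy:.4f}",
            f"  F1 (cell-weighted):       {self.f1:.4f}",
            "",
            "  per reference cell type:",
        ]
        for row in self.per_celltype.itertuples(index=False):
            lines.append(
                f"    {row.cell_type:<32} cells {row.n_cells:>6}  "
                f"acc {row.accuracy:.3f}  F1 {row.f1:.3f}"
            )
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.per_celltype.to_csv(path, sep="\t", index=False)
        return path


def score_benchmark(
    predictions: pd.Series | dict,
    reference: pd.DataFrame,
    synonyms: LabelSynonyms | None = None,
) -> BenchmarkReport:
    """Score per-cluster predictions against reference labels.

    ``predictions`` maps cluster -> predicted cell-type name (the
    ``'unassigned'`` sentinel allowed); ``reference`` has columns cluster,
    cell_type, n_cells. Both label sets are canonicalized through
    ``synonyms`` (package defaults if omitted); clusters whose reference
    label is excluded are dropped from every numerator and denominator.
    """
    syn = synonyms if synonyms is not None else LabelSynonyms.default()
    pred = pd.Series(predictions)
    pred.index = pred.index.astype(str)
    ref = reference.copy()
    ref["cluster"] = ref["cluster"].astype(str)

    unknown = set(pred.index) - set(ref["cluster"])
    if unknown:
        raise ValueError(f"predictions for unknown cluster(s): {sorted(unknown)}")

    ref = ref[ref["cluster"].isin(pred.index)].reset_index(drop=True)
    excluded = ref["cell_type"].map(syn.is_excluded)
    n_excluded = int(excluded.sum())
    ref = ref[~excluded].reset_index(drop=True)
    if ref.empty:
        raise ValueError("no clusters left to evaluate after exclusions")

    ref["ref_canon"] = ref["cell_type"].map(syn.canonical)
    ref["pred_canon"] = [
        UNASSIGNED if pred[c] == UNASSIGNED else syn.canonical(pred[c])
        for c in ref["cluster"]
    ]
    ref["correct"] = ref["ref_canon"] == ref["pred_canon"]

    cells = ref["n_cells"].to_numpy(dtype=float)
    total_cells = float(cells.sum())
    accuracy = float(cells[ref["correct"]].sum() / total_cells)
    cluster_accuracy = float(ref["correct"].mean())

    rows = []
    for ct, grp in ref.groupby("ref_canon", sort=True):
        n_ct = float(grp["n_cells"].sum())
        tp = float(grp.loc[grp["correct"], "n_cells"].sum())
        fn = n_ct - tp
        fp = float(
            ref.loc[(ref["pred_canon"] == ct) & ~ref["correct"], "n_cells"].sum()
        )
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        rows.append((ct, int(n_ct), len(grp), tp / n_ct, precision, recall, f1))
    per_ct = pd.DataFrame(
        rows,
        columns=["cell_type", "n_cells", "n_clusters", "accuracy", "precision", "recall", "f1"],
    )
    weights = per_ct["n_cells"].to_numpy(dtype=float)
    f1_weighted = float((per_ct["f1"].to_numpy() * weights).sum() / weights.sum())

    return BenchmarkReport(
        accuracy=accuracy,
        cluster_accuracy=cluster_accuracy,
        f1=f1_weighted,
        per_celltype=per_ct,
        n_clusters_evaluated=len(ref),
        n_clusters_excluded=n_excluded,
        n_cells_evaluated=int(total_cells),
    )
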