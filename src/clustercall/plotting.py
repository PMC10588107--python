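"""Dot-plot visualization of cluster annotation results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core import AnnotationResult

__all__ = ["render_dotplot"]

# stable SVG ids so re-renders are byte-identical
plt.rcParams["svg.hashsalt"] = "clustercall"


def render_dotplot(
    result: AnnotationResult,
    path: str | Path | None = None,
    max_candidates: int = 10,
    ax: plt.Axes | None = None,
) -> plt.Figure:
    """Draw clusters (rows) x candidate cell types (columns) as a dot grid.

    Dot area and shade encode the within-cluster normalized score (the
    cluster's best candidate is always the largest dot of its row); cell
    types selected by the jump-point rule get a ring. Columns are limited
    to cell types appearing in any cluster's top ``max_candidates``. With
    ``path`` given, both ``<path>.png`` and ``<path>.svg`` are written
    deterministically.
    """
    ranked = result.ranked
    clusters = result.clusters
    shown = ranked[ranked["rank"] <= max_candidates]
    if shown.empty:
        fig, ax_ = plt.subplots(figsize=(4, 2)) if ax is None else (ax.figure, ax)
        ax_.text(0.5, 0.5, "no cluster could be annotated", ha="center", va="center")
        ax_.set_axis_off()
    else:
        cts = sorted(set(zip(shown["tissue"], shown["cell_type"])))
        col = {ct: j for j, ct in enumerate(cts)}
        row = {cl: i for i, cl in enumerate(clusters)}
        if ax is None:
            fig, ax_ = plt.subplots(
                figsize=(1.0 + 0.45 * len(cts), 1.0 + 0.4 * len(clusters))
            )
        else:
            fig, ax_ = ax.figure, ax
        xs = shown.apply(lambda r: col[(r["tissue"], r["cell_type"])], axis=1)
        ys = shown["cluster"].map(row)
        sizes = 20 + 260 * shown["normalized_score"] ** 2
        sc = ax_.scatter(
            xs, ys, s=sizes, c=shown["normalized_score"], cmap="viridis",
            vmin=0, vmax=1, zorder=3,
        )
        sel = shown[shown["selected"]]
        ax_.scatter(
            sel.apply(lambda r: col[(r["tissue"], r["cell_type"])], axis=1),
            sel["cluster"].map(row),
            s=20 + 260 * sel["normalized_score"] ** 2,
            facecolors="none", edgecolors="crimson", linewidths=1.4, zorder=4,
        )
        ax_.set_xticks(range(len(cts)))
        ax_.set_xticklabels(
            [c if len({t for t, _ in cts}) == 1 else f"{t}: {c}" for t, c in cts],
            rotation=60, ha="right", fontsize=8,
        )
        ax_.set_yticks(range(len(clusters)))
        ax_.set_yticklabels(clusters, fontsize=8)
        ax_.invert_yaxis()
        ax_.set_xlabel("candidate cell type")
        ax_.set_ylabel("cluster")
        ax_.set_xlim(-0.5, len(cts) - 0.5)
        ax_.grid(True, linewidth=0.3, alpha=0.5, zorder=0)
        fig.colorbar(sc, ax=ax_, label="normalized score", shrink=0.7)
    fig.tight_layout()
    if path is not None:
        stem = Path(path)
        if stem.suffix:
            stem = stem.with_suffix("")
        fig.savefig(stem.with_suffix(".png"), dpi=150, metadata={"Software": None})
        fig.savefig(stem.with_suffix(".svg"), metadata={"Date": None})
    return fig
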