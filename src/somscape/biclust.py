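"""Hierarchical bi-clustering of genes and samples with heatmap export.

Two independent agglomerative hierarchies (sharing the implementation in
:mod:`somscape.hclust`) are built on the rows (genes) and columns (samples)
of the expression matrix; the matrix is reordered by both dendrograms'
leaf orders and can be exported as a heatmap with a symmetric diverging
colour scale about 0 log2FC, so values are comparable across samples
(unlike the per-sample-scaled SOM portraits).  Column clustering can be
disabled to keep the experimental sample order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from somscape.hclust import MergeTree, cut_k, linkage_tree, pairwise_distance


@dataclass
class BiclusterResult:
    row_tree: MergeTree
    col_tree: MergeTree | None
    row_order: list[str]
    col_order: list[str]
    matrix: pd.DataFrame  # reordered expression matrix


def _leaf_order(tree: MergeTree) -> list[str]:
    leaves = sch.leaves_list(tree.linkage_matrix)
    return [tree.item_ids[i] for i in leaves]


def bicluster(
    expr: pd.DataFrame,
    row_metric: str = "euclidean",
    col_metric: str = "euclidean",
    linkage: str = "complete",
    cluster_columns: bool = True,
) -> BiclusterResult:
    """Independent agglomerative trees on genes and samples, matrix reordered."""
    if expr.shape[0] < 2 or expr.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    row_tree = linkage_tree(pairwise_distance(expr.T, row_metric), linkage)
    row_order = _leaf_order(row_tree)
    if cluster_columns:
        col_tree = linkage_tree(pairwise_distance(expr, col_metric), linkage)
        col_order = _leaf_order(col_tree)
    else:
        col_tree = None
        col_order = [str(c) for c in expr.columns]
    return BiclusterResult(
        row_tree, col_tree, row_order, col_order, expr.loc[row_order, col_order]
    )


def cut_rows(result: BiclusterResult, n_clusters: int = 5) -> pd.Series:
    """Flat row labels from cutting the gene tree into ``n_clusters`` clusters.

    When tied merge heights make the exact count unattainable the nearest
    attainable count is returned with a warning.
    """
    if n_clusters > len(result.row_order):
        raise ValueError("n_clusters exceeds the number of rows")
    part = cut_k(result.row_tree, n_clusters)
    return part.labels


def save_heatmap(result: BiclusterResult, path: str | Path,
                 row_labels: pd.Series | None = None) -> None:
    """PNG heatmap of the reordered matrix, diverging scale symmetric about 0."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = result.matrix.to_numpy(dtype=float)
    lim = float(np.abs(mat).max()) or 1.0
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(mat, cmap="RdBu_r", vmin=-lim, vmax=lim, aspect="auto")
    ax.set_xticks(range(len(result.col_order)))
    ax.set_xticklabels(result.col_order, rotation=90, fontsize=4)
    ax.set_yticks([])
    if row_labels is not None:
        # draw separators between consecutive row clusters
        lab = row_labels.loc[result.row_order].to_numpy()
        breaks = np.flatnonzero(lab[1:] != lab[:-1]) + 0.5
        for b in breaks:
            ax.axhline(b, color="black", lw=0.4)
    fig.colorbar(im, ax=ax, label="log2FC")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
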