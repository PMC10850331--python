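"""Sample-dimension agglomerative clustering, lifetime cuts and validation.

Nine variants -- {euclidean, cosine, pearson} distances x {single, average,
complete} linkage -- are clustered, each dendrogram is cut with the lifetime
criterion (the cut goes through the largest gap between consecutive merge
heights), partitions are scored with the Silhouette coefficient and the
Calinski-Harabasz index, and one partition is selected.  PCA scores and
Newick export round out the sample-level view.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import calinski_harabasz_score, silhouette_score

METRICS = ("euclidean", "cosine", "pearson")
LINKAGES = ("single", "average", "complete")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances between items (samples)."""

    values: np.ndarray  # condensed form (pdist layout)
    item_ids: list[str]
    metric: str

    def square(self) -> np.ndarray:
        return squareform(self.values)


@dataclass
class MergeTree:
    """Agglomerative merge structure (scipy linkage layout)."""

    linkage_matrix: np.ndarray  # (n-1, 4): idx_a, idx_b, height, new_size
    item_ids: list[str]
    metric: str
    linkage: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


@dataclass
class Partition:
    """Flat cluster labelling of items."""

    labels: pd.Series  # item id -> integer cluster id (1-based)
    k: int
    source: tuple[str, str] | str

    def members(self, cluster: int) -> list[str]:
        return self.labels.index[self.labels == cluster].tolist()


@dataclass
class ValidationScores:
    silhouette: float | None
    calinski_harabasz: float | None

    @property
    def defined(self) -> bool:
        return self.silhouette is not None


@dataclass
class VariantResult:
    metric: str
    linkage: str
    tree: MergeTree
    partition: Partition
    scores: ValidationScores
    selected: bool = False


def pairwise_distance(matrix: pd.DataFrame, metric: str) -> DistanceMatrix:
    """Pairwise distances between columns (samples) of a gene x sample matrix.

    ``pearson`` is 1 - Pearson correlation, ``cosine`` is 1 - cosine
    similarity; both require non-constant / non-zero sample vectors.
    """
    x = matrix.to_numpy(dtype=float).T
    ids = [str(c) for c in matrix.columns]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 items")
    if metric == "euclidean":
        d = pdist(x, metric="euclidean")
    elif metric == "cosine":
        norms = np.linalg.norm(x, axis=1)
        if (norms == 0).any():
            bad = [ids[i] for i in np.flatnonzero(norms == 0)]
            raise ValueError(f"zero vectors under cosine distance: {bad}")
        d = pdist(x, metric="cosine")
    elif metric == "pearson":
        sd = x.std(axis=1)
        if (sd == 0).any():
            bad = [ids[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant vectors under pearson distance: {bad}")
        d = pdist(x, metric="correlation")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(np.clip(d, 0.0, None), ids, metric)


def linkage_tree(dist: DistanceMatrix, method: str) -> MergeTree:
    """Agglomerative merge tree with the given linkage rule."""
    if method not in LINKAGES:
        raise ValueError(f"unknown linkage {method!r}")
    z = sch.linkage(dist.values, method=method)
    return MergeTree(z, list(dist.item_ids), dist.metric, method)


def lifetime_cut(tree: MergeTree) -> Partition:
    """Cut the dendrogram inside the largest gap between merge heights.

    With sorted heights d_1 <= ... <= d_(n-1), the partition whose lifetime
    (gap d_(i+1) - d_i) is largest is returned, giving k = n - i clusters.
    When there is no internal gap (two items, or all merges at one height)
    the 1-cluster solution is returned.
    """
    heights = np.sort(tree.heights)
    n = len(tree.item_ids)
    gaps = np.diff(heights)
    if gaps.size == 0 or np.max(gaps) <= 0:
        labels = pd.Series(1, index=pd.Index(tree.item_ids), name="cluster")
        return Partition(labels, 1, (tree.metric, tree.linkage))
    i = int(np.argmax(gaps))  # first largest gap: between heights[i] and heights[i+1]
    threshold = 0.5 * (heights[i] + heights[i + 1])
    raw = sch.fcluster(tree.linkage_matrix, t=threshold, criterion="distance")
    labels = pd.Series(raw, index=pd.Index(tree.item_ids), name="cluster")
    return Partition(labels, int(labels.nunique()), (tree.metric, tree.linkage))


def cut_k(tree: MergeTree, k: int) -> Partition:
    """Cut the dendrogram into (at most) ``k`` clusters."""
    raw = sch.fcluster(tree.linkage_matrix, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=pd.Index(tree.item_ids), name="cluster")
    got = int(labels.nunique())
    if got != k:
        warnings.warn(f"requested {k} clusters, tied heights give {got}", stacklevel=2)
    return Partition(labels, got, (tree.metric, tree.linkage))


def validate_partition(
    matrix: pd.DataFrame, partition: Partition, metric: str = "euclidean"
) -> ValidationScores:
    """Silhouette (under the partition's own metric) and Calinski-Harabasz.

    Undefined (None, None) when k is outside [2, n-1]; such partitions are
    excluded from variant selection.
    """
    x = matrix.to_numpy(dtype=float).T
    labels = partition.labels.loc[[str(c) for c in matrix.columns]].to_numpy()
    n = x.shape[0]
    if not 2 <= partition.k <= n - 1:
        return ValidationScores(None, None)
    dist = pairwise_distance(matrix, metric)
    sil = float(silhouette_score(dist.square(), labels, metric="precomputed"))
    ch = float(calinski_harabasz_score(x, labels))
    return ValidationScores(sil, ch)


def run_all_variants(matrix: pd.DataFrame) -> list[VariantResult]:
    """Cluster with all 9 metric x linkage variants and mark one as selected.

    Selection: among variants with defined validation scores, if one
    partition is best on both Silhouette and Calinski-Harabasz it wins;
    otherwise the minimum rank-sum over the two indices wins, ties broken by
    higher silhouette, then by variant order.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    results: list[VariantResult] = []
    for metric in METRICS:
        dist = pairwise_distance(matrix, metric)
        for method in LINKAGES:
            tree = linkage_tree(dist, method)
            part = lifetime_cut(tree)
            scores = validate_partition(matrix, part, metric)
            results.append(VariantResult(metric, method, tree, part, scores))
    scored = [r for r in results if r.scores.defined]
    if scored:
        sil = np.array([r.scores.silhouette for r in scored])
        ch = np.array([r.scores.calinski_harabasz for r in scored])
        scored[rank_sum_select(sil, ch)].selected = True
    return results


def rank_sum_select(silhouettes: np.ndarray, ch_scores: np.ndarray) -> int:
    """Index of the partition winning on both indices, else minimum rank-sum.

    Ranks are averaged on ties; rank-sum ties are broken by higher
    silhouette, then by input order.
    """
    silhouettes = np.asarray(silhouettes, dtype=float)
    ch_scores = np.asarray(ch_scores, dtype=float)
    if int(np.argmax(silhouettes)) != int(np.argmax(ch_scores)):
        logging.getLogger("somscape.hclust").info(
            "validation indices disagree; using rank-sum selection"
        )
    sil_rank = pd.Series(-silhouettes).rank(method="average").to_numpy()
    ch_rank = pd.Series(-ch_scores).rank(method="average").to_numpy()
    ranksum = sil_rank + ch_rank
    return min(range(len(silhouettes)),
               key=lambda i: (ranksum[i], -silhouettes[i], i))


def selected_variant(results: list[VariantResult]) -> VariantResult:
    for r in results:
        if r.selected:
            return r
    raise ValueError("no variant selected (all partitions degenerate)")


def variant_report(results: list[VariantResult]) -> pd.DataFrame:
    """One row per variant: metric, linkage, k, silhouette, CH, selected."""
    return pd.DataFrame(
        [
            {
                "metric": r.metric,
                "linkage": r.linkage,
                "k": r.partition.k,
                "silhouette": r.scores.silhouette,
                "calinski_harabasz": r.scores.calinski_harabasz,
                "selected": r.selected,
            }
            for r in results
        ]
    )


def pca_scores(expr: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples from the gene-centred expression matrix.

    Returns (sample x component score table, per-component variance
    fractions).  The input rows are already centred across samples, so the
    sample x gene matrix is column-centred by construction and the scores
    come straight from its SVD; no scaling is applied.
    """
    x = expr.to_numpy(dtype=float).T
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    frac = s**2 / np.sum(s**2) if np.sum(s**2) > 0 else np.zeros_like(s)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=expr.columns, columns=cols), frac


def _quote_label(label: str) -> str:
    if any(c in label for c in "(),:;'\" \t\n[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def tree_to_newick(tree: MergeTree, labels: list[str] | None = None) -> str:
    """Newick text for a merge tree; leaf heights 0, internal node heights = merge heights."""
    labels = labels if labels is not None else tree.item_ids
    root = sch.to_tree(tree.linkage_matrix)

    def rec(node, parent_height: float) -> str:
        if node.is_leaf():
            return f"{_quote_label(labels[node.id])}:{parent_height:.10g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{parent_height - node.dist:.10g}"

    left = rec(root.left, root.dist)
    right = rec(root.right, root.dist)
    return f"({left},{right});"
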