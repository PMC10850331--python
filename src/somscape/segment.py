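"""K-means segmentation of the SOM grid, gene selection and efficiency markers.

The metagene grid is partitioned into k (default 20) clusters labelled
A, B, ... by K-means on the node profiles.  Clusters whose mean profile
never leaves the +-1 log2FC band are flagged non-significant (the nearly
invariant parts of the grid); the genes of the significant clusters form an
unsupervised feature selection whose adequacy is checked by re-running the
sample dendrogram on the selected genes only.  The cluster whose profile is
most anti-correlated with replicate differentiation efficiency at late time
points yields candidate efficiency-marker genes, ranked by peak log2FC.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from somscape.hclust import (
    MergeTree,
    lifetime_cut,
    linkage_tree,
    pairwise_distance,
    run_all_variants,
    selected_variant,
)
from somscape.som import MetageneGrid, SOMModel


@dataclass
class GridSegmentation:
    """Flat K-means labelling of SOM nodes with per-cluster mean profiles."""

    node_labels: pd.Series  # flat node index -> cluster letter ('' for empty nodes)
    k: int
    cluster_profiles: pd.DataFrame  # cluster letter x sample mean metagene profile
    significant: pd.Series  # cluster letter -> bool

    @property
    def labels_used(self) -> list[str]:
        return list(self.cluster_profiles.index)

    def nodes_of(self, label: str) -> np.ndarray:
        return self.node_labels.index[self.node_labels == label].to_numpy()


def _letters(n: int) -> list[str]:
    if n <= 26:
        return list(string.ascii_uppercase[:n])
    return [
        string.ascii_uppercase[i // 26 - 1] + string.ascii_uppercase[i % 26]
        if i >= 26 else string.ascii_uppercase[i]
        for i in range(n)
    ]


def kmeans_grid(grid: MetageneGrid, k: int = 20, seed: int = 0) -> GridSegmentation:
    """K-means on occupied node metagene profiles; labels A.. by descending size.

    Standard euclidean K-means with k-means++ seeding and 10 restarts (best
    inertia kept); grid contiguity of the clusters is emergent, never
    enforced.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    occ = grid.occupancy.reshape(-1)
    occupied = np.flatnonzero(occ > 0)
    if k > occupied.size:
        raise ValueError(f"k={k} exceeds the {occupied.size} occupied nodes")
    profiles = grid.values.reshape(-1, grid.values.shape[2])[occupied]
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    raw = km.fit_predict(profiles)
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    letters = _letters(len(order))
    rename = {c: letters[i] for i, c in enumerate(order)}
    labels = pd.Series("", index=pd.RangeIndex(occ.size, name="node"), dtype=object)
    labels.iloc[occupied] = [rename[c] for c in raw]
    cluster_profiles = pd.DataFrame(
        [profiles[raw == c].mean(axis=0) for c in order],
        index=pd.Index(letters[: len(order)], name="cluster"),
        columns=grid.sample_ids,
    )
    significant = pd.Series(True, index=cluster_profiles.index, name="significant")
    return GridSegmentation(labels, len(order), cluster_profiles, significant)


def significance_filter(
    seg: GridSegmentation, min_peak_abs_logfc: float = 1.0
) -> GridSegmentation:
    """Flag clusters whose mean profile never reaches the log2FC threshold.

    A cluster is significant iff max over samples of |mean profile| is at
    least ``min_peak_abs_logfc`` (default 1.0, a two-fold change).
    """
    peaks = seg.cluster_profiles.abs().max(axis=1)
    significant = peaks >= min_peak_abs_logfc
    return GridSegmentation(seg.node_labels, seg.k, seg.cluster_profiles,
                            significant.rename("significant"))


def genes_of_cluster(model: SOMModel, seg: GridSegmentation, label: str) -> list[str]:
    nodes = set(seg.nodes_of(label).tolist())
    mask = model.assignment.isin(nodes)
    return model.assignment.index[mask].tolist()


def select_genes(model: SOMModel, seg: GridSegmentation) -> list[str]:
    """Union of genes assigned to nodes of significant clusters."""
    keep_labels = seg.significant.index[seg.significant].tolist()
    nodes: set[int] = set()
    for lab in keep_labels:
        nodes.update(seg.nodes_of(lab).tolist())
    selected = model.assignment.index[model.assignment.isin(nodes)].tolist()
    if not selected:
        raise ValueError("no genes selected: no cluster passes the significance filter")
    return selected


@dataclass
class HierarchyComparison:
    ari: float
    cophenetic_r: float
    full_k: int
    selected_k: int
    variant: tuple[str, str]


def reconstruct_hierarchy(
    expr_full: pd.DataFrame,
    expr_selected: pd.DataFrame,
    variant: tuple[str, str] | None = None,
) -> HierarchyComparison:
    """Compare sample dendrograms from the full vs the selected gene set.

    Re-clusters both matrices with the same (metric, linkage) variant -- the
    selected variant of the full matrix when not given -- and reports the
    adjusted Rand index between the two lifetime-cut partitions plus the
    Pearson correlation between the trees' cophenetic distances.
    """
    if list(expr_full.columns) != list(expr_selected.columns):
        raise ValueError("matrices must share samples in the same order")
    if variant is None:
        res = run_all_variants(expr_full)
        sel = selected_variant(res)
        variant = (sel.metric, sel.linkage)
        tree_full = sel.tree
        part_full = sel.partition
    else:
        tree_full = linkage_tree(pairwise_distance(expr_full, variant[0]), variant[1])
        part_full = lifetime_cut(tree_full)
    tree_sel = linkage_tree(pairwise_distance(expr_selected, variant[0]), variant[1])
    part_sel = lifetime_cut(tree_sel)
    samples = [str(c) for c in expr_full.columns]
    ari = float(adjusted_rand_score(
        part_full.labels.loc[samples], part_sel.labels.loc[samples]
    ))
    r = float(np.corrcoef(_cophenetic(tree_full), _cophenetic(tree_sel))[0, 1])
    return HierarchyComparison(ari, r, part_full.k, part_sel.k, variant)


def _cophenetic(tree: MergeTree) -> np.ndarray:
    return cophenet(tree.linkage_matrix)


@dataclass
class MarkerReport:
    """Candidate efficiency markers from the most efficiency-anticorrelated cluster."""

    cluster: str
    correlation: float
    genes: pd.DataFrame  # ranked: gene_id, peak_logfc, peak_sample, peak_protocol, peak_day
    trajectories: pd.DataFrame  # gene x sample Delta-e for the ranked genes

    @property
    def top_genes(self) -> list[str]:
        return self.genes.index.tolist()


def efficiency_markers(
    expr: pd.DataFrame,
    model: SOMModel,
    seg: GridSegmentation,
    metadata: pd.DataFrame,
    top_k: int = 10,
    onset_day: int = 7,
) -> MarkerReport:
    """Extract candidate markers of low differentiation efficiency.

    Among significant clusters, picks the one whose mean profile correlates
    most negatively with replicate efficiency across samples from
    ``onset_day`` onward, then ranks that cluster's genes by peak Delta-e
    over all samples (ties broken by gene id) and returns the ``top_k``
    with their expression trajectories.
    """
    meta = metadata.set_index("sample_id")
    if "efficiency" not in meta.columns or meta["efficiency"].dropna().empty:
        raise ValueError("metadata carries no efficiency values")
    late = meta.index[(meta["day"] >= onset_day) & meta["efficiency"].notna()]
    late = [s for s in late if s in expr.columns]
    eff = meta.loc[late, "efficiency"].to_numpy(dtype=float)
    if len(late) < 3 or np.std(eff) < 1e-9:
        raise ValueError("efficiency is constant or too few late samples to correlate")
    sig_labels = seg.significant.index[seg.significant]
    if len(sig_labels) == 0:
        raise ValueError("no significant clusters")
    cors = {}
    for lab in sig_labels:
        profile = seg.cluster_profiles.loc[lab, late].to_numpy(dtype=float)
        if np.std(profile) < 1e-12:
            continue
        r = float(pearsonr(profile, eff)[0])
        if np.isfinite(r):
            cors[lab] = r
    if not cors:
        raise ValueError("no significant cluster varies across late samples")
    best = min(cors, key=lambda lab: (cors[lab], lab))
    members = genes_of_cluster(model, seg, best)
    sub = expr.loc[members]
    peak = sub.max(axis=1)
    peak_sample = sub.idxmax(axis=1)
    ranked = pd.DataFrame({"peak_logfc": peak, "peak_sample": peak_sample})
    ranked = ranked.loc[
        sorted(ranked.index, key=lambda g: (-ranked.loc[g, "peak_logfc"], g))
    ].head(top_k)
    ranked["peak_protocol"] = meta.reindex(ranked["peak_sample"])["protocol"].to_numpy()
    ranked["peak_day"] = meta.reindex(ranked["peak_sample"])["day"].to_numpy()
    ranked.index.name = "gene_id"
    return MarkerReport(best, cors[best], ranked, expr.loc[ranked.index])
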