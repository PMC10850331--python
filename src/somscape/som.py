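"""Self-organising-map metagene grids and expression portraits.

Genes (rows of the centred log2FC matrix) are presented one at a time to a
square grid of nodes; the euclidean-nearest node and its gaussian
neighbourhood move toward the gene, with learning rate and neighbourhood
radius decaying over training.  After the last epoch every gene is assigned
to its nearest node and each occupied node's weight vector is replaced by
the mean profile of its genes -- the *metagene*.  A *portrait* renders one
sample's metagene values on the grid, min-max scaled to that sample's own
range and coloured blue -> green -> yellow -> red.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from somscape.preprocess import average_replicates


@dataclass
class SOMConfig:
    """Training configuration for the square SOM grid.

    Defaults follow the study configuration: a 40x40 grid (about one order
    of magnitude fewer nodes than genes) trained for 3 epochs.  The learning
    rate decays linearly 0.5 -> 0.05 and the gaussian neighbourhood radius
    grid_side/2 -> 1 over all training steps.
    """

    grid_side: int = 40
    epochs: int = 3
    seed: int = 0
    initial_rate: float = 0.5
    final_rate: float = 0.05
    initial_radius: float | None = None  # defaults to grid_side / 2
    final_radius: float = 1.0
    init_jitter: float = 0.05

    def __post_init__(self) -> None:
        if self.grid_side < 1 or self.epochs < 1:
            raise ValueError("grid_side and epochs must be positive")
        if not (0 < self.final_rate <= self.initial_rate <= 1):
            raise ValueError("rates must satisfy 0 < final <= initial <= 1")
        if self.initial_radius is None:
            self.initial_radius = self.grid_side / 2.0

    @property
    def n_nodes(self) -> int:
        return self.grid_side**2


@dataclass
class SOMModel:
    """Trained SOM: node weights over samples plus the gene -> node map."""

    weights: np.ndarray  # (n_nodes, n_samples)
    assignment: pd.Series  # gene id -> flat node index
    sample_ids: list[str]
    config: SOMConfig
    training_log: list[float] = field(default_factory=list)  # per-epoch quantization error

    def node_xy(self, node: int) -> tuple[int, int]:
        """1-based (column, row) grid coordinates of a flat node index."""
        side = self.config.grid_side
        return node % side + 1, node // side + 1

    def gene_positions(self) -> pd.DataFrame:
        """Gene -> 1-based grid (x, y) table."""
        xy = np.array([self.node_xy(n) for n in self.assignment.to_numpy()])
        return pd.DataFrame(
            {"node": self.assignment.to_numpy(), "x": xy[:, 0], "y": xy[:, 1]},
            index=self.assignment.index,
        )

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cfg = {k: getattr(self.config, k) for k in (
            "grid_side", "epochs", "seed", "initial_rate", "final_rate",
            "initial_radius", "final_radius", "init_jitter")}
        cfg["training_log"] = self.training_log
        (outdir / "som_config.json").write_text(json.dumps(cfg))
        pd.DataFrame(self.weights, columns=self.sample_ids).to_csv(
            outdir / "som_weights.tsv", sep="\t", index_label="node"
        )
        self.gene_positions().to_csv(outdir / "gene_positions.tsv", sep="\t",
                                     index_label="gene_id")


def _grid_coords(side: int) -> np.ndarray:
    yy, xx = np.divmod(np.arange(side * side), side)
    return np.column_stack([xx, yy]).astype(float)


def train_som(expr: pd.DataFrame, config: SOMConfig | None = None) -> SOMModel:
    """Train the SOM on genes (rows) of a centred expression matrix.

    Online training: each epoch presents every gene once in a seeded random
    order; the winner (euclidean-nearest node) and its gaussian
    neighbourhood are pulled toward the gene.  Nodes are initialised at
    randomly chosen genes plus small gaussian jitter.  After training, every
    gene is assigned to its nearest node and occupied nodes take the mean of
    their genes.  Deterministic for a fixed seed.
    """
    config = config or SOMConfig()
    x = expr.to_numpy(dtype=float)
    if x.size == 0:
        raise ValueError("empty expression matrix")
    if not np.isfinite(x).all():
        raise ValueError("expression matrix contains non-finite values")
    n_genes, n_samples = x.shape
    n_nodes = config.n_nodes
    if n_genes < n_nodes / 10:
        warnings.warn(
            f"{n_genes} genes for {n_nodes} nodes; the grid should have about "
            "an order of magnitude fewer nodes than genes", stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    w = x[rng.integers(0, n_genes, size=n_nodes)] + rng.normal(
        0.0, config.init_jitter, size=(n_nodes, n_samples)
    )
    coords = _grid_coords(config.grid_side)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)

    total_steps = config.epochs * n_genes
    log: list[float] = []
    step = 0
    for _ in range(config.epochs):
        for g in rng.permutation(n_genes):
            frac = step / max(total_steps - 1, 1)
            rate = config.initial_rate + frac * (config.final_rate - config.initial_rate)
            radius = config.initial_radius + frac * (config.final_radius - config.initial_radius)
            diff = x[g] - w
            winner = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
            h = rate * np.exp(-grid_d2[winner] / (2.0 * radius * radius))
            w += h[:, None] * diff
            step += 1
        log.append(_quantization_error(x, w))

    d2 = (
        (x**2).sum(1)[:, None] - 2.0 * x @ w.T + (w**2).sum(1)[None, :]
    )
    assign = np.argmin(d2, axis=1)
    for node in np.unique(assign):
        w[node] = x[assign == node].mean(axis=0)
    assignment = pd.Series(assign, index=expr.index, name="node")
    return SOMModel(w, assignment, [str(c) for c in expr.columns], config, log)


def _quantization_error(x: np.ndarray, w: np.ndarray) -> float:
    d2 = (x**2).sum(1)[:, None] - 2.0 * x @ w.T + (w**2).sum(1)[None, :]
    return float(np.mean(np.sqrt(np.clip(d2.min(axis=1), 0.0, None))))


@dataclass
class MetageneGrid:
    """Per-node metagene profiles with occupancy and quality statistics."""

    values: np.ndarray  # (grid_side, grid_side, n_samples)
    sample_ids: list[str]
    occupancy: np.ndarray  # (grid_side, grid_side) gene counts
    quality: pd.DataFrame  # node, variance, entropy, mean_gene_correlation

    @property
    def grid_side(self) -> int:
        return self.values.shape[0]

    def sample_matrix(self, sample_id: str) -> np.ndarray:
        return self.values[:, :, self.sample_ids.index(sample_id)]


def _profile_entropy(profile: np.ndarray, bins: int = 10) -> float:
    """Shannon entropy (bits) of the profile discretised into equal-width bins."""
    lo, hi = profile.min(), profile.max()
    if hi - lo == 0:
        return 0.0
    counts, _ = np.histogram(profile, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / profile.size
    return float(-(p * np.log2(p)).sum())


def metagene_grid(model: SOMModel, expr: pd.DataFrame, entropy_bins: int = 10) -> MetageneGrid:
    """Metagene profiles per node, with occupancy and quality statistics.

    Occupied nodes carry the mean profile of their genes; empty nodes keep
    the trained weights so portraits have no gaps.  Quality per node: the
    metagene's variance across samples, its Shannon entropy over
    ``entropy_bins`` equal-width bins, and the mean Pearson correlation
    between member genes and the metagene (NaN for empty nodes).
    """
    side = model.config.grid_side
    x = expr.to_numpy(dtype=float)
    vals = model.weights.copy()
    occ = np.zeros(model.config.n_nodes, dtype=int)
    corr = np.full(model.config.n_nodes, np.nan)
    assign = model.assignment.loc[expr.index].to_numpy()
    for node in np.unique(assign):
        members = x[assign == node]
        vals[node] = members.mean(axis=0)
        occ[node] = members.shape[0]
        mg = vals[node]
        sd = mg.std()
        if sd == 0:
            corr[node] = np.nan
            continue
        msd = members.std(axis=1)
        ok = msd > 0
        if ok.any():
            c = ((members[ok] - members[ok].mean(1, keepdims=True)) @ (mg - mg.mean())) / (
                msd[ok] * sd * mg.size
            )
            corr[node] = float(np.mean(c))
    quality = pd.DataFrame(
        {
            "node": np.arange(model.config.n_nodes),
            "occupancy": occ,
            "variance": vals.var(axis=1),
            "entropy": [_profile_entropy(v, entropy_bins) for v in vals],
            "mean_gene_correlation": corr,
        }
    )
    return MetageneGrid(
        vals.reshape(side, side, -1),
        list(model.sample_ids),
        occ.reshape(side, side),
        quality,
    )


@dataclass
class Portrait:
    """One sample's metagene grid, min-max scaled to that sample's range."""

    sample_id: str
    matrix: np.ndarray  # (grid_side, grid_side) in [0, 1]
    raw_min: float
    raw_max: float


def render_portrait(grid: MetageneGrid, sample_id: str) -> Portrait:
    """Scale one sample's metagene values to [0, 1] (its own min/max)."""
    raw = grid.sample_matrix(sample_id)
    lo, hi = float(raw.min()), float(raw.max())
    if hi - lo == 0:
        warnings.warn(f"constant metagene grid for {sample_id}; flat portrait",
                      stacklevel=2)
        return Portrait(sample_id, np.full_like(raw, 0.5, dtype=float), lo, hi)
    return Portrait(sample_id, (raw - lo) / (hi - lo), lo, hi)


def portrait_colormap():
    """Blue -> green -> yellow -> red, low to high expression."""
    from matplotlib.colors import LinearSegmentedColormap

    return LinearSegmentedColormap.from_list(
        "portrait", ["#00008b", "#2166ac", "#1a9850", "#ffffbf", "#fdae61", "#d73027"]
    )


def save_portrait(portrait: Portrait, outdir: str | Path) -> None:
    """Write the portrait as PNG (coloured) plus a numeric TSV."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(portrait.matrix).to_csv(
        outdir / f"portrait_{portrait.sample_id}.tsv", sep="\t", header=False, index=False
    )
    fig, ax = plt.subplots(figsize=(3, 3))
    ax.imshow(portrait.matrix, cmap=portrait_colormap(), origin="lower",
              vmin=0.0, vmax=1.0)
    ax.set_title(portrait.sample_id, fontsize=9)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(outdir / f"portrait_{portrait.sample_id}.png", dpi=120,
                bbox_inches="tight")
    plt.close(fig)


def condition_portraits(
    model: SOMModel, expr: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[dict[str, Portrait], dict[str, Portrait]]:
    """Portraits for replicate-mean conditions and for individual samples."""
    cond_expr = average_replicates(expr, metadata)
    mean_grid = metagene_grid(model, expr)
    # project condition means through the same gene -> node assignment
    cond_grid = _regrid(model, cond_expr)
    means = {c: render_portrait(cond_grid, c) for c in cond_grid.sample_ids}
    singles = {s: render_portrait(mean_grid, s) for s in mean_grid.sample_ids}
    return means, singles


def _regrid(model: SOMModel, expr: pd.DataFrame) -> MetageneGrid:
    """Metagene grid for a matrix with the model's genes but other columns."""
    side = model.config.grid_side
    x = expr.to_numpy(dtype=float)
    assign = model.assignment.loc[expr.index].to_numpy()
    vals = np.zeros((model.config.n_nodes, x.shape[1]))
    occ = np.zeros(model.config.n_nodes, dtype=int)
    for node in np.unique(assign):
        members = x[assign == node]
        vals[node] = members.mean(axis=0)
        occ[node] = members.shape[0]
    quality = pd.DataFrame({"node": np.arange(model.config.n_nodes), "occupancy": occ})
    return MetageneGrid(
        vals.reshape(side, side, -1), [str(c) for c in expr.columns],
        occ.reshape(side, side), quality,
    )
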