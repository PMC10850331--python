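"""Pipeline orchestration: config schema, per-stage seeds, report bundle."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

import somscape
from somscape import biclust, enrich, hclust, preprocess, segment, simulate, som

log = logging.getLogger("somscape")


class PreprocessParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_count: int = 10
    prior_count: float = 3.0


class SOMParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    grid_side: int = 40
    epochs: int = 3
    initial_rate: float = 0.5
    final_rate: float = 0.05
    final_radius: float = 1.0


class SegmentParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k: int = 20
    min_peak_abs_logfc: float = 1.0
    marker_top_k: int = 10
    marker_onset_day: int = 7


class BiclustParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_row_clusters: int = 5
    cluster_columns: bool = True


class PipelineConfig(BaseModel):
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    counts: str
    metadata: str
    outdir: str
    gmt: str | None = None
    seed: int = 0
    preprocess: PreprocessParams = Field(default_factory=PreprocessParams)
    som: SOMParams = Field(default_factory=SOMParams)
    segment: SegmentParams = Field(default_factory=SegmentParams)
    biclust: BiclustParams = Field(default_factory=BiclustParams)
    write_portraits: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2**31)."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute preprocess -> hclust(+PCA) -> som -> segment -> [enrich] -> biclust.

    Writes stage artifacts plus a manifest (versions, seeds, input hashes)
    and a summary JSON under ``config.outdir`` and returns the summary.
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_path, meta_path = Path(config.counts), Path(config.metadata)
    try:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        metadata = pd.read_csv(meta_path, sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("input", f"cannot read inputs: {exc}") from exc
    for col in ("sample_id", "protocol", "day", "replicate"):
        if col not in metadata.columns:
            raise PipelineError("input", f"metadata misses column {col!r}")

    def _stage(name, fn):
        t = time.time()
        try:
            out = fn()
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(name, str(exc)) from exc
        log.info("stage=%s elapsed=%.1fs", name, time.time() - t)
        return out

    # --- preprocess ---
    def _pre():
        expr, norm = preprocess.preprocess_counts(
            counts, metadata, config.preprocess.min_count, config.preprocess.prior_count
        )
        expr.to_csv(outdir / "expr_logfc.tsv", sep="\t")
        (outdir / "normalization.json").write_text(json.dumps({
            "tmm_factors": norm.tmm_factors.round(6).to_dict(),
            "reference_sample": norm.reference_sample,
            "kept_genes": int(expr.shape[0]),
        }))
        return expr

    expr = _stage("preprocess", _pre)
    cond_expr = preprocess.average_replicates(expr, metadata)

    # --- hierarchical clustering + PCA ---
    def _hc():
        results = hclust.run_all_variants(cond_expr)
        report = hclust.variant_report(results)
        report.to_json(outdir / "hclust_report.json", orient="records", indent=1)
        for r in results:
            name = f"tree_{r.metric}_{r.linkage}.nwk"
            (outdir / name).write_text(hclust.tree_to_newick(r.tree))
        sel = hclust.selected_variant(results)
        sel.partition.labels.to_csv(outdir / "partition_selected.tsv", sep="\t")
        scores, frac = hclust.pca_scores(cond_expr)
        scores.iloc[:, :4].to_csv(outdir / "pca_scores.tsv", sep="\t")
        return results, sel, frac

    hc_results, hc_selected, pca_frac = _stage("hclust", _hc)

    # --- SOM ---
    def _som():
        cfg = som.SOMConfig(
            grid_side=config.som.grid_side, epochs=config.som.epochs,
            seed=stage_seed(config.seed, "som"),
            initial_rate=config.som.initial_rate, final_rate=config.som.final_rate,
            final_radius=config.som.final_radius,
        )
        model = som.train_som(expr, cfg)
        model.save(outdir)
        grid = som.metagene_grid(model, expr)
        if config.write_portraits:
            means, singles = som.condition_portraits(model, expr, metadata)
            for p in list(means.values()) + list(singles.values()):
                som.save_portrait(p, outdir / "portraits")
        return model, grid

    model, grid = _stage("som", _som)

    # --- segmentation / markers ---
    def _seg():
        seg = segment.kmeans_grid(grid, config.segment.k,
                                  seed=stage_seed(config.seed, "kmeans"))
        seg = segment.significance_filter(seg, config.segment.min_peak_abs_logfc)
        side = grid.grid_side
        node_tbl = pd.DataFrame({
            "node": np.arange(side * side),
            "x": np.arange(side * side) % side + 1,
            "y": np.arange(side * side) // side + 1,
            "cluster": seg.node_labels.to_numpy(),
        })
        node_tbl["significant"] = [
            bool(seg.significant.get(c, False)) for c in node_tbl["cluster"]
        ]
        node_tbl.to_csv(outdir / "segmentation.tsv", sep="\t", index=False)
        seg.cluster_profiles.to_csv(outdir / "cluster_profiles.tsv", sep="\t")
        selected_genes = segment.select_genes(model, seg)
        cond_sel = cond_expr.loc[selected_genes]
        comparison = segment.reconstruct_hierarchy(
            cond_expr, cond_sel, variant=(hc_selected.metric, hc_selected.linkage)
        )
        marker = None
        has_eff = "efficiency" in metadata.columns and metadata["efficiency"].notna().any()
        if has_eff:
            try:
                marker = segment.efficiency_markers(
                    expr, model, seg, metadata,
                    top_k=config.segment.marker_top_k,
                    onset_day=config.segment.marker_onset_day,
                )
                marker.genes.to_csv(outdir / "marker_genes.tsv", sep="\t")
                marker.trajectories.to_csv(outdir / "marker_trajectories.tsv", sep="\t")
            except ValueError as exc:
                log.warning("efficiency markers unavailable: %s", exc)
        return seg, selected_genes, comparison, marker

    seg, selected_genes, comparison, marker = _stage("segment", _seg)

    # --- enrichment (optional) ---
    enrich_rows = None
    if config.gmt:
        def _enr():
            collection = enrich.read_gmt(config.gmt)
            universe = expr.index.tolist()
            tables = {}
            for lab in seg.significant.index[seg.significant]:
                genes = segment.genes_of_cluster(model, seg, lab)
                tab = enrich.overrepresentation(genes, collection, universe)
                tab.insert(0, "cluster", lab)
                tables[lab] = tab
            all_tab = pd.concat(tables.values(), ignore_index=True)
            all_tab.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            return int(len(all_tab))

        enrich_rows = _stage("enrich", _enr)

    # --- biclustering ---
    def _bic():
        sel_expr = cond_expr.loc[selected_genes]
        res = biclust.bicluster(sel_expr,
                                cluster_columns=config.biclust.cluster_columns)
        labels = biclust.cut_rows(res, min(config.biclust.n_row_clusters,
                                           len(selected_genes)))
        res.matrix.to_csv(outdir / "bicluster_matrix.tsv", sep="\t")
        labels.to_csv(outdir / "bicluster_row_labels.tsv", sep="\t")
        (outdir / "bicluster_rows.nwk").write_text(
            hclust.tree_to_newick(res.row_tree))
        if res.col_tree is not None:
            (outdir / "bicluster_cols.nwk").write_text(
                hclust.tree_to_newick(res.col_tree))
        biclust.save_heatmap(res, outdir / "bicluster_heatmap.png", labels)
        return res, labels

    _bic_res, _bic_labels = _stage("biclust", _bic)

    summary = {
        "n_samples": int(counts.shape[1]),
        "n_genes_raw": int(counts.shape[0]),
        "n_genes_kept": int(expr.shape[0]),
        "n_conditions": int(cond_expr.shape[1]),
        "n_hc_variants": len(hc_results),
        "selected_variant": {"metric": hc_selected.metric,
                             "linkage": hc_selected.linkage,
                             "k": hc_selected.partition.k},
        "pca_top2_variance_fraction": float(np.sum(pca_frac[:2])),
        "som": {"grid_side": config.som.grid_side, "epochs": config.som.epochs,
                "quantization_error": model.training_log},
        "n_grid_clusters": seg.k,
        "cluster_labels": seg.labels_used,
        "n_significant_clusters": int(seg.significant.sum()),
        "n_selected_genes": len(selected_genes),
        "reconstruction_ari": comparison.ari,
        "reconstruction_cophenetic_r": comparison.cophenetic_r,
        "marker_cluster": marker.cluster if marker else None,
        "marker_genes": marker.top_genes if marker else None,
        "enrichment_rows": enrich_rows,
        "seed": config.seed,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    manifest = {
        "somscape_version": somscape.__version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in ("som", "kmeans")},
        "inputs": {
            "counts": {"path": str(counts_path), "sha256": _sha256(counts_path)},
            "metadata": {"path": str(meta_path), "sha256": _sha256(meta_path)},
        },
        "elapsed_s": round(time.time() - t0, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return summary


class PipelineError(RuntimeError):
    """A stage failure with a machine-readable stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
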