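"""End-to-end pipeline: preprocessing -> specificity -> prioritization -> enrichment.

``run_pipeline`` drives the whole workflow from a :class:`RunConfig`,
writing every stage's output as delimited text plus a YAML manifest that
records versions, seeds and parameters — the manifest alone suffices to
reproduce a run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .containers import METRIC_NAMES, ESMu
from .enrichment import GeneSet, geneset_enrichment
from .metrics import DEFAULT_CONFIG, MetricConfig
from .preprocess import filter_sporadic_genes, map_orthologs, normalize_and_log
from .prioritize import (
    GeneLevelStats,
    all_genes_annotation,
    annotation_size,
    build_snp_annotation,
    prioritize_cell_types,
    results_to_frame,
)
from .specificity import compute_es_mu

logger = logging.getLogger("cellspec")

__all__ = ["RunConfig", "run_pipeline", "specificity_stage"]


@dataclass
class RunConfig:
    """Inputs and parameters of an end-to-end run."""

    # inputs
    expression_path: str | None = None        # delimited text, genes x cells
    expression_mtx: tuple[str, str, str] | None = None  # (mtx, genes, cells)
    annotation_path: str | None = None
    ortholog_map_path: str | None = None
    gene_stats_path: str | None = None        # gene_id, z [, covariates]
    gene_coords_path: str | None = None
    gene_coords_format: str = "bed"
    variants_path: str | None = None          # BIM
    geneset_path: str | None = None
    # parameters
    scale: float = 10_000.0
    anova_alpha: float = 1e-5
    skip_sporadic_filter: bool = False
    metrics: tuple[str, ...] = METRIC_NAMES
    n_null: int = 1000
    alpha: float = 0.05
    seed: int = 0
    pooled_null: bool = True
    metric_config: MetricConfig = field(default_factory=lambda: DEFAULT_CONFIG)
    window_bp: int = 100_000
    use_covariates: bool = False
    condition_on: tuple[str, ...] = ()
    out_dir: str = "cellspec_out"
    trait: str = "trait"
    dataset: str = "dataset"

    def validate(self) -> None:
        if self.expression_path is None and self.expression_mtx is None:
            raise ValueError("an expression input (text or MatrixMarket) is required")
        if self.annotation_path is None:
            raise ValueError("a cell-type annotation table is required")
        paths = [self.expression_path, self.annotation_path, self.ortholog_map_path,
                 self.gene_stats_path, self.gene_coords_path, self.variants_path,
                 self.geneset_path]
        if self.expression_mtx:
            paths.extend(self.expression_mtx)
        for p in paths:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def read_gene_stats(path: str) -> GeneLevelStats:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GeneLevelStats(df)


def specificity_stage(cfg: RunConfig) -> tuple[ESMu, dict, dict]:
    """Preprocess the expression input and compute ES_mu (stages 1-2)."""
    if cfg.expression_mtx:
        matrix = io.read_expression_mtx(*cfg.expression_mtx)
    else:
        matrix = io.read_expression_text(cfg.expression_path)
    annot = io.read_annotation(cfg.annotation_path)
    missing = matrix.cell_ids.difference(annot.mapping.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} matrix cells missing from the annotation, e.g. "
            f"{missing[:5].tolist()}"
        )
    logger.info("loaded %d genes x %d cells", matrix.n_genes, matrix.n_cells)

    matrix = normalize_and_log(matrix, scale=cfg.scale)
    if not cfg.skip_sporadic_filter:
        keep = filter_sporadic_genes(matrix, annot, alpha=cfg.anova_alpha)
        logger.info("sporadic-gene filter kept %d / %d genes", len(keep), matrix.n_genes)
        matrix = matrix.subset_genes(keep)
    if cfg.ortholog_map_path:
        omap = io.read_ortholog_map(cfg.ortholog_map_path)
        matrix = map_orthologs(matrix, omap)
        logger.info("ortholog mapping kept %d genes", matrix.n_genes)

    esmu, starred, gene_sets = compute_es_mu(
        matrix, annot,
        metrics=cfg.metrics, n_null=cfg.n_null, alpha=cfg.alpha,
        seed=cfg.seed, pooled=cfg.pooled_null, cfg=cfg.metric_config,
    )
    return esmu, starred, gene_sets


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every configured stage; returns the output directory."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    esmu, starred, _ = specificity_stage(cfg)
    io.write_es_matrix(esmu, out / "es_mu.tsv")
    for m, df in starred.items():
        io.write_es_matrix(df, out / f"es_wstar_{m}.tsv")
    logger.info("wrote ES matrices for %d cell types", len(esmu.cell_types))

    manifest: dict = {
        "cellspec_version": __version__,
        "trait": cfg.trait,
        "dataset": cfg.dataset,
        "seed": cfg.seed,
        "n_null": cfg.n_null,
        "alpha": cfg.alpha,
        "pooled_null": cfg.pooled_null,
        "metrics": list(cfg.metrics),
        "metric_config": cfg.metric_config.__dict__.copy(),
        "scale": cfg.scale,
        "anova_alpha": cfg.anova_alpha,
        "window_bp": cfg.window_bp,
        "use_covariates": cfg.use_covariates,
        "condition_on": list(cfg.condition_on),
        "n_genes_scored": len(esmu.gene_ids),
        "cell_types": esmu.cell_types,
    }

    if cfg.gene_stats_path:
        stats = read_gene_stats(cfg.gene_stats_path)
        results = prioritize_cell_types(
            esmu, stats,
            use_covariates=cfg.use_covariates, alpha=cfg.alpha,
            condition_on=list(cfg.condition_on) or None,
        )
        frame = results_to_frame(results)
        frame.insert(0, "dataset", cfg.dataset)
        frame.insert(0, "trait", cfg.trait)
        frame.to_csv(out / "prioritization.tsv", sep="\t", index=False)
        logger.info("prioritization: top cell type %s (p=%.3g)",
                    results[0].cell_type, results[0].p_one_sided)

    if cfg.gene_coords_path and cfg.variants_path:
        genes = io.read_gene_coordinates(cfg.gene_coords_path, fmt=cfg.gene_coords_format)
        variants = io.read_variants_bim(cfg.variants_path)
        sizes = {}
        for ct in esmu.cell_types:
            ann = build_snp_annotation(esmu.values[ct], genes, variants, cfg.window_bp)
            tbl = variants.assign(value=ann.to_numpy())
            tbl.to_csv(out / f"annotation.{ct}.tsv", sep="\t", index=False)
            sizes[ct] = annotation_size(ann)
        all_ann = all_genes_annotation(genes, variants, cfg.window_bp)
        variants.assign(value=all_ann.to_numpy()).to_csv(
            out / "annotation.all_genes.tsv", sep="\t", index=False
        )
        sizes["all_genes"] = annotation_size(all_ann)
        manifest["annotation_sizes"] = {k: float(v) for k, v in sizes.items()}
        logger.info("wrote %d annotation files", len(sizes))

    if cfg.geneset_path:
        genes_in_set = io.read_geneset(cfg.geneset_path)
        gs = GeneSet(Path(cfg.geneset_path).stem, tuple(genes_in_set))
        enr = geneset_enrichment(esmu, gs, alpha=cfg.alpha)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        logger.info("geneset enrichment: top cell type %s", enr.iloc[0]["cell_type"])

    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out
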