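"""From raw metric weights to significant gene sets, ES_w* and ES_mu.

The pipeline per metric is:

1. *Empirical significance.* For each cell type, the observed ES_w of every
   gene is compared with "null" weights obtained by re-scoring the metric
   after shuffling the cell-type label vector (sampling the annotations
   without replacement). The one-sided empirical p-value uses the add-one
   estimator; genes with p < alpha form the significant set Gs.
2. *Rank normalization.* Within each cell type, genes in Gs receive
   rank(ES_w)/|Gs| (rank 1 = smallest weight in Gs, so the strongest gene
   scores 1); genes outside Gs score exactly 0.
3. *Combination.* ES_mu is the arithmetic mean of ES_w* across the metrics.

Null weights are, by default, pooled across genes within a (metric, cell
type) pair, which sharpens p-value resolution from 1/n_null to
1/(n_null * n_genes); per-gene nulls are available with ``pooled=False``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .containers import (
    METRIC_NAMES,
    CellTypeAnnotation,
    ESMu,
    ESWeights,
    ExpressionMatrix,
    SignificantGeneSets,
)
from .metrics import DEFAULT_CONFIG, MetricConfig, group_stats, metric_from_stats

__all__ = [
    "empirical_significance",
    "rank_normalize",
    "combine_es_mu",
    "es_gene_set",
    "compute_es_mu",
]

_PERM_BATCH = 50  # label shuffles scored per matmul batch


def _gene_sets_from_p(pdf: pd.DataFrame, alpha: float, adjust: str) -> dict[str, frozenset]:
    """Gs per cell type from empirical p-values, raw or BH-adjusted."""
    if adjust == "none":
        sig = pdf < alpha
    elif adjust == "bh":
        adj = pdf.apply(lambda col: scipy.stats.false_discovery_control(col, method="bh"))
        sig = adj < alpha
    else:
        raise ValueError(f"unknown adjustment {adjust!r}; use 'none' or 'bh'")
    return {ct: frozenset(pdf.index[sig[ct].to_numpy()]) for ct in pdf.columns}


def _null_counts(
    metrics: tuple[str, ...],
    values: np.ndarray,
    codes: np.ndarray,
    cell_types: list[str],
    observed: dict[str, np.ndarray],
    n_null: int,
    rng: np.random.Generator,
    cfg: MetricConfig,
    pooled: bool,
) -> dict[str, np.ndarray]:
    """#{null ES_w >= observed} per gene and cell type, for each metric.

    One global label shuffle per null draw; all metrics (and all cell types)
    are re-scored from the same shuffle, so the null draws are shared across
    metrics and the expensive group sums are computed once per shuffle.
    """
    n_genes = values.shape[0]
    n_types = len(cell_types)
    counts = {m: np.zeros((n_genes, n_types), dtype=np.int64) for m in metrics}
    # pooled mode compares each observed weight against every null weight of
    # the same cell type: count "null < obs" via a sort per batch
    obs_sorted = {m: np.sort(observed[m], axis=0) for m in metrics} if pooled else None
    if pooled:
        less = {m: np.zeros((n_genes, n_types), dtype=np.int64) for m in metrics}

    done = 0
    while done < n_null:
        batch = min(_PERM_BATCH, n_null - done)
        null_w = {m: np.empty((n_genes, n_types, batch)) for m in metrics}
        for b in range(batch):
            perm = rng.permutation(codes)
            stats = group_stats(values, perm, cell_types)
            for m in metrics:
                null_w[m][:, :, b] = metric_from_stats(m, stats, cfg)
        for m in metrics:
            if pooled:
                for c in range(n_types):
                    pool = np.sort(null_w[m][:, c, :], axis=None)
                    # nulls strictly below each observed value; complement gives >=
                    less[m][:, c] += np.searchsorted(pool, observed[m][:, c], side="left")
            else:
                counts[m] += (null_w[m] >= observed[m][:, :, None]).sum(axis=2)
        done += batch

    if pooled:
        total = n_null * n_genes
        for m in metrics:
            counts[m] = total - less[m]
    return counts


def empirical_significance(
    weights: ESWeights,
    matrix: ExpressionMatrix,
    annot: CellTypeAnnotation,
    n_null: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    pooled: bool = True,
    cfg: MetricConfig = DEFAULT_CONFIG,
    adjust: str = "none",
) -> SignificantGeneSets:
    """Permutation test of each ES_w against label-shuffled null weights.

    p = (1 + #{null >= observed}) / (1 + total null draws per gene); with
    pooling the total is ``n_null * n_genes``, otherwise ``n_null``. Gs per
    cell type is {g : p_g < alpha}, optionally after Benjamini-Hochberg
    adjustment (``adjust="bh"``). Deterministic given ``seed``.
    """
    if n_null < 20:
        raise ValueError("n_null < 20 gives too coarse a p-value resolution")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    codes, cell_types = annot.codes_for(matrix.cell_ids)
    if list(weights.weights.columns) != cell_types:
        raise ValueError("weights cell types do not match the annotation")
    if not weights.weights.index.equals(matrix.gene_ids):
        raise ValueError("weights genes do not match the matrix")
    rng = np.random.default_rng(seed)
    observed = {weights.metric: weights.weights.to_numpy()}
    counts = _null_counts(
        (weights.metric,), matrix.values, codes, cell_types, observed,
        n_null, rng, cfg, pooled,
    )[weights.metric]
    total = n_null * (matrix.n_genes if pooled else 1)
    pvals = (1.0 + counts) / (1.0 + total)
    pdf = pd.DataFrame(pvals, index=matrix.gene_ids, columns=cell_types)
    return SignificantGeneSets(
        weights.metric, pdf, alpha, gene_sets=_gene_sets_from_p(pdf, alpha, adjust)
    )


def rank_normalize(weights: ESWeights, gsets: SignificantGeneSets) -> pd.DataFrame:
    """ES_w*: rank(ES_w)/|Gs| within Gs (ties get average rank), 0 outside."""
    if gsets.metric != weights.metric:
        raise ValueError(f"gene sets are for {gsets.metric}, weights for {weights.metric}")
    out = pd.DataFrame(
        0.0, index=weights.weights.index, columns=weights.weights.columns
    )
    for ct in weights.weights.columns:
        members = sorted(gsets.gene_sets.get(ct, frozenset()))
        if not members:
            continue
        w = weights.weights.loc[members, ct].to_numpy()
        ranks = scipy.stats.rankdata(w, method="average")
        out.loc[members, ct] = ranks / len(members)
    return out


def combine_es_mu(normalized: list[pd.DataFrame], metrics: tuple[str, ...] = METRIC_NAMES,
                  provenance: dict | None = None) -> ESMu:
    """ES_mu = elementwise mean of the supplied ES_w* matrices."""
    if not normalized:
        raise ValueError("need at least one ES_w* matrix")
    first = normalized[0]
    for other in normalized[1:]:
        if not first.index.equals(other.index) or not first.columns.equals(other.columns):
            raise ValueError("ES_w* matrices must share gene ids and cell types")
    mean = sum(df.to_numpy() for df in normalized) / len(normalized)
    values = pd.DataFrame(mean, index=first.index, columns=first.columns)
    return ESMu(values, metrics=tuple(metrics), provenance=provenance or {})


def es_gene_set(esmu: ESMu, cell_type: str) -> list[str]:
    """ES genes of a cell type: ES_mu > 0, sorted by descending ES_mu (ties by id)."""
    if cell_type not in esmu.values.columns:
        raise KeyError(f"unknown cell type {cell_type!r}")
    col = esmu.values[cell_type]
    positive = col[col > 0]
    order = sorted(positive.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in order]


def compute_es_mu(
    matrix: ExpressionMatrix,
    annot: CellTypeAnnotation,
    metrics: tuple[str, ...] = METRIC_NAMES,
    n_null: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    pooled: bool = True,
    cfg: MetricConfig = DEFAULT_CONFIG,
    adjust: str = "none",
) -> tuple[ESMu, dict[str, pd.DataFrame], dict[str, SignificantGeneSets]]:
    """Full specificity pipeline: metrics -> Gs -> ES_w* -> ES_mu.

    Shares one set of label shuffles across all metrics, which both matches
    the single-shuffle-per-draw design and quarters the permutation cost
    relative to running ``empirical_significance`` per metric.

    Returns the combined ES_mu, the per-metric ES_w* matrices and the
    per-metric significant gene sets.
    """
    if n_null < 20:
        raise ValueError("n_null < 20 gives too coarse a p-value resolution")
    if matrix.stage != "normalized":
        raise ValueError("compute_es_mu expects a log-normalized matrix")
    codes, cell_types = annot.codes_for(matrix.cell_ids)
    if len(cell_types) < 2:
        raise ValueError("specificity needs >=2 cell types")

    stats = group_stats(matrix.values, codes, cell_types)
    observed = {m: metric_from_stats(m, stats, cfg) for m in metrics}
    rng = np.random.default_rng(seed)
    counts = _null_counts(
        tuple(metrics), matrix.values, codes, cell_types, observed,
        n_null, rng, cfg, pooled,
    )
    total = n_null * (matrix.n_genes if pooled else 1)

    starred: dict[str, pd.DataFrame] = {}
    gene_sets: dict[str, SignificantGeneSets] = {}
    for m in metrics:
        wdf = pd.DataFrame(observed[m], index=matrix.gene_ids, columns=cell_types)
        pdf = pd.DataFrame(
            (1.0 + counts[m]) / (1.0 + total), index=matrix.gene_ids, columns=cell_types
        )
        gsets = SignificantGeneSets(m, pdf, alpha, gene_sets=_gene_sets_from_p(pdf, alpha, adjust))
        gene_sets[m] = gsets
        starred[m] = rank_normalize(ESWeights(m, wdf), gsets)

    provenance = {
        "metrics": list(metrics),
        "n_null": n_null,
        "alpha": alpha,
        "seed": seed,
        "pooled": pooled,
        "adjust": adjust,
        "metric_config": cfg.__dict__.copy(),
    }
    esmu = combine_es_mu([starred[m] for m in metrics], tuple(metrics), provenance)
    return esmu, starred, gene_sets
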