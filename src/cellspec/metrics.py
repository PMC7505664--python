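"""The four per-gene, per-cell-type expression-specificity metrics.

Each metric produces a non-negative weight matrix ES_w (genes x cell types)
from a log-normalized expression matrix and a cell-type annotation:

* EP  (expression proportion)      mu_gc / sum_c' mu_gc'
* GES (gene enrichment score)      fold change of detection fraction times
                                   fold change of mean, each with a
                                   pseudo-count, cell type vs all other cells
* NSI (normalized specificity index)  average rank of the gene's mean-ratio
                                   against every other cell type, rescaled so
                                   the most specific gene scores 1
* DET (differential-expression t)  Welch t-statistic, cell type vs the rest,
                                   negative values floored at 0

All four are pure functions of the per-cell-type sufficient statistics
(count, sum, sum of squares, detection count per gene), which is what makes
the permutation null cheap: a label shuffle only changes the group sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .containers import CellTypeAnnotation, ESWeights, ExpressionMatrix

__all__ = [
    "MetricConfig",
    "GroupStats",
    "group_stats",
    "expression_proportion",
    "gene_enrichment_score",
    "normalized_specificity_index",
    "det_statistic",
    "compute_metric",
    "metric_from_stats",
]


@dataclass(frozen=True)
class MetricConfig:
    """Numerical constants of the metrics.

    ges_pseudo_frac / ges_pseudo_mean
        Pseudo-counts added to the detection fraction and the mean in GES.
    nsi_eps
        Stabilizer added to numerator and denominator of NSI mean ratios.
    det_var_floor
        Floor on the pooled Welch variance term, guarding the all-constant case.
    """

    ges_pseudo_frac: float = 0.1
    ges_pseudo_mean: float = 0.01
    nsi_eps: float = 1e-9
    det_var_floor: float = 1e-12


DEFAULT_CONFIG = MetricConfig()


@dataclass
class GroupStats:
    """Per-cell-type sufficient statistics (each array is genes x cell types)."""

    n: np.ndarray        # (C,) cells per type
    sums: np.ndarray     # (G, C) sum of values
    sumsq: np.ndarray    # (G, C) sum of squared values
    nnz: np.ndarray      # (G, C) number of cells with value > 0
    cell_types: list[str]

    @property
    def mean(self) -> np.ndarray:
        return self.sums / self.n

    @property
    def frac(self) -> np.ndarray:
        return self.nnz / self.n


def group_stats(values: np.ndarray, codes: np.ndarray, cell_types: list[str]) -> GroupStats:
    """Sufficient statistics per cell type from integer label codes."""
    n_types = len(cell_types)
    onehot = np.zeros((values.shape[1], n_types))
    onehot[np.arange(values.shape[1]), codes] = 1.0
    n = onehot.sum(axis=0)
    if np.any(n == 0):
        empty = [cell_types[i] for i in np.flatnonzero(n == 0)]
        raise ValueError(f"cell types with no cells: {empty}")
    return GroupStats(
        n=n,
        sums=values @ onehot,
        sumsq=(values**2) @ onehot,
        nnz=(values > 0).astype(np.float64) @ onehot,
        cell_types=cell_types,
    )


def _ep_from_stats(stats: GroupStats, cfg: MetricConfig) -> np.ndarray:
    mu = stats.mean
    total = mu.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        ep = np.where(total > 0, mu / np.where(total > 0, total, 1.0), 0.0)
    return ep


def _ges_from_stats(stats: GroupStats, cfg: MetricConfig) -> np.ndarray:
    n_tot = stats.n.sum()
    mu = stats.mean
    frac = stats.frac
    # "rest" statistics: all cells outside the focal type
    n_rest = n_tot - stats.n
    mu_rest = (stats.sums.sum(axis=1, keepdims=True) - stats.sums) / n_rest
    frac_rest = (stats.nnz.sum(axis=1, keepdims=True) - stats.nnz) / n_rest
    kf, km = cfg.ges_pseudo_frac, cfg.ges_pseudo_mean
    return ((frac + kf) / (frac_rest + kf)) * ((mu + km) / (mu_rest + km))


def _nsi_from_stats(stats: GroupStats, cfg: MetricConfig) -> np.ndarray:
    mu = stats.mean
    n_genes, n_types = mu.shape
    if n_types < 3:
        raise ValueError("NSI requires >=3 cell types")
    eps = cfg.nsi_eps
    # ratio[g, c, c'] = (mu_gc + eps) / (mu_gc' + eps) for c' != c
    si = np.zeros((n_genes, n_types))
    for c in range(n_types):
        others = [c2 for c2 in range(n_types) if c2 != c]
        ratios = (mu[:, [c]] + eps) / (mu[:, others] + eps)
        # rank 1 = largest ratio (most specific), averaged over comparator types
        ranks = scipy.stats.rankdata(-ratios, axis=0, method="average")
        si[:, c] = ranks.mean(axis=1)
    if n_genes == 1:
        return np.ones_like(si)
    return 1.0 - (si - 1.0) / (n_genes - 1.0)


def _det_from_stats(stats: GroupStats, cfg: MetricConfig) -> np.ndarray:
    n1 = stats.n
    if np.any(n1 < 2):
        small = [stats.cell_types[i] for i in np.flatnonzero(n1 < 2)]
        raise ValueError(f"DET requires >=2 cells per cell type; too few in: {small}")
    sum_tot = stats.sums.sum(axis=1, keepdims=True)
    sumsq_tot = stats.sumsq.sum(axis=1, keepdims=True)
    n2 = stats.n.sum() - n1
    mean1 = stats.mean
    mean2 = (sum_tot - stats.sums) / n2
    var1 = np.maximum(stats.sumsq - n1 * mean1**2, 0.0) / (n1 - 1)
    var2 = np.maximum((sumsq_tot - stats.sumsq) - n2 * mean2**2, 0.0) / (n2 - 1)
    denom = np.sqrt(np.maximum(var1 / n1 + var2 / n2, cfg.det_var_floor))
    t = (mean1 - mean2) / denom
    return np.maximum(t, 0.0)


_METRIC_FNS = {
    "EP": _ep_from_stats,
    "GES": _ges_from_stats,
    "NSI": _nsi_from_stats,
    "DET": _det_from_stats,
}

_MIN_TYPES = {"EP": 2, "GES": 2, "NSI": 3, "DET": 2}


def metric_from_stats(metric: str, stats: GroupStats, cfg: MetricConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Evaluate a metric on precomputed group statistics (array result)."""
    return _METRIC_FNS[metric](stats, cfg)


def compute_metric(
    metric: str,
    matrix: ExpressionMatrix,
    annot: CellTypeAnnotation,
    cfg: MetricConfig = DEFAULT_CONFIG,
) -> ESWeights:
    """Compute one ES_w matrix on a normalized expression matrix."""
    if matrix.stage != "normalized":
        raise ValueError("specificity metrics expect a log-normalized matrix")
    codes, cell_types = annot.codes_for(matrix.cell_ids)
    if len(cell_types) < _MIN_TYPES[metric]:
        raise ValueError(
            f"{metric} requires >={_MIN_TYPES[metric]} cell types, got {len(cell_types)}"
        )
    stats = group_stats(matrix.values, codes, cell_types)
    weights = metric_from_stats(metric, stats, cfg)
    return ESWeights(metric, pd.DataFrame(weights, index=matrix.gene_ids, columns=cell_types))


def expression_proportion(matrix, annot, cfg: MetricConfig = DEFAULT_CONFIG) -> ESWeights:
    """EP_gc = mu_gc / sum_c' mu_gc'; all-zero genes score 0 everywhere."""
    return compute_metric("EP", matrix, annot, cfg)


def gene_enrichment_score(matrix, annot, cfg: MetricConfig = DEFAULT_CONFIG) -> ESWeights:
    """Detection-fraction fold change times mean fold change vs all other cells."""
    return compute_metric("GES", matrix, annot, cfg)


def normalized_specificity_index(matrix, annot, cfg: MetricConfig = DEFAULT_CONFIG) -> ESWeights:
    """Average pairwise mean-ratio rank, rescaled to [0, 1] (1 = most specific)."""
    return compute_metric("NSI", matrix, annot, cfg)


def det_statistic(matrix, annot, cfg: MetricConfig = DEFAULT_CONFIG) -> ESWeights:
    """Welch t of the cell type vs all other cells, floored at 0."""
    return compute_metric("DET", matrix, annot, cfg)
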