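"""Expression preprocessing: library-size normalization, sporadic-gene
filtering and 1-1 ortholog mapping.

The pipeline mirrors standard single-cell practice: each cell is scaled to a
common transcript count (default 10,000) and log(x+1)-transformed; genes
whose expression does not vary systematically across cell types ("sporadic"
genes) are removed with a one-way ANOVA across the cell-type grouping; and,
for cross-species work, genes are optionally renamed through a user-supplied
ortholog table keeping only one-to-one pairs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .containers import CellTypeAnnotation, ExpressionMatrix

__all__ = ["normalize_and_log", "filter_sporadic_genes", "map_orthologs"]


def normalize_and_log(matrix: ExpressionMatrix, scale: float = 10_000.0) -> ExpressionMatrix:
    """Scale each cell to a common transcript count, then log(x+1).

    Parameters
    ----------
    matrix
        Raw count matrix; every cell must have a positive total count.
    scale
        Common transcript count each cell is scaled to before the log.
    """
    if matrix.stage != "raw":
        raise ValueError("matrix is already normalized; normalize_and_log expects raw counts")
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = matrix.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cells with zero total count cannot be normalized: "
            f"{matrix.cell_ids[zero][:5].tolist()}"
        )
    values = np.log1p(matrix.values / totals * scale)
    return ExpressionMatrix(values, matrix.gene_ids, matrix.cell_ids, stage="normalized")


def filter_sporadic_genes(
    matrix: ExpressionMatrix,
    annot: CellTypeAnnotation,
    alpha: float = 1e-5,
) -> list[str]:
    """Genes retained by the one-way ANOVA across cell types (p <= alpha).

    Genes with no variance at all (identical in every cell) have an undefined
    F statistic and are excluded. Cell types with fewer than two cells are
    dropped from the test with a warning.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    labels = annot.labels_for(matrix.cell_ids)
    groups = []
    for label in sorted(pd.unique(labels)):
        cols = matrix.values[:, labels == label]
        if cols.shape[1] < 2:
            warnings.warn(
                f"cell type {label!r} has <2 cells and is dropped from the ANOVA filter"
            )
            continue
        groups.append(cols)
    if len(groups) < 2:
        raise ValueError("ANOVA filter needs >=2 cell types with >=2 cells each")
    with warnings.catch_warnings():
        # constant genes yield F = nan with a degenerate-data warning; they are excluded below
        warnings.simplefilter("ignore")
        _, pvals = scipy.stats.f_oneway(*groups, axis=1)
    keep = np.nan_to_num(pvals, nan=1.0) <= alpha
    return matrix.gene_ids[keep].tolist()


def map_orthologs(matrix: ExpressionMatrix, omap: pd.DataFrame) -> ExpressionMatrix:
    """Rename genes through a source->target ortholog table, keeping 1-1 pairs.

    Pairs whose source or target id occurs more than once in the table are
    discarded entirely; matrix genes without a (surviving) mapping are
    dropped. Rows of the result are sorted by target id.
    """
    omap = omap.drop_duplicates()
    one_to_one = omap[
        ~omap["source"].duplicated(keep=False) & ~omap["target"].duplicated(keep=False)
    ]
    mapping = dict(zip(one_to_one["source"], one_to_one["target"]))
    pairs = sorted(
        ((mapping[g], g) for g in matrix.gene_ids if g in mapping),
    )
    if not pairs:
        raise ValueError("no matrix genes have a 1-1 ortholog mapping")
    targets = [t for t, _ in pairs]
    sources = [s for _, s in pairs]
    idx = matrix.gene_ids.get_indexer(sources)
    return ExpressionMatrix(
        matrix.values[idx, :], pd.Index(targets), matrix.cell_ids, matrix.stage
    )
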