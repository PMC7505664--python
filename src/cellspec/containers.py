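"""Core in-memory containers for expression data and specificity scores.

The package works on three kinds of objects: a gene-by-cell expression
matrix (raw counts or log-normalized values), a per-cell cell-type
annotation, and gene-by-cell-type specificity score matrices (raw per-metric
weights ES_w, rank-normalized ES_w* in [0, 1], and the combined ES_mu).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CellTypeAnnotation",
    "ESWeights",
    "SignificantGeneSets",
    "ESMu",
    "METRIC_NAMES",
]

METRIC_NAMES = ("EP", "GES", "NSI", "DET")


@dataclass
class ExpressionMatrix:
    """Gene-by-cell expression matrix.

    Parameters
    ----------
    values
        Dense non-negative ``(n_genes, n_cells)`` array. Raw counts when
        ``stage == "raw"``, log-normalized values when ``stage == "normalized"``.
    gene_ids, cell_ids
        Unique identifiers for the rows and columns.
    stage
        ``"raw"`` or ``"normalized"``.
    """

    values: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-dimensional")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not self.gene_ids.is_unique:
            raise ValueError("gene_ids must be unique")
        if not self.cell_ids.is_unique:
            raise ValueError("cell_ids must be unique")
        if self.stage not in ("raw", "normalized"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = self.gene_ids.get_indexer(gene_ids)
        if np.any(idx < 0):
            missing = [g for g, i in zip(gene_ids, idx) if i < 0]
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        return ExpressionMatrix(
            self.values[idx, :], pd.Index(gene_ids), self.cell_ids, self.stage
        )


@dataclass
class CellTypeAnnotation:
    """Mapping of each cell id to exactly one cell-type label."""

    mapping: pd.Series  # index: cell_id, values: cell-type label (str)

    def __post_init__(self) -> None:
        self.mapping = pd.Series(self.mapping).astype(str)
        if not self.mapping.index.is_unique:
            dup = self.mapping.index[self.mapping.index.duplicated()][:5].tolist()
            raise ValueError(f"duplicate cell ids in annotation: {dup}")

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.mapping.unique())

    def labels_for(self, cell_ids: pd.Index) -> np.ndarray:
        """Labels aligned to ``cell_ids``; every cell must be annotated."""
        missing = pd.Index(cell_ids).difference(self.mapping.index)
        if len(missing):
            raise KeyError(
                f"{len(missing)} cells missing from annotation, e.g. "
                f"{missing[:5].tolist()}"
            )
        return self.mapping.reindex(cell_ids).to_numpy()

    def codes_for(self, cell_ids: pd.Index) -> tuple[np.ndarray, list[str]]:
        """Integer codes aligned to ``cell_ids`` plus the sorted label list."""
        labels = self.labels_for(cell_ids)
        cats = sorted(pd.unique(labels))
        code_map = {c: i for i, c in enumerate(cats)}
        return np.array([code_map[l] for l in labels], dtype=np.intp), cats


@dataclass
class ESWeights:
    """Raw per-metric specificity weights ES_w (genes x cell types)."""

    metric: str
    weights: pd.DataFrame  # index: gene ids, columns: cell-type labels

    def __post_init__(self) -> None:
        if self.metric not in METRIC_NAMES:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {METRIC_NAMES}")
        if not np.all(np.isfinite(self.weights.to_numpy())):
            raise ValueError(f"{self.metric} weights contain non-finite values")


@dataclass
class SignificantGeneSets:
    """Per-cell-type significant gene sets Gs with empirical p-values."""

    metric: str
    pvalues: pd.DataFrame  # genes x cell types, empirical p in (0, 1]
    alpha: float
    gene_sets: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_sets:
            sig = self.pvalues < self.alpha
            self.gene_sets = {
                ct: frozenset(self.pvalues.index[sig[ct].to_numpy()])
                for ct in self.pvalues.columns
            }


@dataclass
class ESMu:
    """Combined specificity scores ES_mu in [0, 1] (genes x cell types)."""

    values: pd.DataFrame
    metrics: tuple[str, ...] = METRIC_NAMES
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise ValueError("ES_mu values must lie in [0, 1]")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    def es_gene_counts(self) -> pd.Series:
        """Number of ES genes (ES_mu > 0) per cell type."""
        return (self.values > 0).sum(axis=0)
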