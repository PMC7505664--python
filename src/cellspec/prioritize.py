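"""Genetic prioritization of cell types from gene-level GWAS statistics.

For each cell type, gene-level association Z-statistics are regressed on the
cell type's ES_mu scores (ordinary least squares, optionally with technical
covariates: gene size, gene density, inverse mean minor allele count and
their logs). Only a positive ES_mu coefficient counts as enrichment, so the
reported p-value is the one-sided upper tail of the coefficient's
t-distribution. Conditional analysis adds other cell types' ES_mu columns as
covariates to ask whether a signal survives adjustment for a correlated cell
type.

The module also builds per-variant continuous annotations from ES_mu by
assigning each variant the maximum ES_mu among genes whose transcribed
region (plus a symmetric window, default 100 kb) covers the variant — the
file format consumed by partitioned-heritability tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from intervaltree import IntervalTree

from .containers import ESMu

__all__ = [
    "GeneLevelStats",
    "PrioritizationResult",
    "COVARIATE_COLUMNS",
    "prioritize_cell_types",
    "conditional_prioritization",
    "build_snp_annotation",
    "all_genes_annotation",
    "annotation_size",
    "results_to_frame",
]

COVARIATE_COLUMNS = (
    "gene_size",
    "gene_density",
    "inv_mean_mac",
    "log_gene_size",
    "log_gene_density",
    "log_inv_mean_mac",
)

_MIN_SHARED_GENES = 30


@dataclass
class GeneLevelStats:
    """Per-gene association Z-statistics with optional technical covariates."""

    table: pd.DataFrame  # index: gene_id; column "z"; optional covariate columns

    def __post_init__(self) -> None:
        if "z" not in self.table.columns:
            raise ValueError("gene-level statistics need a 'z' column")
        if not self.table.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not np.all(np.isfinite(self.table["z"].to_numpy())):
            raise ValueError("z statistics must be finite")
        present = [c for c in COVARIATE_COLUMNS if c in self.table.columns]
        if present and not np.all(np.isfinite(self.table[present].to_numpy())):
            raise ValueError("covariates must be finite where present")

    @property
    def covariates(self) -> list[str]:
        return [c for c in COVARIATE_COLUMNS if c in self.table.columns]


@dataclass
class PrioritizationResult:
    """One cell type's regression outcome."""

    cell_type: str
    beta: float
    se: float
    p_one_sided: float
    n_genes: int
    bonferroni_significant: bool
    degenerate: bool = False
    conditioned_on: tuple[str, ...] = ()


def _one_sided_fit(
    y: np.ndarray, focal: np.ndarray, covars: np.ndarray | None
) -> tuple[float, float, float, bool]:
    """OLS of y on [intercept, focal, covars]; returns (beta, se, p, degenerate).

    Degenerate when the focal column carries no variation beyond the other
    regressors (constant, or collinear with the conditioning set).
    """
    n = len(y)
    others = np.ones((n, 1))
    if covars is not None and covars.size:
        others = np.column_stack([others, covars])
    # residual variation of the focal column given the other regressors
    resid = focal - others @ np.linalg.lstsq(others, focal, rcond=None)[0]
    denom = np.dot(focal, focal)
    rel_resid = np.dot(resid, resid) / denom if denom > 0 else 0.0
    if denom == 0 or rel_resid < 1e-12:
        return 0.0, np.nan, 1.0, True
    X = np.column_stack([others, focal])
    model = sm.OLS(y, X).fit()
    beta = model.params[-1]
    se = model.bse[-1]
    tval = model.tvalues[-1]
    dof = model.df_resid
    p = scipy_t_sf(tval, dof)
    return float(beta), float(se), float(p), False


def scipy_t_sf(tval: float, dof: float) -> float:
    from scipy.stats import t as t_dist

    # one-sided upper tail; floored at machine tiny rather than reported as 0
    return float(max(t_dist.sf(tval, dof), np.finfo(float).tiny))


def _align(esmu: ESMu, stats: GeneLevelStats) -> tuple[pd.DataFrame, pd.DataFrame]:
    shared = esmu.values.index.intersection(stats.table.index)
    if len(shared) < _MIN_SHARED_GENES:
        raise ValueError(
            f"only {len(shared)} genes shared between ES_mu and gene statistics; "
            f"need >= {_MIN_SHARED_GENES}"
        )
    return esmu.values.loc[shared], stats.table.loc[shared]


def prioritize_cell_types(
    esmu: ESMu,
    stats: GeneLevelStats,
    use_covariates: bool = False,
    alpha: float = 0.05,
    condition_on: list[str] | None = None,
) -> list[PrioritizationResult]:
    """Regress gene-level Z on each cell type's ES_mu; one-sided positive test.

    Results are sorted by p-value; the Bonferroni flag divides ``alpha`` by
    the number of cell types tested. Cell types whose ES_mu column is
    constant over the shared genes (or collinear with the conditioning
    columns) are reported with p = 1 and the degeneracy flag set.
    """
    condition_on = list(condition_on or [])
    for label in condition_on:
        if label not in esmu.values.columns:
            raise KeyError(f"unknown conditioning cell type {label!r}")
    es, tab = _align(esmu, stats)
    y = tab["z"].to_numpy(dtype=np.float64)

    covar_cols: list[np.ndarray] = []
    if use_covariates:
        names = stats.covariates
        if not names:
            raise ValueError("use_covariates=True but no covariate columns present")
        covar_cols.append(tab[names].to_numpy(dtype=np.float64))
    if condition_on:
        covar_cols.append(es[condition_on].to_numpy(dtype=np.float64))
    covars = np.column_stack(covar_cols) if covar_cols else None

    cell_types = list(es.columns)
    n_tests = len(cell_types)
    results = []
    for ct in cell_types:
        focal = es[ct].to_numpy(dtype=np.float64)
        if ct in condition_on:
            beta, se, p, degenerate = 0.0, np.nan, 1.0, True
        else:
            beta, se, p, degenerate = _one_sided_fit(y, focal, covars)
        results.append(
            PrioritizationResult(
                cell_type=ct,
                beta=beta,
                se=se,
                p_one_sided=p,
                n_genes=len(y),
                bonferroni_significant=bool(p < alpha / n_tests),
                degenerate=degenerate,
                conditioned_on=tuple(condition_on),
            )
        )
    results.sort(key=lambda r: (r.p_one_sided, r.cell_type))
    return results


def conditional_prioritization(
    esmu: ESMu,
    stats: GeneLevelStats,
    condition_on: list[str],
    use_covariates: bool = False,
    alpha: float = 0.05,
) -> list[PrioritizationResult]:
    """Prioritization with the conditioning cell types' ES_mu as covariates."""
    if not condition_on:
        raise ValueError("condition_on must name at least one cell type")
    return prioritize_cell_types(
        esmu, stats, use_covariates=use_covariates, alpha=alpha, condition_on=condition_on
    )


def results_to_frame(results: list[PrioritizationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_type": [r.cell_type for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "p_one_sided": [r.p_one_sided for r in results],
            "n_genes": [r.n_genes for r in results],
            "bonferroni_significant": [r.bonferroni_significant for r in results],
            "degenerate": [r.degenerate for r in results],
            "conditioned_on": [",".join(r.conditioned_on) for r in results],
        }
    )


def _gene_window_trees(
    genes: pd.DataFrame, values: np.ndarray, window_bp: int
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in genes.assign(_v=values).groupby("chrom", sort=False):
        tree = IntervalTree()
        starts = np.maximum(sub["start"].to_numpy(np.int64) - window_bp, 1)
        ends = sub["end"].to_numpy(np.int64) + window_bp
        for s, e, v in zip(starts, ends, sub["_v"].to_numpy()):
            tree.addi(int(s), int(e) + 1, float(v))  # +1: inclusive end
        trees[str(chrom)] = tree
    return trees


def build_snp_annotation(
    esmu_column: pd.Series,
    genes: pd.DataFrame,
    variants: pd.DataFrame,
    window_bp: int = 100_000,
) -> pd.Series:
    """Per-variant annotation: max ES_mu over gene windows covering the variant.

    ``esmu_column`` is indexed by gene id; genes absent from the coordinate
    table are ignored, as are coordinate rows without an ES_mu value. A
    variant covered by no window gets 0; variants on chromosomes absent from
    the gene table annotate to 0 with a warning.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be non-negative")
    shared = genes[genes["gene_id"].isin(esmu_column.index)]
    vals = esmu_column.reindex(shared["gene_id"]).to_numpy(dtype=np.float64)
    trees = _gene_window_trees(shared, vals, window_bp)

    out = np.zeros(len(variants))
    missing_chroms = set()
    for i, (chrom, pos) in enumerate(zip(variants["chrom"].astype(str), variants["pos"])):
        tree = trees.get(chrom)
        if tree is None:
            missing_chroms.add(chrom)
            continue
        hits = tree[int(pos)]
        if hits:
            out[i] = max(h.data for h in hits)
    if missing_chroms:
        warnings.warn(
            f"variants on chromosomes absent from the gene table annotate to 0: "
            f"{sorted(missing_chroms)}"
        )
    return pd.Series(out, index=variants["variant_id"].to_numpy(), name="annotation")


def all_genes_annotation(
    genes: pd.DataFrame, variants: pd.DataFrame, window_bp: int = 100_000
) -> pd.Series:
    """Binary annotation: 1 if the variant lies in any gene window, else 0."""
    ones = pd.Series(1.0, index=pd.Index(genes["gene_id"]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ann = build_snp_annotation(ones, genes, variants, window_bp)
    return (ann > 0).astype(float)


def annotation_size(annotation: pd.Series | np.ndarray) -> float:
    """Mean of the annotation vector (proportion of variants covered, if binary)."""
    arr = np.asarray(annotation, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("annotation vector is empty")
    return float(arr.mean())
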