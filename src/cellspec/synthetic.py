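"""Synthetic data generators with the statistical structure the method assumes.

``simulate_expression`` draws a sparse overdispersed count matrix (negative
binomial, variance = mu + mu^2/theta) with planted cell-type marker genes:
each cell type receives a disjoint block of markers whose mean expression is
multiplied by a fold change in that type only. ``simulate_gene_stats`` draws
gene-level association Z-statistics that are either pure noise (null GWAS
analogue) or linearly loaded on one cell type's ES_mu. All generators are
pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CellTypeAnnotation, ESMu, ExpressionMatrix
from .prioritize import GeneLevelStats

__all__ = [
    "SimulationConfig",
    "simulate_expression",
    "simulate_gene_stats",
    "simulate_variants_and_genes",
    "make_correlated_column",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of the planted-marker expression simulator.

    Defaults are the reference desk-scale conditions used throughout the test
    suite: 5 cell types x 200 cells, 2,000 genes, 10 exclusive markers per
    type at a 20-fold mean increase, over a sparse negative-binomial baseline
    (mean 0.5 per gene per cell, dispersion theta = 2, i.e. droplet-like
    overdispersion). Per-gene baseline means are log-normally scattered
    around the configured mean so genes are heterogeneous, as in real data.
    """

    n_cell_types: int = 5
    cells_per_type: int = 200
    n_genes: int = 2000
    n_markers_per_type: int = 10
    marker_fold_change: float = 20.0
    baseline_mean: float = 0.5
    dispersion: float = 2.0
    gene_mean_sigma: float = 1.0
    seed: int = 0

    def validate(self, allow_unit_fold: bool = False) -> None:
        if min(self.n_cell_types, self.cells_per_type, self.n_genes) < 1:
            raise ValueError("counts must be positive")
        if self.n_markers_per_type < 0:
            raise ValueError("n_markers_per_type must be >= 0")
        if self.n_markers_per_type * self.n_cell_types > self.n_genes:
            raise ValueError("more planted markers than genes")
        if self.marker_fold_change <= 1 and not allow_unit_fold:
            raise ValueError("marker_fold_change must be > 1 (pass allow_unit_fold to override)")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline mean and dispersion must be positive")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    # numpy parameterization: n = theta, p = theta / (theta + mu)
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p).astype(np.float64)


def simulate_expression(
    cfg: SimulationConfig, allow_unit_fold: bool = False
) -> tuple[ExpressionMatrix, CellTypeAnnotation, pd.DataFrame]:
    """Planted-marker count matrix, annotation and marker truth table.

    The truth table has columns ``gene_id`` and ``cell_type``; with
    ``marker_fold_change == 1`` (requires ``allow_unit_fold``) it is empty.
    Bit-reproducible for a fixed config.
    """
    cfg.validate(allow_unit_fold=allow_unit_fold)
    rng = np.random.default_rng(cfg.seed)
    n_cells = cfg.n_cell_types * cfg.cells_per_type
    gene_ids = pd.Index([f"gene{i:05d}" for i in range(cfg.n_genes)])
    cell_ids = pd.Index([f"cell{i:05d}" for i in range(n_cells)])
    cell_types = [f"type{t}" for t in range(cfg.n_cell_types)]
    labels = np.repeat(cell_types, cfg.cells_per_type)

    base = cfg.baseline_mean * rng.lognormal(
        mean=-0.5 * cfg.gene_mean_sigma**2, sigma=cfg.gene_mean_sigma, size=cfg.n_genes
    )
    mean = np.tile(base[:, None], (1, n_cells))

    truth_rows = []
    planted = cfg.marker_fold_change > 1
    marker_slots = rng.permutation(cfg.n_genes)[: cfg.n_markers_per_type * cfg.n_cell_types]
    for t, ct in enumerate(cell_types):
        rows = marker_slots[t * cfg.n_markers_per_type : (t + 1) * cfg.n_markers_per_type]
        cols = labels == ct
        mean[np.ix_(rows, cols)] *= cfg.marker_fold_change
        if planted:
            for r in rows:
                truth_rows.append({"gene_id": gene_ids[r], "cell_type": ct})

    counts = _nb_draw(rng, mean, cfg.dispersion)
    matrix = ExpressionMatrix(counts, gene_ids, cell_ids, stage="raw")
    annot = CellTypeAnnotation(pd.Series(labels, index=cell_ids))
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "cell_type"])
    return matrix, annot, truth


def simulate_gene_stats(
    esmu: ESMu,
    causal_type: str | None,
    effect: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    with_covariates: bool = False,
) -> GeneLevelStats:
    """Gene-level Z-statistics, null or loaded on one cell type's ES_mu.

    ``z_g = effect * ES_mu(g, causal_type) + N(0, noise_sd^2)`` when a causal
    type is given; pure ``N(0, noise_sd^2)`` otherwise. Optional technical
    covariates (gene size, gene density, inverse mean minor allele count and
    their logs) are drawn independently of z.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if causal_type is not None and causal_type not in esmu.values.columns:
        raise KeyError(f"unknown causal cell type {causal_type!r}")
    rng = np.random.default_rng(seed)
    genes = esmu.values.index
    z = rng.normal(0.0, noise_sd, size=len(genes))
    if causal_type is not None:
        z = z + effect * esmu.values[causal_type].to_numpy()
    table = pd.DataFrame({"z": z}, index=genes)
    if with_covariates:
        size = rng.lognormal(mean=10.0, sigma=1.0, size=len(genes))  # ~ bp scale
        density = rng.uniform(0.05, 1.0, size=len(genes))
        inv_mac = rng.lognormal(mean=-8.0, sigma=0.5, size=len(genes))
        table["gene_size"] = size
        table["gene_density"] = density
        table["inv_mean_mac"] = inv_mac
        table["log_gene_size"] = np.log(size)
        table["log_gene_density"] = np.log(density)
        table["log_inv_mean_mac"] = np.log(inv_mac)
    return GeneLevelStats(table)


def simulate_variants_and_genes(
    n_genes: int,
    n_variants: int,
    chrom_length: int = 10_000_000,
    seed: int = 0,
    chrom: str = "1",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sorted, non-pathological gene coordinates and variant positions.

    Gene starts are distinct uniform draws on one chromosome; lengths are
    uniform on [1 kb, 50 kb] clipped to the chromosome end. Variant positions
    are uniform draws. Reproducible per seed.
    """
    if n_genes < 0 or n_variants < 0:
        raise ValueError("n_genes and n_variants must be >= 0")
    if n_genes > 0 and chrom_length < 10 * n_genes:
        raise ValueError("chromosome too short to place genes with distinct starts")
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.choice(np.arange(1, chrom_length, dtype=np.int64), size=n_genes, replace=False))
    lengths = rng.integers(1_000, 50_001, size=n_genes)
    ends = np.minimum(starts + lengths, chrom_length)
    genes = pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
            "chrom": chrom,
            "start": starts,
            "end": ends,
        }
    )
    pos = np.sort(rng.integers(1, chrom_length + 1, size=n_variants))
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{i:06d}" for i in range(n_variants)],
            "chrom": chrom,
            "pos": pos,
        }
    )
    return genes, variants


def make_correlated_column(
    esmu: ESMu, source_type: str, rho: float, new_label: str, seed: int = 0
) -> ESMu:
    """Append a decoy cell-type column correlated ~``rho`` with an existing one.

    The decoy is a convex mixture of the source column and a label-shuffled
    copy of it; the mixture weight is searched so the realized sample
    correlation is close to ``rho``. Values stay in [0, 1]. Used to study
    conditional analysis on correlated cell types.
    """
    if source_type not in esmu.values.columns:
        raise KeyError(f"unknown cell type {source_type!r}")
    if not 0 < rho < 1:
        raise ValueError("rho must lie in (0, 1)")
    if new_label in esmu.values.columns:
        raise ValueError(f"label {new_label!r} already present")
    rng = np.random.default_rng(seed)
    x = esmu.values[source_type].to_numpy()
    shuffled = rng.permutation(x)

    def corr(a: float) -> float:
        mix = a * x + (1 - a) * shuffled
        if mix.std() == 0 or x.std() == 0:
            return 0.0
        return float(np.corrcoef(mix, x)[0, 1])

    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = (lo + hi) / 2
        if corr(mid) < rho:
            lo = mid
        else:
            hi = mid
    a = (lo + hi) / 2
    new = esmu.values.copy()
    new[new_label] = a * x + (1 - a) * shuffled
    return ESMu(new, metrics=esmu.metrics, provenance=dict(esmu.provenance))
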