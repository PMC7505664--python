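import numpy as np
import pandas as pd
import pytest

import cellspec as cs


@pytest.fixture(scope="session")
def small_dataset():
    """3 cell types x 30 cells, 200 genes, 5 exclusive markers per type."""
    cfg = cs.SimulationConfig(
        n_cell_types=3, cells_per_type=30, n_genes=200, n_markers_per_type=5, seed=101
    )
    matrix, annot, truth = cs.simulate_expression(cfg)
    return matrix, annot, truth


@pytest.fixture(scope="session")
def small_normalized(small_dataset):
    matrix, annot, truth = small_dataset
    return cs.normalize_and_log(matrix), annot, truth


@pytest.fixture(scope="session")
def small_esmu(small_normalized):
    matrix, annot, truth = small_normalized
    esmu, starred, gene_sets = cs.compute_es_mu(matrix, annot, n_null=200, seed=7)
    return esmu, starred, gene_sets, truth


def make_matrix(values, stage="normalized", genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return cs.ExpressionMatrix(values, pd.Index(genes), pd.Index(cells), stage=stage)


def make_annotation(labels, cells=None):
    cells = cells or [f"c{i}" for i in range(len(labels))]
    return cs.CellTypeAnnotation(pd.Series(list(labels), index=cells))


@pytest.fixture
def two_type_matrix():
    """4 genes x 6 cells, two cell types (A: c0-c2, B: c3-c5), hand values."""
    values = [
        [3.0, 3.0, 3.0, 1.0, 1.0, 1.0],   # mean 3 vs 1
        [2.0, 2.0, 2.0, 0.0, 0.0, 0.0],   # exclusive to A
        [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],   # constant
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],   # absent
    ]
    return make_matrix(values), make_annotation("AAABBB")
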