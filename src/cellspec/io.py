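"""Readers and writers for the delimited-text and MatrixMarket formats.

All text readers transparently accept gzip-compressed files (by ``.gz``
suffix). Expression matrices are genes-as-rows; the MatrixMarket variant
expects a coordinate file plus one-id-per-line row (gene) and column (cell)
files, the layout produced by most single-cell quantifiers.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CellTypeAnnotation, ESMu, ExpressionMatrix

__all__ = [
    "read_expression_text",
    "read_expression_mtx",
    "write_expression_mtx",
    "read_annotation",
    "write_annotation",
    "read_ortholog_map",
    "read_gene_coordinates",
    "read_variants_bim",
    "write_variants_bim",
    "write_gene_coordinates",
    "read_geneset",
    "read_es_matrix",
    "write_es_matrix",
]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_expression_text(path: str | Path, sep: str = "\t", stage: str = "raw") -> ExpressionMatrix:
    """Read a delimited gene-by-cell matrix (header row of cell ids)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(df.to_numpy(dtype=np.float64), df.index, df.columns, stage=stage)


def read_expression_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    stage: str = "raw",
) -> ExpressionMatrix:
    """Read MatrixMarket coordinate file + row/column id files (genes x cells)."""
    with _open_text(mtx_path, "rb") as fh:
        mat = scipy.io.mmread(fh)
    genes = _read_id_list(genes_path)
    cells = _read_id_list(cells_path)
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.float64)
    return ExpressionMatrix(dense, pd.Index(genes), pd.Index(cells), stage=stage)


def write_expression_mtx(
    matrix: ExpressionMatrix,
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    sparse = scipy.sparse.coo_matrix(matrix.values)
    scipy.io.mmwrite(str(mtx_path), sparse)
    _write_id_list(genes_path, matrix.gene_ids)
    _write_id_list(cells_path, matrix.cell_ids)


def _read_id_list(path: str | Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def _write_id_list(path: str | Path, ids) -> None:
    with _open_text(path, "wt") as fh:
        for i in ids:
            fh.write(f"{i}\n")


def read_annotation(path: str | Path, sep: str = "\t") -> CellTypeAnnotation:
    """Two-column table (cell_id, cell_type); a header row is auto-detected."""
    df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("annotation table needs two columns: cell_id, cell_type")
    if df.iloc[0, 0].lower() in ("cell_id", "cell", "barcode"):
        df = df.iloc[1:]
    return CellTypeAnnotation(pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values))


def write_annotation(annot: CellTypeAnnotation, path: str | Path, sep: str = "\t") -> None:
    with _open_text(path, "wt") as fh:
        for cell, label in annot.mapping.items():
            fh.write(f"{cell}{sep}{label}\n")


def read_ortholog_map(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Two-column (source_gene_id, target_gene_id) table, no header."""
    df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("ortholog map needs two columns: source_id, target_id")
    df = df.iloc[:, :2]
    df.columns = ["source", "target"]
    return df


def read_gene_coordinates(path: str | Path, fmt: str = "bed", sep: str = "\t") -> pd.DataFrame:
    """Gene coordinate table with columns gene_id, chrom, start, end (1-based inclusive).

    ``fmt="bed"`` reads BED (chrom, start, end, name; 0-based half-open,
    converted internally); ``fmt="table"`` reads a 4-column 1-based table
    (gene_id, chrom, start, end).
    """
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if fmt == "bed":
        if df.shape[1] < 4:
            raise ValueError("BED input needs at least 4 columns (chrom, start, end, name)")
        out = pd.DataFrame(
            {
                "gene_id": df.iloc[:, 3],
                "chrom": df.iloc[:, 0],
                "start": df.iloc[:, 1].astype(np.int64) + 1,  # 0-based -> 1-based
                "end": df.iloc[:, 2].astype(np.int64),
            }
        )
    elif fmt == "table":
        if df.shape[1] < 4:
            raise ValueError("coordinate table needs 4 columns (gene_id, chrom, start, end)")
        out = pd.DataFrame(
            {
                "gene_id": df.iloc[:, 0],
                "chrom": df.iloc[:, 1],
                "start": df.iloc[:, 2].astype(np.int64),
                "end": df.iloc[:, 3].astype(np.int64),
            }
        )
    else:
        raise ValueError(f"unknown coordinate format {fmt!r}; use 'bed' or 'table'")
    if (out["start"] > out["end"]).any():
        bad = out.loc[out["start"] > out["end"], "gene_id"].tolist()[:5]
        raise ValueError(f"start > end for genes {bad}")
    if out["gene_id"].duplicated().any():
        dup = out.loc[out["gene_id"].duplicated(), "gene_id"].tolist()[:5]
        raise ValueError(f"duplicate gene ids in coordinates: {dup}")
    return out.reset_index(drop=True)


def write_gene_coordinates(genes: pd.DataFrame, path: str | Path, fmt: str = "bed") -> None:
    if fmt == "bed":
        bed = pd.DataFrame(
            {
                "chrom": genes["chrom"],
                "start": genes["start"].astype(np.int64) - 1,
                "end": genes["end"].astype(np.int64),
                "name": genes["gene_id"],
            }
        )
        bed.to_csv(path, sep="\t", header=False, index=False)
    elif fmt == "table":
        genes[["gene_id", "chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)
    else:
        raise ValueError(f"unknown coordinate format {fmt!r}")


def read_variants_bim(path: str | Path) -> pd.DataFrame:
    """PLINK BIM file: chrom, variant_id, cM, pos, A1, A2 (only 3 used)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] < 4:
        raise ValueError("BIM file needs at least 4 columns (chrom, id, cM, pos)")
    out = pd.DataFrame(
        {
            "variant_id": df.iloc[:, 1],
            "chrom": df.iloc[:, 0],
            "pos": df.iloc[:, 3].astype(np.int64),
        }
    )
    if out["variant_id"].duplicated().any():
        dup = out.loc[out["variant_id"].duplicated(), "variant_id"].tolist()[:5]
        raise ValueError(f"duplicate variant ids: {dup}")
    return out


def write_variants_bim(variants: pd.DataFrame, path: str | Path) -> None:
    bim = pd.DataFrame(
        {
            0: variants["chrom"],
            1: variants["variant_id"],
            2: 0,
            3: variants["pos"].astype(np.int64),
            4: "A",
            5: "G",
        }
    )
    bim.to_csv(path, sep="\t", header=False, index=False)


def read_geneset(path: str | Path) -> list[str]:
    """One gene id per line; a 'gene' / 'gene_id' header line is skipped."""
    ids = _read_id_list(path)
    if ids and ids[0].lower() in ("gene", "gene_id", "genes"):
        ids = ids[1:]
    seen: dict[str, None] = {}
    for g in ids:
        seen.setdefault(g, None)
    return list(seen)


def read_es_matrix(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, index_col=0)


def write_es_matrix(es: pd.DataFrame | ESMu, path: str | Path, sep: str = "\t") -> None:
    df = es.values if isinstance(es, ESMu) else es
    df.to_csv(path, sep=sep)
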