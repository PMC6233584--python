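"""Reading and writing of expression matrices and imputation artifacts.

The canonical in-memory orientation is cells x genes: row i is a cell,
column j is a gene.  File readers normalize to it regardless of the on-disk
layout, so downstream code never has to guess.

Supported formats:

* dense TSV/CSV with a header row and an id column;
* MatrixMarket coordinate (``.mtx``) with two plain-text sidecar files,
  one gene id per line and one cell id per line (1-based indices inside
  the ``.mtx`` as the standard requires).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

Layout = Literal["genes_by_cells", "cells_by_genes"]
ReadFormat = Literal["tsv", "csv", "matrixmarket"]

_DELIMS = {"tsv": "\t", "csv": ","}


class MatrixParseError(ValueError):
    """Malformed input file (bad token, ragged row, missing sidecar)."""


class MatrixValidationError(ValueError):
    """Structurally valid file with invalid content (negative counts, duplicate ids)."""


@dataclass
class CountMatrix:
    """Non-negative integer expression counts, cells x genes.

    ``counts[i, j]`` is the observed count of gene ``gene_ids[j]`` in cell
    ``cell_ids[i]``.
    """

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        validate_counts(self.counts, self.cell_ids, self.gene_ids)
        self.counts = self.counts.astype(np.int64, copy=False)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def depths(self) -> np.ndarray:
        """Total read depth N_i per cell."""
        return self.counts.sum(axis=1)

    def subset_cells(self, idx: np.ndarray) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(self.counts[idx], [self.cell_ids[i] for i in idx], list(self.gene_ids))

    def subset_genes(self, idx: np.ndarray) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(self.counts[:, idx], list(self.cell_ids), [self.gene_ids[i] for i in idx])


@dataclass
class ImputationOutput:
    """Result of imputing a log-expression matrix.

    ``imputed`` is on the log-RPM scale, same shape as the (filtered) input;
    ``imputed_mask`` is True exactly where a zero count was replaced;
    ``weights`` is the sparse cell x cell matrix of imputation weights
    b_{i,l} (row = target cell, column = neighbor), zero diagonal, each
    non-empty row summing to one.
    """

    imputed: np.ndarray
    imputed_mask: np.ndarray
    weights: sparse.csr_matrix
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    failed_cells: list[str] = field(default_factory=list)


def validate_counts(counts: np.ndarray, cell_ids: list[str], gene_ids: list[str]) -> None:
    if counts.ndim != 2:
        raise MatrixValidationError(f"count matrix must be 2-D, got shape {counts.shape}")
    if counts.shape != (len(cell_ids), len(gene_ids)):
        raise MatrixValidationError(
            f"shape {counts.shape} does not match {len(cell_ids)} cell ids x {len(gene_ids)} gene ids"
        )
    if len(set(cell_ids)) != len(cell_ids):
        dupes = sorted({c for c in cell_ids if cell_ids.count(c) > 1})
        raise MatrixValidationError(f"duplicate cell ids: {dupes[:5]}")
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise MatrixValidationError(f"duplicate gene ids: {dupes[:5]}")
    arr = np.asarray(counts)
    if not np.issubdtype(arr.dtype, np.number):
        raise MatrixValidationError(f"non-numeric count matrix (dtype {arr.dtype})")
    if np.any(arr < 0):
        i, j = np.argwhere(arr < 0)[0]
        raise MatrixValidationError(f"negative count at cell {cell_ids[i]!r}, gene {gene_ids[j]!r}")
    if not np.issubdtype(arr.dtype, np.integer):
        frac = arr - np.round(arr)
        if np.any(np.abs(frac) > 0):
            i, j = np.argwhere(np.abs(frac) > 0)[0]
            raise MatrixValidationError(
                f"non-integer count {arr[i, j]} at cell {cell_ids[i]!r}, gene {gene_ids[j]!r}"
            )


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("") if path.suffix == ".mtx" else path
    return Path(f"{stem}.genes.txt"), Path(f"{stem}.cells.txt")


def _read_ids(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise MatrixParseError(f"missing {what} sidecar file: {path}")
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if not ids:
        raise MatrixParseError(f"empty {what} sidecar file: {path}")
    return ids


def read_counts(path: str | Path, layout: Layout = "genes_by_cells", format: ReadFormat | None = None) -> CountMatrix:
    """Read a count matrix, normalizing to the canonical cells x genes orientation.

    ``layout`` states how the file is oriented on disk.  ``format`` defaults
    to a guess from the file extension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout not in ("genes_by_cells", "cells_by_genes"):
        raise ValueError(f"unknown layout {layout!r}")
    if format is None:
        format = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".mtx": "matrixmarket"}.get(
            path.suffix, "tsv"
        )

    if format == "matrixmarket":
        genes_path, cells_path = _sidecar_paths(path)
        gene_ids = _read_ids(genes_path, "gene id")
        cell_ids = _read_ids(cells_path, "cell id")
        try:
            mat = spio.mmread(path)
        except Exception as exc:  # scipy raises bare ValueError with line context
            raise MatrixParseError(f"cannot parse MatrixMarket file {path}: {exc}") from exc
        arr = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        row_ids, col_ids = (gene_ids, cell_ids) if layout == "genes_by_cells" else (cell_ids, gene_ids)
        if arr.shape != (len(row_ids), len(col_ids)):
            raise MatrixValidationError(
                f"matrix shape {arr.shape} does not match sidecars "
                f"({len(gene_ids)} genes, {len(cell_ids)} cells, layout {layout})"
            )
    elif format in ("tsv", "csv"):
        try:
            df = pd.read_csv(path, sep=_DELIMS[format], index_col=0)
        except Exception as exc:
            raise MatrixParseError(f"cannot parse {format} file {path}: {exc}") from exc
        bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
        if bad:
            raise MatrixParseError(f"non-numeric column(s) {bad[:3]} in {path}")
        arr = df.to_numpy()
        row_ids = [str(r) for r in df.index]
        col_ids = [str(c) for c in df.columns]
    else:
        raise ValueError(f"unknown format {format!r}")

    if layout == "genes_by_cells":
        arr = arr.T
        cell_ids, gene_ids = col_ids, row_ids
    else:
        cell_ids, gene_ids = row_ids, col_ids
    return CountMatrix(arr, list(cell_ids), list(gene_ids))


def write_counts(cm: CountMatrix, path: str | Path, layout: Layout = "genes_by_cells", format: ReadFormat | None = None) -> None:
    """Write a count matrix in the given on-disk layout and format."""
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".mtx": "matrixmarket"}.get(
            path.suffix, "tsv"
        )
    if layout == "genes_by_cells":
        arr, row_ids, col_ids = cm.counts.T, cm.gene_ids, cm.cell_ids
    else:
        arr, row_ids, col_ids = cm.counts, cm.cell_ids, cm.gene_ids
    if format == "matrixmarket":
        genes_path, cells_path = _sidecar_paths(path)
        spio.mmwrite(path, sparse.coo_matrix(arr))
        genes_path.write_text("\n".join(cm.gene_ids) + "\n")
        cells_path.write_text("\n".join(cm.cell_ids) + "\n")
    elif format in ("tsv", "csv"):
        pd.DataFrame(arr, index=row_ids, columns=col_ids).to_csv(path, sep=_DELIMS[format])
    else:
        raise ValueError(f"unknown format {format!r}")


def write_imputed(result: ImputationOutput, path: str | Path, format: Literal["tsv", "matrixmarket"] = "tsv") -> None:
    """Write an imputed matrix plus its weight triplets.

    The matrix goes to ``path`` (cells x genes for tsv; genes x cells
    MatrixMarket with sidecars).  Weights are written next to it as
    ``<path>.weights.tsv``, a 3-column triplet file
    (target_cell, neighbor_cell, weight); cells with no weights contribute
    no lines.
    """
    path = Path(path)
    cell_ids = result.cell_ids or [f"cell{i}" for i in range(result.imputed.shape[0])]
    gene_ids = result.gene_ids or [f"gene{j}" for j in range(result.imputed.shape[1])]
    if format == "tsv":
        pd.DataFrame(result.imputed, index=cell_ids, columns=gene_ids).to_csv(
            path, sep="\t", float_format="%.8g"
        )
    elif format == "matrixmarket":
        genes_path, cells_path = _sidecar_paths(path)
        spio.mmwrite(path, sparse.coo_matrix(result.imputed.T), precision=8)
        genes_path.write_text("\n".join(gene_ids) + "\n")
        cells_path.write_text("\n".join(cell_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")

    coo = result.weights.tocoo()
    wpath = Path(f"{path}.weights.tsv")
    with open(wpath, "w") as fh:
        fh.write("target_cell\tneighbor_cell\tweight\n")
        for i, l, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{cell_ids[i]}\t{cell_ids[l]}\t{w:.10g}\n")


def read_weight_triplets(path: str | Path, cell_ids: list[str]) -> sparse.csr_matrix:
    """Read a weight triplet file back into a sparse cell x cell matrix."""
    df = pd.read_csv(path, sep="\t")
    pos = {c: i for i, c in enumerate(cell_ids)}
    n = len(cell_ids)
    rows = [pos[c] for c in df["target_cell"]]
    cols = [pos[c] for c in df["neighbor_cell"]]
    return sparse.coo_matrix((df["weight"], (rows, cols)), shape=(n, n)).tocsr()
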