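"""Reading and writing UMI count matrices and cell labels.

The in-memory data model is :class:`CountMatrix`: raw non-negative integer
UMI counts oriented cells x genes everywhere in the package.  10x-style
Matrix Market directories (which store genes x cells) are transposed at
read time.  Counts are backed sparsely (CSR) when the matrix is mostly
zeros, densely otherwise; downstream code accepts both backings.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "CountMatrix",
    "LabelVector",
    "FormatError",
    "ValidationError",
    "read_10x_mtx",
    "read_dense",
    "read_labels",
    "write_counts",
    "write_labels",
]

#: density above which counts are stored densely
_DENSE_THRESHOLD = 0.5
#: tolerance within which float input is accepted as integral
_INT_TOL = 1e-6


class FormatError(ValueError):
    """A file or directory does not have the expected on-disk layout."""


class ValidationError(ValueError):
    """Data violates a CountMatrix/LabelVector invariant."""


def _check_integral(values: np.ndarray) -> np.ndarray:
    """Cast to integer counts, accepting floats only if integral within 1e-6."""
    if np.issubdtype(values.dtype, np.integer):
        return values
    rounded = np.rint(values)
    if not np.allclose(values, rounded, rtol=0, atol=_INT_TOL):
        raise ValidationError(
            "count matrix contains non-integer values (beyond 1e-6 tolerance)"
        )
    return rounded.astype(np.int64)


def _choose_backing(counts: Union[np.ndarray, sp.spmatrix]):
    """Store sparsely when density < 50%, densely otherwise."""
    if sp.issparse(counts):
        density = counts.nnz / max(1, counts.shape[0] * counts.shape[1])
        if density >= _DENSE_THRESHOLD:
            return np.asarray(counts.todense())
        return sp.csr_matrix(counts)
    density = np.count_nonzero(counts) / max(1, counts.size)
    if density < _DENSE_THRESHOLD:
        return sp.csr_matrix(counts)
    return np.asarray(counts)


@dataclass
class CountMatrix:
    """Raw UMI counts, cells (rows) x genes (columns), with identifiers."""

    counts: Union[np.ndarray, sp.spmatrix]
    cell_ids: List[str] = field(default_factory=list)
    gene_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sp.issparse(self.counts):
            self.counts = self.counts.tocsr()
            self.counts.data = _check_integral(self.counts.data)
            if self.counts.nnz and self.counts.data.min() < 0:
                raise ValidationError("count matrix contains negative values")
        else:
            self.counts = _check_integral(np.asarray(self.counts))
            if self.counts.size and self.counts.min() < 0:
                raise ValidationError("count matrix contains negative values")
        self.counts = _choose_backing(self.counts)
        n, m = self.counts.shape
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(n)]
        if not self.gene_ids:
            self.gene_ids = [f"gene_{j}" for j in range(m)]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.cell_ids) != n:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n} matrix rows"
            )
        if len(self.gene_ids) != m:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {m} matrix columns"
            )
        if len(set(self.cell_ids)) != n:
            raise ValidationError("duplicate cell ids")
        if len(set(self.gene_ids)) != m:
            raise ValidationError("duplicate gene ids")

    # -- convenience accessors -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        """Counts as a dense int array (copy if sparse-backed)."""
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return self.counts

    def cell_totals(self) -> np.ndarray:
        """Per-cell total UMI count n_i over all genes."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset(self, rows=None, cols=None) -> "CountMatrix":
        """Row/column subset preserving source order of the given indices."""
        counts = self.counts
        cell_ids = self.cell_ids
        gene_ids = self.gene_ids
        if rows is not None:
            rows = np.asarray(rows)
            counts = counts[rows]
            cell_ids = [cell_ids[i] for i in rows]
        if cols is not None:
            cols = np.asarray(cols)
            counts = counts[:, cols]
            gene_ids = [gene_ids[j] for j in cols]
        return CountMatrix(counts, cell_ids, gene_ids)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        if self.cell_ids != other.cell_ids or self.gene_ids != other.gene_ids:
            return False
        return np.array_equal(self.dense(), other.dense())


@dataclass
class LabelVector:
    """Per-cell categorical assignment aligned with a CountMatrix's rows."""

    labels: np.ndarray
    cell_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(len(self.labels))]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.cell_ids) != len(self.labels):
            raise ValidationError("labels and cell_ids differ in length")

    def __len__(self) -> int:
        return len(self.labels)

    def codes(self) -> np.ndarray:
        """Labels as integer codes (first-appearance order)."""
        _, codes = np.unique(self.labels, return_inverse=True)
        return codes


# -- file discovery helpers ----------------------------------------------------

def _find_component(dir_path: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            candidate = dir_path / f"{stem}{suffix}"
            if candidate.is_file():
                return candidate
    raise FormatError(
        f"missing component in {dir_path}: expected one of {list(stems)} "
        "(optionally gzipped)"
    )


def _read_tsv_column(path: Path, column: int = 0) -> List[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    out: List[str] = []
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            out.append(line.split("\t")[column])
    return out


def read_10x_mtx(dir_path) -> CountMatrix:
    """Read a 10x-style directory (matrix.mtx + barcodes.tsv + genes/features.tsv).

    The matrix file is stored genes x cells per the 10x convention and is
    transposed to cells x genes.  Gzipped components are accepted.
    """
    dir_path = Path(dir_path)
    if not dir_path.is_dir():
        raise FormatError(f"not a directory: {dir_path}")
    mtx_path = _find_component(dir_path, ["matrix.mtx"])
    barcodes_path = _find_component(dir_path, ["barcodes.tsv"])
    features_path = _find_component(dir_path, ["genes.tsv", "features.tsv"])

    try:
        mat = mmread(os.fspath(mtx_path))
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise FormatError(f"cannot parse Matrix Market file {mtx_path}: {exc}")
    barcodes = _read_tsv_column(barcodes_path)
    features = _read_tsv_column(features_path)

    mat = sp.csr_matrix(mat).T  # genes x cells -> cells x genes
    if mat.shape[0] != len(barcodes):
        raise FormatError(
            f"matrix has {mat.shape[0]} cells but {len(barcodes)} barcodes"
        )
    if mat.shape[1] != len(features):
        raise FormatError(
            f"matrix has {mat.shape[1]} genes but {len(features)} features"
        )
    return CountMatrix(mat, barcodes, features)


def read_dense(path, orientation: str = "cells_by_genes") -> CountMatrix:
    """Read a dense CSV/TSV count table (header row + index column)."""
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"non-numeric entries in {path}")
    if orientation == "genes_by_cells":
        df = df.T
        values = values.T
    return CountMatrix(values, list(df.index), list(df.columns))


def read_labels(path) -> LabelVector:
    """Read labels from CSV with a header; one or two columns.

    Two columns are read as (cell_id, label); a single column as labels with
    positional cell ids.
    """
    df = pd.read_csv(path)
    if df.shape[1] >= 2:
        return LabelVector(df.iloc[:, 1].to_numpy(), list(df.iloc[:, 0].astype(str)))
    return LabelVector(df.iloc[:, 0].to_numpy())


def write_counts(matrix: CountMatrix, path, format: str = "mtx") -> None:
    """Write a CountMatrix; ``read_*(write_counts(M))`` is the identity.

    ``mtx`` writes a 10x-style directory (genes x cells matrix.mtx, barcodes.tsv,
    genes.tsv); ``csv`` writes a single cells x genes table.
    """
    path = Path(path)
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        mmwrite(
            os.fspath(path / "matrix.mtx"),
            sp.coo_matrix(matrix.counts.T),  # cells x genes -> genes x cells
            field="integer",
        )
        (path / "barcodes.tsv").write_text("\n".join(matrix.cell_ids) + "\n")
        (path / "genes.tsv").write_text(
            "\n".join(f"{g}\t{g}" for g in matrix.gene_ids) + "\n"
        )
    elif format == "csv":
        df = pd.DataFrame(
            matrix.dense(), index=matrix.cell_ids, columns=matrix.gene_ids
        )
        df.to_csv(path)
    else:
        raise ValueError(f"unknown format: {format!r}")


def write_labels(labels: LabelVector, path) -> None:
    pd.DataFrame({"cell_id": labels.cell_ids, "label": labels.labels}).to_csv(
        path, index=False
    )
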