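"""Filtering, highly-variable-gene selection, and the network-input transform.

The clustering model consumes two row-aligned views of the same cells:

* ``raw_selected`` — untouched integer UMI counts on the selected genes,
  which the multinomial reconstruction likelihood is evaluated on;
* ``x_input`` — median-depth-normalized, log1p-transformed, per-gene
  z-scored values, which the encoder consumes for numerical stability.

Gene selection ranks genes by normalized dispersion (variance/mean of the
depth-normalized expression, standardized within 20 mean-expression bins —
the Seurat-style recipe popularized by scanpy) and keeps the top ``n_top``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_io import CountMatrix, ValidationError

__all__ = [
    "PreparedData",
    "filter_matrix",
    "select_hvg",
    "normalize_transform",
    "prepare",
]


@dataclass
class PreparedData:
    """Selected-gene raw counts paired row-wise with the z-scored model input."""

    raw_selected: np.ndarray  # cells x m_sel, integer counts
    x_input: np.ndarray  # cells x m_sel, float32 z-scores
    cell_totals: np.ndarray  # per-cell sum of raw_selected
    selected_gene_ids: List[str]
    cell_ids: List[str]
    transform_params: Dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.raw_selected.shape[0]

    @property
    def n_genes(self) -> int:
        return self.raw_selected.shape[1]

    def subset_cells(self, rows) -> "PreparedData":
        rows = np.asarray(rows)
        return PreparedData(
            raw_selected=self.raw_selected[rows],
            x_input=self.x_input[rows],
            cell_totals=self.cell_totals[rows],
            selected_gene_ids=self.selected_gene_ids,
            cell_ids=[self.cell_ids[i] for i in rows],
            transform_params=self.transform_params,
        )


def filter_matrix(matrix: CountMatrix) -> CountMatrix:
    """Drop all-zero genes, then all-zero cells (in that order)."""
    gene_sums = np.asarray(matrix.counts.sum(axis=0)).ravel()
    keep_genes = np.flatnonzero(gene_sums > 0)
    if keep_genes.size == 0:
        raise ValidationError("no cells/genes survive filtering")
    out = matrix.subset(cols=keep_genes)
    cell_sums = np.asarray(out.counts.sum(axis=1)).ravel()
    keep_cells = np.flatnonzero(cell_sums > 0)
    if keep_cells.size == 0:
        raise ValidationError("no cells/genes survive filtering")
    if keep_cells.size < out.n_cells:
        out = out.subset(rows=keep_cells)
    return out


def _normalized_matrix(matrix: CountMatrix) -> np.ndarray:
    """Depth-normalize each cell to the median total count (dense float64)."""
    counts = matrix.dense().astype(np.float64)
    totals = counts.sum(axis=1)
    if np.any(totals <= 0):
        raise ValidationError("cells with zero total count; run filter_matrix first")
    median_total = float(np.median(totals))
    return counts * (median_total / totals)[:, None]


def normalized_dispersion(matrix: CountMatrix) -> np.ndarray:
    """Per-gene normalized dispersion score (Seurat-style binned z-score).

    Depth-normalize to the median cell total; per gene compute mean and
    dispersion = variance/mean (sample variance); log-transform dispersion
    and log1p the mean; cut genes into 20 equal-width bins of log-mean and
    z-score the log-dispersion within each bin.  Genes in single-gene bins
    score 1; genes with undefined dispersion score -inf.
    """
    m = matrix.n_genes
    norm = _normalized_matrix(matrix)
    mean = norm.mean(axis=0)
    var = norm.var(axis=0, ddof=1) if norm.shape[0] > 1 else np.zeros(m)
    mean_safe = np.where(mean == 0, 1e-12, mean)
    dispersion = var / mean_safe
    with np.errstate(divide="ignore"):
        log_disp = np.where(dispersion > 0, np.log(dispersion), np.nan)
    log_mean = np.log1p(mean)

    df = pd.DataFrame({"mean": log_mean, "disp": log_disp})
    df["bin"] = pd.cut(df["mean"], bins=20)
    grouped = df.groupby("bin", observed=True)["disp"]
    bin_mean = grouped.mean()
    bin_std = grouped.std(ddof=1)
    # single-gene bins have undefined std: that gene scores disp/disp = 1
    # (Seurat convention)
    single = bin_std.isna()
    bin_std[single] = bin_mean[single]
    bin_mean[single] = 0.0
    bin_std = bin_std.replace(0.0, np.nan)

    score = (df["disp"].values - bin_mean[df["bin"].values].values) / bin_std[
        df["bin"].values
    ].values
    return np.where(np.isfinite(score), score, -np.inf)


def select_hvg(matrix: CountMatrix, n_top: int = 500) -> np.ndarray:
    """Indices of the ``n_top`` genes with highest normalized dispersion.

    Ties and the ordering of equal scores are broken by original column
    order, so the result is deterministic given the matrix.
    """
    if n_top < 1:
        raise ValueError(f"n_top must be >= 1, got {n_top}")
    m = matrix.n_genes
    if n_top > m:
        import warnings

        warnings.warn(
            f"n_top={n_top} exceeds gene count {m}; returning all genes",
            stacklevel=2,
        )
        n_top = m
    score = normalized_dispersion(matrix)
    # stable sort on (-score, original index)
    order = np.lexsort((np.arange(m), -score))
    return order[:n_top]


def normalize_transform(
    matrix: CountMatrix,
    gene_subset: Sequence[int],
    clip_value: Optional[float] = 10.0,
    size_factor_scope: str = "all",
) -> PreparedData:
    """Build the two aligned views the model trains on.

    Pipeline, in order: (a) per-cell depth normalization to the median
    total (computed over all retained genes, or over the subset when
    ``size_factor_scope='hvg'``); (b) restriction to ``gene_subset``;
    (c) ``log1p``; (d) per-gene z-score with an sd guard (constant genes
    get an all-zero column) and optional clipping to ``[-clip, clip]``.

    ``raw_selected`` and ``cell_totals`` come from the untransformed counts
    on the subset: the likelihood always sees raw integers.
    """
    gene_subset = np.asarray(gene_subset)
    if gene_subset.size == 0:
        raise ValueError("gene_subset is empty")
    if size_factor_scope not in ("all", "hvg"):
        raise ValueError(f"unknown size_factor_scope: {size_factor_scope!r}")

    counts = matrix.dense().astype(np.float64)
    raw_selected = matrix.dense()[:, gene_subset].astype(np.int64)

    scope = counts[:, gene_subset] if size_factor_scope == "hvg" else counts
    totals = scope.sum(axis=1)
    if np.any(totals <= 0):
        raise ValidationError("cells with zero total count; run filter_matrix first")
    median_total = float(np.median(totals))
    v = counts[:, gene_subset] * (median_total / totals)[:, None]
    logged = np.log1p(v)

    mu = logged.mean(axis=0)
    sd = logged.std(axis=0)
    sd_guarded = np.where(sd <= 1e-12, 1.0, sd)
    x = (logged - mu) / sd_guarded
    if clip_value is not None:
        np.clip(x, -clip_value, clip_value, out=x)

    cell_totals = raw_selected.sum(axis=1)
    if np.any(cell_totals <= 0):
        raise ValidationError(
            "a cell has zero counts over the selected genes; "
            "select more genes or filter the cell"
        )
    return PreparedData(
        raw_selected=raw_selected,
        x_input=x.astype(np.float32),
        cell_totals=cell_totals,
        selected_gene_ids=[matrix.gene_ids[j] for j in gene_subset],
        cell_ids=list(matrix.cell_ids),
        transform_params={
            "gene_mean": mu,
            "gene_sd": sd_guarded,
            "median_total": median_total,
            "clip_value": clip_value,
            "size_factor_scope": size_factor_scope,
        },
    )


def prepare(
    matrix: CountMatrix,
    n_top_genes: int = 500,
    clip_value: Optional[float] = 10.0,
    size_factor_scope: str = "all",
) -> PreparedData:
    """filter -> select HVGs -> normalize/transform, the standard chain."""
    filtered = filter_matrix(matrix)
    hvg = select_hvg(filtered, n_top=n_top_genes)
    return normalize_transform(
        filtered, hvg, clip_value=clip_value, size_factor_scope=size_factor_scope
    )
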