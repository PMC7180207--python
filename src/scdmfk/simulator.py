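"""Gamma-Poisson scRNA-seq count simulator with ground-truth group labels.

The generative model follows the Splatter family: gene base means are drawn
from a gamma distribution; each group receives multiplicative
differential-expression factors on a random subset of genes; per-cell
library sizes are log-normal; a biological coefficient of variation (BCV)
inflates the mean-variance trend by gamma-mixing the per-entry means before
Poisson sampling; finally a logistic-in-log-mean dropout step zeroes
entries with probability rising for low-expressed genes.

Two experimental designs are provided: a *balanced* design (5-9 groups of
500 cells each) and an *imbalanced* design (5 groups whose sizes form a
geometric series totalling 2500 cells).  Both use 2500 genes, DE factor
scale 0.2 and dropout shape -1, with the dropout midpoint controlling the
overall zero fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .data_io import CountMatrix, LabelVector

__all__ = [
    "SimParams",
    "SimResult",
    "simulate",
    "balanced_design",
    "imbalanced_design",
    "geometric_sizes",
]


@dataclass
class SimParams:
    """Simulation parameters; defaults mirror the published Splatter defaults
    except where the simulation designs override them."""

    n_groups: int = 5
    cells_per_group: List[int] = field(default_factory=lambda: [500] * 5)
    n_genes: int = 2500
    de_prob: float = 0.1
    de_fac_loc: float = 0.1
    de_fac_scale: float = 0.2
    de_down_prob: float = 0.5
    dropout_mid: float = -1.5
    dropout_shape: float = -1.0
    dropout: bool = True
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    lib_loc: float = 11.0
    lib_scale: float = 0.2
    bcv_common: float = 0.1
    bcv_df: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.cells_per_group = [int(c) for c in self.cells_per_group]
        if len(self.cells_per_group) != self.n_groups:
            raise ValueError(
                f"{len(self.cells_per_group)} group sizes for {self.n_groups} groups"
            )
        if any(c < 1 for c in self.cells_per_group):
            raise ValueError("every group needs at least one cell")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.de_fac_scale <= 0:
            raise ValueError("de_fac_scale must be > 0")
        if not (0 <= self.de_prob <= 1):
            raise ValueError("de_prob must be in [0, 1]")
        if self.mean_shape <= 0 or self.mean_rate <= 0:
            raise ValueError("gamma mean parameters must be > 0")
        if self.lib_scale <= 0:
            raise ValueError("lib_scale must be > 0")
        if self.bcv_common < 0:
            raise ValueError("bcv_common must be >= 0")


@dataclass
class SimResult:
    """Simulated counts with ground truth."""

    counts: CountMatrix
    labels: LabelVector
    true_means: np.ndarray  # cells x genes expected expression before dropout
    dropout_mask: sp.csr_matrix  # 1 where dropout zeroed the entry
    params: SimParams

    @property
    def zero_fraction(self) -> float:
        """Fraction of zero entries in the final count matrix."""
        n, m = self.counts.counts.shape
        if sp.issparse(self.counts.counts):
            return 1.0 - self.counts.counts.nnz / (n * m)
        return float(np.mean(self.counts.dense() == 0))

    @property
    def dropout_fraction(self) -> float:
        """Fraction of entries zeroed by the dropout step (extra zeros)."""
        n, m = self.counts.counts.shape
        return self.dropout_mask.nnz / (n * m)


def simulate(params: SimParams) -> SimResult:
    """Draw a dataset from the gamma-Poisson model; fully seeded."""
    rng = np.random.default_rng(params.seed)
    n_cells = sum(params.cells_per_group)
    m = params.n_genes

    # (a) gene base means
    base_means = rng.gamma(params.mean_shape, 1.0 / params.mean_rate, size=m)

    # (b) per-group multiplicative DE factors on a random gene subset
    group_means = np.empty((params.n_groups, m))
    for g in range(params.n_groups):
        factors = np.ones(m)
        is_de = rng.random(m) < params.de_prob
        n_de = int(is_de.sum())
        if n_de:
            fac = np.exp(rng.normal(params.de_fac_loc, params.de_fac_scale, n_de))
            down = rng.random(n_de) < params.de_down_prob
            fac[down] = 1.0 / fac[down]
            factors[is_de] = fac
        group_means[g] = base_means * factors

    # group assignment in contiguous blocks
    labels = np.repeat(np.arange(params.n_groups), params.cells_per_group)

    # (c) library sizes; cell mean profile rescaled to library size
    lib = rng.lognormal(params.lib_loc, params.lib_scale, size=n_cells)
    profiles = group_means[labels]
    profiles = profiles / profiles.sum(axis=1, keepdims=True)
    cell_means = profiles * lib[:, None]

    # (d) BCV mean inflation + (e) Poisson sampling.  The per-entry BCV
    # follows the mean-variance trend bcv.common + 1/sqrt(mean), scaled by a
    # per-gene chi-square factor with bcv_df degrees of freedom; the entry
    # mean is then gamma-mixed with shape 1/BCV^2 before Poisson sampling.
    if params.bcv_common > 0:
        chisq = rng.chisquare(params.bcv_df, size=m) / params.bcv_df
        bcv = (params.bcv_common + 1.0 / np.sqrt(cell_means)) * np.sqrt(
            1.0 / chisq
        )[None, :]
        shape = 1.0 / bcv**2
        lam = rng.gamma(shape, cell_means * bcv**2)
    else:
        lam = cell_means
    counts = rng.poisson(lam)

    # (f) logistic dropout: P(zeroed) = sigmoid(shape * (log(lam+1) - mid)),
    # oriented so that with shape=-1 a larger midpoint zeroes more entries
    if params.dropout:
        logit = params.dropout_shape * (np.log(lam + 1.0) - params.dropout_mid)
        p_drop = 1.0 / (1.0 + np.exp(-logit))
        mask = rng.random((n_cells, m)) < p_drop
        counts = np.where(mask, 0, counts)
        dropout_mask = sp.csr_matrix(mask)
    else:
        dropout_mask = sp.csr_matrix((n_cells, m), dtype=bool)

    cell_ids = [f"cell_{i}" for i in range(n_cells)]
    gene_ids = [f"gene_{j}" for j in range(m)]
    return SimResult(
        counts=CountMatrix(counts, cell_ids, gene_ids),
        labels=LabelVector(labels.astype(int), cell_ids),
        true_means=lam,
        dropout_mask=dropout_mask,
        params=params,
    )


def balanced_design(
    n_groups: int,
    dropout_mid: float,
    seed: int = 0,
    cells_per_group: int = 500,
    n_genes: int = 2500,
    **overrides,
) -> SimResult:
    """Balanced study design: ``n_groups`` in [5, 9] equal groups of cells."""
    if not 5 <= n_groups <= 9:
        raise ValueError(f"n_groups must be in [5, 9], got {n_groups}")
    params = SimParams(
        n_groups=n_groups,
        cells_per_group=[cells_per_group] * n_groups,
        n_genes=n_genes,
        de_fac_scale=0.2,
        dropout_shape=-1.0,
        dropout_mid=dropout_mid,
        seed=seed,
        **overrides,
    )
    return simulate(params)


def geometric_sizes(ratio: float, n_groups: int = 5, total: int = 2500) -> List[int]:
    """Group sizes forming a geometric series with common ratio ``ratio``,
    scaled and rounded (largest remainder) to sum exactly to ``total``."""
    if not 0 < ratio <= 1:
        raise ValueError(f"ratio must be in (0, 1], got {ratio}")
    raw = np.array([ratio**g for g in range(n_groups)], dtype=np.float64)
    raw = raw / raw.sum() * total
    sizes = np.floor(raw).astype(int)
    remainder = total - sizes.sum()
    order = np.argsort(-(raw - sizes))
    sizes[order[:remainder]] += 1
    return [int(s) for s in sizes]


def imbalanced_design(
    ratio: float,
    dropout_mid: float,
    seed: int = 0,
    n_groups: int = 5,
    total_cells: int = 2500,
    n_genes: int = 2500,
    **overrides,
) -> SimResult:
    """Imbalanced design: 5 groups in geometric proportion, 2500 cells total."""
    if not 0.6 <= ratio <= 1.0:
        raise ValueError(f"ratio must be in [0.6, 1], got {ratio}")
    sizes = geometric_sizes(ratio, n_groups=n_groups, total=total_cells)
    params = SimParams(
        n_groups=n_groups,
        cells_per_group=sizes,
        n_genes=n_genes,
        de_fac_scale=0.2,
        dropout_shape=-1.0,
        dropout_mid=dropout_mid,
        seed=seed,
        **overrides,
    )
    return simulate(params)
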