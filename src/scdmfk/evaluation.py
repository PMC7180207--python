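"""Clustering metrics (ARI, NMI) and robustness-experiment harnesses.

ARI is the Hubert-Arabie adjusted Rand index computed from the contingency
table; NMI is mutual information normalized (by default) by the arithmetic
mean of the two label entropies.  Both are implemented here from the
contingency table — the formulas are short and the test suite cross-checks
them against scikit-learn — so the normalization convention stays explicit
and switchable.

The experiment harnesses (cell downsampling, artificial dropout masking,
cluster-number perturbation) rerun the same public pipeline entry point the
command line uses, so ablation variants reuse them unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.special import comb

from .data_io import CountMatrix, LabelVector, ValidationError
from .preprocess import PreparedData

__all__ = [
    "MetricReport",
    "contingency_table",
    "adjusted_rand_index",
    "normalized_mutual_info",
    "metric_report",
    "downsample_experiment",
    "mask_experiment",
    "k_perturbation",
]


def _as_codes(labels) -> np.ndarray:
    if isinstance(labels, LabelVector):
        labels = labels.labels
    _, codes = np.unique(np.asarray(labels), return_inverse=True)
    return codes


def contingency_table(truth, pred) -> np.ndarray:
    """K_true x K_pred table of co-occurrence counts."""
    t = _as_codes(truth)
    p = _as_codes(pred)
    if len(t) != len(p):
        raise ValidationError(f"label length mismatch: {len(t)} vs {len(p)}")
    table = np.zeros((t.max() + 1, p.max() + 1), dtype=np.int64)
    np.add.at(table, (t, p), 1)
    return table


def adjusted_rand_index(truth, pred) -> float:
    """Hubert-Arabie ARI from the contingency table."""
    C = contingency_table(truth, pred)
    n = C.sum()
    sum_ij = comb(C, 2).sum()
    a = comb(C.sum(axis=1), 2).sum()
    b = comb(C.sum(axis=0), 2).sum()
    expected = a * b / comb(n, 2)
    max_index = 0.5 * (a + b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def normalized_mutual_info(truth, pred, normalization: str = "arithmetic") -> float:
    """NMI = I(T;P) / mean(H(T), H(P)) with natural logarithms.

    ``normalization`` may be 'arithmetic' (default), 'geometric', 'min' or
    'max'.  If either partition has zero entropy the score is 0, except when
    both are identical single-cluster partitions (1 by convention).
    """
    C = contingency_table(truth, pred).astype(np.float64)
    n = C.sum()
    a = C.sum(axis=1)
    b = C.sum(axis=0)
    h_t = _entropy(a)
    h_p = _entropy(b)
    if h_t == 0.0 and h_p == 0.0:
        return 1.0
    if h_t == 0.0 or h_p == 0.0:
        return 0.0
    nz = C > 0
    mi = (C[nz] / n * np.log(C[nz] * n / np.outer(a, b)[nz])).sum()
    denom = {
        "arithmetic": 0.5 * (h_t + h_p),
        "geometric": np.sqrt(h_t * h_p),
        "min": min(h_t, h_p),
        "max": max(h_t, h_p),
    }[normalization]
    return float(max(0.0, mi / denom))


@dataclass
class MetricReport:
    ari: float
    nmi: float
    contingency: np.ndarray
    n_cells: int

    def to_dict(self) -> Dict:
        return {
            "ari": self.ari,
            "nmi": self.nmi,
            "n_cells": self.n_cells,
            "contingency": self.contingency.tolist(),
        }


def metric_report(truth, pred) -> MetricReport:
    C = contingency_table(truth, pred)
    return MetricReport(
        ari=adjusted_rand_index(truth, pred),
        nmi=normalized_mutual_info(truth, pred),
        contingency=C,
        n_cells=int(C.sum()),
    )


# -- robustness harnesses ------------------------------------------------------

def _run(data: CountMatrix, k: int, pipeline_config: Dict) -> np.ndarray:
    from .pipeline import run_pipeline

    return run_pipeline(data, k, **pipeline_config).labels


def downsample_experiment(
    data: CountMatrix,
    truth: LabelVector,
    fraction: float,
    reps: int = 10,
    pipeline_config: Optional[Dict] = None,
    seed: int = 0,
) -> List[MetricReport]:
    """Cluster random cell subsets and score against the restricted truth.

    Each rep draws ``round(fraction * n)`` cells without replacement, reruns
    the full pipeline on the subset, and reports ARI/NMI against the truth
    labels of those cells.  The median over reps is the summary statistic.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    pipeline_config = dict(pipeline_config or {})
    k = pipeline_config.pop("k", None) or len(np.unique(truth.labels))
    rng = np.random.default_rng(seed)
    n = data.n_cells
    size = int(round(fraction * n))
    reports = []
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=size, replace=False))
        sub = data.subset(rows=idx)
        sub_truth = truth.labels[idx]
        labels = _run(sub, k, pipeline_config)
        reports.append(metric_report(sub_truth, labels))
    return reports


def mask_experiment(
    data: CountMatrix,
    truth: LabelVector,
    prob: float = 0.15,
    reps: int = 10,
    pipeline_config: Optional[Dict] = None,
    seed: int = 0,
) -> List[MetricReport]:
    """Randomly zero non-zero counts with the given probability and recluster."""
    if not 0 <= prob < 1:
        raise ValueError(f"prob must be in [0, 1), got {prob}")
    pipeline_config = dict(pipeline_config or {})
    k = pipeline_config.pop("k", None) or len(np.unique(truth.labels))
    rng = np.random.default_rng(seed)
    dense = data.dense()
    reports = []
    for _ in range(reps):
        mask = (dense > 0) & (rng.random(dense.shape) < prob)
        noisy = CountMatrix(
            np.where(mask, 0, dense), list(data.cell_ids), list(data.gene_ids)
        )
        labels = _run(noisy, k, pipeline_config)
        reports.append(metric_report(truth.labels, labels))
    return reports


def k_perturbation(
    data: CountMatrix,
    truth: LabelVector,
    true_k: int,
    pipeline_config: Optional[Dict] = None,
) -> Dict[int, MetricReport]:
    """Refit at K in {true_k-2, ..., true_k+2}; K < 1 values are skipped."""
    pipeline_config = dict(pipeline_config or {})
    pipeline_config.pop("k", None)
    out: Dict[int, MetricReport] = {}
    for k in range(true_k - 2, true_k + 3):
        if k < 1:
            import warnings

            warnings.warn(f"skipping K={k} < 1", stacklevel=2)
            continue
        labels = _run(data, k, pipeline_config)
        out[k] = metric_report(truth.labels, labels)
    return out
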