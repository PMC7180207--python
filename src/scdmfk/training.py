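"""Fitting procedure: likelihood pretraining, center initialization, and the
joint reconstruction + clustering phase.

The total objective is L = L1 + alpha * L2: the multinomial reconstruction
negative log-likelihood plus the entropy-regularized adaptive fuzzy k-means
loss on the latent embedding.  Training first minimizes L1 alone, then
initializes cluster centers by standard k-means in the learned latent space,
and finally takes joint Adam steps on L over network weights and centers.
Memberships are recomputed in closed form every step (coefficients, not
gradient variables).  The joint phase stops once the fraction of cells whose
hard label changed between consecutive epochs falls below ``tol``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans

from . import fuzzy_kmeans as fk
from .model import ModelConfig, ModelState
from .preprocess import PreparedData

__all__ = ["FitResult", "pretrain", "fit", "estimate_k"]

logger = logging.getLogger(__name__)


@dataclass
class FitResult:
    """Output of :func:`fit`: hard labels, soft memberships, embedding."""

    labels: np.ndarray  # per-cell hard assignment
    memberships: np.ndarray  # cells x K
    embedding: np.ndarray  # cells x latent_dim
    centers: np.ndarray  # K x latent_dim
    history: List[Dict] = field(default_factory=list)
    config_echo: Dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return self.centers.shape[0]


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    """Shuffled minibatch index lists; the last incomplete batch is kept."""
    order = rng.permutation(n)
    return [order[i : i + batch_size] for i in range(0, n, batch_size)]


def pretrain(
    model: ModelState,
    data: PreparedData,
    epochs: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> ModelState:
    """Minimize the reconstruction loss L1 alone for ``epochs`` passes."""
    if epochs is None:
        epochs = model.config.pretrain_epochs
    if epochs < 0:
        raise ValueError("epochs must be >= 0")
    if rng is None:
        rng = np.random.default_rng(model.config.seed + 1)
    n = data.n_cells
    for epoch in range(epochs):
        total = 0.0
        for idx in _epoch_batches(n, model.config.batch_size, rng):
            L1, _, grads, _ = model.loss_and_grads(
                data.x_input[idx], data.raw_selected[idx]
            )
            if not np.isfinite(L1):
                raise FloatingPointError(
                    "NaN/inf reconstruction loss during pretraining; consider "
                    "a lower learning rate or smaller z-score clip value"
                )
            model.adam_step(grads)
            total += L1 * len(idx)
        if epoch % 50 == 0 or epoch == epochs - 1:
            logger.info("pretrain epoch %d: L1=%.4f", epoch, total / n)
    return model


def _full_pass(
    model: ModelState,
    data: PreparedData,
    centers: np.ndarray,
    sigma: float,
    lam: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    Z = model.latent(data.x_input)
    W = fk.soft_assign(Z, centers, sigma, lam)
    return Z, W, fk.hard_labels(W)


def fit(
    model: ModelState,
    data: PreparedData,
    K: int,
    config: Optional[ModelConfig] = None,
    sigma: float = 1.0,
    lam: float = 1.0,
    tol: float = 1e-3,
    max_epochs: int = 300,
    pretrain_epochs: Optional[int] = None,
    run_pretrain: bool = True,
) -> FitResult:
    """Full training: (optional) pretrain, k-means center init, joint phase.

    When ``alpha == 0`` the clustering term vanishes from the objective and
    the procedure reduces to the likelihood-only baseline: the pretrained
    embedding is clustered by standard k-means (the "+kmeans" ablation),
    with memberships reported from the closed-form soft assignment at the
    k-means centers.
    """
    if config is None:
        config = model.config
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(config.seed + 1)
    if run_pretrain:
        pretrain(model, data, epochs=pretrain_epochs, rng=rng)

    n = data.n_cells
    Z = model.latent(data.x_input)
    centers = fk.init_centers(Z, K, seed=config.seed)
    history: List[Dict] = []
    alpha = config.alpha

    if alpha == 0:
        W = fk.soft_assign(Z, centers, sigma, lam)
        if K == 1:
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=K, n_init=20, max_iter=300, random_state=config.seed)
            labels = km.fit_predict(Z)
            centers = km.cluster_centers_
            W = fk.soft_assign(Z, centers, sigma, lam)
        history.append(
            {"epoch": 0, "L1": np.nan, "L2": np.nan, "total": np.nan,
             "changed_fraction": 0.0, "stopped": "alpha=0 baseline"}
        )
        return FitResult(labels, W, Z, centers, history, _echo(config, K, sigma, lam, tol, max_epochs))

    centers = np.asarray(centers, dtype=np.float64)
    _, _, prev_labels = _full_pass(model, data, centers, sigma, lam)
    stopped = "max_epochs"
    for epoch in range(max_epochs):
        sum_l1 = 0.0
        sum_l2 = 0.0
        for idx in _epoch_batches(n, config.batch_size, rng):
            L1, L2, grads, g_centers = model.loss_and_grads(
                data.x_input[idx],
                data.raw_selected[idx],
                centers=centers,
                alpha=alpha,
                sigma=sigma,
                lam=lam,
            )
            if not np.isfinite(L1) or not np.isfinite(L2):
                raise FloatingPointError("non-finite loss during joint training")
            model.adam_step(grads, extra=[(centers, g_centers)])
            sum_l1 += L1 * len(idx)
            sum_l2 += L2 * len(idx)
        Z, W, labels = _full_pass(model, data, centers, sigma, lam)
        changed = float(np.mean(labels != prev_labels))
        occupied = np.unique(labels).size
        entry = {
            "epoch": epoch,
            "L1": sum_l1 / n,
            "L2": sum_l2 / n,
            "total": (sum_l1 + alpha * sum_l2) / n,
            "changed_fraction": changed,
        }
        if occupied < K:
            entry["warning"] = f"only {occupied}/{K} clusters occupied"
        history.append(entry)
        prev_labels = labels
        if changed < tol:
            stopped = "assignment_stable"
            break
    history[-1]["stopped"] = stopped
    logger.info(
        "joint phase finished after %d epochs (%s)", len(history), stopped
    )
    Z, W, labels = _full_pass(model, data, centers, sigma, lam)
    return FitResult(labels, W, Z, centers, history, _echo(config, K, sigma, lam, tol, max_epochs))


def _echo(config: ModelConfig, K, sigma, lam, tol, max_epochs) -> Dict:
    from dataclasses import asdict

    return {
        **asdict(config),
        "K": K,
        "sigma": sigma,
        "lam": lam,
        "tol": tol,
        "max_epochs": max_epochs,
    }


def _pooled_within_dispersion(X: np.ndarray, k: int, seed: int) -> float:
    """log(W_k): within-cluster sum of squares from a k-means partition."""
    if k == 1:
        centers = X.mean(axis=0, keepdims=True)
        labels = np.zeros(X.shape[0], dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=10, max_iter=300, random_state=seed)
        labels = km.fit_predict(X)
        centers = km.cluster_centers_
    w = ((X - centers[labels]) ** 2).sum()
    return float(np.log(w + 1e-300))


def estimate_k(
    embedding: np.ndarray,
    k_range: Sequence[int] = range(1, 11),
    seed: int = 0,
    n_refs: int = 10,
) -> Tuple[int, "np.ndarray"]:
    """Gap-statistic estimate of the number of clusters in the embedding.

    For each k, gap(k) = E*[log W_k] - log W_k, with the reference
    expectation taken over ``n_refs`` uniform samples drawn from the
    embedding's bounding box.  Returns the smallest k with
    gap(k) >= gap(k+1) - s_{k+1}, together with the per-k gap profile
    (array of (k, gap, s) rows).
    """
    X = np.asarray(embedding, dtype=np.float64)
    k_range = list(k_range)
    if not k_range or min(k_range) < 1 or max(k_range) >= X.shape[0]:
        raise ValueError("k_range must lie within [1, n_cells)")
    if np.allclose(X, X[0]):
        profile = np.array([[k, 0.0, 0.0] for k in k_range])
        return 1, profile

    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    gaps = np.zeros(len(k_range))
    sks = np.zeros(len(k_range))
    for i, k in enumerate(k_range):
        log_wk = _pooled_within_dispersion(X, k, seed)
        ref = np.empty(n_refs)
        for b in range(n_refs):
            Xref = rng.uniform(lo, hi, size=X.shape)
            ref[b] = _pooled_within_dispersion(Xref, k, seed)
        gaps[i] = ref.mean() - log_wk
        sks[i] = ref.std(ddof=0) * np.sqrt(1.0 + 1.0 / n_refs)

    best = k_range[-1]
    for i in range(len(k_range) - 1):
        if gaps[i] >= gaps[i + 1] - sks[i + 1]:
            best = k_range[i]
            break
    profile = np.column_stack([k_range, gaps, sks])
    return int(best), profile
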