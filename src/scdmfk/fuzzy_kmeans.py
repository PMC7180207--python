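"""Entropy-regularized fuzzy k-means with a robust adaptive distance.

The distance between an embedded cell z and a center mu is

    ||z - mu||_sigma = (1 + sigma) * d^2 / (d + sigma),   d = ||z - mu||_2,

which interpolates between the Euclidean distance (sigma -> 0) and the
squared Euclidean distance (sigma -> infinity); sigma trades off robustness
to outliers.  Soft memberships minimize the weighted-distance objective
plus a lambda-scaled entropy penalty and therefore have the closed form

    w_ij = softmax_j(-||z_i - mu_j||_sigma / lambda),

computed with max-subtraction stabilization.  The clustering loss treats w
as a fixed coefficient (it is recomputed from the current embedding and
centers at every step, not optimized through).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "ClusterState",
    "adaptive_distance",
    "pairwise_distance",
    "sigma_transform",
    "soft_assign",
    "clustering_loss",
    "init_centers",
    "hard_labels",
]


def sigma_transform(d: np.ndarray, sigma: float) -> np.ndarray:
    """Apply the robust transform (1+sigma) d^2 / (d + sigma) elementwise."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    d = np.asarray(d, dtype=np.float64)
    return (1.0 + sigma) * d * d / (d + sigma)


def adaptive_distance(z: np.ndarray, mu: np.ndarray, sigma: float) -> float:
    """Robust sigma-distance between two vectors; 0 iff z == mu."""
    z = np.asarray(z, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    if z.shape != mu.shape:
        raise ValueError(f"shape mismatch: {z.shape} vs {mu.shape}")
    d = float(np.linalg.norm(z - mu))
    return float(sigma_transform(d, sigma))


def pairwise_distance(Z: np.ndarray, centers: np.ndarray, sigma: float) -> np.ndarray:
    """(n_cells x K) matrix of sigma-distances."""
    Z = np.asarray(Z, dtype=np.float64)
    centers = np.asarray(centers, dtype=np.float64)
    diff = Z[:, None, :] - centers[None, :, :]
    d = np.sqrt(np.maximum((diff * diff).sum(axis=2), 0.0))
    return sigma_transform(d, sigma)


@dataclass
class ClusterState:
    """Centers, soft memberships, and the (sigma, lambda, K) hyperparameters."""

    centers: np.ndarray  # K x latent_dim
    sigma: float = 1.0
    lam: float = 1.0
    memberships: np.ndarray = field(default=None)  # cells x K

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.centers.ndim != 2:
            raise ValueError("centers must be a K x latent_dim matrix")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("centers must be finite")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.lam <= 0:
            raise ValueError(f"lambda must be > 0, got {self.lam}")

    @property
    def K(self) -> int:
        return self.centers.shape[0]


def soft_assign(
    Z: np.ndarray, centers: np.ndarray, sigma: float = 1.0, lam: float = 1.0
) -> np.ndarray:
    """Closed-form memberships w_ij = softmax_j(-dist_sigma(z_i, mu_j)/lambda).

    Stabilized by subtracting the row-minimum distance before
    exponentiation, so extreme distances or tiny lambda never overflow.
    """
    Z = np.asarray(Z, dtype=np.float64)
    if not np.all(np.isfinite(Z)):
        raise ValueError("non-finite entries in embedding")
    if lam <= 0:
        raise ValueError(f"lambda must be > 0, got {lam}")
    dist = pairwise_distance(Z, centers, sigma)
    scaled = -dist / lam
    scaled -= scaled.max(axis=1, keepdims=True)
    w = np.exp(scaled)
    w /= w.sum(axis=1, keepdims=True)
    return w


def clustering_loss(Z: np.ndarray, state: ClusterState) -> float:
    """Batch-mean of sum_j w_ij ||z_i - mu_j||_sigma with w from soft_assign."""
    Z = np.asarray(Z, dtype=np.float64)
    if Z.shape[1] != state.centers.shape[1]:
        raise ValueError(
            f"embedding dim {Z.shape[1]} != center dim {state.centers.shape[1]}"
        )
    dist = pairwise_distance(Z, state.centers, state.sigma)
    w = soft_assign(Z, state.centers, state.sigma, state.lam)
    state.memberships = w
    return float((w * dist).sum(axis=1).mean())


def init_centers(Z: np.ndarray, K: int, seed: int = 0) -> np.ndarray:
    """Standard k-means centers in the latent space (k-means++, 20 restarts)."""
    Z = np.asarray(Z, dtype=np.float64)
    if K > Z.shape[0]:
        raise ValueError(f"K={K} exceeds number of cells {Z.shape[0]}")
    if K == 1:
        return Z.mean(axis=0, keepdims=True)
    km = KMeans(n_clusters=K, n_init=20, max_iter=300, random_state=seed)
    km.fit(Z)
    return km.cluster_centers_.astype(np.float64)


def hard_labels(memberships: np.ndarray) -> np.ndarray:
    """Per-row argmax; ties go to the lowest cluster index."""
    return np.argmax(np.asarray(memberships), axis=1)
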