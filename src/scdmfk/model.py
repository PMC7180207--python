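"""Denoising autoencoder with a multinomial reconstruction likelihood.

Each cell's UMI counts X_i are modeled as n_i multinomial draws over the
selected genes with cell-specific simplex probabilities p_i.  The encoder
maps the z-scored input to a latent embedding Z; the decoder maps Z back
to a hidden representation from which two heads estimate

* ``pi`` = sigmoid(...)  — per-entry dropout-retention probabilities, and
* ``V``  = exp(...)      — expected relative expression (positive),

combined as p_ij = pi_ij V_ij / sum_j pi_ij V_ij (the ``standard``
variant).  The ``direct`` variant replaces the two heads with a single
softmax head that outputs p directly, which can work better when the
zero fraction of the data is moderate.  The reconstruction loss L1 is the
multinomial negative log-likelihood -sum_ij X_ij log p_ij (the count-only
part; the multinomial coefficient is constant in p), averaged over the
cells in the batch.

The network is implemented directly on NumPy arrays with hand-derived
backpropagation and an Adam optimizer; gradients are validated against
finite differences in the test suite.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np

from .data_io import ValidationError

__all__ = [
    "ModelConfig",
    "ModelState",
    "build_model",
    "compose_p",
    "multinomial_nll",
    "EPS",
]

#: floor added inside every log and to normalization denominators
EPS = 1e-10
#: clip on the exp-head preactivation (exp(30) ~ 1e13 keeps float32 finite)
_EXP_CLIP = 30.0

_ACTIVATIONS = {
    "relu": (lambda s: np.maximum(s, 0.0), lambda s: (s > 0).astype(s.dtype)),
    "sigmoid": (
        lambda s: 1.0 / (1.0 + np.exp(-s)),
        lambda s: (1.0 / (1.0 + np.exp(-s))) * (1.0 - 1.0 / (1.0 + np.exp(-s))),
    ),
    "tanh": (np.tanh, lambda s: 1.0 - np.tanh(s) ** 2),
}


@dataclass
class ModelConfig:
    """Topology and optimization settings.

    The decoder always mirrors the encoder ("reverse structure"), so only
    encoder widths are given.  Defaults: hidden sizes 256 and 64, a
    32-dimensional latent space, Adam with learning rate 1e-4, minibatches
    of 256 cells, and a 1000-epoch likelihood-only pretraining phase.
    """

    encoder_sizes: Tuple[int, ...] = (256, 64)
    latent_dim: int = 32
    variant: str = "standard"  # or "direct"
    hidden_activation: str = "relu"
    alpha: float = 1.0
    learning_rate: float = 1e-4
    batch_size: int = 256
    pretrain_epochs: int = 1000
    seed: int = 0
    head_bias: bool = True
    dtype: str = "float32"

    def __post_init__(self) -> None:
        self.encoder_sizes = tuple(int(s) for s in self.encoder_sizes)
        if self.variant not in ("standard", "direct"):
            raise ValueError(f"unknown variant: {self.variant!r}")
        if self.hidden_activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation: {self.hidden_activation!r}")
        if not self.encoder_sizes:
            raise ValueError("encoder_sizes must be non-empty")
        if any(s < 1 for s in self.encoder_sizes):
            raise ValueError("encoder widths must be positive")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be positive")
        if self.latent_dim >= min(self.encoder_sizes):
            raise ValueError(
                f"latent_dim {self.latent_dim} must be smaller than the "
                f"narrowest hidden layer {min(self.encoder_sizes)}"
            )
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("invalid optimizer settings")

    @property
    def decoder_sizes(self) -> Tuple[int, ...]:
        return tuple(reversed(self.encoder_sizes))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype)


class ModelState:
    """Learnable parameters plus Adam state; see :func:`build_model`."""

    def __init__(self, config: ModelConfig, n_genes: int):
        if n_genes < config.latent_dim:
            raise ValueError(
                f"n_genes={n_genes} smaller than latent_dim={config.latent_dim}"
            )
        self.config = config
        self.n_genes = int(n_genes)
        self.dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(config.seed)
        self.params: Dict[str, np.ndarray] = {}
        dt = self.dtype

        widths = [n_genes, *config.encoder_sizes]
        for i in range(len(config.encoder_sizes)):
            self.params[f"enc{i}_W"] = _glorot(rng, widths[i], widths[i + 1], dt)
            self.params[f"enc{i}_b"] = np.zeros(widths[i + 1], dtype=dt)
        self.params["lat_W"] = _glorot(rng, widths[-1], config.latent_dim, dt)
        self.params["lat_b"] = np.zeros(config.latent_dim, dtype=dt)
        dwidths = [config.latent_dim, *config.decoder_sizes]
        for i in range(len(config.decoder_sizes)):
            self.params[f"dec{i}_W"] = _glorot(rng, dwidths[i], dwidths[i + 1], dt)
            self.params[f"dec{i}_b"] = np.zeros(dwidths[i + 1], dtype=dt)
        top = dwidths[-1]
        if config.variant == "standard":
            self.params["pi_W"] = _glorot(rng, top, n_genes, dt)
            self.params["v_W"] = _glorot(rng, top, n_genes, dt)
            if config.head_bias:
                self.params["pi_b"] = np.zeros(n_genes, dtype=dt)
                self.params["v_b"] = np.zeros(n_genes, dtype=dt)
        else:
            self.params["p_W"] = _glorot(rng, top, n_genes, dt)
            if config.head_bias:
                self.params["p_b"] = np.zeros(n_genes, dtype=dt)

        # Adam state
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward passes --------------------------------------------------------
    def _act(self):
        return _ACTIVATIONS[self.config.hidden_activation]

    def _encode(self, X: np.ndarray, cache: Optional[dict] = None) -> np.ndarray:
        act, _ = self._act()
        a = np.asarray(X, dtype=self.dtype)
        acts = [a]
        pre = []
        for i in range(len(self.config.encoder_sizes)):
            s = a @ self.params[f"enc{i}_W"] + self.params[f"enc{i}_b"]
            pre.append(s)
            a = act(s)
            acts.append(a)
        z = a @ self.params["lat_W"] + self.params["lat_b"]
        if cache is not None:
            cache["enc_pre"] = pre
            cache["enc_acts"] = acts
        return z

    def _decode(self, z: np.ndarray, cache: Optional[dict] = None) -> np.ndarray:
        act, _ = self._act()
        a = z
        acts = [a]
        pre = []
        for i in range(len(self.config.decoder_sizes)):
            s = a @ self.params[f"dec{i}_W"] + self.params[f"dec{i}_b"]
            pre.append(s)
            a = act(s)
            acts.append(a)
        if cache is not None:
            cache["dec_pre"] = pre
            cache["dec_acts"] = acts
        return a

    def latent(self, X: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        """Latent embedding Z for the given input rows (deterministic)."""
        X = np.asarray(X, dtype=self.dtype)
        out = [
            self._encode(X[i : i + batch_size])
            for i in range(0, X.shape[0], batch_size)
        ]
        return np.concatenate(out, axis=0) if out else np.zeros((0, self.config.latent_dim))

    def heads(self, X: np.ndarray) -> Dict[str, np.ndarray]:
        """Forward pass returning the reconstruction heads.

        For the standard variant: ``pi`` (in (0,1)), ``V`` (positive) and the
        composed simplex rows ``p``; for the direct variant only ``p``.
        """
        cache: dict = {}
        z = self._encode(X, cache)
        h = self._decode(z, cache)
        out: Dict[str, np.ndarray] = {"z": z}
        if self.config.variant == "standard":
            a_pi = h @ self.params["pi_W"]
            a_v = h @ self.params["v_W"]
            if self.config.head_bias:
                a_pi = a_pi + self.params["pi_b"]
                a_v = a_v + self.params["v_b"]
            a_v = np.clip(a_v, -_EXP_CLIP, _EXP_CLIP)
            pi = 1.0 / (1.0 + np.exp(-a_pi))
            V = np.exp(a_v)
            out.update(pi=pi, V=V, p=compose_p(pi, V))
        else:
            a_p = h @ self.params["p_W"]
            if self.config.head_bias:
                a_p = a_p + self.params["p_b"]
            a_p = a_p - a_p.max(axis=1, keepdims=True)
            e = np.exp(a_p)
            out["p"] = e / e.sum(axis=1, keepdims=True)
        return out

    # -- loss + gradients ------------------------------------------------------
    def loss_and_grads(
        self,
        x_input: np.ndarray,
        raw_counts: np.ndarray,
        centers: Optional[np.ndarray] = None,
        alpha: float = 0.0,
        sigma: float = 1.0,
        lam: float = 1.0,
    ) -> Tuple[float, float, Dict[str, np.ndarray], Optional[np.ndarray]]:
        """Compute (L1, L2, parameter gradients, center gradient) for a batch.

        L2 uses memberships recomputed in closed form from the current batch
        embedding and centers and treated as constants; gradients flow through
        the sigma-distance into both the encoder weights and the centers.
        """
        from . import fuzzy_kmeans as fk

        X = np.asarray(x_input, dtype=self.dtype)
        raw = np.asarray(raw_counts)
        if raw.min() < 0:
            raise ValidationError("negative counts in reconstruction target")
        raw = raw.astype(self.dtype)
        B = X.shape[0]
        _, dact = self._act()

        cache: dict = {}
        z = self._encode(X, cache)
        h = self._decode(z, cache)

        grads: Dict[str, np.ndarray] = {}
        n_i = raw.sum(axis=1, dtype=np.float64).astype(self.dtype)

        if self.config.variant == "standard":
            a_pi = h @ self.params["pi_W"]
            a_v = h @ self.params["v_W"]
            if self.config.head_bias:
                a_pi = a_pi + self.params["pi_b"]
                a_v = a_v + self.params["v_b"]
            clip_mask = np.abs(a_v) < _EXP_CLIP
            np.clip(a_v, -_EXP_CLIP, _EXP_CLIP, out=a_v)
            pi = 1.0 / (1.0 + np.exp(-a_pi))
            V = np.exp(a_v)
            num = pi * V
            S = num.sum(axis=1) + EPS
            L1 = float(
                -(raw * (np.log(num + EPS) - np.log(S)[:, None])).sum(dtype=np.float64) / B
            )
            g_num = ((n_i / S)[:, None] - raw / (num + EPS)) / B
            g_a_pi = g_num * num * (1.0 - pi)
            g_a_v = g_num * num
            g_a_v[~clip_mask] = 0.0
            grads["pi_W"] = h.T @ g_a_pi
            grads["v_W"] = h.T @ g_a_v
            if self.config.head_bias:
                grads["pi_b"] = g_a_pi.sum(axis=0)
                grads["v_b"] = g_a_v.sum(axis=0)
            g_h = g_a_pi @ self.params["pi_W"].T + g_a_v @ self.params["v_W"].T
        else:
            a_p = h @ self.params["p_W"]
            if self.config.head_bias:
                a_p = a_p + self.params["p_b"]
            a_p -= a_p.max(axis=1, keepdims=True)
            e = np.exp(a_p)
            p = e / e.sum(axis=1, keepdims=True)
            L1 = float(-(raw * np.log(p + EPS)).sum(dtype=np.float64) / B)
            g_a_p = (p * n_i[:, None] - raw) / B
            grads["p_W"] = h.T @ g_a_p
            if self.config.head_bias:
                grads["p_b"] = g_a_p.sum(axis=0)
            g_h = g_a_p @ self.params["p_W"].T

        # clustering loss and its gradient at z
        L2 = 0.0
        g_centers: Optional[np.ndarray] = None
        g_z_cluster = 0.0
        if centers is not None and alpha > 0:
            z64 = np.asarray(z, dtype=np.float64)
            mu = np.asarray(centers, dtype=np.float64)
            diff = z64[:, None, :] - mu[None, :, :]  # B x K x d
            d = np.sqrt(np.maximum((diff * diff).sum(axis=2), 0.0))
            dist = (1.0 + sigma) * d * d / (d + sigma)
            w = fk.soft_assign(z64, mu, sigma, lam)  # detached coefficients
            L2 = float((w * dist).sum(axis=1).mean())
            # d(dist)/dz = g'(d) * (z-mu)/d with g'(d)/d = (1+s)(d+2s)/(d+s)^2
            ratio = (1.0 + sigma) * (d + 2.0 * sigma) / (d + sigma) ** 2
            coeff = (alpha / B) * w * ratio  # B x K
            g_z_cluster = (coeff[:, :, None] * diff).sum(axis=1).astype(self.dtype)
            g_centers = -(coeff[:, :, None] * diff).sum(axis=0)

        # backprop decoder
        g = g_h
        for i in reversed(range(len(self.config.decoder_sizes))):
            g = g * dact(cache["dec_pre"][i])
            grads[f"dec{i}_W"] = cache["dec_acts"][i].T @ g
            grads[f"dec{i}_b"] = g.sum(axis=0)
            g = g @ self.params[f"dec{i}_W"].T

        g_z = g + g_z_cluster
        grads["lat_W"] = cache["enc_acts"][-1].T @ g_z
        grads["lat_b"] = g_z.sum(axis=0)
        g = g_z @ self.params["lat_W"].T
        for i in reversed(range(len(self.config.encoder_sizes))):
            g = g * dact(cache["enc_pre"][i])
            grads[f"enc{i}_W"] = cache["enc_acts"][i].T @ g
            grads[f"enc{i}_b"] = g.sum(axis=0)
            g = g @ self.params[f"enc{i}_W"].T

        return L1, L2, grads, g_centers

    def adam_step(
        self,
        grads: Dict[str, np.ndarray],
        extra: Optional[List[Tuple[np.ndarray, np.ndarray]]] = None,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        """One Adam update on the network parameters (and optional extra
        (param, grad) pairs such as the cluster centers, which share the
        optimizer and step counter)."""
        self._adam_t += 1
        t = self._adam_t
        lr = self.config.learning_rate
        corr = np.sqrt(1.0 - beta2**t) / (1.0 - beta1**t)
        for k, g in grads.items():
            m = self._adam_m[k]
            v = self._adam_v[k]
            m += (1.0 - beta1) * (g - m)
            v += (1.0 - beta2) * (g * g - v)
            self.params[k] -= (lr * corr) * m / (np.sqrt(v) + eps)
        if extra:
            if not hasattr(self, "_adam_extra"):
                self._adam_extra = [
                    (np.zeros_like(p), np.zeros_like(p)) for p, _ in extra
                ]
            for (p, g), (m, v) in zip(extra, self._adam_extra):
                m += (1.0 - beta1) * (g - m)
                v += (1.0 - beta2) * (g * g - v)
                p -= (lr * corr) * m / (np.sqrt(v) + eps)

    def reset_optimizer(self) -> None:
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        if hasattr(self, "_adam_extra"):
            del self._adam_extra

    # -- persistence -----------------------------------------------------------
    def save(self, path) -> None:
        """Save weights + config into a single zip container."""
        buf = io.BytesIO()
        np.savez(buf, **self.params)
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps({**asdict(self.config), "n_genes": self.n_genes}))
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "ModelState":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("config.json"))
            n_genes = meta.pop("n_genes")
            config = ModelConfig(**meta)
            with zf.open("weights.npz") as fh:
                weights = np.load(io.BytesIO(fh.read()))
                state = cls(config, n_genes)
                for k in state.params:
                    state.params[k] = weights[k]
        return state


def build_model(config: ModelConfig, n_genes: int) -> ModelState:
    """Construct a seeded model for ``n_genes`` input features."""
    return ModelState(config, n_genes)


def compose_p(pi: np.ndarray, V: np.ndarray) -> np.ndarray:
    """p_ij = pi_ij V_ij / sum_j pi_ij V_ij (rows on the simplex)."""
    pi = np.atleast_2d(np.asarray(pi, dtype=np.float64))
    V = np.atleast_2d(np.asarray(V, dtype=np.float64))
    if pi.shape != V.shape:
        raise ValueError(f"shape mismatch: {pi.shape} vs {V.shape}")
    num = pi * V
    denom = num.sum(axis=1, keepdims=True) + EPS
    if np.any(denom <= EPS):
        raise FloatingPointError("a row of pi*V underflowed to zero")
    return num / denom


def multinomial_nll(raw_counts: np.ndarray, p: np.ndarray) -> float:
    """Multinomial negative log-likelihood -sum X log(p), mean over cells.

    The multinomial coefficient (constant in p) is dropped.
    """
    X = np.atleast_2d(np.asarray(raw_counts, dtype=np.float64))
    p = np.atleast_2d(np.asarray(p, dtype=np.float64))
    if X.shape != p.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {p.shape}")
    if X.min() < 0:
        raise ValidationError("negative counts")
    return float(-(X * np.log(p + EPS)).sum() / X.shape[0])
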