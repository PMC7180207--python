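"""Multinomial heads, reconstruction loss, and backpropagation correctness."""

import numpy as np
import pytest
from scipy.optimize import minimize

from scdmfk.data_io import ValidationError
from scdmfk.fuzzy_kmeans import pairwise_distance, soft_assign
from scdmfk.model import EPS, ModelConfig, ModelState, build_model, compose_p, multinomial_nll


class TestComposeP:
    def test_uniform(self):
        m = 7
        p = compose_p(np.full((2, m), 0.5), np.ones((2, m)))
        np.testing.assert_allclose(p, 1.0 / m)

    def test_hand_value(self):
        p = compose_p([[0.5, 0.5]], [[2.0, 6.0]])
        np.testing.assert_allclose(p, [[0.25, 0.75]], atol=1e-9)

    def test_pi_near_one_limit(self):
        V = np.array([[3.0, 1.0, 6.0]])
        p = compose_p(np.full((1, 3), 1 - 1e-9), V)
        np.testing.assert_allclose(p, V / V.sum(), atol=1e-6)

    def test_rows_sum_to_one_random(self):
        rng = np.random.default_rng(0)
        pi = rng.uniform(0.01, 0.99, size=(20, 30))
        V = np.exp(rng.normal(size=(20, 30)))
        p = compose_p(pi, V)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p > 0)


class TestMultinomialNLL:
    def test_one_hot_uniform_closed_form(self):
        m = 8
        X = np.eye(m)[:3]
        p = np.full((3, m), 1.0 / m)
        assert multinomial_nll(X, p) == pytest.approx(np.log(m), rel=1e-6)

    def test_hand_value(self):
        X = [[2, 1, 1]]
        p = [[0.5, 0.3, 0.2]]
        expected = -(2 * np.log(0.5) + np.log(0.3) + np.log(0.2))
        assert multinomial_nll(X, p) == pytest.approx(expected, rel=1e-7)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            multinomial_nll([[-1, 2]], [[0.5, 0.5]])

    def test_empirical_proportions_are_mle(self):
        """X/n minimizes the loss over the simplex (numeric optimizer check)."""
        X = np.array([5.0, 2.0, 1.0, 0.0])
        n = X.sum()

        def nll(q3):
            q = np.concatenate([q3, [1.0 - q3.sum()]])
            return -(X * np.log(q + EPS)).sum()

        res = minimize(
            nll,
            np.array([0.25, 0.25, 0.25]),
            bounds=[(1e-6, 1.0)] * 3,
            constraints=[{"type": "ineq", "fun": lambda q: 1.0 - q.sum() - 1e-6}],
            method="SLSQP",
        )
        assert res.success
        np.testing.assert_allclose(res.x, (X / n)[:3], atol=1e-4)
        # and random distributions never beat the empirical one
        rng = np.random.default_rng(1)
        base = multinomial_nll(X[None], (X / n)[None] + EPS)
        for q in rng.dirichlet(np.ones(4), size=50):
            assert multinomial_nll(X[None], q[None]) >= base - 1e-9


class TestBuildModel:
    def test_default_layer_widths(self):
        model = build_model(ModelConfig(seed=0), n_genes=500)
        assert model.params["enc0_W"].shape == (500, 256)
        assert model.params["enc1_W"].shape == (256, 64)
        assert model.params["lat_W"].shape == (64, 32)
        assert model.params["dec0_W"].shape == (32, 64)
        assert model.params["dec1_W"].shape == (64, 256)
        assert model.params["pi_W"].shape == (256, 500)
        assert model.params["v_W"].shape == (256, 500)

    def test_direct_head_rows_on_simplex(self):
        model = build_model(ModelConfig(seed=1, variant="direct"), n_genes=40)
        X = np.random.default_rng(2).normal(size=(6, 40))
        out = model.heads(X)
        np.testing.assert_allclose(out["p"].sum(axis=1), 1.0, atol=1e-6)
        assert np.all(out["p"] > 0)
        assert "pi" not in out

    def test_standard_head_ranges(self):
        model = build_model(ModelConfig(seed=1), n_genes=40)
        X = np.random.default_rng(2).normal(size=(6, 40))
        out = model.heads(X)
        assert np.all((out["pi"] > 0) & (out["pi"] < 1))
        assert np.all(out["V"] > 0)
        np.testing.assert_allclose(out["p"].sum(axis=1), 1.0, atol=1e-6)

    def test_seed_determinism(self):
        X = np.random.default_rng(3).normal(size=(5, 40))
        out = [
            build_model(ModelConfig(seed=11), n_genes=40).heads(X)["p"]
            for _ in range(2)
        ]
        np.testing.assert_array_equal(out[0], out[1])

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            ModelConfig(latent_dim=64, encoder_sizes=(256, 64))
        with pytest.raises(ValueError):
            build_model(ModelConfig(), n_genes=16)  # smaller than latent_dim


def _logsumexp_potential(z, centers, sigma, lam):
    """-lam * log sum_k exp(-dist_sigma/lam), averaged over cells.

    By the envelope theorem its gradient equals the semi-gradient of the
    clustering loss with memberships held fixed at their closed-form values,
    which is exactly what training backpropagates.
    """
    dist = pairwise_distance(z, centers, sigma)
    a = -dist / lam
    amax = a.max(axis=1, keepdims=True)
    return float((-lam * (amax[:, 0] + np.log(np.exp(a - amax).sum(axis=1)))).mean())


@pytest.mark.parametrize("variant", ["standard", "direct"])
def test_gradients_match_finite_differences(variant):
    """Analytic backprop equals numeric differentiation of L1 + alpha*Phi."""
    rng = np.random.default_rng(0)
    config = ModelConfig(
        encoder_sizes=(10, 8),
        latent_dim=4,
        variant=variant,
        dtype="float64",
        seed=5,
    )
    model = build_model(config, n_genes=12)
    B = 5
    X = rng.normal(size=(B, 12))
    raw = rng.poisson(3.0, size=(B, 12)).astype(float)
    centers = rng.normal(size=(3, 4))
    alpha, sigma, lam = 0.7, 1.4, 0.6

    L1, L2, grads, g_centers = model.loss_and_grads(
        X, raw, centers=centers, alpha=alpha, sigma=sigma, lam=lam
    )

    def total_loss():
        l1, _, _, _ = model.loss_and_grads(X, raw)
        z = model.latent(X)
        return l1 + alpha * _logsumexp_potential(z, centers, sigma, lam)

    h = 1e-6
    for name in ["enc0_W", "lat_W", "dec1_W", list(grads)[0]]:
        W = model.params[name]
        idx = tuple(rng.integers(0, s) for s in W.shape)
        orig = W[idx]
        W[idx] = orig + h
        up = total_loss()
        W[idx] = orig - h
        down = total_loss()
        W[idx] = orig
        numeric = (up - down) / (2 * h)
        assert grads[name][idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7), name

    # centers gradient
    for idx in [(0, 0), (2, 3)]:
        orig = centers[idx]

        def phi():
            z = model.latent(X)
            return alpha * _logsumexp_potential(z, centers, sigma, lam)

        centers[idx] = orig + h
        up = phi()
        centers[idx] = orig - h
        down = phi()
        centers[idx] = orig
        numeric = (up - down) / (2 * h)
        assert g_centers[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7)


def test_memberships_detached_from_gradient():
    """The clustering semi-gradient treats w as a constant coefficient: at a
    point where all centers are equidistant, the center gradients are exactly
    opposite, not perturbed by membership sensitivity."""
    config = ModelConfig(encoder_sizes=(6, 5), latent_dim=2, dtype="float64", seed=0)
    model = build_model(config, n_genes=8)
    X = np.random.default_rng(1).normal(size=(1, 8))
    raw = np.ones((1, 8))
    z = model.latent(X)[0]
    centers = np.stack([z + [1.0, 0.0], z - [1.0, 0.0]])
    _, _, _, g_centers = model.loss_and_grads(
        X, raw, centers=centers, alpha=1.0, sigma=1.0, lam=1.0
    )
    np.testing.assert_allclose(g_centers[0], -g_centers[1], atol=1e-10)


def test_save_load_roundtrip(tmp_path):
    model = build_model(ModelConfig(seed=4, encoder_sizes=(16, 12), latent_dim=5), 20)
    X = np.random.default_rng(0).normal(size=(3, 20))
    before = model.heads(X)["p"]
    path = tmp_path / "model.scdmfk"
    model.save(path)
    loaded = ModelState.load(path)
    np.testing.assert_array_equal(loaded.heads(X)["p"], before)
    assert loaded.config.encoder_sizes == (16, 12)
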