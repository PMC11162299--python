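import numpy as np
import pytest

from hgcomplex.hgvae import (
    HGVAE,
    HGVAEConfig,
    decode,
    elbo_loss,
    hgnn_layer,
    hyperedge_pool,
    kl_divergence,
    load_hgvae,
    reparameterize,
    save_hgvae,
    train_hgvae,
)
from hgcomplex.hypergraph import build_hypergraph
from hgcomplex.io import InteractionNetwork

from conftest import random_network


def toy_hypergraph(rng, n=8, p=0.45, d_features=6):
    net = random_network(rng, n, p)
    X = rng.random((n, d_features))
    return build_hypergraph(net, X=X, min_size=2)


class TestHgnnLayer:
    def test_identity_propagation_identity_weights(self, rng):
        X = rng.random((5, 4))
        out = hgnn_layer(X, np.eye(5), np.eye(4))
        np.testing.assert_allclose(out, X)

    def test_zero_weights_give_zero(self, rng):
        X = rng.random((5, 4))
        assert not hgnn_layer(X, np.eye(5), np.zeros((4, 3))).any()

    def test_explicit_matrix_product_oracle(self, rng):
        X = rng.standard_normal((3, 4))
        A = rng.random((3, 3))
        theta = rng.standard_normal((4, 2))
        expected = np.maximum(A.dot(X).dot(theta), 0)
        np.testing.assert_allclose(hgnn_layer(X, A, theta), expected, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            hgnn_layer(rng.random((3, 4)), np.eye(3), rng.random((5, 2)))


class TestReparameterize:
    def test_zero_variance_limit_returns_mu(self, rng):
        mu = rng.standard_normal((4, 3))
        z = reparameterize(mu, np.full((4, 3), -700.0), seed=0)
        np.testing.assert_allclose(z, mu)

    def test_fixed_seed_reproducible(self, rng):
        mu, lv = rng.standard_normal((4, 3)), rng.standard_normal((4, 3))
        np.testing.assert_array_equal(
            reparameterize(mu, lv, seed=42), reparameterize(mu, lv, seed=42)
        )

    def test_monte_carlo_mean_matches_mu(self):
        # E[z] = mu; check within 4 standard errors over 1e5 draws
        mu = np.array([[0.7, -1.2]])
        lv = np.array([[0.4, -0.3]])
        rng = np.random.default_rng(0)
        draws = np.stack(
            [reparameterize(mu, lv, seed=rng)[0] for _ in range(100_000)]
        )
        se = np.exp(0.5 * lv[0]) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - mu[0]) < 4 * se)


class TestHyperedgePool:
    def _proj(self, rng, d, p=5):
        return {
            "P1": rng.standard_normal((d, p)) * 0.3,
            "bp1": rng.standard_normal(p) * 0.1,
            "P2": rng.standard_normal((p, 1)) * 0.3,
            "bp2": rng.standard_normal(1) * 0.1,
        }

    def test_singleton_hyperedge(self, rng):
        net = InteractionNetwork(nodes=["a", "b"], edges=set())
        hg = build_hypergraph(net, min_size=3)  # two singletons
        z = rng.standard_normal((2, 4))
        embed, att = hyperedge_pool(z, hg, self._proj(rng, 4))
        for a in att:
            np.testing.assert_allclose(a, [1.0])
        np.testing.assert_allclose(embed, np.where(z > 0, z, 0.01 * z), atol=1e-12)

    def test_identical_latents_give_uniform_attention(self, rng):
        net = InteractionNetwork(
            nodes=["a", "b", "c"], edges={("a", "b"), ("a", "c"), ("b", "c")}
        )
        hg = build_hypergraph(net, min_size=3)
        z = np.tile(rng.standard_normal(4), (3, 1))
        _, att = hyperedge_pool(z, hg, self._proj(rng, 4))
        np.testing.assert_allclose(att[0], np.full(3, 1 / 3), atol=1e-12)

    def test_hand_unrolled_three_member_edge(self, rng):
        net = InteractionNetwork(
            nodes=["a", "b", "c"], edges={("a", "b"), ("a", "c"), ("b", "c")}
        )
        hg = build_hypergraph(net, min_size=3)
        z = rng.standard_normal((3, 4))
        proj = self._proj(rng, 4)
        embed, att = hyperedge_pool(z, hg, proj)

        def leaky(x):
            return np.where(x > 0, x, 0.01 * x)

        scores = []
        for i in range(3):
            h = leaky(z[i] @ proj["P1"] + proj["bp1"])
            scores.append(float(leaky(h @ proj["P2"] + proj["bp2"])[0]))
        ex = np.exp(np.array(scores) - max(scores))
        w = ex / ex.sum()
        e_hand = leaky((w[:, None] * z).sum(axis=0))
        np.testing.assert_allclose(att[0], w, atol=1e-12)
        np.testing.assert_allclose(embed[0], e_hand, atol=1e-12)

    def test_attention_sums_to_one(self, rng):
        hg = toy_hypergraph(rng, n=12)
        z = rng.standard_normal((12, 5))
        _, att = hyperedge_pool(z, hg, self._proj(rng, 5))
        for a in att:
            assert np.all(a >= 0)
            assert abs(a.sum() - 1.0) < 1e-6


class TestDecode:
    def test_orthogonal_gives_half(self):
        z = np.array([[1.0, 0.0]])
        e = np.array([[0.0, 1.0]])
        assert decode(z, e)[0, 0] == pytest.approx(0.5)

    def test_large_aligned_scale_saturates(self):
        z = np.array([[1000.0, 0.0]])
        e = np.array([[1.0, 0.0]])
        assert decode(z, e)[0, 0] == pytest.approx(1.0)

    def test_double_loop_sigmoid_oracle(self, rng):
        z = rng.standard_normal((6, 3))
        e = rng.standard_normal((4, 3))
        H_hat = decode(z, e)
        for i in range(6):
            for j in range(4):
                expected = 1.0 / (1.0 + np.exp(-float(z[i] @ e[j])))
                assert H_hat[i, j] == pytest.approx(expected, abs=1e-12)


class TestElboLoss:
    def test_kl_zero_at_standard_normal_posterior(self, rng):
        mu = np.zeros((5, 3))
        lv = np.zeros((5, 3))
        assert kl_divergence(mu, lv) == pytest.approx(0.0)
        H = rng.integers(0, 2, (5, 4)).astype(float)
        eps = 1e-7
        H_hat = np.where(H > 0, 1 - eps, eps)
        assert elbo_loss(H, H_hat, mu, lv) == pytest.approx(0.0, abs=1e-5)

    def test_elementwise_oracle(self, rng):
        H = rng.integers(0, 2, (4, 3)).astype(float)
        H_hat = rng.uniform(0.05, 0.95, (4, 3))
        mu = rng.standard_normal((4, 2))
        lv = rng.standard_normal((4, 2))
        pw = 2.5
        # element-wise summation oracle
        rec = 0.0
        for i in range(4):
            for j in range(3):
                rec -= pw * H[i, j] * np.log(H_hat[i, j]) + (1 - H[i, j]) * np.log(
                    1 - H_hat[i, j]
                )
        rec /= H.size
        kl = 0.0
        for i in range(4):
            for j in range(2):
                kl += 0.5 * (
                    mu[i, j] ** 2 + np.exp(lv[i, j]) - 1.0 - lv[i, j]
                )
        kl /= 4
        assert elbo_loss(H, H_hat, mu, lv, pos_weight=pw) == pytest.approx(
            rec + kl, abs=1e-8
        )

    def test_kl_matches_monte_carlo_estimate(self):
        # KL(q||p) = E_q[log q - log p]; MC estimate within 3 SE
        rng = np.random.default_rng(3)
        mu = rng.standard_normal((2, 2)) * 0.5
        lv = rng.standard_normal((2, 2)) * 0.5
        sig = np.exp(0.5 * lv)
        n_draws = 200_000
        eps = rng.standard_normal((n_draws, 2, 2))
        z = mu + sig * eps
        log_q = -0.5 * (np.log(2 * np.pi) + lv + eps**2)
        log_p = -0.5 * (np.log(2 * np.pi) + z**2)
        samples = (log_q - log_p).sum(axis=(1, 2)) / 2  # per-node average
        mc = samples.mean()
        se = samples.std(ddof=1) / np.sqrt(n_draws)
        assert abs(kl_divergence(mu, lv) - mc) < 3 * se


class TestGradients:
    """Hand-derived backprop vs central finite differences."""

    def _check(self, config, hg, tol=2e-5):
        model = HGVAE(config)
        n = hg.n_nodes
        rng = np.random.default_rng(99)
        X = hg.X if config.feature_mode == "ct" else np.eye(n)
        if config.propagation == "identity":
            A = np.eye(n)
        else:
            from hgcomplex.hypergraph import propagation_operator

            A = propagation_operator(hg)
        if config.decoder == "hyperedge":
            target = hg.H
            node_idx, edge_idx = hg.memberships()
            counts = hg.H.sum(axis=0).astype(int)
            starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
            memb = (node_idx, edge_idx, starts, counts)
        else:
            target = (hg.H @ hg.H.T > 0).astype(float)
            np.fill_diagonal(target, 1.0)
            memb = None
        eps = rng.standard_normal((n, config.latent_dim))
        pw = 1.7

        _, grads = model._forward_backward(A, X, target, eps, memb, pw)

        h = 1e-6
        for key, param in model.params.items():
            flat = param.ravel()
            idx = rng.choice(flat.size, size=min(6, flat.size), replace=False)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + h
                lp, _ = model._forward_backward(A, X, target, eps, memb, pw)
                flat[i] = orig - h
                lm, _ = model._forward_backward(A, X, target, eps, memb, pw)
                flat[i] = orig
                numeric = (lp - lm) / (2 * h)
                analytic = grads[key].ravel()[i]
                assert analytic == pytest.approx(numeric, abs=tol, rel=1e-3), key

    def test_hyperedge_decoder_gradients(self, rng):
        hg = toy_hypergraph(rng, n=7, d_features=5)
        cfg = HGVAEConfig(
            input_dim=5, hidden_dim=6, latent_dim=4, proj_dim=3, seed=1
        )
        self._check(cfg, hg)

    def test_adjacency_decoder_gradients(self, rng):
        hg = toy_hypergraph(rng, n=7, d_features=5)
        cfg = HGVAEConfig(
            input_dim=5, hidden_dim=6, latent_dim=4, seed=1, decoder="adjacency"
        )
        self._check(cfg, hg)

    def test_identity_propagation_gradients(self, rng):
        hg = toy_hypergraph(rng, n=6, d_features=4)
        cfg = HGVAEConfig(
            input_dim=4, hidden_dim=5, latent_dim=3, proj_dim=3, seed=2,
            propagation="identity",
        )
        self._check(cfg, hg)


class TestTraining:
    def test_loss_decreases_on_toy_hypergraph(self, rng):
        hg = toy_hypergraph(rng, n=12, d_features=6)
        cfg = HGVAEConfig(
            input_dim=6, hidden_dim=16, latent_dim=8, epochs=200, seed=0
        )
        model, latent = train_hgvae(hg, cfg)
        assert model.loss_trace[-1] < model.loss_trace[0]
        assert latent.mu.shape == (12, 8)

    def test_fixed_seed_identical_trace(self, rng):
        hg = toy_hypergraph(rng, n=10, d_features=5)
        cfg = HGVAEConfig(input_dim=5, hidden_dim=8, latent_dim=4, epochs=30, seed=5)
        m1, _ = train_hgvae(hg, cfg)
        m2, _ = train_hgvae(hg, cfg)
        assert m1.loss_trace == m2.loss_trace

    def test_encode_deterministic(self, rng):
        hg = toy_hypergraph(rng, n=10, d_features=5)
        cfg = HGVAEConfig(input_dim=5, hidden_dim=8, latent_dim=4, epochs=10, seed=5)
        model, _ = train_hgvae(hg, cfg)
        from hgcomplex.hypergraph import propagation_operator

        A = propagation_operator(hg)
        mu1, lv1 = model.encode(A, hg.X)
        mu2, lv2 = model.encode(A, hg.X)
        np.testing.assert_array_equal(mu1, mu2)
        np.testing.assert_array_equal(lv1, lv2)

    def test_two_block_embedding_separation(self):
        # two planted cliques joined by one bridge edge; one-hot features
        nodes = [f"n{i}" for i in range(16)]
        edges = set()
        for block in (range(8), range(8, 16)):
            block = list(block)
            for i in range(len(block)):
                for j in range(i + 1, len(block)):
                    edges.add((nodes[block[i]], nodes[block[j]]))
        edges.add(("n0", "n8"))
        net = InteractionNetwork(nodes=nodes, edges=edges)
        hg = build_hypergraph(net, min_size=3)
        cfg = HGVAEConfig(
            input_dim=16, hidden_dim=16, latent_dim=8, epochs=200, seed=0,
            feature_mode="onehot",
        )
        _, latent = train_hgvae(hg, cfg)
        mu = latent.mu / np.linalg.norm(latent.mu, axis=1, keepdims=True)
        sim = mu @ mu.T
        within = np.concatenate(
            [sim[:8, :8][np.triu_indices(8, 1)], sim[8:, 8:][np.triu_indices(8, 1)]]
        )
        between = sim[:8, 8:].ravel()
        assert within.mean() > between.mean()

    def test_checkpoint_round_trip(self, rng, tmp_path):
        hg = toy_hypergraph(rng, n=8, d_features=5)
        cfg = HGVAEConfig(input_dim=5, hidden_dim=6, latent_dim=4, epochs=5, seed=3)
        model, _ = train_hgvae(hg, cfg)
        save_hgvae(model, hg.nodes, tmp_path / "ckpt")
        back = load_hgvae(tmp_path / "ckpt", nodes=hg.nodes)
        for k in model.params:
            np.testing.assert_array_equal(model.params[k], back.params[k])
        with pytest.raises(ValueError):
            load_hgvae(tmp_path / "ckpt", nodes=list(reversed(hg.nodes)))
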