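import numpy as np
import pytest

import protfuse as pf
from protfuse.config import TrainRun
from protfuse.graph_vae import (GaussianNodeLatent, VGAEParams, gcn_encode,
                                init_vgae, inner_product_decode, negative_sample,
                                normalized_adjacency, reconstruction_loss,
                                sample_latent, train_vgae)
from protfuse.residue_graph import ResidueGraph, build_residue_graph
from protfuse.nn import sigmoid


def path_graph(n, n_features=21, rng=None):
    X = np.zeros((n, n_features))
    for i in range(n):
        X[i, i % n_features] = 1.0
    edges = frozenset(frozenset((i, i + 1)) for i in range(n - 1))
    return ResidueGraph(node_features=X, edges=edges, n_nodes=n)


class TestGCNEncode:
    def test_zero_weights_give_zero_latent(self):
        g = path_graph(4)
        p = VGAEParams(np.zeros((21, 8)), np.zeros((8, 5)), np.zeros((8, 5)))
        lat = gcn_encode(g, p)
        assert not lat.mu.any() and not lat.logvar.any()

    def test_hand_computed_matrix_chain(self):
        # 4-node path, explicit A-hat chain computed element by element
        g = path_graph(4)
        rng = np.random.default_rng(0)
        p = VGAEParams(rng.normal(size=(21, 3)), rng.normal(size=(3, 2)),
                       rng.normal(size=(3, 2)))
        A = np.zeros((4, 4))
        for e in g.edges:
            i, j = tuple(e)
            A[i, j] = A[j, i] = 1.0
        A += np.eye(4)
        d = A.sum(1)
        a_hat = np.array([[A[i, j] / np.sqrt(d[i] * d[j]) for j in range(4)]
                          for i in range(4)])
        H1 = np.maximum(a_hat @ g.node_features @ p.W1, 0.0)
        mu_hand = a_hat @ H1 @ p.Wmu
        lat = gcn_encode(g, p)
        np.testing.assert_allclose(lat.mu, mu_hand, atol=1e-10)

    def test_permutation_equivariance(self, rng):
        g = build_residue_graph(pf.make_helix(12, 0.4, 3))
        p = init_vgae(hidden=16, latent=8, seed=0)
        lat = gcn_encode(g, p)
        perm = rng.permutation(g.n_nodes)
        inv = np.argsort(perm)
        edges_p = frozenset(frozenset((int(inv[i]), int(inv[j])))
                            for e in g.edges for i, j in [tuple(e)])
        gp = ResidueGraph(g.node_features[perm], edges_p, g.n_nodes)
        lat_p = gcn_encode(gp, p)
        np.testing.assert_allclose(lat_p.mu, lat.mu[perm], atol=1e-8)
        np.testing.assert_allclose(lat_p.logvar, lat.logvar[perm], atol=1e-8)


class TestSampleLatent:
    def test_vanishing_variance_returns_mu(self, rng):
        mu = rng.normal(size=(5, 4))
        lat = GaussianNodeLatent(mu, np.full((5, 4), -50.0))
        np.testing.assert_allclose(sample_latent(lat, 0), mu, atol=1e-8)

    def test_seeded_determinism(self, rng):
        lat = GaussianNodeLatent(rng.normal(size=(5, 4)), rng.normal(size=(5, 4)))
        assert np.array_equal(sample_latent(lat, 3), sample_latent(lat, 3))

    def test_monte_carlo_mean(self):
        lat = GaussianNodeLatent(np.array([[2.0]]), np.array([[np.log(4.0)]]))
        draws = np.array([sample_latent(lat, s)[0, 0] for s in range(10_000)])
        # sd = 2, so the mean of 1e4 draws is within 4*2/100 of mu
        assert abs(draws.mean() - 2.0) < 0.08


class TestInnerProductDecode:
    def test_orthogonal_vectors_give_half(self):
        Z = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert inner_product_decode(Z, [(0, 1)])[0] == pytest.approx(0.5)

    def test_log3_norm_gives_three_quarters(self):
        z = np.zeros((2, 4))
        z[0, 0] = z[1, 0] = np.sqrt(np.log(3.0))
        assert inner_product_decode(z, [(0, 1)])[0] == pytest.approx(0.75)

    def test_matches_scalar_loop_oracle(self, rng):
        Z = rng.normal(size=(10, 6))
        pairs = [(i, j) for i in range(10) for j in range(i + 1, 10)]
        p = inner_product_decode(Z, np.array(pairs))
        for val, (i, j) in zip(p, pairs):
            s = sum(Z[i, d] * Z[j, d] for d in range(6))
            assert val == pytest.approx(1.0 / (1.0 + np.exp(-s)), abs=1e-12)

    def test_out_of_range_pair(self):
        with pytest.raises(IndexError):
            inner_product_decode(np.zeros((3, 2)), [(0, 5)])


class TestNegativeSample:
    def test_complete_graph_has_no_negatives(self):
        g = path_graph(3)
        complete = ResidueGraph(g.node_features,
                                frozenset(frozenset(p) for p in [(0, 1), (1, 2), (0, 2)]), 3)
        with pytest.raises(ValueError):
            negative_sample(complete, 1, 0)

    def test_negatives_disjoint_from_edges(self):
        g = build_residue_graph(pf.make_helix(15, 0.3, 1))
        neg = negative_sample(g, len(g.edges), 5)
        assert len(neg) == len(g.edges)
        assert not (neg & g.edges)

    def test_seeded_determinism(self):
        g = path_graph(8)
        assert negative_sample(g, 5, 9) == negative_sample(g, 5, 9)


class TestReconstructionLoss:
    def test_closed_form_at_half(self):
        val = reconstruction_loss(np.full(2, 0.5), np.full(2, 0.5))
        assert val == pytest.approx(4 * np.log(2.0))

    def test_perfect_predictions_vanish(self):
        assert reconstruction_loss(np.array([1.0, 1.0]), np.array([0.0])) \
            == pytest.approx(0.0, abs=1e-9)

    def test_matches_scalar_loop_oracle(self, rng):
        p_pos, p_neg = rng.uniform(0.01, 0.99, 7), rng.uniform(0.01, 0.99, 5)
        expect = -sum(np.log(p) for p in p_pos) - sum(np.log(1 - p) for p in p_neg)
        assert reconstruction_loss(p_pos, p_neg) == pytest.approx(expect, abs=1e-10)


class TestTrainVGAE:
    @pytest.fixture(scope="class")
    def tiny_graphs(self):
        return [build_residue_graph(pf.make_helix(12, 0.3, s)) for s in range(4)]

    def test_seeded_runs_identical(self, tiny_graphs):
        cfg = TrainRun(epochs=2, seed=3)
        _, h1 = train_vgae(tiny_graphs, cfg, hidden=32, latent=16)
        _, h2 = train_vgae(tiny_graphs, cfg, hidden=32, latent=16)
        assert h1 == h2

    def test_loss_decreases(self, tiny_graphs):
        _, hist = train_vgae(tiny_graphs, TrainRun(epochs=15, seed=0),
                             hidden=64, latent=32)
        assert hist[-1] < hist[0]

    def test_memorization_single_graph(self):
        g = build_residue_graph(pf.make_helix(15, 0.3, 8))
        _, hist = train_vgae([g], TrainRun(epochs=200, seed=1, learning_rate=1e-2),
                             hidden=64, latent=32, edge_dropout=0.0)
        assert hist[-1] < 0.2 * hist[0]

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError):
            TrainRun(epochs=0)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_vgae([], TrainRun(epochs=1))
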