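"""Graph network forward semantics checked against dense-loop oracles and
symmetry properties."""

import numpy as np
import pytest

from evograph.graphnet import (
    ModelParameters,
    ProteinGraph,
    forward,
    gcn_layer,
    init_parameters,
    load_model,
    normalize_adjacency,
    relu,
    save_model,
    sigmoid,
)

from conftest import random_graph


def dense_forward_oracle(g, params):
    """Brute-force re-implementation of the forward pass with explicit loops."""
    p = params.arrays
    X = g.feature_array
    L = X.shape[0]
    outs = []
    for ch, A in (("evc", g.evc_array), ("rc", g.rc_array)):
        Ahat = A + np.eye(L)
        deg = Ahat.sum(axis=1)
        An = np.zeros((L, L))
        for i in range(L):
            for j in range(L):
                An[i, j] = Ahat[i, j] / np.sqrt(deg[i] * deg[j])
        H = X
        for k in (1, 2, 3):
            W, b = p[f"W_{ch}{k}"], p[f"b_{ch}{k}"]
            Z = np.zeros((L, W.shape[1]))
            for i in range(L):
                for o in range(W.shape[1]):
                    acc = 0.0
                    for j in range(L):
                        for d in range(W.shape[0]):
                            acc += An[i, j] * H[j, d] * W[d, o]
                    Z[i, o] = acc + b[o]
            H = np.maximum(Z, 0.0)
        outs.append(H)
    fmap = np.concatenate(outs, axis=1)
    pooled = fmap.sum(axis=0)
    h1 = np.maximum(pooled @ p["W_fc1"] + p["b_fc1"], 0.0)
    logits = h1 @ p["W_fc2"] + p["b_fc2"]
    return 1.0 / (1.0 + np.exp(-logits)), fmap


class TestNormalizeAdjacency:
    def test_zero_graph_gives_identity(self):
        out = normalize_adjacency(np.zeros((4, 4)))
        assert np.allclose(out.values, np.eye(4))

    def test_two_nodes_single_edge(self):
        out = normalize_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.allclose(out.values, 0.5 * np.ones((2, 2)))

    @pytest.mark.parametrize("seed", range(5))
    def test_unit_spectral_radius_bound(self, seed):
        rng = np.random.default_rng(seed)
        A = (rng.random((8, 8)) < 0.4).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        vals = np.linalg.eigvalsh(normalize_adjacency(A).values)
        assert np.max(np.abs(vals)) <= 1.0 + 1e-12


class TestGcnLayer:
    def test_identity_limit(self, rng):
        H = rng.standard_normal((5, 3))
        out = gcn_layer(np.abs(H), np.eye(5), np.eye(3))
        assert np.allclose(out, np.abs(H))

    def test_single_node_scalar(self):
        out = gcn_layer(np.array([[2.0]]), np.eye(1), np.array([[-3.0]]))
        assert out[0, 0] == 0.0  # ReLU(2 * -3)
        out = gcn_layer(np.array([[2.0]]), np.eye(1), np.array([[3.0]]))
        assert out[0, 0] == 6.0

    def test_matches_triple_loop_oracle(self, rng):
        L, d, do = 5, 4, 3
        A = normalize_adjacency((np.tri(L, L, -1).T + np.tri(L, L, -1)) > 0).values
        H = rng.standard_normal((L, d))
        W = rng.standard_normal((d, do))
        expected = np.zeros((L, do))
        for i in range(L):
            for o in range(do):
                for j in range(L):
                    for k in range(d):
                        expected[i, o] += A[i, j] * H[j, k] * W[k, o]
        assert np.allclose(gcn_layer(H, A, W), np.maximum(expected, 0), atol=1e-6)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            gcn_layer(rng.standard_normal((4, 3)), np.eye(4), rng.standard_normal((5, 2)))

    @pytest.mark.parametrize("seed", range(3))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        L, d = 6, 4
        A = (rng.random((L, L)) < 0.5).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        An = normalize_adjacency(A).values
        H = rng.standard_normal((L, d))
        W = rng.standard_normal((d, d))
        perm = rng.permutation(L)
        P = np.eye(L)[perm]
        lhs = P @ gcn_layer(H, An, W)
        rhs = gcn_layer(P @ H, P @ An @ P.T, W)
        assert np.allclose(lhs, rhs, atol=1e-10)


class TestForward:
    def test_matches_dense_oracle(self, rng):
        g, params = random_graph(rng, L=7, D=4, F=3, h=5)
        result = forward(g, params)
        probs, fmap = dense_forward_oracle(g, params)
        assert np.allclose(result.probabilities, probs, atol=1e-5)
        assert np.allclose(result.pooled_feature_map, fmap, atol=1e-5)

    def test_probabilities_in_unit_interval(self, rng):
        g, params = random_graph(rng, L=10, D=6, F=4)
        probs = forward(g, params).probabilities
        assert np.all(probs >= 0) and np.all(probs <= 1)

    def test_end_to_end_permutation_invariance(self, rng):
        g, params = random_graph(rng, L=8, D=4, F=3)
        perm = rng.permutation(8)
        gp = ProteinGraph(
            features=g.feature_array[perm],
            adjacency_evc=g.evc_array[np.ix_(perm, perm)],
            adjacency_rc=g.rc_array[np.ix_(perm, perm)],
        )
        assert np.allclose(
            forward(g, params).probabilities,
            forward(gp, params).probabilities,
            atol=1e-10,
        )

    def test_isolated_zero_feature_node_is_inert(self, rng):
        # with zero GCN biases, a disconnected all-zero residue contributes
        # nothing to the sum pool
        g, params = random_graph(rng, L=6, D=4, F=2)
        L = 6
        X2 = np.vstack([g.feature_array, np.zeros((1, 4))])
        pad = np.zeros((L + 1, L + 1))
        pad[:L, :L] = g.evc_array
        pad2 = np.zeros((L + 1, L + 1))
        pad2[:L, :L] = g.rc_array
        g2 = ProteinGraph(features=X2, adjacency_evc=pad, adjacency_rc=pad2)
        assert np.allclose(
            forward(g, params).probabilities,
            forward(g2, params).probabilities,
            atol=1e-10,
        )

    def test_dropout_only_in_training_mode(self, rng):
        g, params = random_graph(rng, L=5, D=4, F=2, h=16, seed=11)
        g = ProteinGraph(
            features=np.abs(g.feature_array),
            adjacency_evc=g.evc_array,
            adjacency_rc=g.rc_array,
        )
        params.config["dropout"] = 0.5
        a = forward(g, params).probabilities
        b = forward(g, params).probabilities
        assert np.array_equal(a, b)
        t = forward(g, params, training_mode=True, rng=np.random.default_rng(0))
        t2 = forward(g, params, training_mode=True, rng=np.random.default_rng(1))
        assert not np.allclose(t.probabilities, t2.probabilities)


def test_model_roundtrip(tmp_path, rng):
    g, params = random_graph(rng, L=5, D=4, F=3)
    path = tmp_path / "model.npz"
    save_model(params, path)
    back = load_model(path)
    assert back.config == params.config
    for k, v in params.arrays.items():
        assert np.array_equal(back.arrays[k], v)
    assert np.allclose(
        forward(g, back).probabilities, forward(g, params).probabilities
    )
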