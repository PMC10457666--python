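"""Message passing: hand-checked algebra and the node-wise brute-force oracle."""

import numpy as np
import pytest

from circgcf.data_io import AssociationMatrix
from circgcf.propagation import (
    EmbeddingTable,
    PropagationConfig,
    PropagationWeights,
    attention_scores,
    build_laplacian,
    message,
    propagate,
    propagate_layer,
)
from tests.conftest import random_bipartite


def nodewise_propagate(assoc, initial, weights, config):
    """Reference multilayer run built from explicit per-node layers."""
    stack = build_laplacian(assoc)
    stack.embeddings = [initial.rows.copy()]
    states = []
    for layer in range(weights.n_layers):
        nxt, state = propagate_layer(stack, layer, weights, config)
        stack.embeddings.append(nxt)
        states.append(state)
    return stack, states


class TestLaplacian:
    def test_perfect_matching_laplacian_equals_adjacency(self):
        m = AssociationMatrix(np.eye(3, dtype=int),
                              {f"c{i}": i for i in range(3)},
                              {f"d{j}": j for j in range(3)})
        stack = build_laplacian(m)
        np.testing.assert_allclose(stack.laplacian, stack.adjacency)

    def test_star_normalization(self):
        # one disease linked to 4 circRNAs: entries 1/sqrt(1*4) = 0.5
        values = np.ones((4, 1), dtype=int)
        m = AssociationMatrix(values, {f"c{i}": i for i in range(4)}, {"d": 0})
        stack = build_laplacian(m)
        edges = stack.laplacian[stack.adjacency > 0]
        np.testing.assert_allclose(edges, 0.5)

    def test_laplacian_symmetric_with_zero_rows_for_isolates(self, toy_assoc):
        values = toy_assoc.values.copy()
        values[5, :] = 0
        m = AssociationMatrix(values, toy_assoc.circrna_index, toy_assoc.disease_index)
        stack = build_laplacian(m)
        np.testing.assert_allclose(stack.laplacian, stack.laplacian.T, atol=1e-15)
        np.testing.assert_array_equal(stack.laplacian[5], 0.0)


class TestMessage:
    def test_zero_source_embedding_gives_zero_message(self):
        out = message(np.zeros(3), np.ones(3), 0.7, np.eye(3), np.eye(3))
        np.testing.assert_array_equal(out, 0.0)

    def test_w2_zero_reduces_to_plain_convolution(self):
        rng = np.random.default_rng(0)
        ec, ed = rng.normal(size=3), rng.normal(size=3)
        w1 = rng.normal(size=(3, 3))
        np.testing.assert_allclose(message(ec, ed, 0.5, w1, np.zeros((3, 3))),
                                   0.5 * ec @ w1)

    def test_hand_example_identity_transforms(self):
        out = message(np.array([1.0, 2.0]), np.array([3.0, 0.0]), 1.0,
                      np.eye(2), np.eye(2))
        np.testing.assert_allclose(out, [4.0, 2.0])


class TestAttention:
    def test_single_neighbor_gets_weight_one(self):
        rng = np.random.default_rng(1)
        alpha = attention_scores(rng.normal(size=4), rng.normal(size=(1, 4)),
                                 rng.normal(size=(4, 4)), rng.normal(size=8))
        np.testing.assert_allclose(alpha, [1.0])

    def test_identical_neighbors_split_evenly(self):
        rng = np.random.default_rng(2)
        nb = np.tile(rng.normal(size=4), (2, 1))
        alpha = attention_scores(rng.normal(size=4), nb,
                                 rng.normal(size=(4, 4)), rng.normal(size=8))
        np.testing.assert_allclose(alpha, [0.5, 0.5])

    def test_no_neighbors_rejected(self):
        with pytest.raises(ValueError):
            attention_scores(np.ones(3), np.empty((0, 3)), np.eye(3), np.ones(6))

    @pytest.mark.parametrize("attention", ["learned", "uniform"])
    def test_weights_positive_and_normalized_every_layer(self, attention):
        rng = np.random.default_rng(3)
        m = random_bipartite(rng)
        k = 5
        initial = EmbeddingTable(rng.normal(size=(m.n_circrna + m.n_disease, k)),
                                 m.n_circrna, m.n_disease)
        config = PropagationConfig(layers=3, attention=attention)
        weights = PropagationWeights.initialize(k, [k] * 3, seed=0,
                                                attention_init="xavier")
        stack = propagate(initial, m, weights, config)
        assert len(stack.attention) == 3
        for state in stack.attention:
            assert state.check_normalized(tol=1e-6)


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(12))
    def test_vectorized_equals_nodewise_on_random_graphs(self, trial):
        rng = np.random.default_rng(200 + trial)
        m = random_bipartite(rng, max_n=12, max_m=8)
        layers = int(rng.integers(1, 6))
        k = int(rng.integers(2, 6))
        attention = ["learned", "uniform", "none"][trial % 3]
        config = PropagationConfig(layers=layers, attention=attention)
        weights = PropagationWeights.initialize(k, [k] * layers, seed=trial,
                                                attention_init="xavier")
        initial = EmbeddingTable(rng.normal(size=(m.n_circrna + m.n_disease, k)),
                                 m.n_circrna, m.n_disease)
        fast = propagate(initial, m, weights, config)
        slow, states = nodewise_propagate(m, initial, weights, config)
        for a, b in zip(fast.embeddings, slow.embeddings):
            np.testing.assert_allclose(a, b, atol=1e-6)
        for sa, sb in zip(fast.attention, states):
            for center in range(m.n_circrna + m.n_disease):
                wa, wb = sa.weights_for(center), sb.weights_for(center)
                assert wa.keys() == wb.keys()
                for nb in wa:
                    assert wa[nb] == pytest.approx(wb[nb], abs=1e-6)


class TestPropagate:
    def test_empty_graph_leaves_only_self_messages(self):
        values = np.zeros((3, 2), dtype=int)
        values[0, 0] = 1  # one edge so the matrix is valid; isolate the rest
        m = AssociationMatrix(values, {f"c{i}": i for i in range(3)},
                              {"d0": 0, "d1": 1})
        rng = np.random.default_rng(0)
        k = 4
        initial = EmbeddingTable(rng.normal(size=(5, k)), 3, 2)
        weights = PropagationWeights.initialize(k, [k], seed=0)
        config = PropagationConfig(layers=1)
        stack = propagate(initial, m, weights, config)
        w1 = weights.layers[0]["W1"]
        for isolated in (1, 2, 4):  # c1, c2, d1 have no edges
            expected = initial.rows[isolated] @ w1
            expected = np.where(expected > 0, expected, 0.2 * expected)
            np.testing.assert_allclose(stack.embeddings[1][isolated], expected,
                                       atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        m = random_bipartite(rng, max_n=8, max_m=6)
        n, d = m.n_circrna, m.n_disease
        k = 3
        initial = EmbeddingTable(rng.normal(size=(n + d, k)), n, d)
        weights = PropagationWeights.initialize(k, [k, k], seed=1,
                                                attention_init="xavier")
        config = PropagationConfig(layers=2)
        base = propagate(initial, m, weights, config)
        perm_rows = rng.permutation(n)
        perm_cols = rng.permutation(d)
        m2 = AssociationMatrix(m.values[np.ix_(perm_rows, perm_cols)],
                               {f"c{i}": i for i in range(n)},
                               {f"d{j}": j for j in range(d)})
        node_perm = np.concatenate([perm_rows, n + perm_cols])
        initial2 = EmbeddingTable(initial.rows[node_perm], n, d)
        permuted = propagate(initial2, m2, weights, config)
        np.testing.assert_allclose(permuted.embeddings[-1],
                                   base.embeddings[-1][node_perm], atol=1e-10)

    def test_norms_stay_finite_after_five_layers(self):
        rng = np.random.default_rng(4)
        m = random_bipartite(rng)
        k = 6
        initial = EmbeddingTable(rng.normal(size=(m.n_circrna + m.n_disease, k)),
                                 m.n_circrna, m.n_disease)
        weights = PropagationWeights.initialize(k, [k] * 5, seed=0)
        stack = propagate(initial, m, weights, PropagationConfig(layers=5))
        final_norm = np.linalg.norm(stack.embeddings[-1])
        assert np.isfinite(final_norm)
        assert final_norm < 100 * np.linalg.norm(initial.rows)

    def test_attention_table_export(self, toy_assoc):
        rng = np.random.default_rng(0)
        initial = EmbeddingTable(rng.normal(size=(10, 3)), 6, 4)
        stack = propagate(initial, toy_assoc, config=PropagationConfig(layers=2))
        table = stack.attention_table()
        n_edges = int(toy_assoc.values.sum()) * 2
        assert len(table) == 2 * n_edges
        assert set(table.layer) == {1, 2}
        assert (table.alpha > 0).all()

    def test_layer_count_mismatch_rejected(self, toy_assoc):
        initial = EmbeddingTable(np.zeros((10, 2)), 6, 4)
        weights = PropagationWeights.initialize(2, [2, 2], seed=0)
        with pytest.raises(ValueError, match="layer count"):
            propagate(initial, toy_assoc, weights, PropagationConfig(layers=3))
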