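"""Similarity kernels checked against hand computations and brute force."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circgcf.data_io import AssociationMatrix, DiseaseDAG
from circgcf.similarity import (
    SimilarityMatrix,
    fuse_circrna_descriptor,
    fuse_disease_descriptor,
    functional_similarity,
    gip_kernel,
    semantic_contributions,
    semantic_similarity,
)


def brute_force_contributions(edges, disease, delta):
    """Oracle: enumerate every child-to-parent path exhaustively."""
    parents = {}
    for c, p in edges:
        parents.setdefault(c, []).append(p)
    best = {disease: 1.0}
    stack = [(disease, 1.0)]
    while stack:
        node, value = stack.pop()
        for parent in parents.get(node, []):
            v = value * delta
            if v > best.get(parent, 0.0):
                best[parent] = v
                stack.append((parent, v))
    return best


def brute_force_similarity(edges, a, b, delta):
    da = brute_force_contributions(edges, a, delta)
    db = brute_force_contributions(edges, b, delta)
    shared = da.keys() & db.keys()
    if not shared:
        return 0.0
    return sum(da[t] + db[t] for t in shared) / (sum(da.values()) + sum(db.values()))


class TestSemanticSimilarity:
    def test_disease_vs_itself_is_one(self, sibling_dag):
        sim = semantic_similarity(sibling_dag, ["A", "B"])
        assert sim.values[0, 0] == 1.0

    def test_siblings_under_single_root(self, sibling_dag):
        # D-values {A:1, root:0.5} each; shared {root} -> (0.5+0.5)/(1.5+1.5)
        sim = semantic_similarity(sibling_dag, ["A", "B"], delta=0.5)
        assert sim.values[0, 1] == pytest.approx(1 / 3)

    def test_disjoint_components_have_zero_similarity(self):
        dag = DiseaseDAG([("A", "r1"), ("B", "r2")])
        sim = semantic_similarity(dag, ["A", "B"])
        assert sim.values[0, 1] == 0.0

    def test_missing_disease_error_names_id(self, sibling_dag):
        with pytest.raises(KeyError, match="ghost"):
            semantic_similarity(sibling_dag, ["A", "ghost"])

    def test_contributions_decay_toward_roots(self):
        dag = DiseaseDAG([("leaf", "mid"), ("mid", "root")])
        contrib = semantic_contributions(dag, "leaf", delta=0.5)
        assert contrib == {"leaf": 1.0, "mid": 0.5, "root": 0.25}

    @pytest.mark.parametrize("trial", range(25))
    def test_agrees_with_exhaustive_path_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(4, 13))
        # random DAG: each non-root node gets 1-2 parents among earlier nodes
        edges = []
        for child in range(1, n):
            for parent in rng.choice(child, size=min(child, int(rng.integers(1, 3))),
                                     replace=False):
                edges.append((f"t{child}", f"t{parent}"))
        dag = DiseaseDAG(edges)
        nodes = sorted(dag.nodes())
        delta = float(rng.uniform(0.2, 0.8))
        sim = semantic_similarity(dag, nodes, delta=delta)
        for i, a in enumerate(nodes):
            for j, b in enumerate(nodes):
                expected = 1.0 if i == j else brute_force_similarity(edges, a, b, delta)
                assert sim.values[i, j] == pytest.approx(expected, abs=1e-12)


class TestGIPKernel:
    def test_identical_profiles_similarity_one(self):
        sim = gip_kernel(np.array([[1, 0], [1, 0]]), ["a", "b"])
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_orthogonal_unit_profiles(self):
        # mean squared norm 1 -> gamma 1 -> K = exp(-2)
        sim = gip_kernel(np.array([[1, 0], [0, 1]]), ["a", "b"], gamma_prime=1.0)
        assert sim.values[0, 1] == pytest.approx(np.exp(-2), abs=1e-12)

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(2)
        profiles = (rng.random((9, 6)) < 0.5).astype(float)
        profiles[0] = 1
        sim = gip_kernel(profiles, [str(i) for i in range(9)])
        assert sim.values.min() > 0 and sim.values.max() <= 1

    def test_all_zero_profiles_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            gip_kernel(np.zeros((3, 4)), ["a", "b", "c"])

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        profiles = (rng.random((7, 5)) < 0.5).astype(float)
        profiles[0, 0] = 1
        ids = [f"e{i}" for i in range(7)]
        perm = rng.permutation(7)
        base = gip_kernel(profiles, ids).values
        permuted = gip_kernel(profiles[perm], [ids[i] for i in perm]).values
        np.testing.assert_allclose(permuted, base[np.ix_(perm, perm)], atol=1e-12)


class TestFunctionalSimilarity:
    def make_disease_sim(self, values, ids):
        return SimilarityMatrix(np.asarray(values, float), {d: i for i, d in enumerate(ids)},
                                kind="semantic")

    def test_identical_disease_sets_give_one(self):
        assoc = AssociationMatrix(np.array([[1, 1], [1, 1]]),
                                  {"c1": 0, "c2": 1}, {"A": 0, "B": 1})
        sim = functional_similarity(assoc, self.make_disease_sim(np.eye(2), ["A", "B"]))
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_single_disease_pair_reduces_to_disease_similarity(self):
        assoc = AssociationMatrix(np.array([[1, 0], [0, 1]]),
                                  {"c1": 0, "c2": 1}, {"A": 0, "B": 1})
        ds = self.make_disease_sim([[1, 1 / 3], [1 / 3, 1]], ["A", "B"])
        sim = functional_similarity(assoc, ds)
        assert sim.values[0, 1] == pytest.approx(1 / 3)

    def test_nested_disease_sets(self):
        # c1 -> {A}, c2 -> {A, B}, sim(A,B)=0 -> (1 + 1 + 0) / 3
        assoc = AssociationMatrix(np.array([[1, 0], [1, 1]]),
                                  {"c1": 0, "c2": 1}, {"A": 0, "B": 1})
        sim = functional_similarity(assoc, self.make_disease_sim(np.eye(2), ["A", "B"]))
        assert sim.values[0, 1] == pytest.approx(2 / 3)

    def test_empty_disease_set_flagged_as_zero_row(self):
        assoc = AssociationMatrix(np.array([[1, 1], [0, 0]]),
                                  {"c1": 0, "c2": 1}, {"A": 0, "B": 1})
        sim = functional_similarity(assoc, self.make_disease_sim(np.eye(2), ["A", "B"]))
        assert sim.values[0, 1] == 0.0
        assert sim.values[1, 1] == 1.0

    def test_identity_disease_sim_bounded_overlap(self, toy_assoc):
        m = toy_assoc.n_disease
        ds = self.make_disease_sim(np.eye(m), toy_assoc.disease_ids())
        sim = functional_similarity(toy_assoc, ds)
        sets = [frozenset(np.flatnonzero(r)) for r in toy_assoc.values]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] and sets[j]:
                    assert sim.values[i, j] <= 1.0 + 1e-12
                    if sim.values[i, j] == pytest.approx(1.0):
                        assert sets[i] == sets[j]


class TestFusion:
    def two_by_two(self, primary, fallback, mask):
        ids = ["x", "y"]
        p = SimilarityMatrix(np.array([[1.0, primary], [primary, 1.0]]),
                             {i: k for k, i in enumerate(ids)}, kind="semantic")
        g = SimilarityMatrix(np.array([[1.0, fallback], [fallback, 1.0]]),
                             {i: k for k, i in enumerate(ids)}, kind="gip")
        has = np.full((2, 2), mask)
        return p, g, has

    def test_primary_branch_selected_where_defined(self):
        p, g, has = self.two_by_two(0.4, 0.9, True)
        assert fuse_disease_descriptor(p, g, has).values[0, 1] == pytest.approx(0.4)

    def test_fallback_branch_elsewhere(self):
        p, g, has = self.two_by_two(0.25, 0.8, False)
        assert fuse_circrna_descriptor(p, g, has).values[0, 1] == pytest.approx(0.8)

    def test_diagonal_is_one_either_way(self):
        for mask in (True, False):
            p, g, has = self.two_by_two(0.4, 0.9, mask)
            fused = fuse_disease_descriptor(p, g, has)
            np.testing.assert_allclose(np.diag(fused.values), 1.0)

    def test_index_mismatch_rejected(self):
        p, g, has = self.two_by_two(0.4, 0.9, True)
        g.index = {"p": 0, "q": 1}
        with pytest.raises(ValueError, match="indices"):
            fuse_disease_descriptor(p, g, has)


def test_similarity_matrix_validates_symmetry_and_range():
    with pytest.raises(ValueError, match="symmetric"):
        SimilarityMatrix(np.array([[1.0, 0.5], [0.2, 1.0]]), {"a": 0, "b": 1})
    with pytest.raises(ValueError, match="\\[0, 1\\]"):
        SimilarityMatrix(np.array([[1.0, 1.5], [1.5, 1.0]]), {"a": 0, "b": 1})
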