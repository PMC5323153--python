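import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdinfer import (
    AssociationMatrix,
    BandwidthUndefinedError,
    KernelConfig,
    PartialSimilarity,
    SemanticConfig,
    SimilarityMatrix,
    ValidationError,
    build_dag,
    gip_bandwidth,
    gip_kernel,
    integrate_similarity,
    interaction_kernels,
    semantic_contributions,
    semantic_similarity,
    semantic_similarity_matrix,
    semantic_value,
)
from mdinfer.graph_data import DiseaseDAG


def chain_index():
    """Grandparent -> parent -> disease chain: G=C04, P=C04.1, D=C04.1.1."""
    tree_index = {"C04": "G", "C04.1": "P", "C04.1.1": "D"}
    term_numbers = {"G": {"C04"}, "P": {"C04.1"}, "D": {"C04.1.1"}}
    return tree_index, term_numbers


class TestBuildDag:
    def test_single_node(self):
        dag = build_dag("Neoplasms", {"C04": "Neoplasms"}, {"Neoplasms": {"C04"}})
        assert dag.nodes == {"Neoplasms"} and dag.edges == set()
        dag.validate()

    def test_parent_child(self):
        dag = build_dag(
            "B", {"C04": "A", "C04.557": "B"}, {"B": {"C04.557"}, "A": {"C04"}}
        )
        assert dag.nodes == {"A", "B"}
        assert dag.edges == {("A", "B")}

    def test_union_of_ancestor_paths(self):
        tree_index = {"C04": "T4", "C06": "T6", "C04.1": "C", "C06.2": "C"}
        term_numbers = {"C": {"C04.1", "C06.2"}, "T4": {"C04"}, "T6": {"C06"}}
        dag = build_dag("C", tree_index, term_numbers)
        assert dag.nodes == {"C", "T4", "T6"}
        assert dag.edges == {("T4", "C"), ("T6", "C")}
        dag.validate()

    def test_unindexed_prefix_skipped(self):
        # C04.5 owns no term: the edge connects the nearest indexed ancestor
        tree_index = {"C04": "A", "C04.5.1": "B"}
        term_numbers = {"B": {"C04.5.1"}, "A": {"C04"}}
        dag = build_dag("B", tree_index, term_numbers)
        assert dag.edges == {("A", "B")}

    def test_no_tree_numbers_rejected(self):
        with pytest.raises(ValidationError):
            build_dag("X", {}, {})


class TestSemanticContributions:
    def test_chain_decay(self):
        ti, tn = chain_index()
        dag = build_dag("D", ti, tn)
        dd = semantic_contributions(dag, SemanticConfig(delta=0.5))
        assert dd == {"D": 1.0, "P": 0.5, "G": 0.25}
        assert semantic_value(dd) == pytest.approx(1.75)

    def test_single_node(self):
        dag = DiseaseDAG("D", {"D"}, set())
        assert semantic_contributions(dag) == {"D": 1.0}
        assert semantic_value({"D": 1.0}) == 1.0

    def test_max_over_children(self):
        # X has two children: the root (DD=1) and P (DD=0.5)
        dag = DiseaseDAG(
            "D", {"D", "P", "X"}, {("P", "D"), ("X", "D"), ("X", "P")}
        )
        dd = semantic_contributions(dag, SemanticConfig(delta=0.5))
        assert dd["X"] == max(0.5 * dd["D"], 0.5 * dd["P"]) == 0.5

    def test_star_semantic_value(self):
        # root with k parents each contributing delta
        k, delta = 4, 0.3
        nodes = {"D"} | {f"p{i}" for i in range(k)}
        edges = {(f"p{i}", "D") for i in range(k)}
        dd = semantic_contributions(
            DiseaseDAG("D", nodes, edges), SemanticConfig(delta=delta)
        )
        assert semantic_value(dd) == pytest.approx(1 + k * delta)


class TestSemanticSimilarity:
    def test_identical_dags(self):
        ti, tn = chain_index()
        dag = build_dag("D", ti, tn)
        assert semantic_similarity(dag, dag) == 1.0

    def test_disjoint_dags(self):
        a = DiseaseDAG("A", {"A"}, set())
        b = DiseaseDAG("B", {"B"}, set())
        assert semantic_similarity(a, b) == 0.0

    def test_siblings_under_chain(self):
        # D1, D2 both children of P, with grandparent G; delta = 0.5
        tree_index = {"C04": "G", "C04.1": "P", "C04.1.1": "D1", "C04.1.2": "D2"}
        term_numbers = {
            "G": {"C04"}, "P": {"C04.1"}, "D1": {"C04.1.1"}, "D2": {"C04.1.2"}
        }
        d1 = build_dag("D1", tree_index, term_numbers)
        d2 = build_dag("D2", tree_index, term_numbers)
        ss = semantic_similarity(d1, d2, SemanticConfig(delta=0.5))
        assert ss == pytest.approx(3.0 / 7.0, abs=1e-12)

    def test_symmetric_in_arguments(self):
        ti, tn = chain_index()
        p = build_dag("P", ti, tn)
        d = build_dag("D", ti, tn)
        assert semantic_similarity(p, d) == semantic_similarity(d, p)

    def test_shared_ancestor_never_decreases_similarity(self, rng):
        """Growing both DAGs by a shared ancestor adds the same mass to
        numerator and denominator, so SS cannot drop (N <= D)."""
        for _ in range(30):
            depth = int(rng.integers(1, 5))
            shared = [f"s{k}" for k in range(depth)]
            # two sibling chains hanging off the shared ancestor chain
            def make(root, extra):
                nodes = {root, *extra, *shared}
                chain = [root, *extra, *shared]
                edges = {(chain[k + 1], chain[k]) for k in range(len(chain) - 1)}
                return DiseaseDAG(root, nodes, edges)

            extra_a = [f"a{k}" for k in range(int(rng.integers(0, 3)))]
            extra_b = [f"b{k}" for k in range(int(rng.integers(0, 3)))]
            small_a = make("A", extra_a)
            small_b = make("B", extra_b)
            grown_a = DiseaseDAG("A", small_a.nodes | {"top"},
                                 small_a.edges | {("top", shared[-1])})
            grown_b = DiseaseDAG("B", small_b.nodes | {"top"},
                                 small_b.edges | {("top", shared[-1])})
            cfg = SemanticConfig(delta=float(rng.uniform(0.2, 0.8)))
            assert semantic_similarity(grown_a, grown_b, cfg) >= (
                semantic_similarity(small_a, small_b, cfg) - 1e-12
            )

    def test_matrix_marks_unannotated_diseases_unobserved(self):
        ti, tn = chain_index()
        ss = semantic_similarity_matrix(["D", "P", "NoMesh"], ti, tn)
        ss.validate()
        assert ss.observed[0, 1] and not ss.observed[0, 2]
        assert ss.values[0, 0] == 1.0


class TestGipKernel:
    def test_bandwidth_unit_profiles(self):
        assert gip_bandwidth(np.array([[1.0, 0.0], [0.0, 1.0]]), 1.0) == 1.0

    def test_bandwidth_denser_profiles(self):
        assert gip_bandwidth(np.array([[1.0, 1.0], [1.0, 1.0]]), 2.0) == 1.0

    def test_bandwidth_all_zero_rejected(self):
        with pytest.raises(BandwidthUndefinedError):
            gip_bandwidth(np.zeros((2, 2)), 1.0)

    def test_identical_profiles_similarity_one(self):
        k = gip_kernel(np.ones((3, 4)), 1.0)
        assert np.allclose(k.values, 1.0)

    def test_golden_values(self):
        k = gip_kernel(np.array([[1.0, 0.0], [0.0, 1.0]]), 1.0)
        assert k.values[0, 1] == pytest.approx(math.exp(-2.0), abs=1e-12)
        k2 = gip_kernel(np.array([[1, 1, 0], [1, 0, 1]], dtype=float), 0.5)
        assert k2.values[0, 1] == pytest.approx(math.exp(-1.0), abs=1e-12)

    def test_kernel_properties(self, rng):
        profiles = (rng.random((6, 8)) < 0.4).astype(float)
        k = gip_kernel(profiles, 0.7)
        k.validate()
        assert (k.values > 0).all() and (k.values <= 1).all()

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_coordinate_permutation(self, seed):
        rng = np.random.default_rng(seed)
        profiles = (rng.random((5, 7)) < 0.5).astype(float)
        perm = rng.permutation(7)
        k1 = gip_kernel(profiles, 0.9).values
        k2 = gip_kernel(profiles[:, perm], 0.9).values
        assert np.allclose(k1, k2)

    def test_denser_matrix_lowers_bandwidth(self, rng):
        sparse = (rng.random((10, 12)) < 0.2).astype(float)
        dense = np.clip(sparse + (rng.random((10, 12)) < 0.4), 0, 1)
        assert gip_bandwidth(dense, 1.0) < gip_bandwidth(sparse, 1.0)

    def test_interaction_kernels_fallback(self, caplog):
        empty = AssociationMatrix(["m1"], ["d1"], np.zeros((1, 1)))
        with pytest.raises(BandwidthUndefinedError):
            interaction_kernels(empty)
        with caplog.at_level("WARNING"):
            km, kd = interaction_kernels(empty, bandwidth_fallback=True)
        assert km.values[0, 0] == kd.values[0, 0] == 1.0
        assert any("falling back" in r.message for r in caplog.records)


class TestIntegrateSimilarity:
    def test_observed_pairs_averaged(self):
        kernel = SimilarityMatrix(["a", "b"], np.array([[1.0, 0.8], [0.8, 1.0]]))
        partial = PartialSimilarity(
            ["a", "b"], np.array([[1.0, 0.6], [0.6, 1.0]]), np.ones((2, 2), bool)
        )
        out = integrate_similarity(kernel, partial)
        assert out.values[0, 1] == pytest.approx(0.7)
        assert out.values[0, 0] == 1.0

    def test_unobserved_pairs_keep_kernel(self):
        kernel = SimilarityMatrix(["a", "b"], np.array([[1.0, 0.3], [0.3, 1.0]]))
        partial = PartialSimilarity(
            ["a", "b"], np.eye(2), np.eye(2, dtype=bool)
        )
        out = integrate_similarity(kernel, partial)
        assert out.values[0, 1] == 0.3

    def test_id_mismatch_rejected(self):
        kernel = SimilarityMatrix(["a", "b"], np.eye(2))
        partial = PartialSimilarity(["a", "c"], np.eye(2), np.eye(2, dtype=bool))
        with pytest.raises(ValidationError):
            integrate_similarity(kernel, partial)

    def test_result_is_valid_similarity(self, rng):
        from conftest import random_similarity

        kernel = random_similarity(rng, 5)
        values = np.clip(random_similarity(rng, 5).values, 0, 1)
        np.fill_diagonal(values, 1.0)
        mask = rng.random((5, 5)) < 0.5
        mask = np.triu(mask) | np.triu(mask, 1).T
        np.fill_diagonal(mask, True)
        out = integrate_similarity(
            kernel, PartialSimilarity(kernel.ids, values, mask)
        )
        out.validate()
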