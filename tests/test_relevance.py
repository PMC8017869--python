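import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hierfs.encoding import Cohort
from hierfs.graph import KnowledgeGraph
from hierfs.relevance import (build_candidate_pairs, conditional_entropy,
                              entropy, gene_anchors, mi_filter,
                              mutual_information, pearson_binary)
from tests.conftest import make_node

L4 = np.array([1, 1, 0, 0])


class TestEntropy:
    def test_balanced_binary_is_one_bit(self):
        assert entropy(np.array([1, 0] * 4)) == pytest.approx(1.0, abs=1e-12)

    def test_constant_is_zero(self):
        assert entropy(np.zeros(7)) == 0.0

    def test_conditional_worked_example(self):
        # H(L|B) = 3/4 * H(2/3) + 1/4 * 0
        h = conditional_entropy(L4, np.array([1, 1, 1, 0]))
        assert h == pytest.approx(0.6887218755408672, abs=1e-12)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            conditional_entropy(L4, np.array([1, 0]))


class TestMutualInformation:
    def test_identical_balanced_feature_is_one_bit(self):
        assert mutual_information(L4, L4) == pytest.approx(1.0, abs=1e-12)

    def test_independent_product_structure_is_zero(self):
        assert mutual_information(np.array([1, 0, 1, 0]), L4) == pytest.approx(0.0, abs=1e-12)

    def test_worked_four_sample_case(self):
        assert mutual_information(np.array([1, 1, 1, 0]), L4) == pytest.approx(
            0.3112781244591328, abs=1e-9)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import mutual_info_score
        for _ in range(20):
            b = rng.integers(0, 2, 30)
            l = rng.integers(0, 3, 30)
            assert mutual_information(b, l) == pytest.approx(
                mutual_info_score(l, b) / np.log(2), abs=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_joint_permutation_invariance(self, seed):
        r = np.random.default_rng(seed)
        b = r.integers(0, 2, 24)
        l = r.integers(0, 2, 24)
        perm = r.permutation(24)
        assert mutual_information(b[perm], l[perm]) == pytest.approx(
            mutual_information(b, l), abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounded_by_marginal_entropies(self, seed):
        r = np.random.default_rng(seed)
        b = r.integers(0, 2, 20)
        l = r.integers(0, 3, 20)
        mi = mutual_information(b, l)
        assert -1e-12 <= mi <= min(entropy(b), entropy(l)) + 1e-12


class TestMiFilter:
    def graph(self):
        kg = KnowledgeGraph()
        kg.add_node(make_node("a", vector=[1, 1, 0, 0]))  # MI 1
        kg.add_node(make_node("b", vector=[1, 1, 1, 0]))  # MI 0.311
        kg.add_node(make_node("c", vector=[1, 0, 1, 0]))  # MI 0
        return kg, Cohort(list("wxyz"), L4)

    def test_threshold_partitions(self):
        kg, cohort = self.graph()
        retained, table = mi_filter(kg, cohort, 0.1)
        assert retained == {"a", "b"}
        assert set(table.mi) == {"a", "b", "c"}

    def test_zero_threshold_retains_all(self):
        kg, cohort = self.graph()
        retained, _ = mi_filter(kg, cohort, 0.0)
        assert retained == {"a", "b", "c"}

    def test_above_label_entropy_retains_none(self):
        kg, cohort = self.graph()
        retained, _ = mi_filter(kg, cohort, 1.5)
        assert retained == set()

    def test_negative_threshold_errors(self):
        kg, cohort = self.graph()
        with pytest.raises(ValueError):
            mi_filter(kg, cohort, -0.1)

    def test_retained_sets_nest_as_threshold_grows(self, rng):
        kg = KnowledgeGraph()
        for k in range(12):
            kg.add_node(make_node(f"n{k}", vector=rng.random(16) < 0.5))
        cohort = Cohort([f"S{i}" for i in range(16)], rng.integers(0, 2, 16))
        prev = None
        for t in [0.0, 0.05, 0.1, 0.2, 0.5, 1.0]:
            cur, _ = mi_filter(kg, cohort, t)
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestPearson:
    def test_identical(self):
        assert pearson_binary([1, 1, 0, 0], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_complementary(self):
        assert pearson_binary([1, 1, 0, 0], [0, 0, 1, 1]) == pytest.approx(-1.0)

    def test_orthogonal_balanced(self):
        assert pearson_binary([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(0.0)

    def test_constant_defined_as_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert pearson_binary([1, 1, 1, 1], [1, 0, 1, 0]) == 0.0


def brute_force_pairs(kg, retained, gate):
    """Independent all-pairs oracle: DFS reachability, gene anchors by
    path in either direction, interval overlap, then the |corr| gate."""
    import networkx as nx
    g = nx.DiGraph()
    g.add_nodes_from(kg.nodes)
    g.add_edges_from(kg.edges)
    genes = [n for n in kg.nodes if kg.nodes[n].kind == "gene"]

    def anchors(n):
        return {x for x in genes
                if x == n or nx.has_path(g, n, x) or nx.has_path(g, x, n)}

    def overlap(a, b):
        ia, ib = kg.nodes[a].interval, kg.nodes[b].interval
        return (ia is not None and ib is not None and ia[0] == ib[0]
                and ia[1] < ib[2] and ib[1] < ia[2])

    out = set()
    for a, b in itertools.combinations(sorted(retained), 2):
        rule1 = bool(anchors(a) & anchors(b))
        rule2 = any(overlap(ga, gb) for ga in anchors(a) for gb in anchors(b))
        rule3 = nx.has_path(g, a, b) or nx.has_path(g, b, a)
        if not (rule1 or rule2 or rule3):
            continue
        x = kg.nodes[a].vector.astype(float)
        y = kg.nodes[b].vector.astype(float)
        if x.std() == 0 or y.std() == 0:
            corr = 0.0
        else:
            corr = float(np.corrcoef(x, y)[0, 1])
        if abs(corr) >= gate:
            out.add((a, b))
    return out


class TestCandidatePairs:
    def test_shared_gene_pair_included(self):
        kg = KnowledgeGraph()
        kg.add_node(make_node("g", kind="gene", interval=("c1", 0, 100),
                              vector=[1, 1, 0, 0]))
        kg.add_node(make_node("t", kind="transcript", vector=[1, 1, 0, 0]))
        kg.add_node(make_node("e", kind="exon", vector=[1, 0, 0, 0]))
        kg.add_edge("t", "g")
        kg.add_edge("e", "t")
        pairs = build_candidate_pairs(kg, {"e", "t"}, pair_gate=0.3)
        assert ("e", "t") in pairs.keys()

    def test_gate_excludes_weak_correlation(self):
        kg = KnowledgeGraph()
        a = [1] * 8 + [0] * 8
        b = [1] * 5 + [0] * 3 + [1] * 3 + [0] * 5
        kg.add_node(make_node("a", kind="go_term", vector=a))
        kg.add_node(make_node("b", kind="go_term", vector=b))
        kg.add_edge("a", "b")  # directed path, but corr = 0.25, below the gate
        corr = pearson_binary(kg.nodes["a"].vector, kg.nodes["b"].vector)
        assert abs(corr) == pytest.approx(0.25)
        pairs = build_candidate_pairs(kg, {"a", "b"}, pair_gate=0.3)
        assert len(pairs) == 0

    def test_unrelated_nodes_excluded_despite_high_corr(self):
        kg = KnowledgeGraph()
        kg.add_node(make_node("a", kind="snp", vector=[1, 1, 0, 0]))
        kg.add_node(make_node("b", kind="snp", vector=[1, 1, 0, 0]))
        pairs = build_candidate_pairs(kg, {"a", "b"}, pair_gate=0.3)
        assert len(pairs) == 0

    def test_go_terms_of_same_gene_are_candidates(self):
        kg = KnowledgeGraph()
        kg.add_node(make_node("g", kind="gene", interval=("c1", 0, 9),
                              vector=[1, 1, 0, 0]))
        for term in ("GO:0000010", "GO:0000011"):
            kg.add_node(make_node(term, kind="go_term", rule="threshold",
                                  vector=[1, 1, 0, 0], genes=["g"]))
            kg.add_edge("g", term)
        pairs = build_candidate_pairs(kg, {"GO:0000010", "GO:0000011"}, pair_gate=0.3)
        assert ("GO:0000010", "GO:0000011") in pairs.keys()

    def test_matches_bruteforce_oracle_on_random_graphs(self, rng):
        from hierfs.encoding import Cohort, propagate_or
        from tests.conftest import random_structured_graph
        for _ in range(30):
            kg = random_structured_graph(rng, n_samples=10)
            propagate_or(kg, Cohort([f"S{i}" for i in range(10)],
                                    np.zeros(10, dtype=int)))
            retained = {n for n in kg.nodes if kg.nodes[n].vector.any()
                        and not kg.nodes[n].vector.all()}
            retained = set(sorted(retained)[:30])
            got = build_candidate_pairs(kg, retained, pair_gate=0.3)
            assert got.keys() == brute_force_pairs(kg, retained, 0.3)
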