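"""Walktrap communities, modularity and partition comparison."""

import itertools

import networkx as nx
import numpy as np
import pytest

from hbmnet import (
    CommunityPartition,
    DataError,
    classify_edges,
    compare_partitions,
    modularity,
    walktrap,
)


def set_partitions(items):
    """All set partitions of a list (Bell-number enumeration)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def best_modularity_partition(G):
    """Exhaustive modularity maximisation — oracle for small graphs."""
    nodes = list(G.nodes)
    best_q, best = -1.0, None
    for part in set_partitions(nodes):
        assignment = {}
        for cid, block in enumerate(part, start=1):
            for n in block:
                assignment[n] = cid
        q = modularity(G, assignment)
        if q > best_q:
            best_q, best = q, assignment
    return best, best_q


def clique_pair(k, bridge=True):
    G = nx.Graph()
    G.add_edges_from(itertools.combinations(range(k), 2))
    G.add_edges_from(itertools.combinations(range(k, 2 * k), 2))
    if bridge:
        G.add_edge(0, k)
    return G


def groups(assignment):
    out = {}
    for n, c in assignment.items():
        out.setdefault(c, set()).add(n)
    return {frozenset(v) for v in out.values()}


class TestWalktrap:
    @pytest.mark.parametrize("k", [3, 4])
    def test_matches_exhaustive_modularity_maximisation(self, k):
        G = clique_pair(k)
        part = walktrap(G)
        oracle, oracle_q = best_modularity_partition(G)
        assert groups(part.assignment) == groups(oracle)
        assert part.modularity == pytest.approx(oracle_q)

    def test_single_clique_is_one_community(self):
        G = nx.complete_graph(5)
        part = walktrap(G)
        assert part.n_communities == 1

    def test_disconnected_triangles_modularity_half(self):
        # Q = sum(e_ii - a_i^2) = 2*(0.5 - 0.25) = 0.5 exactly
        G = clique_pair(3, bridge=False)
        part = walktrap(G)
        assert part.n_communities == 2
        assert part.modularity == pytest.approx(0.5)

    def test_relabelling_invariance(self):
        G = clique_pair(4)
        mapping = {i: f"node_{i}" for i in G.nodes}
        H = nx.relabel_nodes(G, mapping)
        pg, ph = walktrap(G), walktrap(H)
        renamed = {mapping[n]: c for n, c in pg.assignment.items()}
        assert groups(renamed) == groups(ph.assignment)

    def test_empty_graph_gives_singletons(self):
        G = nx.empty_graph(4)
        with pytest.warns(UserWarning, match="no edges"):
            part = walktrap(G)
        assert part.n_communities == 4
        assert part.modularity == 0.0

    def test_isolated_nodes_become_singletons(self):
        G = clique_pair(3, bridge=False)
        G.add_node("loner")
        part = walktrap(G)
        assert [part.assignment["loner"]] == [
            c for n, c in part.assignment.items() if n == "loner"
        ]
        assert sum(1 for c in part.members().values() if len(c) == 1) == 1

    def test_weighted_uses_absolute_weights(self):
        G = clique_pair(3, bridge=False)
        for u, v in G.edges:
            G[u][v]["weight"] = -0.4  # negative partial correlations
        part = walktrap(G)
        assert part.n_communities == 2

    def test_beats_trivial_partition(self):
        G = clique_pair(4)
        part = walktrap(G)
        trivial = {n: 1 for n in G.nodes}
        assert part.modularity >= modularity(G, trivial)


class TestModularity:
    def test_single_community_is_zero(self):
        G = clique_pair(3)
        assert modularity(G, {n: 1 for n in G.nodes}) == pytest.approx(0.0)

    @pytest.mark.parametrize("k_blocks", [2, 3, 4])
    def test_disconnected_equal_cliques_closed_form(self, k_blocks):
        G = nx.Graph()
        assignment = {}
        for b in range(k_blocks):
            nodes = [f"{b}_{i}" for i in range(4)]
            G.add_edges_from(itertools.combinations(nodes, 2))
            assignment.update({n: b + 1 for n in nodes})
        assert modularity(G, assignment) == pytest.approx((k_blocks - 1) / k_blocks)

    def test_random_assignment_on_er_graph_is_small(self):
        qs = []
        for seed in range(5):
            G = nx.erdos_renyi_graph(100, 0.08, seed=seed)
            rng = np.random.default_rng(seed)
            assignment = {n: int(rng.integers(1, 5)) for n in G.nodes}
            qs.append(modularity(G, assignment))
        assert abs(np.mean(qs)) < 0.15

    def test_missing_nodes_rejected(self):
        G = clique_pair(3)
        with pytest.raises(DataError):
            modularity(G, {0: 1})


class TestEdgeClassification:
    def test_single_community_all_intra(self):
        G = clique_pair(3, bridge=False)
        part = CommunityPartition({n: 1 for n in G.nodes}, 0.0)
        classes = classify_edges(G, part)
        assert set(classes.values()) == {"intra"}

    def test_bipartite_crossing_all_inter(self):
        G = nx.complete_bipartite_graph(3, 3)
        assignment = {n: 1 if n < 3 else 2 for n in G.nodes}
        part = CommunityPartition(assignment, 0.0)
        assert set(classify_edges(G, part).values()) == {"inter"}

    def test_classes_partition_edge_set(self):
        G = clique_pair(4)
        part = walktrap(G)
        classes = part.edge_classes
        n_intra = sum(1 for v in classes.values() if v == "intra")
        n_inter = sum(1 for v in classes.values() if v == "inter")
        assert n_intra + n_inter == G.number_of_edges()
        assert n_inter == 1  # only the bridge


class TestComparePartitions:
    def _p(self, assignment):
        return CommunityPartition(assignment, 0.0)

    def test_identical_partitions(self):
        p = self._p({"a": 1, "b": 1, "c": 2})
        out = compare_partitions(p, p)
        assert out["adjusted_rand"] == pytest.approx(1.0)
        assert out["n_shared_nodes"] == 3

    def test_singletons_vs_one_block(self):
        nodes = list("abcdef")
        p1 = self._p({n: i + 1 for i, n in enumerate(nodes)})
        p2 = self._p({n: 1 for n in nodes})
        assert compare_partitions(p1, p2)["adjusted_rand"] == pytest.approx(0.0)

    def test_hand_built_contingency_matches_formula(self):
        # partitions {ab|cd|ef} vs {ab|cdef}: pair counts by hand
        p1 = self._p({"a": 1, "b": 1, "c": 2, "d": 2, "e": 3, "f": 3})
        p2 = self._p({"a": 1, "b": 1, "c": 2, "d": 2, "e": 2, "f": 2})
        # sum_ij C(n_ij,2)=3, sum_i C(a_i,2)=3, sum_j C(b_j,2)=7, C(6,2)=15
        expected = (3 - 3 * 7 / 15) / (0.5 * (3 + 7) - 3 * 7 / 15)
        out = compare_partitions(p1, p2)
        assert out["adjusted_rand"] == pytest.approx(expected)

    def test_restricted_to_shared_nodes(self):
        p1 = self._p({"a": 1, "b": 1, "c": 2, "x": 3})
        p2 = self._p({"a": 1, "b": 1, "c": 2, "y": 3})
        out = compare_partitions(p1, p2)
        assert out["n_shared_nodes"] == 3
        assert out["adjusted_rand"] == pytest.approx(1.0)

    def test_too_few_shared_nodes(self):
        with pytest.raises(DataError):
            compare_partitions(self._p({"a": 1}), self._p({"b": 1}))
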