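"""Similarity network construction, clustering and partition agreement."""

import networkx as nx
import numpy as np
import pytest

from _oracles import brute_force_best_modularity, rand_index_by_pairs
from retronet import (
    DistanceMatrix,
    ModularityUndefinedError,
    Partition,
    PartitionMismatchError,
    SSNClustering,
    build_ssn,
    cluster_report,
    connected_components,
    louvain_cluster,
    modularity,
    rand_index,
)


def _dm(ids, dense):
    vals = np.array(dense, dtype=float)
    return DistanceMatrix(ids=ids, values=vals)


class TestBuildSSN:
    def test_threshold_arithmetic_at_0666(self):
        dm = _dm(["a", "b", "c"], [[0, 1.5, 2.0], [1.5, 0, 2.0], [2.0, 2.0, 0]])
        g = build_ssn(dm, tau=0.666)
        assert g.has_edge("a", "b")  # w = 0.6667 >= 0.666
        assert not g.has_edge("a", "c")  # w = 0.5 < 0.666
        assert set(g.nodes) == {"a", "b", "c"}  # isolated node retained

    def test_tiny_tau_gives_complete_graph(self):
        n = 5
        vals = np.full((n, n), 2.0)
        np.fill_diagonal(vals, 0.0)
        g = build_ssn(_dm([f"s{i}" for i in range(n)], vals), tau=1e-9)
        assert g.number_of_edges() == n * (n - 1) // 2

    def test_weight_cap_for_identical_sequences(self):
        dm = _dm(["a", "b"], [[0, 0], [0, 0]])
        g = build_ssn(dm, tau=0.666, w_cap=1000.0)
        assert g["a"]["b"]["weight"] == 1000.0

    def test_edge_count_nonincreasing_in_tau(self, rng):
        n = 10
        vals = rng.uniform(0.5, 3.0, size=(n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        dm = _dm([f"s{i}" for i in range(n)], vals)
        counts = [build_ssn(dm, tau=t).number_of_edges() for t in (0.1, 0.4, 0.666, 1.2)]
        assert counts == sorted(counts, reverse=True)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            build_ssn(_dm(["a", "b"], [[0, 1], [1, 0]]), tau=0.0)


class TestConnectedComponents:
    def test_edgeless_graph_all_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abcde")
        assert connected_components(g).n_clusters == 5

    def test_two_disjoint_triangles(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")])
        part = connected_components(g)
        assert part.n_clusters == 2
        assert sorted(len(m) for m in part.groups().values()) == [3, 3]

    def test_path_plus_isolated_node(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        g.add_node("d")
        groups = connected_components(g).groups()
        assert sorted(map(tuple, groups.values())) == [("a", "b", "c"), ("d",)]

    def test_matches_bfs_transitive_closure(self, rng):
        g = nx.gnp_random_graph(12, 0.2, seed=3)
        part = connected_components(g)
        for u in g.nodes:
            reachable = set(nx.bfs_tree(g, u).nodes)
            labels = {part.assignment[v] for v in reachable}
            assert len(labels) == 1


class TestModularity:
    def test_single_cluster_is_zero(self, bridge_triangles):
        part = Partition({n: 0 for n in bridge_triangles.nodes})
        assert modularity(bridge_triangles, part) == pytest.approx(0.0, abs=1e-12)

    def test_bridge_triangles_hand_value(self, bridge_triangles):
        part = Partition({n: (0 if n in "abc" else 1) for n in bridge_triangles.nodes})
        # 2 * (3/7 - (7/14)^2) by direct evaluation
        assert modularity(bridge_triangles, part, weighted=False) == pytest.approx(
            0.357143, abs=1e-6
        )

    def test_triangle_all_singletons_negative(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        part = Partition({"a": 0, "b": 1, "c": 2})
        assert modularity(g, part) == pytest.approx(-1.0 / 3.0, abs=1e-12)

    def test_zero_edge_graph_undefined(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        with pytest.raises(ModularityUndefinedError):
            modularity(g, Partition({"a": 0, "b": 0}))

    def test_agrees_with_networkx_weighted_and_unweighted(self, rng):
        for trial in range(5):
            g = nx.gnp_random_graph(8, 0.5, seed=10 + trial)
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.5, 3.0))
            labels = {n: int(rng.integers(0, 3)) for n in g.nodes}
            part = Partition(labels)
            comms = [
                {n for n in g.nodes if part.assignment[n] == c}
                for c in set(part.assignment.values())
            ]
            for weighted in (True, False):
                ref = nx.community.modularity(
                    g, comms, weight="weight" if weighted else None
                )
                assert modularity(g, part, weighted=weighted) == pytest.approx(ref, abs=1e-12)


class TestLouvain:
    def test_disjoint_triangles_recovered_any_seed(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")])
        for seed in range(5):
            part = louvain_cluster(g, seed=seed)
            assert sorted(map(tuple, part.groups().values())) == [("a", "b", "c"), ("d", "e", "f")]

    def test_bridge_triangles_optimum(self, bridge_triangles):
        part = louvain_cluster(bridge_triangles, seed=0, weighted=False)
        assert part.quality == pytest.approx(0.357143, abs=1e-6)
        assert sorted(map(tuple, part.groups().values())) == [("a", "b", "c"), ("d", "e", "f")]

    def test_complete_graph_single_cluster(self):
        part = louvain_cluster(nx.complete_graph(4), seed=1, weighted=False)
        assert part.n_clusters == 1
        assert part.quality == pytest.approx(0.0, abs=1e-12)

    def test_quality_self_consistent_with_modularity(self, small_graph_pool):
        for g in small_graph_pool[:10]:
            part = louvain_cluster(g, seed=2, weighted=False)
            assert part.quality == pytest.approx(
                modularity(g, part, weighted=False), abs=1e-9
            )

    def test_edgeless_graph_rejected(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        with pytest.raises(ModularityUndefinedError):
            louvain_cluster(g)


class TestRandIndex:
    def test_identical_partitions_give_one(self):
        p = Partition({"a": 0, "b": 0, "c": 1})
        assert rand_index(p, p, adjusted=False) == 1.0
        assert rand_index(p, p, adjusted=True) == 1.0

    def test_crossed_pairs_hand_value(self):
        a = Partition(dict(zip("wxyz", [1, 1, 2, 2])))
        b = Partition(dict(zip("wxyz", [1, 2, 1, 2])))
        assert rand_index(a, b, adjusted=False) == pytest.approx(2.0 / 6.0)

    def test_singletons_vs_one_cluster(self):
        a = Partition(dict(zip("wxyz", [0, 1, 2, 3])))
        b = Partition(dict(zip("wxyz", [0, 0, 0, 0])))
        assert rand_index(a, b, adjusted=False) == 0.0

    def test_adjusted_one_iff_identical_up_to_relabeling(self):
        a = Partition(dict(zip("vwxyz", [0, 0, 1, 1, 2])))
        b = Partition(dict(zip("vwxyz", [7, 7, 3, 3, 9])))
        c = Partition(dict(zip("vwxyz", [0, 0, 1, 1, 1])))
        assert rand_index(a, b, adjusted=True) == 1.0
        assert rand_index(a, c, adjusted=True) < 1.0

    def test_symmetry_and_range(self, rng):
        ids = [f"i{k}" for k in range(20)]
        for _ in range(10):
            a = Partition(dict(zip(ids, rng.integers(0, 4, size=20))))
            b = Partition(dict(zip(ids, rng.integers(0, 4, size=20))))
            r1 = rand_index(a, b, adjusted=False)
            assert r1 == rand_index(b, a, adjusted=False)
            assert 0.0 <= r1 <= 1.0

    def test_identifier_mismatch_is_an_error(self):
        a = Partition({"a": 0, "b": 0})
        b = Partition({"a": 0, "c": 0})
        with pytest.raises(PartitionMismatchError, match="offenders"):
            rand_index(a, b)


class TestPartitionCanonicalization:
    def test_labels_by_decreasing_size_ties_by_smallest_member(self):
        part = Partition({"z": 9, "a": 5, "b": 5, "m": 7, "n": 7})
        groups = part.groups()
        assert groups[1] == ["a", "b"]  # size-2 tie broken by smallest member
        assert groups[2] == ["m", "n"]
        assert groups[3] == ["z"]


class TestClusterReport:
    def test_report_rows_and_contingency_marginals(self, small_families):
        from retronet import build_ssn, distance_matrix

        aln, truth = small_families
        g = build_ssn(distance_matrix(aln, model="poisson"))
        mc = louvain_cluster(g, seed=0)
        cc = connected_components(g)
        report, cont = cluster_report(g, [mc, cc], truth.labels)
        assert list(report["method"]) == ["MC", "CC"]
        sizes = {lab: len(m) for lab, m in mc.groups().items()}
        assert all(cont.sum(axis=1)[lab] == sizes[lab] for lab in cont.index)

    def test_unlabeled_node_is_an_error(self, small_families):
        from retronet import build_ssn, distance_matrix

        aln, truth = small_families
        g = build_ssn(distance_matrix(aln, model="poisson"))
        cc = connected_components(g)
        labels = dict(truth.labels)
        labels.pop(aln.ids[0])
        with pytest.raises(PartitionMismatchError):
            cluster_report(g, [cc], labels)


class TestEstimator:
    def test_fit_matches_functional_api(self):
        vals = np.array(
            [[0, 0.1, 3.0, 3.0], [0.1, 0, 3.0, 3.0], [3.0, 3.0, 0, 0.1], [3.0, 3.0, 0.1, 0]]
        )
        est = SSNClustering(method="cc").fit(vals)
        assert est.n_clusters_ == 2
        assert est.labels_[0] == est.labels_[1] != est.labels_[2]
        mc = SSNClustering(method="mc", random_state=1).fit(vals)
        assert mc.n_clusters_ == 2
        assert mc.modularity_ == pytest.approx(
            modularity(mc.graph_, mc.partition_), abs=1e-12
        )

    def test_sklearn_protocol(self):
        from sklearn.base import clone

        est = SSNClustering(tau=0.5, method="cc")
        cloned = clone(est)
        assert cloned.get_params()["tau"] == 0.5
        cloned.set_params(method="mc")
        assert cloned.method == "mc"


@pytest.fixture(scope="module")
def small_graph_pool():
    """Random connected-ish graphs with at least one edge, n <= 8."""
    rng = np.random.default_rng(77)
    pool = []
    while len(pool) < 20:
        n = int(rng.integers(4, 9))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.3, 0.7)), seed=int(rng.integers(1 << 30)))
        if g.number_of_edges() >= 1:
            pool.append(g)
    return pool


def test_louvain_attains_brute_force_optimum_on_small_graphs(small_graph_pool):
    for g in small_graph_pool:
        A = nx.to_numpy_array(g)
        best = brute_force_best_modularity(A)
        part = louvain_cluster(g, seed=0, weighted=False)
        assert part.quality == pytest.approx(best, abs=1e-9)


def test_unadjusted_rand_matches_pair_enumeration(rng):
    ids = [f"i{k}" for k in range(25)]
    for _ in range(20):
        la = rng.integers(0, 5, size=25)
        lb = rng.integers(0, 5, size=25)
        a = Partition(dict(zip(ids, (int(x) for x in la))))
        b = Partition(dict(zip(ids, (int(x) for x in lb))))
        assert rand_index(a, b, adjusted=False) == pytest.approx(
            rand_index_by_pairs(la, lb), abs=1e-12
        )
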