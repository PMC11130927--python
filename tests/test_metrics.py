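import time

import networkx as nx
import numpy as np
import pytest

from fcnet import (
    BinaryGraph,
    avg_clustering,
    global_efficiency,
    induced_subgraph,
    mean_degree,
    metric_battery,
    modularity,
)
from conftest import graph_from_dense, parcellation_of
from oracles import (
    clustering_naive,
    floyd_warshall_efficiency,
    mean_degree_naive,
    modularity_naive,
    random_graph,
)


def complete(n):
    return graph_from_dense(np.ones((n, n)) - np.eye(n))


def two_disjoint_edges():
    a = np.zeros((4, 4), dtype=int)
    a[0, 1] = a[1, 0] = 1
    a[2, 3] = a[3, 2] = 1
    return graph_from_dense(a)


class TestMeanDegree:
    def test_complete_graph(self):
        assert mean_degree(complete(4)) == 3.0

    def test_empty_graph(self):
        assert mean_degree(graph_from_dense(np.zeros((5, 5)))) == 0.0

    def test_path_graph(self):
        a = np.zeros((4, 4), dtype=int)
        for i in range(3):
            a[i, i + 1] = a[i + 1, i] = 1
        assert mean_degree(graph_from_dense(a)) == 1.5


class TestGlobalEfficiency:
    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    def test_complete_graph_is_one(self, n):
        assert global_efficiency(complete(n)) == pytest.approx(1.0, abs=1e-12)

    def test_two_disjoint_edges(self):
        # 4 ordered pairs at distance 1, 8 unreachable: 4 / (4*3)
        assert global_efficiency(two_disjoint_edges()) == pytest.approx(1 / 3)

    def test_matches_floyd_warshall_on_random_graphs(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 13))
            a = random_graph(rng, n, float(rng.uniform(0.1, 0.9)))
            got = global_efficiency(graph_from_dense(a))
            assert got == pytest.approx(floyd_warshall_efficiency(a), abs=1e-12)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            global_efficiency(graph_from_dense(np.zeros((1, 1))))

    def test_batched_bfs_handles_sparse_2000_node_graph(self, rng):
        """Per-source BFS in batches: no dense n x n distance matrix."""
        n = 2000
        rows = rng.integers(0, n, size=int(0.05 * n * (n - 1) / 2))
        cols = rng.integers(0, n, size=len(rows))
        keep = rows != cols
        g = BinaryGraph.from_edges([f"v{i}" for i in range(n)],
                                   np.column_stack([rows[keep], cols[keep]]))
        t0 = time.time()
        e = global_efficiency(g, batch_size=128)
        assert 0.0 < e < 1.0
        assert time.time() - t0 < 60


class TestModularity:
    def test_single_community_is_zero(self, rng):
        a = random_graph(rng, 8, 0.5)
        if a.sum() == 0:
            a[0, 1] = a[1, 0] = 1
        g = graph_from_dense(a)
        p = parcellation_of(["R"] * 8)
        assert modularity(g, p) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_edges_matched_partition(self):
        g = two_disjoint_edges()
        p = parcellation_of(["A", "A", "B", "B"])
        assert modularity(g, p) == pytest.approx(0.5, abs=1e-12)

    def test_matches_double_loop_oracle_on_random_partitions(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 13))
            a = random_graph(rng, n, 0.5)
            if a.sum() == 0:
                continue
            labels = [str(rng.integers(0, 3)) for _ in range(n)]
            g = graph_from_dense(a)
            p = parcellation_of(labels)
            assert modularity(g, p) == pytest.approx(
                modularity_naive(a, labels), abs=1e-12
            )

    def test_edgeless_graph_rejected(self):
        g = graph_from_dense(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="no edges"):
            modularity(g, parcellation_of(["A", "A", "B", "B"]))

    def test_stream_level_partition(self):
        g = two_disjoint_edges()
        p = parcellation_of(
            ["A", "A", "B", "B"],
            streams={"A": "early", "B": "early"},
        )
        # at stream level everything is one community -> Q = 0
        assert modularity(g, p, level="stream") == pytest.approx(0.0, abs=1e-12)
        assert modularity(g, p, level="region") == pytest.approx(0.5)


class TestClustering:
    def test_triangle(self):
        assert avg_clustering(complete(3)) == 1.0

    def test_star_has_no_triangles(self):
        a = np.zeros((5, 5), dtype=int)
        a[0, 1:] = 1
        a[1:, 0] = 1
        assert avg_clustering(graph_from_dense(a)) == 0.0

    def test_matches_triple_enumeration_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 13))
            a = random_graph(rng, n, float(rng.uniform(0.2, 0.8)))
            g = graph_from_dense(a)
            for flag in (False, True):
                assert avg_clustering(g, exclude_low_degree=flag) == pytest.approx(
                    clustering_naive(a, exclude_low_degree=flag), abs=1e-12
                )

    def test_low_degree_exclusion_changes_average(self):
        # triangle plus a pendant vertex: included-zero vs excluded
        a = np.zeros((4, 4), dtype=int)
        for i, j in [(0, 1), (1, 2), (0, 2), (0, 3)]:
            a[i, j] = a[j, i] = 1
        g = graph_from_dense(a)
        # C = 1/3 for the triangle vertex carrying the pendant, 1 for the
        # other two triangle vertices, 0 for the pendant itself
        assert avg_clustering(g) == pytest.approx((1 / 3 + 1 + 1 + 0) / 4)
        assert avg_clustering(g, exclude_low_degree=True) == pytest.approx(
            (1 / 3 + 1 + 1) / 3
        )


class TestInducedSubgraph:
    def test_full_subset_is_identity(self, rng):
        a = random_graph(rng, 6, 0.5)
        g = graph_from_dense(a)
        sub = induced_subgraph(g, g.node_ids)
        assert sub.is_same_graph(g)

    def test_single_node(self):
        g = complete(5)
        sub = induced_subgraph(g, ["v2"])
        assert sub.n == 1 and sub.k == 0

    def test_k5_restricted_to_three_nodes_is_k3(self):
        sub = induced_subgraph(complete(5), ["v0", "v2", "v4"])
        assert sub.k == 3
        assert mean_degree(sub) == 2.0

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError, match="nope"):
            induced_subgraph(complete(3), ["v0", "nope"])

    def test_edges_match_manual_restriction(self, rng):
        for _ in range(20):
            a = random_graph(rng, 10, 0.4)
            g = graph_from_dense(a)
            keep = sorted(rng.choice(10, size=5, replace=False))
            sub = induced_subgraph(g, [f"v{i}" for i in keep])
            assert np.array_equal(sub.adj.toarray(), a[np.ix_(keep, keep)])


class TestInvariants:
    def test_adding_edge_never_decreases_degree_or_efficiency(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 10))
            a = random_graph(rng, n, 0.4)
            missing = [(i, j) for i in range(n) for j in range(i + 1, n)
                       if not a[i, j]]
            if not missing:
                continue
            i, j = missing[rng.integers(len(missing))]
            b = a.copy()
            b[i, j] = b[j, i] = 1
            ga, gb = graph_from_dense(a), graph_from_dense(b)
            assert mean_degree(gb) >= mean_degree(ga)
            assert global_efficiency(gb) >= global_efficiency(ga) - 1e-12

    def test_unit_clustering_and_efficiency_iff_complete(self, rng):
        """Both directions, via exhaustive 4-node enumeration."""
        import itertools

        for bits in itertools.product([0, 1], repeat=6):
            a = np.zeros((4, 4), dtype=int)
            for (i, j), b in zip(itertools.combinations(range(4), 2), bits):
                a[i, j] = a[j, i] = b
            g = graph_from_dense(a)
            is_complete = all(bits)
            assert (global_efficiency(g) == 1.0) == is_complete
            assert (avg_clustering(g) == 1.0) == is_complete

    def test_isomorphism_invariance(self, rng):
        a = random_graph(rng, 9, 0.45)
        labels = [str(rng.integers(0, 3)) for _ in range(9)]
        g = graph_from_dense(a)
        p = parcellation_of(labels)
        perm = rng.permutation(9)
        g2 = graph_from_dense(a[np.ix_(perm, perm)],
                              ids=[f"v{i}" for i in perm])
        from fcnet import Parcellation

        p2 = Parcellation(
            np.array([f"v{i}" for i in perm], dtype=object),
            np.array([labels[i] for i in perm], dtype=object),
            {lab: "early" for lab in set(labels)},
        )
        assert mean_degree(g) == mean_degree(g2)
        assert global_efficiency(g) == pytest.approx(global_efficiency(g2), abs=1e-12)
        assert avg_clustering(g) == pytest.approx(avg_clustering(g2), abs=1e-12)
        if a.sum():
            assert modularity(g, p) == pytest.approx(modularity(g2, p2), abs=1e-12)

    def test_agrees_with_networkx(self, rng):
        """Independent library cross-check on a mid-sized random graph."""
        a = random_graph(rng, 40, 0.15)
        g = graph_from_dense(a)
        nxg = g.to_networkx()
        assert mean_degree(g) == pytest.approx(
            2 * nxg.number_of_edges() / 40, abs=1e-12)
        assert global_efficiency(g) == pytest.approx(
            nx.global_efficiency(nxg), abs=1e-10)
        assert avg_clustering(g) == pytest.approx(
            nx.average_clustering(nxg), abs=1e-10)
        labels = {f"v{i}": i % 4 for i in range(40)}
        communities = [{v for v, c in labels.items() if c == k} for k in range(4)]
        p = parcellation_of([str(labels[f"v{i}"]) for i in range(40)])
        assert modularity(g, p) == pytest.approx(
            nx.community.modularity(nxg, communities), abs=1e-10)


class TestMetricBattery:
    def _parc_4x8(self):
        labels = []
        streams = {}
        for s_i, stream in enumerate(
            ["early", "ventral", "dorsal", "fronto-parietal"]
        ):
            for r_i in range(2):
                name = f"R{s_i}{r_i}"
                labels += [name] * 4
                streams[name] = stream
        return parcellation_of(labels, streams)

    def test_row_bookkeeping_4_streams_8_regions(self, rng):
        p = self._parc_4x8()
        a = random_graph(rng, 32, 0.4)
        g = graph_from_dense(a)
        rows = metric_battery(g, p)
        # 4 global + 4 streams x 4 + 8 regions x 1
        assert len(rows) == 4 + 16 + 8 == 28
        assert (rows[rows.scope == "global"].metric.tolist()
                == ["mean_degree", "efficiency", "clustering", "modularity"])

    def test_empty_graph_rows(self):
        p = self._parc_4x8()
        g = graph_from_dense(np.zeros((32, 32)))
        rows = metric_battery(g, p)
        assert not (rows.metric == "modularity").any()
        assert (rows.value == 0).all()

    def test_scope_filtering(self, rng):
        p = self._parc_4x8()
        g = graph_from_dense(random_graph(rng, 32, 0.4))
        rows = metric_battery(g, p, scopes=("global", "streams"))
        assert not rows.scope.str.startswith("region:").any()
        assert rows.scope.str.startswith("stream:").sum() == 16

    def test_planted_structure_beats_degree_preserving_rewiring(self, rng):
        """Modularity of a modular graph drops under double-edge swaps."""
        blocks = np.kron(np.eye(4), np.ones((8, 8)))
        prob = np.where(blocks, 0.8, 0.05)
        a = (rng.random((32, 32)) < prob).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        g = graph_from_dense(a)
        labels = [f"B{i // 8}" for i in range(32)]
        p = parcellation_of(labels)
        q_planted = modularity(g, p)
        for swap_seed in range(20):
            nxg = g.to_networkx()
            nx.double_edge_swap(nxg, nswap=4 * g.k, max_tries=10**5,
                                seed=swap_seed)
            rewired = graph_from_dense(
                nx.to_numpy_array(nxg, nodelist=list(g.node_ids)).astype(int)
            )
            assert modularity(rewired, p) < q_planted
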