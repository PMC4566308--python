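"""Co-expression network construction and Markov clustering."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import leafcorr as lc
from leafcorr.network import _mcl_matrix


def _expr_from_rows(rows: dict[str, np.ndarray]) -> lc.ExpressionMatrix:
    df = pd.DataFrame(rows).T
    df.columns = [f"s{j}" for j in range(df.shape[1])]
    return lc.ExpressionMatrix(df)


def reference_mcl(adj: list[list[float]], inflation: float = 2.0,
                  n_iter: int = 200, prune: float = 1e-5) -> list[set[int]]:
    """Deliberately naive MCL (pure-Python loops) used as an independent oracle."""
    n = len(adj)
    M = [row[:] for row in adj]
    for i in range(n):
        incident = max(M[i][j] for j in range(n))
        M[i][i] = incident if incident > 0 else 1.0
    for j in range(n):
        s = sum(M[i][j] for i in range(n))
        for i in range(n):
            M[i][j] /= s
    for _ in range(n_iter):
        # expansion: M @ M
        E = [[sum(M[i][k] * M[k][j] for k in range(n)) for j in range(n)]
             for i in range(n)]
        # inflation + prune + renormalize
        for j in range(n):
            col = [E[i][j] ** inflation for i in range(n)]
            col = [c if c >= prune else 0.0 for c in col]
            s = sum(col) or 1.0
            for i in range(n):
                E[i][j] = col[i] / s
        M = E
    clusters = []
    for i in range(n):
        if M[i][i] > 1e-6:
            members = {j for j in range(n) if M[i][j] > 1e-6} | {i}
            for c in clusters:
                if c & members:
                    c |= members
                    break
            else:
                clusters.append(members)
    return clusters


class TestBuildNetwork:
    def test_scaled_and_negated_profiles(self, rng):
        base = rng.normal(size=30)
        expr = _expr_from_rows(
            {"g1": base, "g2": 2 * base, "g3": -base, "g4": rng.normal(size=30)}
        )
        net = lc.build_network(expr, ["g1", "g2", "g3", "g4"], threshold=0.6)
        assert net["g1"]["g2"]["r"] == pytest.approx(1.0)
        assert net["g1"]["g3"]["r"] == pytest.approx(-1.0)
        assert net["g1"]["g3"]["weight"] == pytest.approx(1.0)
        assert not net.has_edge("g1", "g4") or abs(net["g1"]["g4"]["r"]) >= 0.6

    def test_edge_set_matches_bruteforce(self, rng):
        X = rng.normal(size=(50, 40))
        # plant a few correlated pairs
        X[1] = X[0] + rng.normal(0, 0.3, 40)
        X[3] = -X[2] + rng.normal(0, 0.3, 40)
        rows = {f"g{i:02d}": X[i] for i in range(50)}
        expr = _expr_from_rows(rows)
        net = lc.build_network(expr, list(rows), threshold=0.6)
        expected = set()
        names = sorted(rows)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                r = np.corrcoef(rows[a], rows[b])[0, 1]
                if abs(r) >= 0.6:
                    expected.add((a, b))
        assert {tuple(sorted(e)) for e in net.edges} == expected

    def test_constant_gene_excluded_with_warning(self, rng):
        expr = _expr_from_rows(
            {"g1": rng.normal(size=10), "g2": np.full(10, 2.0), "g3": rng.normal(size=10)}
        )
        with pytest.warns(UserWarning, match="constant"):
            net = lc.build_network(expr, ["g1", "g2", "g3"])
        assert "g2" not in net

    def test_edge_symmetry(self, rng):
        base = rng.normal(size=20)
        expr = _expr_from_rows({"g1": base, "g2": base + rng.normal(0, 0.1, 20)})
        net = lc.build_network(expr, ["g1", "g2"])
        assert net["g1"]["g2"]["r"] == net["g2"]["g1"]["r"]


class TestMcl:
    def _graph(self, edges):
        G = nx.Graph()
        G.add_weighted_edges_from([(a, b, 1.0) for a, b in edges], weight="weight")
        return G

    def test_two_disjoint_triangles(self):
        G = self._graph([("a", "b"), ("b", "c"), ("a", "c"),
                         ("x", "y"), ("y", "z"), ("x", "z")])
        assign = lc.mcl(G)
        sizes = sorted(assign.sizes())
        assert sizes == [3, 3]
        assert assign.labels["a"] == assign.labels["b"] == assign.labels["c"]
        assert assign.labels["a"] != assign.labels["x"]

    def test_single_edge_single_cluster(self):
        assign = lc.mcl(self._graph([("a", "b")]))
        assert assign.labels["a"] == assign.labels["b"]
        assert len(assign.sizes()) == 1

    def test_barbell_matches_reference_implementation(self):
        # two 5-cliques joined by a 2-path through nodes 10 and 11
        G = nx.Graph()
        for base in (0, 5):
            for i in range(base, base + 5):
                for j in range(i + 1, base + 5):
                    G.add_edge(i, j, weight=1.0)
        G.add_edge(4, 10, weight=1.0)
        G.add_edge(10, 11, weight=1.0)
        G.add_edge(11, 5, weight=1.0)
        assign = lc.mcl(G, inflation=2.0)
        nodes = sorted(G.nodes)
        adj = [[G[a][b]["weight"] if G.has_edge(a, b) else 0.0 for b in nodes]
               for a in nodes]
        ref_clusters = reference_mcl(adj, inflation=2.0)
        ref_labels = {}
        for cid, members in enumerate(sorted(ref_clusters, key=lambda c: sorted(c)[0])):
            for m in members:
                ref_labels[nodes[m]] = cid
        # same partition up to label renaming
        ours = assign.labels
        pairs = {(ours[a] == ours[b], ref_labels[a] == ref_labels[b])
                 for i, a in enumerate(nodes) for b in nodes[i + 1:]}
        assert all(x == y for x, y in pairs)
        # splits at the bridge into two communities
        assert len(set(ours[n] for n in nodes)) >= 2
        assert ours[0] == ours[1] == ours[2] == ours[3]
        assert ours[5] == ours[6] == ours[7] == ours[8]
        assert ours[0] != ours[5]

    def test_disjoint_union_equals_union_of_parts(self):
        G1 = self._graph([("a", "b"), ("b", "c"), ("a", "c")])
        G2 = self._graph([("p", "q"), ("q", "r")])
        both = nx.union(G1, G2)
        a1, a2, ab = lc.mcl(G1), lc.mcl(G2), lc.mcl(both)
        for G, part in ((G1, a1), (G2, a2)):
            for x in G.nodes:
                for y in G.nodes:
                    assert (ab.labels[x] == ab.labels[y]) == (
                        part.labels[x] == part.labels[y]
                    )

    def test_relabeling_invariance_and_determinism(self):
        G = self._graph([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"),
                         ("d", "e"), ("e", "f"), ("d", "f")])
        a1, a2 = lc.mcl(G), lc.mcl(G)
        assert a1.labels.equals(a2.labels)
        mapping = {n: f"node_{n}" for n in G.nodes}
        H = nx.relabel_nodes(G, mapping)
        ah = lc.mcl(H)
        for x in G.nodes:
            for y in G.nodes:
                assert (a1.labels[x] == a1.labels[y]) == (
                    ah.labels[mapping[x]] == ah.labels[mapping[y]]
                )

    def test_column_sums_stay_stochastic(self):
        G = self._graph([("a", "b"), ("b", "c"), ("c", "d")])
        A = nx.to_numpy_array(G, nodelist=sorted(G.nodes), weight="weight")
        M, converged = _mcl_matrix(A, 2.0, 2, 1e-5, 100, 1e-8)
        assert converged
        assert np.allclose(M.sum(axis=0), 1.0, atol=1e-9)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lc.mcl(nx.Graph())


class TestClusterSummary:
    def test_min_size_count(self):
        labels = pd.Series(
            {f"g{i}": (0 if i < 20 else 1 if i < 36 else 2) for i in range(39)}
        )
        summary = lc.cluster_summary(lc.ClusterAssignment(labels), min_size=15)
        assert summary["large"].sum() == 2
        assert list(summary["size"]) == [20, 16, 3]

    def test_empty_assignment(self):
        summary = lc.cluster_summary(
            lc.ClusterAssignment(pd.Series(dtype=int)), min_size=15
        )
        assert summary.empty

    def test_planted_modules_recovered(self, rng):
        # 3 modules of sizes 30/20/10 with strong within-module correlation
        sizes = [30, 20, 10]
        rows = {}
        n = 60
        gid = 0
        for m, size in enumerate(sizes):
            latent = rng.normal(size=n)
            for _ in range(size):
                rows[f"g{gid:03d}"] = latent + rng.normal(0, 0.45, n)
                gid += 1
        expr = _expr_from_rows(rows)
        net = lc.build_network(expr, list(rows), threshold=0.6)
        assign = lc.mcl(net)
        summary = lc.cluster_summary(assign, min_size=15)
        assert summary["large"].sum() == 2
        large_sizes = sorted(summary.loc[summary["large"], "size"])
        assert large_sizes[0] >= 18 and large_sizes[1] >= 28
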