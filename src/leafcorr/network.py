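"""Thresholded co-expression network and a from-scratch Markov Cluster algorithm.

Nodes are trait-associated transcripts; edges connect pairs whose
expression profiles correlate with |r| at or above the threshold (0.6 by
default).  The signed correlation is kept as an edge attribute; MCL
operates on the non-negative weight |r|.

MCL alternates expansion (stochastic-matrix powering) and inflation
(elementwise powering with column renormalization), pruning tiny
entries, until the matrix is numerically idempotent.  Clusters are read
off the limit matrix through its attractors.  The algorithm is fully
deterministic.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .types import ClusterAssignment, ExpressionMatrix


def build_network(
    expr: ExpressionMatrix, genes: list[str] | set[str], threshold: float = 0.6
) -> nx.Graph:
    """All-pairs PCC graph over ``genes``, keeping edges with |r| >= threshold.

    Constant genes cannot carry a correlation and are dropped (with a
    warning); every retained node appears in the graph even if isolated.
    Edge attributes: ``r`` (signed) and ``weight`` (= |r|).
    """
    genes = sorted(set(genes))
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to build a network")
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing[:10]}")
    X = expr.values.loc[genes].to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant genes excluded from the network",
            stacklevel=2,
        )
        genes = [g for g, c in zip(genes, const) if not c]
        X = X[~const]
    R = np.corrcoef(X)
    G = nx.Graph()
    G.add_nodes_from(genes)
    idx_i, idx_j = np.triu_indices(len(genes), k=1)
    keep = np.abs(R[idx_i, idx_j]) >= threshold
    for i, j in zip(idx_i[keep], idx_j[keep]):
        r = float(R[i, j])
        G.add_edge(genes[i], genes[j], r=r, weight=abs(r))
    G.graph["threshold"] = threshold
    return G


def _mcl_matrix(
    A: np.ndarray,
    inflation: float,
    expansion: int,
    prune: float,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, bool]:
    n = A.shape[0]
    A = A.copy()
    # self-loops at the node's max incident weight (1 for isolated nodes)
    maxw = A.max(axis=0)
    np.fill_diagonal(A, np.where(maxw > 0, maxw, 1.0))
    M = A / A.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = M**inflation
        M /= M.sum(axis=0, keepdims=True)
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if np.max(np.abs(M - prev)) < tol:
            converged = True
            break
    return M, converged


def mcl(
    network: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    prune: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ClusterAssignment:
    """Markov clustering of the weighted network.

    The limit matrix's attractors (nodes with positive return mass)
    define cluster cores; attractors reaching each other merge, and each
    remaining node joins the cluster of an attractor that claims it.
    Nodes claimed by several clusters go to the largest (ties to the
    lowest cluster id); unclaimed nodes become singleton clusters.
    Cluster ids are assigned by decreasing size, then lowest member id.
    """
    nodes = sorted(network.nodes)
    if not nodes:
        raise ValueError("empty network")
    A = nx.to_numpy_array(network, nodelist=nodes, weight="weight")
    M, converged = _mcl_matrix(A, inflation, expansion, prune, max_iter, tol)
    if not converged:
        warnings.warn("MCL did not converge within max_iter", stacklevel=2)
    eps = max(tol, 1e-9)
    attractors = [i for i in range(len(nodes)) if M[i, i] > eps]
    # union attractors that occur in each other's rows
    parent = {i: i for i in attractors}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    attr_set = set(attractors)
    members = {i: set(np.nonzero(M[i] > eps)[0]) | {i} for i in attractors}
    for i in attractors:
        for j in members[i] & attr_set:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
    cores: dict[int, set[int]] = {}
    for i in attractors:
        cores.setdefault(find(i), set()).update(members[i])
    clusters = sorted(
        cores.values(), key=lambda c: (-len(c), min(nodes[i] for i in c))
    )
    claim: dict[int, int] = {}
    for cid, cluster in enumerate(clusters):
        for i in cluster:
            if i not in claim:  # earlier (larger / lower-id) cluster wins
                claim[i] = cid
    next_id = len(clusters)
    labels = {}
    for i, node in enumerate(nodes):
        if i in claim:
            labels[node] = claim[i]
        else:
            labels[node] = next_id
            next_id += 1
    return ClusterAssignment(pd.Series(labels, name="cluster"), converged=converged)


def cluster_summary(
    assignment: ClusterAssignment, min_size: int = 15
) -> pd.DataFrame:
    """Cluster sizes and member lists, ordered by size then lowest gene id.

    The ``large`` flag marks clusters with at least ``min_size`` members
    (the circular-layout / enrichment-eligible clusters).
    """
    rows = []
    for cid, members in assignment.labels.groupby(assignment.labels).groups.items():
        genes = sorted(members)
        rows.append(
            {
                "cluster": cid,
                "size": len(genes),
                "large": len(genes) >= min_size,
                "genes": genes,
            }
        )
    rows.sort(key=lambda r: (-r["size"], r["genes"][0]))
    return pd.DataFrame(rows, columns=["cluster", "size", "large", "genes"])


def write_edge_list(network: nx.Graph, path) -> None:
    rows = [
        {"gene_a": a, "gene_b": b, "r": d["r"], "weight": d["weight"]}
        for a, b, d in sorted(network.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "weight"]).to_csv(
        path, sep="\t", index=False
    )
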