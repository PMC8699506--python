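"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (all-pairs scans, dense matrix
powers, union-find, exhaustive search) and shares no code with the
implementation it checks.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np


def edit_distance(a, b) -> int:
    """Plain Wagner-Fischer edit distance over symbol sequences."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[m]


def all_pairs_network(lexicon) -> set[frozenset]:
    """Edge set of the unit-edit-distance graph by O(n^2) comparison."""
    edges = set()
    entries = list(lexicon)
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            if edit_distance(entries[i].transcription, entries[j].transcription) == 1:
                edges.add(frozenset({entries[i].word_id, entries[j].word_id}))
    return edges


def bfs_two_hop(G: nx.Graph, source) -> set:
    """Nodes within BFS depth 2 of source."""
    seen = {source}
    frontier = {source}
    for _ in range(2):
        frontier = {w for v in frontier for w in G.neighbors(v)} - seen
        seen |= frontier
    return seen


def clustering_by_triples(G: nx.Graph, node) -> float:
    """Local clustering by enumerating all neighbor pairs."""
    nbrs = list(G.neighbors(node))
    k = len(nbrs)
    if k < 2:
        return 0.0
    closed = sum(
        1
        for i in range(k)
        for j in range(i + 1, k)
        if G.has_edge(nbrs[i], nbrs[j])
    )
    return closed / (k * (k - 1) / 2)


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def components_by_union_find(G: nx.Graph) -> set[frozenset]:
    uf = UnionFind(G.nodes())
    for u, v in G.edges():
        uf.union(u, v)
    groups: dict = {}
    for node in G.nodes():
        groups.setdefault(uf.find(node), set()).add(node)
    return {frozenset(s) for s in groups.values()}


def fragmentation_by_definition(G: nx.Graph) -> float:
    """F as the fraction of ordered distinct node pairs that are
    mutually unreachable, counted pair by pair."""
    nodes = list(G.nodes())
    n = len(nodes)
    unreachable = 0
    for i in range(n):
        reach = set(nx.node_connected_component(G, nodes[i]))
        for j in range(n):
            if i != j and nodes[j] not in reach:
                unreachable += 1
    return unreachable / (n * (n - 1))


def best_single_removal(G: nx.Graph):
    """Exhaustive argmax over single-node removals (smallest-id ties)."""
    best_node, best_f = None, -1.0
    for node in sorted(G.nodes()):
        H = G.copy()
        H.remove_node(node)
        if H.number_of_nodes() < 2:
            f = 0.0
        else:
            f = fragmentation_by_definition(H)
        if f > best_f:
            best_node, best_f = node, f
    return best_node, best_f


def transfer_matrix(G: nx.Graph, params) -> tuple[np.ndarray, list]:
    """Dense one-step matrix M with state' = (1 - d) * M @ state
    (suppress must be 0 for this closed form)."""
    nodes = sorted(G.nodes())
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for v in nodes:
        k = G.degree(v)
        if k == 0:
            M[idx[v], idx[v]] = 1.0
        else:
            M[idx[v], idx[v]] = params.r
            for w in G.neighbors(v):
                M[idx[w], idx[v]] = (1.0 - params.r) / k
    return (1.0 - params.d) * M, nodes


def diffusion_by_matrix_power(G: nx.Graph, seeds: dict, params) -> dict:
    """State after params.t steps via the t-th matrix power."""
    M, nodes = transfer_matrix(G, params)
    a0 = np.array([seeds.get(v, 0.0) for v in nodes])
    a = np.linalg.matrix_power(M, params.t) @ a0
    return dict(zip(nodes, a))


def textbook_t_test(x1, x2):
    """Pooled two-sample t written straight from the textbook formula,
    with the p-value from scipy's reference routine."""
    from scipy.stats import ttest_ind

    n1, n2 = len(x1), len(x2)
    m1 = sum(x1) / n1
    m2 = sum(x2) / n2
    s1 = sum((x - m1) ** 2 for x in x1) / (n1 - 1)
    s2 = sum((x - m2) ** 2 for x in x2) / (n2 - 1)
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    ref = ttest_ind(x1, x2, equal_var=True)
    return t, ref.statistic, ref.pvalue
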