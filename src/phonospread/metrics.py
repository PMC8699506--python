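"""Structure of the phonological network at three scales.

Micro: the local clustering coefficient ``C`` — the fraction of a word's
neighbor pairs that are themselves neighbors (``C := 0`` for degree < 2,
so group means over stimulus sets are always defined).

Macro: the partition into connected components, classified as the giant
component (largest, if it has at least two nodes), lexical islands
(other components of size >= 2), and lexical hermits / isolates
(degree-0 singletons).

Meso: key players — node sets whose removal maximally fragments the
residual graph under the fragmentation measure

    F = 1 - sum_k s_k (s_k - 1) / (n (n - 1)),

where the ``s_k`` are component sizes of a graph on ``n`` nodes.  F is 0
for a connected graph and 1 for an edgeless one.  Selection is a greedy
search with one pairwise-swap refinement pass and deterministic
smallest-id tie-breaking.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterable

import networkx as nx

from .errors import ResolutionError, ValidationError

__all__ = [
    "ComponentPartition",
    "KeyPlayerResult",
    "local_clustering",
    "component_partition",
    "fragmentation",
    "key_players",
    "node_metrics_table",
    "write_node_metrics",
]


def local_clustering(network: nx.Graph, word_id: Hashable) -> float:
    """Local clustering coefficient of one node.

    C = (edges among neighbors) / (k choose 2); 0 when k < 2.
    """
    if word_id not in network:
        raise ResolutionError(f"node {word_id!r} not in network")
    neighbors = list(network.neighbors(word_id))
    k = len(neighbors)
    if k < 2:
        return 0.0
    nbr_set = set(neighbors)
    links = 0
    for v in neighbors:
        links += sum(1 for w in network.neighbors(v) if w in nbr_set)
    links //= 2  # each neighbor-neighbor edge counted from both ends
    return links / (k * (k - 1) / 2)


@dataclass(frozen=True)
class ComponentPartition:
    """Connected components sorted by decreasing size, classified.

    The giant component is the largest component provided it holds at
    least two nodes; in an edgeless graph every node is an isolate and
    ``giant`` is empty.  Ties for largest break on the smallest node id.
    """

    components: tuple[frozenset, ...]
    giant: frozenset
    islands: tuple[frozenset, ...]
    isolates: frozenset

    def classify(self, node: Hashable) -> str:
        if node in self.isolates:
            return "isolate"
        if node in self.giant:
            return "giant"
        return "island"


def component_partition(network: nx.Graph) -> ComponentPartition:
    """Partition the node set into giant / islands / isolates."""
    comps = [frozenset(c) for c in nx.connected_components(network)]
    comps.sort(key=lambda c: (-len(c), min(c) if c else 0))
    if comps and len(comps[0]) >= 2:
        giant = comps[0]
        rest = comps[1:]
    else:
        giant = frozenset()
        rest = comps
    islands = tuple(c for c in rest if len(c) >= 2)
    isolates = frozenset().union(*(c for c in rest if len(c) == 1)) if rest else frozenset()
    return ComponentPartition(tuple(comps), giant, islands, isolates)


def fragmentation(network: nx.Graph) -> float:
    """Fragmentation F of a graph on n >= 2 nodes.

    F = 1 - sum s(s-1) / (n(n-1)) over component sizes s: the
    probability that two distinct nodes chosen at random cannot reach
    each other.
    """
    n = network.number_of_nodes()
    if n < 2:
        raise ValidationError(f"fragmentation undefined for n = {n} < 2")
    reach = sum(
        len(c) * (len(c) - 1) for c in nx.connected_components(network)
    )
    return 1.0 - reach / (n * (n - 1))


def _residual_fragmentation(network: nx.Graph, removed: set) -> float:
    residual = network.subgraph(n for n in network if n not in removed)
    if residual.number_of_nodes() < 2:
        return 0.0  # trivially one component
    return fragmentation(residual)


@dataclass(frozen=True)
class KeyPlayerResult:
    """Selected key-player set and the residual graph's fragmentation."""

    selected: frozenset
    F: float


def key_players(network: nx.Graph, k_target: int) -> KeyPlayerResult:
    """Greedy key-player search for the set of ``k_target`` nodes whose
    removal maximizes residual fragmentation.

    Greedy forward selection (best single node first, then the node with
    the largest fragmentation gain at each step) followed by one pass of
    pairwise swap refinement.  All ties break on the smallest node id,
    so the result is deterministic.  The residual F is computed on the
    graph after removal, with n = remaining node count.
    """
    n = network.number_of_nodes()
    if not (0 < k_target < n):
        raise ValidationError(
            f"k_target must be in [1, n-1]; got {k_target} with n = {n}"
        )
    nodes = sorted(network.nodes())
    selected: set = set()
    for _ in range(k_target):
        best_node, best_f = None, -1.0
        for cand in nodes:
            if cand in selected:
                continue
            f = _residual_fragmentation(network, selected | {cand})
            if f > best_f:  # first-seen wins ties; nodes is sorted by id
                best_node, best_f = cand, f
        selected.add(best_node)
    current_f = _residual_fragmentation(network, selected)

    # one swap-refinement pass: for each selected node (ascending id),
    # adopt the single best strict improvement among outside candidates
    for inside in sorted(selected):
        best_swap, best_f = None, current_f
        for cand in nodes:
            if cand in selected:
                continue
            trial = (selected - {inside}) | {cand}
            f = _residual_fragmentation(network, trial)
            if f > best_f:
                best_swap, best_f = cand, f
        if best_swap is not None:
            selected.remove(inside)
            selected.add(best_swap)
            current_f = best_f
    return KeyPlayerResult(frozenset(selected), current_f)


def node_metrics_table(
    network: nx.Graph, nodes: Iterable[Hashable] | None = None
) -> list[dict]:
    """Per-node rows: label, degree, clustering, component_class."""
    partition = component_partition(network)
    if nodes is None:
        nodes = sorted(network.nodes())
    rows = []
    for node in nodes:
        data = network.nodes[node]
        rows.append(
            {
                "label": data.get("label", str(node)),
                "degree": network.degree(node),
                "clustering": local_clustering(network, node),
                "component_class": partition.classify(node),
            }
        )
    return rows


def write_node_metrics(network: nx.Graph, path: str | Path) -> None:
    """Write the node-metrics table as TSV (deterministic node order)."""
    rows = node_metrics_table(network)
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["label", "degree", "clustering", "component_class"])
        for row in rows:
            writer.writerow(
                [
                    row["label"],
                    row["degree"],
                    repr(row["clustering"]),
                    row["component_class"],
                ]
            )
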