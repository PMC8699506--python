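"""Phonological network construction.

Edges join words whose transcriptions differ by the addition, deletion,
or substitution of exactly one phoneme (unit edit distance, no
transposition).  The network is an undirected simple ``networkx.Graph``
whose nodes are word_ids carrying a ``label`` attribute.

Construction uses deletion-key hashing rather than all-pairs
comparison: deletion/insertion pairs share a full transcription with a
single-deletion variant, and substitution pairs share a
(position, sequence-with-position-removed) key.  This is near-linear in
lexicon size — all-pairs at 20k words is ~2e8 sequence comparisons,
keyed lookup is ~1e5 dictionary probes — and is verified edge-for-edge
against the brute-force oracle in the test suite.
"""

from __future__ import annotations

from pathlib import Path
from typing import Hashable, Sequence

import networkx as nx

from .errors import ResolutionError
from .lexicon import Lexicon

__all__ = [
    "one_phoneme_distance",
    "build_network",
    "two_hop_subnetwork",
    "degree",
    "write_edgelist",
    "label_index",
]


def one_phoneme_distance(t1: Sequence[str], t2: Sequence[str]) -> bool:
    """True iff ``t2`` differs from ``t1`` by exactly one phoneme
    insertion, deletion, or substitution.

    Identity (distance 0) is *not* a neighbor relation, so equal
    sequences return False.
    """
    n1, n2 = len(t1), len(t2)
    if abs(n1 - n2) > 1:
        return False
    if n1 == n2:
        # exactly one substitution
        return sum(a != b for a, b in zip(t1, t2)) == 1
    if n1 > n2:
        t1, t2, n1, n2 = t2, t1, n2, n1
    # t2 is one longer: t1 must be t2 with one symbol deleted
    i = 0
    while i < n1 and t1[i] == t2[i]:
        i += 1
    return tuple(t1[i:]) == tuple(t2[i + 1 :])


def _deletion_variants(trans: tuple[str, ...]):
    for i in range(len(trans)):
        yield trans[:i] + trans[i + 1 :]


def build_network(lexicon: Lexicon) -> nx.Graph:
    """Build the phonological network over all lexicon entries.

    Nodes are word_ids (``label`` node attribute holds the orthographic
    label); edges satisfy :func:`one_phoneme_distance`.  Homophones
    (distance 0) are never linked.
    """
    G = nx.Graph()
    for entry in lexicon:
        G.add_node(entry.word_id, label=entry.label)

    # full transcription -> word_ids (homophones share a key)
    full_index: dict[tuple[str, ...], list[int]] = {}
    for entry in lexicon:
        full_index.setdefault(entry.transcription, []).append(entry.word_id)

    # insertion/deletion: a deletion variant of u equals the full
    # transcription of v (lengths differ by one, so u != v always)
    for entry in lexicon:
        for variant in _deletion_variants(entry.transcription):
            for other_id in full_index.get(variant, ()):
                G.add_edge(entry.word_id, other_id)

    # substitution: same length, identical everywhere except position i;
    # an edge requires the symbols at i to differ (equal symbols at every
    # shared key means homophone, not neighbor)
    sub_index: dict[tuple[int, tuple[str, ...]], list[tuple[int, str]]] = {}
    for entry in lexicon:
        t = entry.transcription
        for i in range(len(t)):
            key = (i, t[:i] + t[i + 1 :])
            sub_index.setdefault(key, []).append((entry.word_id, t[i]))
    for group in sub_index.values():
        if len(group) < 2:
            continue
        for a in range(len(group)):
            id_a, sym_a = group[a]
            for b in range(a + 1, len(group)):
                id_b, sym_b = group[b]
                if sym_a != sym_b:
                    G.add_edge(id_a, id_b)
    return G


def two_hop_subnetwork(network: nx.Graph, word_id: Hashable) -> nx.Graph:
    """Induced subgraph on a word, its neighbors, and their neighbors."""
    if word_id not in network:
        raise ResolutionError(f"node {word_id!r} not in network")
    nodes = {word_id}
    first_hop = set(network.neighbors(word_id))
    nodes |= first_hop
    for v in first_hop:
        nodes |= set(network.neighbors(v))
    return network.subgraph(nodes).copy()


def degree(network: nx.Graph, word_id: Hashable) -> int:
    """Neighbor count of a node; 0 for lexical hermits."""
    if word_id not in network:
        raise ResolutionError(f"node {word_id!r} not in network")
    return network.degree(word_id)


def label_index(network: nx.Graph) -> dict[str, Hashable]:
    """Map node labels back to node ids.

    Nodes without a ``label`` attribute are indexed by ``str(node)``.
    """
    index: dict[str, Hashable] = {}
    for node, data in network.nodes(data=True):
        index[data.get("label", str(node))] = node
    return index


def write_edgelist(network: nx.Graph, path: str | Path) -> None:
    """Write the undirected edge list as ``label_u\\tlabel_v`` TSV.

    Each edge appears once with its endpoint labels in lexicographic
    order and lines sorted lexicographically — bit-exact across runs for
    regression comparisons.
    """
    labels = {
        node: data.get("label", str(node))
        for node, data in network.nodes(data=True)
    }
    lines = sorted(
        tuple(sorted((labels[u], labels[v]))) for u, v in network.edges()
    )
    text = "".join(f"{a}\t{b}\n" for a, b in lines)
    Path(path).write_text(text, encoding="utf-8", newline="\n")
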