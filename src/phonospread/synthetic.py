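"""Synthetic lexicons and controlled network topologies.

The reference lexicon behind the published phonological network is not
publicly archived, so every pipeline stage is exercised on generated
data instead.  Two kinds of generators live here:

* :func:`random_lexicon` draws phoneme strings from an alphabet and a
  word-length distribution; passed through the network builder it yields
  a one-phoneme-distance network with the macro profile the analysis
  assumes — a giant component holding roughly a third of the words, a
  majority of lexical hermits, and a sprinkling of small islands.  The
  default length distribution was calibrated once at n_words = 2000 to
  land near the reference profile (53% isolates / 34% giant).

* the three ``*_contrast`` generators build graphs *directly* (realizing
  an exact clustering or bridge structure as a 1-edit-distance lexicon
  is a hard inverse problem the experiments do not require) together
  with the two stimulus sets of the corresponding experiment design:
  degree-matched high- vs low-clustering targets, island vs
  giant-component targets, and key (sole-bridge) vs foil
  (redundant-bridge) targets with the 0.1/0.3 per-condition decay of
  the decay-manipulation design.

All generators are pure functions of their :class:`GeneratorSpec`:
identical spec (seed included) gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np

from .errors import CapacityError, ContrastError, ValidationError
from .lexicon import Lexicon, StimulusSet

__all__ = [
    "GeneratorSpec",
    "random_lexicon",
    "clustering_contrast",
    "component_contrast",
    "keyplayer_contrast",
]

DEFAULT_ALPHABET = tuple("abcdefghijklmnopqrst")  # 20 symbols

# Word-length weights calibrated once at n_words = 2000 over the
# default alphabet: short words are neighbor-dense (they knit the giant
# component), long words are almost surely hermits.  Measured profile
# at the defaults: ~58% isolates, ~35% giant, ~7% small islands.
DEFAULT_LENGTH_WEIGHTS: Mapping[int, float] = {
    2: 0.05,
    3: 0.22,
    4: 0.33,
    5: 0.18,
    6: 0.10,
    7: 0.07,
    8: 0.05,
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of all synthetic generators; ``seed`` fixes every
    random choice.

    Lexicon parameters: ``n_words``, ``alphabet``, ``length_weights``.

    Clustering-contrast parameters: ``n_targets`` per condition,
    ``target_degree`` (identical for every target), neighbor
    interconnection probabilities ``p_high`` > ``p_low``, a shared
    connected background of ``background_n`` nodes with
    ``background_extra_edges`` beyond its spanning tree, and
    ``dispersal_links`` outward edges per target neighbor so activation
    can leave the neighborhood.

    Component-contrast parameters: ``giant_size``, ``n_islands``,
    ``island_size`` (targets are drawn equally from islands and from the
    giant, degree-matched where possible).

    Key-player parameters: ``n_keys`` sole-bridge targets and
    ``n_foils`` redundant-bridge targets between chained clusters of
    ``cluster_size_min``..``cluster_size_max`` nodes;
    ``key_decay`` / ``foil_decay`` populate the per-condition decay of
    the decay-manipulation design.
    """

    seed: int = 0
    # lexicon
    n_words: int = 2000
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    length_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS)
    )
    # clustering contrast
    n_targets: int = 20
    target_degree: int = 4
    p_high: float = 0.8
    p_low: float = 0.0
    background_n: int = 100
    background_extra_edges: int = 60
    dispersal_links: int = 1
    # component contrast
    giant_size: int = 200
    n_islands: int = 10
    island_size: int = 5
    # key-player contrast
    n_keys: int = 20
    n_foils: int = 20
    cluster_size_min: int = 5
    cluster_size_max: int = 9
    key_decay: float = 0.1
    foil_decay: float = 0.3

    def __post_init__(self):
        for name in ("p_high", "p_low", "key_decay", "foil_decay"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_words",
            "n_targets",
            "background_n",
            "giant_size",
            "n_islands",
            "island_size",
            "n_keys",
            "n_foils",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if any(w < 0 for w in self.length_weights.values()):
            raise ValidationError("length weights must be nonnegative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# string-based lexicon generator


def random_lexicon(spec: GeneratorSpec) -> Lexicon:
    """Draw ``n_words`` distinct transcriptions by rejection sampling.

    Lengths follow ``length_weights``; symbols are uniform over the
    alphabet.  Labels are the joined transcription strings (distinct by
    construction).  Raises :class:`CapacityError` if the alphabet and
    length support cannot host ``n_words`` distinct strings.
    """
    lengths = sorted(L for L, w in spec.length_weights.items() if w > 0)
    if spec.n_words > 0 and not lengths:
        raise CapacityError("no word length has positive weight")
    if any(L < 1 for L in lengths):
        raise ValidationError("word lengths must be >= 1")
    a = len(spec.alphabet)
    if len(set(spec.alphabet)) != a:
        raise ValidationError("alphabet symbols must be distinct")
    capacity = sum(a**L for L in lengths)
    if spec.n_words > capacity:
        raise CapacityError(
            f"alphabet of {a} symbols with lengths {lengths} hosts only "
            f"{capacity} distinct words; {spec.n_words} requested"
        )
    rng = spec.rng()
    weights = np.array([spec.length_weights[L] for L in lengths], dtype=float)
    weights /= weights.sum()
    seen: set[tuple[str, ...]] = set()
    out: list[tuple[str, tuple[str, ...]]] = []
    while len(out) < spec.n_words:
        L = int(rng.choice(lengths, p=weights))
        trans = tuple(
            spec.alphabet[i] for i in rng.integers(0, a, size=L)
        )
        if trans in seen:
            continue
        seen.add(trans)
        out.append(("".join(trans), trans))
    return Lexicon.from_pairs(out)


# ---------------------------------------------------------------------------
# direct-graph contrast generators


def _relabel(G: nx.Graph) -> None:
    for node in G.nodes():
        G.nodes[node]["label"] = f"n{node}"


def _random_connected(
    rng: np.random.Generator, nodes: list[int], extra_edges: int, G: nx.Graph
) -> None:
    """Wire ``nodes`` into a connected subgraph: random recursive tree
    plus ``extra_edges`` random non-parallel chords."""
    for i in range(1, len(nodes)):
        j = int(rng.integers(0, i))
        G.add_edge(nodes[i], nodes[j])
    added = 0
    attempts = 0
    while added < extra_edges and attempts < 50 * (extra_edges + 1):
        attempts += 1
        i, j = rng.integers(0, len(nodes), size=2)
        u, v = nodes[int(i)], nodes[int(j)]
        if u != v and not G.has_edge(u, v):
            G.add_edge(u, v)
            added += 1


def clustering_contrast(
    spec: GeneratorSpec,
) -> tuple[nx.Graph, tuple[StimulusSet, StimulusSet]]:
    """Degree-matched targets whose neighborhoods differ in clustering.

    Every target has degree exactly ``target_degree``; high-C targets'
    neighbors are interconnected with probability ``p_high``, low-C with
    ``p_low``; each neighbor is linked outward to a shared connected
    background so activation can disperse.  With ``p_high = 1`` and
    ``p_low = 0`` the measured C is exactly 1 vs 0.
    """
    if spec.target_degree < 2:
        raise ContrastError(
            f"target_degree must be >= 2, got {spec.target_degree}"
        )
    if spec.p_high <= spec.p_low:
        raise ContrastError(
            f"p_high ({spec.p_high}) must exceed p_low ({spec.p_low})"
        )
    rng = spec.rng()
    G = nx.Graph()
    background = list(range(spec.background_n))
    G.add_nodes_from(background)
    _random_connected(rng, background, spec.background_extra_edges, G)

    next_id = spec.background_n
    conditions: dict[str, list[str]] = {"high_C": [], "low_C": []}
    for cond, p in (("high_C", spec.p_high), ("low_C", spec.p_low)):
        for _ in range(spec.n_targets):
            target = next_id
            next_id += 1
            nbrs = list(range(next_id, next_id + spec.target_degree))
            next_id += spec.target_degree
            G.add_node(target)
            G.add_nodes_from(nbrs)
            for v in nbrs:
                G.add_edge(target, v)
            for i in range(len(nbrs)):
                for j in range(i + 1, len(nbrs)):
                    if rng.random() < p:
                        G.add_edge(nbrs[i], nbrs[j])
            for v in nbrs:
                picks = rng.choice(
                    spec.background_n,
                    size=min(spec.dispersal_links, spec.background_n),
                    replace=False,
                )
                for b in picks:
                    G.add_edge(v, int(b))
            conditions[cond].append(target)
    _relabel(G)
    sets = tuple(
        StimulusSet(cond, tuple(f"n{t}" for t in targets))
        for cond, targets in conditions.items()
    )
    return G, (sets[0], sets[1])


def component_contrast(
    spec: GeneratorSpec,
) -> tuple[nx.Graph, tuple[StimulusSet, StimulusSet]]:
    """One large connected component plus small islands, with
    equal-count target sets drawn from each, degree-matched where
    possible.

    At d = 0 activation seeded inside an island can never leave it
    (there are no edges out), which is the trapping mechanism the
    island > giant contrast rests on.
    """
    if spec.island_size < 2:
        raise ValidationError(
            f"island_size must be >= 2, got {spec.island_size}"
        )
    if spec.giant_size <= spec.island_size:
        raise ValidationError(
            "giant_size must exceed island_size "
            f"({spec.giant_size} vs {spec.island_size})"
        )
    if spec.n_targets > spec.n_islands * spec.island_size:
        raise ValidationError("not enough island nodes for n_targets")
    rng = spec.rng()
    G = nx.Graph()
    giant_nodes = list(range(spec.giant_size))
    G.add_nodes_from(giant_nodes)
    # mean degree ~3 in the giant: spanning tree + giant_size/2 chords
    _random_connected(rng, giant_nodes, spec.giant_size // 2, G)

    next_id = spec.giant_size
    island_nodes: list[list[int]] = []
    for _ in range(spec.n_islands):
        nodes = list(range(next_id, next_id + spec.island_size))
        next_id += spec.island_size
        G.add_nodes_from(nodes)
        _random_connected(rng, nodes, 1, G)
        island_nodes.append(nodes)

    # island targets: spread evenly over islands
    island_targets: list[int] = []
    per_island = spec.n_targets // spec.n_islands
    remainder = spec.n_targets - per_island * spec.n_islands
    for idx, nodes in enumerate(island_nodes):
        want = per_island + (1 if idx < remainder else 0)
        picks = rng.choice(len(nodes), size=want, replace=False)
        island_targets.extend(nodes[int(i)] for i in picks)

    # giant targets: greedy degree matching against the island targets
    wanted = sorted(G.degree(v) for v in island_targets)
    pool = sorted(giant_nodes, key=lambda v: (G.degree(v), v))
    giant_targets: list[int] = []
    used: set[int] = set()
    for k in wanted:
        best, best_gap = None, None
        for v in pool:
            if v in used:
                continue
            gap = abs(G.degree(v) - k)
            if best_gap is None or gap < best_gap:
                best, best_gap = v, gap
                if gap == 0:
                    break
        used.add(best)
        giant_targets.append(best)
    _relabel(G)
    island_set = StimulusSet("island", tuple(f"n{v}" for v in island_targets))
    giant_set = StimulusSet("giant", tuple(f"n{v}" for v in giant_targets))
    return G, (island_set, giant_set)


def keyplayer_contrast(
    spec: GeneratorSpec,
) -> tuple[nx.Graph, tuple[StimulusSet, StimulusSet]]:
    """Key (cut-vertex bridge) vs foil (redundant bridge) targets.

    Clusters are random-size cycles (removing any cluster node keeps the
    cluster connected), joined by degree-2 connector nodes into one
    connected graph shaped like a lollipop: ``n_foils`` clusters form a
    *ring* whose connectors are the foils — removing a foil leaves the
    ring connected the long way round, so fragmentation stays 0 — and
    ``n_keys`` further clusters hang off the ring as a *tail chain*
    whose connectors are the keys — removing a key cuts off every
    cluster beyond it, strictly increasing fragmentation.

    Keys and foils are exactly matched on degree (2) and clustering (0),
    and a connector's local environment — a chain of cycle-clusters in
    both directions — is the same in the ring as in the tail; the
    redundancy that distinguishes foils is global (the long way round
    the ring), not local.  That is what makes the uniform-decay
    comparison a true null.

    The returned stimulus sets carry ``per_condition_decay``
    (``key_decay`` / ``foil_decay``) for the decay-manipulation design;
    strip it with :meth:`StimulusSet.with_decay` for uniform-decay runs.
    """
    if spec.n_keys < 1 or spec.n_foils < 1:
        raise ContrastError("need at least one key and one foil")
    if spec.cluster_size_min < 4 or spec.cluster_size_max < spec.cluster_size_min:
        raise ValidationError("cluster sizes must satisfy 4 <= min <= max")
    rng = spec.rng()
    # pad each segment with boundary clusters so every *target* connector
    # sits in an interior (chain-of-clusters) environment: the ring/tail
    # junction cluster and the tail's end cluster have atypical
    # attachment counts, and targets adjacent to them would not be
    # exchangeable with the rest
    n_ring = spec.n_foils + 2
    n_tail = spec.n_keys + 2
    n_clusters = n_ring + n_tail

    G = nx.Graph()
    next_id = 0
    clusters: list[list[int]] = []
    for _ in range(n_clusters):
        m = int(rng.integers(spec.cluster_size_min, spec.cluster_size_max + 1))
        nodes = list(range(next_id, next_id + m))
        next_id += m
        G.add_nodes_from(nodes)
        for i in range(m):
            G.add_edge(nodes[i], nodes[(i + 1) % m])
        clusters.append(nodes)

    attachment_taken: dict[int, set[int]] = {i: set() for i in range(n_clusters)}

    def fresh_attachment(cluster_idx: int) -> int:
        cluster = clusters[cluster_idx]
        taken = attachment_taken[cluster_idx]
        free = [v for v in cluster if v not in taken]
        pool = free if free else cluster
        pick = pool[int(rng.integers(0, len(pool)))]
        taken.add(pick)
        return pick

    def add_connector(left: int, right: int) -> int:
        nonlocal next_id
        connector = next_id
        next_id += 1
        G.add_node(connector)
        G.add_edge(connector, fresh_attachment(left))
        G.add_edge(connector, fresh_attachment(right))
        return connector

    # ring: clusters 0..n_ring-1, one foil connector per adjacent pair;
    # the two connectors touching the junction cluster 0 are excluded
    # from the foil set
    ring_connectors = [
        add_connector(i, (i + 1) % n_ring) for i in range(n_ring)
    ]
    foils = ring_connectors[1 : n_ring - 1]
    # tail: clusters n_ring..n_clusters-1 chained off ring cluster 0,
    # one key connector per gap; the junction-adjacent and end-adjacent
    # connectors are excluded from the key set
    tail_connectors = []
    prev = 0
    for i in range(n_ring, n_clusters):
        tail_connectors.append(add_connector(prev, i))
        prev = i
    keys = tail_connectors[1:-1]
    _relabel(G)
    key_set = StimulusSet(
        "key", tuple(f"n{v}" for v in keys), per_condition_decay=spec.key_decay
    )
    foil_set = StimulusSet(
        "foil",
        tuple(f"n{v}" for v in foils),
        per_condition_decay=spec.foil_decay,
    )
    return G, (key_set, foil_set)
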