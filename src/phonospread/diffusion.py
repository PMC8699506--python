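"""The spreading-activation engine.

Activation is seeded on target nodes and diffused over the undirected
network for ``t`` discrete timesteps.  One timestep applies, in order:

1. retention/spread, simultaneously for all nodes: a node with
   activation ``a`` and degree ``k >= 1`` retains ``r * a`` and sends
   ``(1 - r) * a / k`` to each neighbor; a degree-0 node (lexical
   hermit) retains everything;
2. decay: every activation is multiplied by ``(1 - d)``;
3. suppress: activations strictly below ``s`` are zeroed.

With ``s = 0`` this order gives the closed form
``total(m) = (sum of seeds) * (1 - d)**m`` — strict conservation when
``d = 0`` — which is the property the conservation tests pin down.
Everything here is double-precision and deterministic; there is no
randomness in this module.

The update is implemented by per-edge accumulation over a compiled edge
list (``numpy.add.at``), not by matrix powers; the dense transfer-matrix
oracle it must agree with lives in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import ResolutionError, ValidationError

__all__ = [
    "DiffusionParams",
    "ActivationTrajectory",
    "initialize_state",
    "step",
    "spread",
    "target_activation",
    "write_trajectory",
]


@dataclass(frozen=True)
class DiffusionParams:
    """One run's diffusion parameterization.

    a0 : initial activation, in activation units (> 0); 20 by default.
    r  : retention — proportion of activation a node keeps when it
         diffuses to its neighbors; 0.5 by default.
    d  : decay — proportion of activation lost network-wide at each
         timestep; 0 by default.
    s  : suppress — activations strictly below this threshold are
         zeroed; 0 by default (a no-op, since activations are >= 0).
    t  : number of timesteps; 5 by default.
    """

    a0: float = 20.0
    r: float = 0.5
    d: float = 0.0
    s: float = 0.0
    t: int = 5

    def __post_init__(self):
        if self.a0 <= 0:
            raise ValidationError(f"a0 must be > 0, got {self.a0}")
        for name in ("r", "d"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.s < 0:
            raise ValidationError(f"s must be >= 0, got {self.s}")
        if not (isinstance(self.t, int) and self.t >= 1):
            raise ValidationError(f"t must be a positive integer, got {self.t}")

    def replace(self, **kwargs) -> "DiffusionParams":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


class _CompiledGraph:
    """Node ordering, degree vector, and directed edge arrays for fast
    repeated diffusion on one topology."""

    def __init__(self, network: nx.Graph):
        self.nodes: list = sorted(network.nodes())
        self.index: dict = {v: i for i, v in enumerate(self.nodes)}
        n = len(self.nodes)
        self.degree = np.zeros(n, dtype=np.int64)
        src, dst = [], []
        for u, v in network.edges():
            iu, iv = self.index[u], self.index[v]
            src.extend((iu, iv))
            dst.extend((iv, iu))
            self.degree[iu] += 1
            self.degree[iv] += 1
        self.src = np.asarray(src, dtype=np.intp)
        self.dst = np.asarray(dst, dtype=np.intp)

    def step(self, a: np.ndarray, params: DiffusionParams) -> np.ndarray:
        r, d, s = params.r, params.d, params.s
        has_nbrs = self.degree > 0
        new = np.where(has_nbrs, r * a, a)
        if self.src.size:
            share = np.zeros_like(a)
            share[has_nbrs] = (1.0 - r) * a[has_nbrs] / self.degree[has_nbrs]
            np.add.at(new, self.dst, share[self.src])
        new *= 1.0 - d
        if s > 0.0:
            new[new < s] = 0.0
        return new


@dataclass(frozen=True)
class ActivationTrajectory:
    """Per-timestep activation states of one seeded run.

    ``states[0]`` is the seeded state; ``states[m]`` the state after m
    timesteps.  Each state maps every network node to its activation.
    """

    states: tuple[Mapping[Hashable, float], ...]
    seed_nodes: frozenset
    params: DiffusionParams

    @property
    def t(self) -> int:
        return len(self.states) - 1

    def total(self, at: int) -> float:
        return float(sum(self.states[at].values()))


def initialize_state(
    network: nx.Graph, seeds: Mapping[Hashable, float]
) -> dict[Hashable, float]:
    """Activation state with the given seed values and 0 elsewhere."""
    for node, a in seeds.items():
        if node not in network:
            raise ResolutionError(f"seed node {node!r} not in network")
        if a <= 0:
            raise ValidationError(
                f"seed activation must be > 0, got {a} at {node!r}"
            )
    state = {node: 0.0 for node in network.nodes()}
    state.update({node: float(a) for node, a in seeds.items()})
    return state


def step(
    state: Mapping[Hashable, float],
    network: nx.Graph,
    params: DiffusionParams,
) -> dict[Hashable, float]:
    """Apply one retention/spread -> decay -> suppress update."""
    cg = _CompiledGraph(network)
    a = np.array([state[v] for v in cg.nodes], dtype=np.float64)
    new = cg.step(a, params)
    return dict(zip(cg.nodes, new.tolist()))


def spread(
    network: nx.Graph,
    seeds: Mapping[Hashable, float],
    params: DiffusionParams,
    _compiled: _CompiledGraph | None = None,
) -> ActivationTrajectory:
    """Seed activation and iterate the update for ``params.t`` steps."""
    state0 = initialize_state(network, seeds)
    cg = _compiled if _compiled is not None else _CompiledGraph(network)
    a = np.array([state0[v] for v in cg.nodes], dtype=np.float64)
    states = [dict(zip(cg.nodes, a.tolist()))]
    for _ in range(params.t):
        a = cg.step(a, params)
        states.append(dict(zip(cg.nodes, a.tolist())))
    return ActivationTrajectory(
        tuple(states), frozenset(seeds), params
    )


def target_activation(
    trajectory: ActivationTrajectory, word_id: Hashable, at: int
) -> float:
    """A node's activation at a given timestep (0 = seeded state)."""
    if not (0 <= at <= trajectory.t):
        raise ResolutionError(
            f"timestep {at} outside [0, {trajectory.t}]"
        )
    state = trajectory.states[at]
    if word_id not in state:
        raise ResolutionError(f"node {word_id!r} not in trajectory")
    return state[word_id]


def write_trajectory(
    trajectory: ActivationTrajectory,
    network: nx.Graph,
    path: str | Path,
) -> None:
    """Long-format TSV ``timestep\\tlabel\\tactivation`` at full precision."""
    labels = {
        node: data.get("label", str(node))
        for node, data in network.nodes(data=True)
    }
    lines = ["timestep\tlabel\tactivation\n"]
    for m, state in enumerate(trajectory.states):
        for node in sorted(state):
            lines.append(f"{m}\t{labels[node]}\t{state[node]!r}\n")
    Path(path).write_text("".join(lines), encoding="utf-8", newline="\n")
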