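"""Two-condition simulation experiments on a phonological network.

An experiment seeds each stimulus word in its own run (initial
activation ``a0`` on that word alone), diffuses for ``t`` timesteps, and
reads the word's *own* residual activation at the read timestep — the
proxy for retrieval ease (larger residual activation ~ faster / more
accurate responses).  The two conditions' activations are then compared
with a Student pooled-variance two-sample t-test (df = n1 + n2 - 2,
two-tailed p).

Per-condition decay designs (key words diffusing under d = 0.1, foils
under d = 0.3) are realized by overriding ``d`` per run according to the
stimulus word's condition; everything else is shared.

The :class:`Experiment` / :class:`ExperimentResult` pair is the
object-oriented surface: build an Experiment from a network, exactly two
stimulus sets, and a config; ``run()`` returns a result carrying
per-word activations, group statistics, the test, and a ``summary()``
table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats as _scipy_stats

from .diffusion import DiffusionParams, _CompiledGraph, spread, target_activation
from .errors import DegenerateDataError, DesignError, ResolutionError, ValidationError
from .lexicon import StimulusSet
from .network import label_index

__all__ = [
    "SimulationConfig",
    "TestResult",
    "GroupStats",
    "ExperimentResult",
    "Experiment",
    "run_condition",
    "pooled_t_test",
    "run_experiment",
    "write_report",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Shared diffusion parameters plus per-condition decay overrides.

    ``decay_overrides`` maps condition labels to decay proportions and
    takes precedence over a stimulus set's own ``per_condition_decay``;
    conditions in neither fall back to ``params.d``.  ``read_timestep``
    defaults to the final step.
    """

    params: DiffusionParams = field(default_factory=DiffusionParams)
    decay_overrides: Mapping[str, float] = field(default_factory=dict)
    read_timestep: int | None = None

    def __post_init__(self):
        for label, d in self.decay_overrides.items():
            if not (0.0 <= d <= 1.0):
                raise ValidationError(
                    f"decay override {d} for {label!r} outside [0, 1]"
                )
        if self.read_timestep is not None and not (
            0 <= self.read_timestep <= self.params.t
        ):
            raise ValidationError(
                f"read_timestep {self.read_timestep} outside [0, {self.params.t}]"
            )

    @property
    def effective_read_timestep(self) -> int:
        return self.params.t if self.read_timestep is None else self.read_timestep

    def decay_for(self, stimulus_set: StimulusSet) -> float:
        if stimulus_set.condition_label in self.decay_overrides:
            return self.decay_overrides[stimulus_set.condition_label]
        if stimulus_set.per_condition_decay is not None:
            return stimulus_set.per_condition_decay
        return self.params.d


@dataclass(frozen=True)
class TestResult:
    """Pooled two-sample t-test outcome; sign follows mean1 - mean2."""

    t_stat: float
    df: int
    p: float
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int


@dataclass(frozen=True)
class GroupStats:
    condition_label: str
    mean: float
    sd: float
    n: int


def pooled_t_test(
    group1: Sequence[float], group2: Sequence[float]
) -> TestResult:
    """Student's independent-samples t-test with pooled variance.

    df = n1 + n2 - 2; two-tailed p.  Sample SDs use the n-1 denominator.
    Zero pooled variance with equal means gives t = 0, p = 1; with
    unequal means the statistic is undefined and raises.
    """
    x1 = np.asarray(group1, dtype=np.float64)
    x2 = np.asarray(group2, dtype=np.float64)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValidationError(
            f"each group needs n >= 2, got {n1} and {n2}"
        )
    m1, m2 = float(x1.mean()), float(x2.mean())
    v1, v2 = float(x1.var(ddof=1)), float(x2.var(ddof=1))
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        if m1 == m2:
            t_stat, p = 0.0, 1.0
        else:
            raise DegenerateDataError(
                "zero pooled variance with unequal means: t undefined"
            )
    else:
        t_stat = (m1 - m2) / se
        p = 2.0 * float(_scipy_stats.t.sf(abs(t_stat), df))
    return TestResult(
        t_stat=t_stat,
        df=df,
        p=p,
        mean1=m1,
        sd1=math.sqrt(v1),
        n1=n1,
        mean2=m2,
        sd2=math.sqrt(v2),
        n2=n2,
    )


def run_condition(
    network: nx.Graph,
    words: Iterable[str],
    params: DiffusionParams,
    read_timestep: int | None = None,
    _compiled: _CompiledGraph | None = None,
    _labels: Mapping[str, Hashable] | None = None,
) -> dict[str, float]:
    """Seed each word alone with ``params.a0``, diffuse, and read the
    word's own activation at ``read_timestep`` (default: final step).

    Returns word label -> activation units.  Words absent from the
    network abort the run (no silent zero-assignment).
    """
    at = params.t if read_timestep is None else read_timestep
    labels = label_index(network) if _labels is None else _labels
    words = list(words)
    missing = [w for w in words if w not in labels]
    if missing:
        raise ResolutionError(
            f"stimulus words not in network: {', '.join(sorted(missing))}"
        )
    cg = _compiled if _compiled is not None else _CompiledGraph(network)
    out: dict[str, float] = {}
    for word in words:
        node = labels[word]
        traj = spread(network, {node: params.a0}, params, _compiled=cg)
        out[word] = target_activation(traj, node, at)
    return out


@dataclass(frozen=True)
class ExperimentResult:
    """Outcome of one two-condition experiment.

    Carries per-word final activations, per-condition (mean, sd, n), and
    the pooled t-test with group 1 = first stimulus set in design order.
    """

    experiment_label: str
    per_word: Mapping[str, float]
    conditions: tuple[GroupStats, GroupStats]
    word_conditions: Mapping[str, str]
    test: TestResult
    config: SimulationConfig

    def summary(self) -> str:
        """Plain-text summary table of group statistics and the test."""
        g1, g2 = self.conditions
        lines = [
            f"Experiment: {self.experiment_label}",
            f"{'condition':<16}{'n':>5}{'mean':>10}{'sd':>10}",
            f"{g1.condition_label:<16}{g1.n:>5}{g1.mean:>10.3f}{g1.sd:>10.3f}",
            f"{g2.condition_label:<16}{g2.n:>5}{g2.mean:>10.3f}{g2.sd:>10.3f}",
            (
                f"t({self.test.df}) = {self.test.t_stat:.2f}, "
                f"p = {self.test.p:.4f}   "
                f"[t = ({g1.condition_label} - {g2.condition_label}) "
                "difference / pooled SE]"
            ),
        ]
        return "\n".join(lines)


class Experiment:
    """A two-condition spreading-activation experiment.

    Parameters
    ----------
    network : networkx.Graph
        Phonological network; nodes carry ``label`` attributes.
    stimulus_sets : sequence of StimulusSet
        Exactly two condition-labeled word sets (the designs replicated
        here are all two-group).
    config : SimulationConfig, optional
        Diffusion parameters, per-condition decay overrides, and the
        read timestep.  Defaults: a0=20, r=0.5, d=0, s=0, t=5, read at t.
    label : str, optional
        Name recorded in the result.
    """

    def __init__(
        self,
        network: nx.Graph,
        stimulus_sets: Sequence[StimulusSet],
        config: SimulationConfig | None = None,
        label: str = "experiment",
    ):
        if len(stimulus_sets) != 2:
            raise DesignError(
                f"expected exactly 2 conditions, got {len(stimulus_sets)}"
            )
        c1, c2 = stimulus_sets
        if c1.condition_label == c2.condition_label:
            raise DesignError(
                f"conditions must be distinct, both are {c1.condition_label!r}"
            )
        overlap = set(c1.words) & set(c2.words)
        if overlap:
            raise DesignError(
                f"conditions overlap on: {', '.join(sorted(overlap))}"
            )
        self.network = network
        self.stimulus_sets = tuple(stimulus_sets)
        self.config = config if config is not None else SimulationConfig()
        self.label = label

    def run(self) -> ExperimentResult:
        cfg = self.config
        at = cfg.effective_read_timestep
        compiled = _CompiledGraph(self.network)
        labels = label_index(self.network)
        per_word: dict[str, float] = {}
        word_conditions: dict[str, str] = {}
        groups: list[GroupStats] = []
        group_values: list[list[float]] = []
        for sset in self.stimulus_sets:
            params = cfg.params.replace(d=cfg.decay_for(sset))
            activations = run_condition(
                self.network,
                sset.words,
                params,
                read_timestep=at,
                _compiled=compiled,
                _labels=labels,
            )
            values = [activations[w] for w in sset.words]
            per_word.update(activations)
            word_conditions.update(
                {w: sset.condition_label for w in sset.words}
            )
            arr = np.asarray(values)
            groups.append(
                GroupStats(
                    sset.condition_label,
                    float(arr.mean()),
                    float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                    len(arr),
                )
            )
            group_values.append(values)
        test = pooled_t_test(group_values[0], group_values[1])
        return ExperimentResult(
            experiment_label=self.label,
            per_word=per_word,
            conditions=(groups[0], groups[1]),
            word_conditions=word_conditions,
            test=test,
            config=cfg,
        )


def run_experiment(
    network: nx.Graph,
    stimulus_sets: Sequence[StimulusSet],
    config: SimulationConfig | None = None,
    label: str = "experiment",
) -> ExperimentResult:
    """Functional wrapper around :class:`Experiment`."""
    return Experiment(network, stimulus_sets, config, label).run()


def write_report(result: ExperimentResult, path_prefix: str | Path) -> None:
    """Write ``<prefix>_words.tsv`` (per-word activations) and
    ``<prefix>_summary.json`` (group stats + test), deterministically."""
    prefix = Path(path_prefix)
    words_path = prefix.parent / (prefix.name + "_words.tsv")
    json_path = prefix.parent / (prefix.name + "_summary.json")
    lines = ["condition\tword\tactivation\n"]
    for word in result.per_word:
        lines.append(
            f"{result.word_conditions[word]}\t{word}\t{result.per_word[word]!r}\n"
        )
    words_path.write_text("".join(lines), encoding="utf-8", newline="\n")
    summary = {
        "experiment": result.experiment_label,
        "conditions": [
            {
                "condition": g.condition_label,
                "mean": g.mean,
                "sd": g.sd,
                "n": g.n,
            }
            for g in result.conditions
        ],
        "test": {
            "t": result.test.t_stat,
            "df": result.test.df,
            "p": result.test.p,
        },
    }
    json_path.write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
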