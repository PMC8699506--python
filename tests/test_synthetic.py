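import networkx as nx
import numpy as np
import pytest

from phonospread import (
    build_network,
    component_partition,
    fragmentation,
    label_index,
    local_clustering,
    run_experiment,
    spread,
)
from phonospread.diffusion import DiffusionParams
from phonospread.errors import CapacityError, ContrastError
from phonospread.synthetic import (
    GeneratorSpec,
    clustering_contrast,
    component_contrast,
    keyplayer_contrast,
    random_lexicon,
)


class TestRandomLexicon:
    def test_empty_spec_gives_empty_lexicon(self):
        lex = random_lexicon(GeneratorSpec(seed=0, n_words=0))
        assert len(lex) == 0

    def test_same_seed_identical_lexicons(self):
        a = random_lexicon(GeneratorSpec(seed=5, n_words=200))
        b = random_lexicon(GeneratorSpec(seed=5, n_words=200))
        assert a == b

    def test_different_seeds_differ(self):
        a = random_lexicon(GeneratorSpec(seed=5, n_words=200))
        b = random_lexicon(GeneratorSpec(seed=6, n_words=200))
        assert a != b

    def test_transcriptions_distinct_and_lengths_in_support(self):
        spec = GeneratorSpec(seed=2, n_words=300)
        lex = random_lexicon(spec)
        trans = [e.transcription for e in lex]
        assert len(set(trans)) == len(trans)
        support = {L for L, w in spec.length_weights.items() if w > 0}
        assert {len(t) for t in trans} <= support

    def test_infeasible_spec_raises_capacity_error(self):
        with pytest.raises(CapacityError):
            random_lexicon(
                GeneratorSpec(
                    seed=0,
                    n_words=2,
                    alphabet=("a",),
                    length_weights={1: 1.0},
                )
            )

    def test_macro_profile_within_calibration_band(self):
        """At the defaults and n = 2000, the one-phoneme network has an
        isolate fraction in [30%, 70%] and a largest component holding
        [15%, 55%] of nodes."""
        spec = GeneratorSpec(seed=11, n_words=2000)
        G = build_network(random_lexicon(spec))
        part = component_partition(G)
        n = G.number_of_nodes()
        assert 0.30 <= len(part.isolates) / n <= 0.70
        assert 0.15 <= len(part.giant) / n <= 0.55


class TestClusteringContrast:
    def test_extreme_probabilities_force_c_one_vs_zero(self):
        spec = GeneratorSpec(seed=0, p_high=1.0, p_low=0.0, n_targets=5)
        G, (high, low) = clustering_contrast(spec)
        idx = label_index(G)
        assert all(local_clustering(G, idx[w]) == 1.0 for w in high.words)
        assert all(local_clustering(G, idx[w]) == 0.0 for w in low.words)

    def test_all_targets_have_the_spec_degree(self):
        spec = GeneratorSpec(seed=3, target_degree=6)
        G, (high, low) = clustering_contrast(spec)
        idx = label_index(G)
        assert all(
            G.degree(idx[w]) == 6 for w in high.words + low.words
        )

    def test_measured_contrast_separates_groups(self):
        spec = GeneratorSpec(seed=4)
        G, (high, low) = clustering_contrast(spec)
        idx = label_index(G)
        mean_high = np.mean([local_clustering(G, idx[w]) for w in high.words])
        mean_low = np.mean([local_clustering(G, idx[w]) for w in low.words])
        assert mean_high > mean_low

    def test_inverted_probabilities_rejected(self):
        with pytest.raises(ContrastError):
            clustering_contrast(GeneratorSpec(seed=0, p_high=0.2, p_low=0.5))

    def test_deterministic_given_spec(self):
        spec = GeneratorSpec(seed=9)
        G1, sets1 = clustering_contrast(spec)
        G2, sets2 = clustering_contrast(spec)
        assert sets1 == sets2
        assert sorted(G1.edges()) == sorted(G2.edges())

    def test_direction_low_clustering_retains_more(self):
        """Targets with independent neighbors keep more activation than
        targets with interconnected neighbors (dispersal beats
        recirculation at the default parameterization)."""
        G, (high, low) = clustering_contrast(GeneratorSpec(seed=0))
        res = run_experiment(G, (low, high))
        assert res.conditions[0].mean > res.conditions[1].mean
        assert res.test.t_stat > 0


class TestComponentContrast:
    def test_partition_recovered_exactly(self):
        spec = GeneratorSpec(seed=0)
        G, (island, giant) = component_contrast(spec)
        part = component_partition(G)
        assert len(part.giant) == spec.giant_size
        assert len(part.islands) == spec.n_islands
        assert all(len(c) == spec.island_size for c in part.islands)
        idx = label_index(G)
        assert all(idx[w] in part.giant for w in giant.words)
        island_nodes = set().union(*part.islands)
        assert all(idx[w] in island_nodes for w in island.words)

    def test_activation_trapped_inside_island_at_zero_decay(self):
        spec = GeneratorSpec(seed=1)
        G, (island, _) = component_contrast(spec)
        idx = label_index(G)
        seed_node = idx[island.words[0]]
        part = component_partition(G)
        home = next(c for c in part.islands if seed_node in c)
        traj = spread(G, {seed_node: 20.0}, DiffusionParams(t=5))
        for state in traj.states:
            inside = sum(state[v] for v in home)
            assert inside == pytest.approx(20.0, rel=1e-12)

    def test_direction_island_targets_retain_more(self):
        G, sets = component_contrast(GeneratorSpec(seed=2))
        res = run_experiment(G, sets)
        assert res.conditions[0].mean > res.conditions[1].mean
        assert res.test.t_stat > 0


class TestKeyplayerContrast:
    def test_counts_and_decay_annotations(self):
        spec = GeneratorSpec(seed=0)
        G, (key, foil) = keyplayer_contrast(spec)
        assert len(key) == spec.n_keys and len(foil) == spec.n_foils
        assert key.per_condition_decay == spec.key_decay
        assert foil.per_condition_decay == spec.foil_decay

    def test_degree_sequences_identical(self):
        G, (key, foil) = keyplayer_contrast(GeneratorSpec(seed=1))
        idx = label_index(G)
        kd = sorted(G.degree(idx[w]) for w in key.words)
        fd = sorted(G.degree(idx[w]) for w in foil.words)
        assert kd == fd

    def test_key_removal_fragments_foil_removal_does_not(self):
        G, (key, foil) = keyplayer_contrast(GeneratorSpec(seed=2))
        idx = label_index(G)
        assert fragmentation(G) == 0.0
        for w in key.words:
            H = G.copy()
            H.remove_node(idx[w])
            assert fragmentation(H) > 0.0
        for w in foil.words:
            H = G.copy()
            H.remove_node(idx[w])
            assert fragmentation(H) == 0.0

    def test_direction_lower_decay_group_retains_more(self):
        """With the annotated 0.1/0.3 decay contrast the key group mean
        strictly exceeds the foil group mean on matched topology."""
        G, sets = keyplayer_contrast(GeneratorSpec(seed=3))
        res = run_experiment(G, sets)
        assert res.conditions[0].mean > res.conditions[1].mean
        assert res.test.t_stat > 0

    def test_uniform_decay_null_across_seeds(self):
        """Degree- and clustering-matched keys vs foils under uniform
        decay are statistically indistinguishable: the mean |t| across
        seeds stays well inside the null band frozen at design time."""
        ts = []
        for seed in range(5):
            G, (key, foil) = keyplayer_contrast(GeneratorSpec(seed=seed))
            res = run_experiment(G, (key.with_decay(None), foil.with_decay(None)))
            ts.append(res.test.t_stat)
        assert np.mean(np.abs(ts)) < 2.0


def test_generators_pure_functions_of_spec():
    spec = GeneratorSpec(seed=17)
    for gen in (component_contrast, keyplayer_contrast):
        G1, s1 = gen(spec)
        G2, s2 = gen(spec)
        assert s1 == s2
        assert sorted(G1.edges()) == sorted(G2.edges())
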