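# Methods

## The diffusion model

The network is an undirected simple graph over a lexicon; an edge joins
two words whose phoneme-sequence transcriptions are at unit edit
distance (one insertion, deletion, or substitution; transpositions do
not count, and identical transcriptions — homophones — are distinct
nodes at distance 0, never linked).

Activation is a nonnegative quantity in arbitrary units.  One run seeds
`a0` units on a single target node; one timestep applies three stages
in a fixed order:

1. **Retention/spread**, simultaneously for all nodes: a node with
   activation *a* and degree *k* ≥ 1 keeps `r·a` and sends
   `(1 − r)·a/k` to each neighbor; a degree-0 node keeps *a* in full.
2. **Decay**: every activation is multiplied by `(1 − d)`.
3. **Suppress**: activations strictly below *s* are set to 0.

The model's parameters, their units and defaults:

| parameter | meaning | range | default |
|---|---|---|---|
| `a0` | initial activation on the seeded word (units) | > 0 | 20 |
| `r` | proportion retained when spreading | [0, 1] | 0.5 |
| `d` | proportion lost network-wide per step | [0, 1] | 0 |
| `s` | threshold below which activation is zeroed (units) | ≥ 0 | 0 |
| `t` | number of timesteps | ≥ 1 | 5 |

The stage order is a modelling choice: the published description of the
parameters fixes their meaning but not the within-step order.  The
order above makes *d* literally "the proportion of activation lost at
each time step": with `s = 0` the network total after *m* steps is
exactly `a0·(1 − d)^m`, and at `d = 0` activation is strictly conserved
(the retention/spread stage is a column-stochastic linear map).  Both
facts are enforced as tests at 1e−9 relative tolerance; in practice the
engine agrees with the closed form to ~1e−15.  Full retention at
degree-0 nodes is required for that conservation law and for the
island-trapping mechanism of the component experiment.  The suppress
comparison is strict (`a < s → 0`), which makes `s = 0` a no-op since
activations are always ≥ 0 — so the choice of strict vs non-strict is
inert for every default-parameter run.  The engine is dense
double-precision arithmetic with per-edge accumulation, no randomness
anywhere; an independent dense transfer-matrix-power oracle in the test
suite pins the implementation down on small graphs.

With `s = 0` the trajectory is linear in the seed vector and the
target's readout is nonincreasing in *d* elementwise in time — both
property-tested, and the latter is the mechanism behind the
condition-specific decay design.

## Experiments and the test

An experiment takes exactly two disjoint stimulus sets.  Every word is
seeded *alone* in its own run and its **own** activation is read at the
final timestep (`read_timestep` is exposed for sensitivity checks but
defaults to *t*).  Condition-specific decay is realized by overriding
*d* per run according to the word's condition — resolution order:
explicit config override, then the stimulus set's annotation, then the
shared default.  Group means are compared with Student's
pooled-variance two-sample t-test (df = n₁ + n₂ − 2, two-tailed p; the
statistic is computed from the textbook pooled formula, the p-value via
the t distribution's survival function).  Zero pooled variance with
equal means returns t = 0, p = 1; with unequal means it is treated as a
degenerate-input error rather than ±∞.  Words missing from the network
abort the run — no silent zero-assignment.

## Network algorithms

**Construction.**  All unit-edit-distance pairs are found by keyed
hashing: insertion/deletion pairs share a full transcription with a
single-deletion variant; substitution pairs share a
(position, sequence-minus-position) key with differing symbols at the
held-out position (equal symbols there means homophone, not neighbor).
This is near-linear in lexicon size and is verified edge-for-edge
against an all-pairs Wagner–Fischer oracle on random lexicons.

**Clustering.**  `C = (edges among neighbors) / (k(k−1)/2)`, with
`C := 0` for `k < 2` — the literature leaves that case undefined; zero
keeps group means over stimulus sets well-defined.

**Component classes.**  Giant = largest connected component *provided
it has ≥ 2 nodes* (in an edgeless graph there is no giant and every
node is an isolate); islands = other components of size ≥ 2; isolates =
degree-0 singletons.  Size ties break on the smallest node id.

**Fragmentation and key players.**
`F = 1 − Σ s_k(s_k − 1)/(n(n − 1))` over component sizes — the
probability that two random distinct nodes cannot reach each other.
The key-player search is greedy forward selection plus one
pairwise-swap refinement pass, all ties broken by smallest node id, so
results are fully deterministic; the distance-weighted variant of the
objective is deliberately out of scope.  Residual F is computed on the
graph after removal with *n* = remaining nodes (a residual of one node
counts as trivially connected, F = 0).  Greedy selection is a
heuristic: it is exact for k = 1 (tested against exhaustive removal up
to 50 nodes) but makes no optimality claim for larger k.

## Synthetic data

**What the lexicon generator emulates.**  `random_lexicon` draws
distinct phoneme strings (rejection sampling) over a 20-symbol
alphabet with word lengths 2–8.  The length weights
{2: .05, 3: .22, 4: .33, 5: .18, 6: .10, 7: .07, 8: .05} were frozen
after a one-off calibration at n = 2000 so the resulting one-phoneme
network lands near the macro profile the analysis assumes: measured
≈ 58% hermits and ≈ 35% giant component (regression band 30–70% and
15–55%).  What it does **not** emulate: real phonotactics, a realistic
(right-skewed) degree distribution, frequency structure, or the
reference network's ~13% island mass — in an i.i.d.-string ensemble at
this size, island mass and hermit mass trade off and islands stay
small and rare (~7%).  Passing tests therefore show the pipeline's
mechanics and directions, not quantitative agreement with any real
lexicon.

**Contrast generators build graphs directly.**  Realizing an exact
clustering or bridge structure as a 1-edit-distance lexicon is a hard
inverse problem the experiments never require; the diffusion and
metrics layers are topology-only, so direct graphs suffice
(`random_lexicon` provides the string-based path for end-to-end I/O
tests).  All generators are pure functions of their spec, seed
included.

* *Clustering contrast*: each target gets exactly `target_degree`
  fresh neighbors, interconnected with probability `p_high` (default
  0.8) or `p_low` (default 0); each neighbor is linked outward
  (`dispersal_links`, default 1) to a shared connected background
  (default 100 nodes, spanning tree + 60 chords) so dispersal is
  possible.  With p = 1 vs 0 the measured C is exactly 1 vs 0.
* *Component contrast*: one connected background of 200 nodes (mean
  degree ≈ 3) plus 10 connected 5-node islands; 20 targets per side,
  giant-side targets greedily matched to the island targets' degrees.
* *Key-player contrast*: a "lollipop" of cycle-clusters (sizes drawn
  from 5–9).  A ring of clusters is joined by degree-2 connector nodes
  — the **foils**: removing one leaves the ring connected the long way
  round, F stays 0.  A tail chain of clusters hangs off the ring,
  joined by degree-2 connectors — the **keys**: each is a cut vertex
  whose removal strictly increases F.  Keys and foils are exactly
  matched on degree (2) and clustering (0), and a connector's local
  surroundings — a chain of cycle-clusters in both directions — are
  the same in ring and tail, so the uniform-decay comparison is a true
  null; the property that distinguishes foils (global redundancy) is
  invisible to a 5-step diffusion.  One padding cluster at the
  ring/tail junction and at the tail end keeps boundary connectors
  (whose environments are atypical) out of the target sets.  The null
  band asserted in tests — mean |t| over 10 seeds below 2.0 — was
  frozen from a design-time calibration (observed mean |t| ≈ 0.8–1.6;
  within-network dependence between targets inflates |t| somewhat
  above the i.i.d. expectation of ≈ 0.8).  The sets carry the 0.1/0.3
  decay annotations of the condition-specific design; uniform-decay
  runs strip them with `StimulusSet.with_decay(None)`.

## Problem sizes

Test and acceptance runs use sizes chosen to exercise each algorithm
well past its edge cases while keeping the whole suite interactive:
conservation on 200 random graphs of ≤ 200 nodes; construction oracle
on 50 random lexicons of ≤ 500 words; diffusion oracle on graphs of
≤ 20 nodes; key-player oracle on graphs of ≤ 50 nodes; clustering
oracle exhaustively on the full ≤ 7-node graph atlas plus 200 random
8-node graphs; experiments at 20 targets per group; lexicon calibration
at n = 2000.

## Known limitations

* The greedy key-player search is not exact for k > 1.
* The generated degree distribution is roughly Poisson-like within a
  length stratum, not the heavy-tailed distribution of real
  phonological networks.
* No frequency, familiarity, or phonotactic-probability covariates are
  modelled; matching in the synthetic designs is on degree (and
  implicitly clustering) only.
* The pipeline reads the target at a fixed timestep; per-run maxima or
  time-to-threshold readouts are not implemented (only exposed
  indirectly via `read_timestep`).
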