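# Methods

## Model and scope

`boolobs` works with synchronous Boolean networks: n binary genes,
each updated by a truth table over its input genes, all genes updating
simultaneously. Asynchronous and probabilistic semantics are out of
scope. Attractors are the cycles of the functional graph of the update
map; for small networks (default cap n ≤ 20, overridable via
`max_nodes`) they are enumerated exhaustively by trajectory-following
with a visited map, never by materialising a 2^n × 2^n matrix. The cap
is a practical guard on the 2^n traversal, not a property of the
algorithmic contribution — the observability solver itself never
touches the state space and handles large n directly.

Attractors are canonicalised by rotating each cycle to start at its
lexicographically smallest state and sorting attractors by that state,
so enumeration output is deterministic and comparable.

## The observability solver

Definitions: m attractors with periods l_1..l_m over n genes; a phase
combination is one m×n matrix A of chosen states, L = l_1⋯l_m in
total; the pairwise difference matrix holds the XOR of every unordered
row pair of A. The per-combination minimum derives from runs of
consecutive zeros (columns where a pair agrees):

- Runs shorter than ⌈log₂ m⌉ are discarded: no window of at least the
  information-theoretic lower bound fits inside them.
- If the surviving runs miss a column x, any window of length
  ⌈log₂ m⌉ containing x pokes out of every run, so that combination's
  minimum is exactly ⌈log₂ m⌉.
- Otherwise runs are sorted by start. Among runs sharing a start only
  the longest is kept, and **any run strictly contained in another is
  also removed**. Containment pruning is a deliberate strengthening of
  plain same-start deduplication: a contained run disqualifies no
  window its container doesn't, and without the removal the
  adjacent-run candidate window `end_j + 1` can fall past column n.
  With it, the surviving runs have strictly increasing starts and
  ends, and the adjacent-pair formula
  `max(min_j [end_j − start_{j+1} + 3], ⌈log₂ m⌉)` is well defined;
  this reproduces all of the worked per-combination minima.
- A single surviving run necessarily spans [1, n] (it arises from an
  all-zero difference row, i.e. two identical chosen states); such a
  combination is infeasible and excluded from the minimum. Because an
  `AttractorSet` enforces globally distinct states — attractors of a
  deterministic network are disjoint — a fully infeasible instance
  cannot be constructed through the public container, but the solver
  still reports the flag for robustness.

Semantics for cyclic attractors follow the problem definition: a
window is sufficient if *some* phase assignment separates all
attractors, even though an observer sampling at an unknown phase
cannot choose it. A stricter all-phase semantics would be a different
(harder) problem and is intentionally not implemented.

Early termination is the default: the combination scan stops once some
minL_i reaches ⌈log₂ m⌉, which no later combination can undercut.
`exhaustive=True` evaluates every combination and records all minL_i.
Both modes provably return the same minimum, and the test suite checks
that agreement on random instances.

All reported indices are 1-based closed intervals, matching the
conventional gene numbering x1..xn. Achieving windows are recovered by
direct restriction: every start a such that the m row patterns on
[a, a+w−1] are pairwise distinct, for every combination attaining the
minimum, reported in (combination, start) order.

## The brute-force oracle

`brute_force_min` scans window lengths ascending and tests every
(combination, start) by comparing restricted rows for distinctness. It
shares no XOR-run machinery with the solver, so its agreement with the
solver — exercised on 500 seeded random instances in the acceptance
suite plus property tests — is independent evidence, not a tautology.
Its cost is O(L·n²·m²) and a budget guard refuses larger requests; it
is a validation device, not a production path.

## Random-instance experiments

`random_attractor_set` draws every bit as an independent fair coin and
redraws until all m·period states are pairwise distinct (collisions
are vanishingly rare at the sizes of interest; a resample counter is
logged). Distinctness makes every generated instance feasible. Cyclic
attractors are random distinct state lists, **not** cycles of an
actual network: the solver consumes only the states, so the generating
dynamics cannot affect the measured quantity. What the generator does
not emulate: correlated gene states, biased activation frequencies,
and attractor structure induced by a specific wiring — conclusions
from these experiments concern the combinatorics of random binary
matrices, not any particular biological network.

Experiment defaults mirror the study conditions: grid points are
(n, m, period) with ten trials per point originally; the bundled
experiments and the acceptance script use 50 trials per point to
tighten the mean at negligible cost (each trial solves in
milliseconds). Reported per-point statistics are the per-trial minimal
window lengths ("numNode") and their mean. Wall-clock timings are not
a measured output: they are hardware-dependent and carry no
algorithmic information.

## Numerical and design choices

- Truth tables are addressed little-endian: the first listed input of
  a node is the lowest-order bit. Rule expressions admit `& | ! ^`
  and parentheses; inputs are ordered by first appearance.
- State integers encode v1 as the most significant bit, so numeric
  order equals lexicographic order of gene activity profiles and
  transition tables list states in ascending binary order.
- Pairs (i, k), i < k are enumerated lexicographically; any stable
  sort satisfies the run-sorting contract (bucket sort would be an
  optimisation, not a semantic requirement at these sizes).
- Windows are linear, never wrap-around.
- m = 1 returns minimum 0: nothing needs distinguishing, and running
  the machinery with threshold ⌈log₂ 1⌉ = 0 would be meaningless.
- Ties: *all* achieving (combination, window) pairs are reported, in
  deterministic order.
- The Drosophila fixture stores the ten 60-character steady-state
  strings verbatim in a packaged data file; a checksum test pins the
  bytes. The variable-to-name map is generated from the model's
  regular layout (four compartments × the 15-symbol gene/protein
  order), which covers columns 1..60 exactly.

## Limitations

- Exhaustive attractor enumeration is exponential in n and guarded at
  n ≤ 20 by default; attractor detection for large networks
  (SAT/ILP-based) is out of scope — attractor sets for large n enter
  through files or the random generator.
- The solver's combination scan is exponential in m through L = P^m;
  it is intended for the small m typical of regulatory models.
- Only contiguous windows are considered; the general minimal-key
  problem (arbitrary gene subsets) is NP-hard and out of scope.
- The command-line `sweep --histogram` plot requires matplotlib
  (optional extra `plot`).
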