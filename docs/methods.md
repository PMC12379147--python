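# Methods

## Scope and model

The package targets undirected, unweighted simple graphs. Directed or
weighted input is symmetrized/flattened on load (each edge kept once,
self-loops dropped, duplicates collapsed; cleanup counts are logged at INFO).
All shortest paths are hop counts computed by breadth-first search — on
unweighted graphs this is the exact specialization of Dijkstra's algorithm.
Unreachable pairs carry an explicit `inf` sentinel and contribute 0 to every
inverse-distance sum (`1/inf = 0`).

## The EDDC score

`EDDC(v) = (deg(v)/N) · Σ_{j≠v} √(e(v)+e(j)) / dist(v,j)`, with `e(v)` the
base-2 entropy of the neighbor-degree distribution `p(u) = deg(u)/Σ deg(w)`.
Conventions:

- `e(v) = 0` for degree-0 (empty sum) and degree-1 (point mass) nodes.
- Entropy is bounded: `0 ≤ e(v) ≤ log₂ deg(v)`, with equality exactly when
  all neighbor degrees coincide. This is property-tested.
- The radical aggregation `√(e_i + e_j)` is implemented exactly as defined;
  there is no alternative linear mode. Its purpose is to moderate the
  influence of high-entropy regions (sublinear growth).
- An optional `max_hops` cutoff truncates the BFS frontier, implementing the
  hop-limited approximation recommended for very large graphs. The default
  is no cutoff, so the score is exact.

An isolated node scores 0. `eddc_aggregate` exposes the pure formula
assembly (degree, N, own entropy, and a list of `(entropy, distance)` pairs)
so individual terms can be audited against hand computations.

## Baseline conventions

- **Closeness**: `(N−1) / Σ dist` with the sum restricted to reachable
  nodes; the `N−1` numerator is kept even on disconnected graphs because
  that is the printed form of the formula. Isolated nodes score 0.
- **CLC**: 0 for degree ≤ 1 nodes (vanishing denominator).
- **ISC**: the threshold set `Deg_δ` is read as "nodes with degree ≥ δ", so
  a node whose neighbors fall below the threshold scores low. The convention
  is isolated in one predicate (`_meets_isc_threshold`) so it can be swapped;
  δ defaults to 2 and is recorded in the score table's params.
- **ECLGC**: local term `CLC(v) + mean over neighbors of √CLC`, global term
  the inverse-distance sum of the square roots of other nodes' local terms.
- **k-shell**: iterative peeling; delegated to a core-number routine and
  cross-checked in tests against a from-scratch naive peeling oracle.
- **Ranking**: descending score with ties broken by ascending node label.
  Score equality (ranking ties and the monotonicity index) is decided after
  rounding to 10 decimal places to absorb float noise; the constant is
  `SCORE_DECIMALS`.

## SIR simulator

Synchronous discrete-time dynamics: at each step every infected node
independently attempts to infect each susceptible neighbor with probability
β, computed from the start-of-step infected set; recoveries (probability λ
per step) are applied afterwards, so with λ = 1 every node transmits for
exactly one step. Spreading ability of a node is the mean final outbreak
size (`|R|` at absorption) over `runs` independent simulations seeded at it;
defaults are λ = 1 and 1000 runs.

Randomness: one master seed; node `i` draws all its runs from the substream
`SeedSequence(master, spawn_key=(i,))`, so adding nodes never perturbs other
nodes' streams and results are bit-reproducible. `simulate_once` accepts an
optional per-directed-edge uniform source; memoizing it couples runs across
β values, which is how the monotonicity-in-β property is tested (with λ = 1
each directed edge is attempted at most once, so the coupling is exact).

The epidemic threshold uses the heterogeneous mean-field estimate
`β_th = ⟨k⟩/(⟨k²⟩−⟨k⟩)`. For graphs where `⟨k²⟩ ≤ ⟨k⟩` (e.g. perfect
matchings) it is undefined and the code raises; a β grid can always be given
explicitly instead.

## Evaluation metrics

- **Kendall τ** defaults to the untied tau-a form `(N_c − N_d)/(n(n−1)/2)`:
  SIR mean outbreak sizes tie frequently, tied pairs count in neither N_c
  nor N_d, and the denominator is not tie-corrected. A tau-b variant
  (scipy) is available behind a flag. τ is computed between score vectors
  aligned on node identity, not between rank vectors.
- **σ(τ)** is the arithmetic mean of τ over a β grid; the canonical grid is
  `β_th + 0.01·i`, `i = 1..15`.
- **Monotonicity** `M = (1 − Σ N_i(N_i−1)/(N(N−1)))²` over groups of equal
  scores (equality after the rounding rule); invariant under strictly
  monotone transforms of the scores.
- **η%** merges the two sign branches of the printed definition into
  `(τ_C − τ_φ)/|τ_φ|·100`, which reproduces both; it is 0 when τ_φ = 0.
  `evaluate_methods` reports η per grid point (as the gain curves are
  plotted) and additionally on σ(τ), since the aggregation level of the
  tabulated gains is not specified.

## Synthetic data and the toy fixture

The ER/BA/WS generators wrap the standard networkx constructions with
seeded, bit-reproducible output. They emulate the three canonical regimes —
homogeneous random, scale-free, small-world — but none of the messiness of
real contact networks (degree correlations, community structure, temporal
edges), so a green stochastic test establishes correct behavior of the
method on idealized topologies, not performance claims on any real dataset.

The packaged 16-node / 21-edge toy network is *reconstructed*, not copied:
its drawing is not machine-readable, but the worked example fixes node 2's
neighborhood and degrees, the full hop-distance profile from node 2, and all
16 node entropies to ~3 decimals. Entropy targets propagate to exact
degrees (entropy 0 forces degree 1; a target t forces degree ≥ 2^t; the
bounds meet the handshake identity exactly), and a branch-and-prune search
over distance-layer-respecting edge sets (`scripts/build_toy_fixture.py`)
proves exactly one graph satisfies every constraint — the shipped fixture.

The worked example's own grand total (13.265) is not consistent with the
formula it illustrates: recomputing the printed 15-term bracket gives
13.0134, and 3.2533 after the 4/16 prefactor. The package follows the
formula literally; tests pin `eddc_aggregate` to an independent
high-precision recomputation of the printed terms. Similarly, the printed
entropy 1.752 of node 2 carries 3-decimal intermediate rounding — exact
evaluation gives 1.7527 — so entropy checks against printed values use a
5e-3 tolerance while implementation-vs-oracle checks use 1e-9.

## Small-world diagnostic

`small_world_report` compares mean path length L (connected pairs only) and
mean clustering against ER baselines matched in node count and edge density,
averaged over a configurable number of draws (disconnected baselines are
redrawn, logged). The property "holds" when `L_actual ≥ L_random` and
`CLC_actual ≥ CLC_random`.

## Numerical and design notes

- Logarithms are base 2 throughout the entropy computations.
- Scores are validated finite on construction of a score table.
- The CLI merges a YAML config under explicit flags (flags win) and logs the
  resolved configuration and master seed to stderr, keeping stdout/files
  pipeable and runs reproducible from the log alone.
- Benchmark timings are reported but hardware-dependent by nature; only
  orderings (e.g. EDDC growing superlinearly with N at fixed density) are
  meaningful.

## Known limitations

- Exact EDDC needs all-pairs BFS: `O(N(N+E))` time. The hop-limited variant
  trades exactness for locality on large graphs; no error bound is provided.
- The SIR simulator is synchronous-update only (no Gillespie dynamics, no
  SIS/SEIR variants).
- Weighted and directed generalizations are out of scope by design.
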