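# Methods

## Model and semantics

A Boolean network over nodes `v_1 … v_n` assigns each node a Boolean update
function `f_i` over the node values.  A state `s ∈ {0,1}^n` is printed as a
binary string with the first declared node leftmost (bit `i` of the string is
node `i`'s value); internally a state is the integer with that binary
expansion, so lexicographic order on bitstrings equals numeric order.

Two update semantics are supported:

* **Synchronous (SBN).**  All nodes update at once: `F(s) = (f_1(s), …,
  f_n(s))`.  `F` is a total function, so every trajectory enters a cycle and
  the attractors are exactly the cycles of `F`.
* **General asynchronous (ABN).**  Exactly one node updates per step: `s`
  has one successor `s ⊕ e_i` for every node `i` with `f_i(s) ≠ s_i`
  (no-op updates produce no edge; a global fixed point keeps an explicit
  self-loop so a single-state attractor is a literal loop in the graph).
  The attractors are the bottom strongly connected components (SCCs with no
  escaping edge) of this nondeterministic state transition graph.  Random
  subsets and priority classes are out of scope.

Attractors are classified into the standard four-type taxonomy:

| type | definition |
|---|---|
| self loop | single fixed state (attractor of both semantics) |
| simple loop | cycle of ≥ 2 states, consecutive states differ in exactly 1 bit (both semantics) |
| syn-complex loop | synchronous cycle with some step flipping ≥ 2 bits (sync-only) |
| asyn-complex loop | multi-state asynchronous bottom SCC with branching (async-only) |

Tags are structural per semantics: a synchronous cycle is classified by the
Hamming distances along its cycle order, an asynchronous bottom SCC by its
shape (singleton / deterministic cycle / branching).  Which synchronous
attractors an asynchronous attractor contains is reported separately by
`containment_map`, not by mutating tags.

## The set-based engine

`StateSet` is the characteristic boolean vector of a subset of `{0,1}^n`;
`TransitionRelation` is a sparse boolean matrix over (current, next) state
pairs.  Image, preimage, composition (`R1∘R2` via sparse matrix product),
fixed-state extraction (the matrix diagonal) and frontier-based
forward/backward reachability are bulk vectorised operations; the engine
manipulates whole state sets per step rather than individual trajectories.
The representation is explicit in the number of states, so both this engine
and the brute-force oracle carry a hard width cap of **n ≤ 20** (2^20
states); the practical comfort zone on one core is n ≤ 16.  Reachability
iterates to an exact fixpoint (set equality), which monotonicity bounds by
2^n rounds; no iteration cap is needed.

## Synchronous attractor detection

Let `A_k = {s : F^k(s) = s}` be the fixed states of the k-fold composed
relation.  `A_k` contains exactly the attractors whose period divides `k`
(divisor monotonicity: `d | k ⇒ A_d ⊆ A_k`).  The detector keeps an
unvisited set `U` (initially the universe) and iterates `k = 1, 2, …`:

1. compose `R_k = R_{k-1} ∘ R` (sequential powers, not repeated squaring —
   every divisor must be visited in order);
2. **periodicity check:** if `R_k` equals an earlier power `R_j`, every
   remaining state of `U` lies on a cycle, so `U` is decomposed into cycles
   and the run terminates.  The seen-table is seeded with the identity as
   the 0-th power.  With `U` nonempty this branch can only fire against
   `j = 0` (i.e. `F` is a permutation): if `F^k = F^j` with `j ≥ 1`, every
   cycle period divides `k − j`, so all attractors were already reported at
   iterations `≤ k − j` and their basins — which partition the state space —
   had emptied `U` beforehand.  Held-value (identity) dynamics therefore
   terminate here at `k = 1`;
3. **new attractors:** `N = A_k ∩ U` is decomposed into cycles by following
   the unique successor from the smallest unassigned state, each cycle's
   period recorded; the full basin `BR(N)` is then deleted from `U` so no
   attractor is ever re-reported;
4. terminate when `U = ∅`; a hard cap `max_k` (default 2^n, always
   sufficient since no cycle is longer than 2^n) raises an error rather
   than truncating silently.

Every power's canonical CSR key (indptr+indices bytes) is kept in the
seen-table.  At the enforced width cap this is cheap and exact; a bounded
window would only trade memory for a later detection point.

## Asynchronous derivation

The synchronous attractors seed the asynchronous search (each is
re-verified to be closed under `F` before use):

* **fixed point** → self loop under both semantics; its asynchronous basin
  is removed from the candidate set.
* **simple loop** → shared by both semantics.  This is provable, not just
  assumed: if consecutive cycle states differ in exactly one bit, then in
  each cycle state exactly one node is unstable, so the asynchronous
  successor relation restricted to the loop coincides with the synchronous
  cycle.  The closure check (`FR_async` of a member equals the loop) is
  still executed defensively and falls through to the complex branch if it
  ever failed.
* **syn-complex loop `L`** → compute the asynchronous forward closure
  `C = FR_async(L)`.  If `C` equals an already-found asyn-complex loop, `L`
  lies inside a visited attractor.  Else if `C` is a bottom SCC (closed,
  and strongly connected — checked with one anchor state `t`: `FR(t) = C`
  and `C ⊆ BR(t)`), it is a new asyn-complex loop containing `L`.
  Otherwise the closure leaks and **nothing is deleted**: see below.
* **sweep.**  Remaining unvisited states are tested in ascending order:
  state `s` lies in an attractor iff `FR(s) ⊆ BR(s)`, in which case
  `FR(s)` is that attractor (an additional asyn-complex loop); otherwise
  `s` is transient and so is its entire backward closure `BR(s)` — any
  state that reaches a transient state is itself transient, because an
  attractor state's forward closure never leaves its attractor — so
  `BR(s)` is deleted wholesale.

The leaking-closure case deliberately defers to the sweep.  The tempting
shortcut — "the loop's states are transient, delete their backward
closure" — is unsound: an asynchronous attractor can overlap a synchronous
cycle *partially*.  Smallest example found (random N-K network, n = 2,
k = 2, generator seed 7): `f_1 = ¬x_1 ∧ ¬x_2`,
`f_2 = (¬x_1 ∧ ¬x_2) ∨ (x_1 ∧ x_2)` has the synchronous 3-cycle
{00, 11, 01} while the asynchronous attractor is {00, 01, 10} — two of the
cycle's states are in the attractor and one is transient, and the
attractor contains a state the cycle lacks.  Deleting `BR(L)` there
removes attractor states and the attractor is lost.  Per-single-state
transience, by contrast, is always sound.  Consequently
`containment_map` may report an asyn-complex loop as "transient-only"
(no synchronous attractor wholly contained) even when it shares some
states with one; the value lists only whole containments.

The final result equals the set of bottom SCCs of the asynchronous graph —
enforced in tests by exact comparison with the independent oracle.

## Brute-force oracle

The oracle enumerates the full state transition graph state-by-state with
scalar Python evaluation (a deliberately separate code path from the
vectorised engine) and computes bottom SCCs with scipy's iterative
strongly-connected-components routine — for the deterministic synchronous
graph the bottom SCCs are exactly the cycles.  A second, third route
(trajectory walking with colouring) cross-checks the synchronous attractor
union in the tests.  The oracle is the correctness authority: the engine
must match it exactly (state sets, periods, type tags) on every test
network.

## Translation schemes

The rule dialect is the primary input.  Signed interaction graphs
(`A -> B` activation, `A -| B` inhibition) are translated to rules by, for
node `i` with activator set `A_i` and inhibitor set `I_i`:

* `classical`: `f_i = (∨ A_i) ∧ ¬(∨ I_i)`; with no activators the
  activation term defaults to `x_i` (value held), with no inhibitors the
  inhibition term vanishes; a node with no regulators holds its value.
* `inhibitor_priority`: the inhibitors-dominate reading
  `f_i = ¬(∨ I_i) ∧ (∨ A_i)`, same defaults.  With binary logic the two
  schemes compute the same function and differ in reading and rendering
  order; they are kept distinct because the per-node `combined` scheme
  selects between them by name and because richer schemes (e.g. ones where
  inhibitors only veto when no activator is active) can slot into the same
  interface.
* `combined`: per-node choice via a mapping, defaulting to classical.

These formulas are this package's documented choice for the
activator/inhibitor-priority families in the literature; tools in this
space differ in detail, so reproductions of published counts should start
from explicit rule files rather than from a graph plus a scheme guess.

## Random N-K networks

`random_network(n, k, seed)` draws, per node, `k` distinct regulators
uniformly and a uniform random truth table over them, redrawn while
constant (a constant function would render as `0`/`1` and reference no
regulator; all non-constant tables keep every regulator syntactically
present via minterm expansion).  With `numpy.random.default_rng` the
generator is reproducible across runs and platforms for a fixed
`(n, k, seed)`.  These networks are the package's synthetic test surface:
they cover deterministic cycles, branching asynchronous dynamics, partial
overlap cases and permutation dynamics, but they are *not* biologically
realistic (no canalising bias, no scale-free wiring), so agreement on them
demonstrates algorithmic correctness, not biological calibration.

## Problem sizes used in tests and the acceptance script

Exhaustive cross-validation uses 100 seeded N-K networks with `n ∈ 2..10`,
`k ∈ 1..3` (both semantics, exact match), theorem properties use 50
networks with `n ≤ 6`, and reachability/BFS agreement uses 30 networks
with `n ≤ 8` over all states.  These sizes keep the full state space
enumerable by the oracle while covering every taxonomy case observed;
the whole suite runs in well under a minute on one core.  The benchmark
model (10 nodes, 1024 states) runs in milliseconds.

## Known limitations

* Width cap n ≤ 20 for both engines (explicit 2^n representations); truly
  large models need a decision-diagram backend, which the relation/state-set
  interfaces were shaped to accommodate.
* General asynchronous semantics only; no update probabilities, priority
  classes or steady-state distributions.
* No SBML-qual import; rule files and signed edge lists only.
* The synchronous report's cycle order starts each cycle at its smallest
  state; JSON output sorts attractors by (type, smallest member bitstring)
  and is byte-stable across runs and engines.
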