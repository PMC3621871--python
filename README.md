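# boolattract

Attractor detection and classification for Boolean models of gene
regulatory networks, under both synchronous and general asynchronous
update semantics.

Boolean networks model each gene as a binary node with a logical update
rule over its regulators.  Their long-run behaviours — the **attractors** —
correspond to cell fates and cycles: under synchronous updates (all nodes
at once) the dynamics are a deterministic map `F` whose attractors are its
cycles; under asynchronous updates (one node per step) the dynamics form a
nondeterministic state transition graph whose attractors are the bottom
strongly connected components.  `boolattract` computes both and classifies
every attractor into the four-type taxonomy used in this field:

* **self loop** — a fixed point `F(s) = s` (attractor of both semantics);
* **simple loop** — a cycle whose consecutive states differ in exactly one
  bit (also shared by both semantics);
* **syn-complex loop** — a synchronous cycle with a multi-bit step
  (synchronous-only);
* **asyn-complex loop** — a branching asynchronous bottom SCC
  (asynchronous-only).

The synchronous detector avoids trajectory enumeration: it iterates the
relation power `R^k` and reads the fixed-state sets
`A_k = {s : F^k(s) = s}`, which contain exactly the attractors whose
period divides `k`.  Reported attractors have their whole basin (backward
reachable set) deleted from the unvisited set, and the run stops when the
unvisited set empties or a repeated relation power proves every remaining
state lies on a cycle.  The asynchronous attractors are then derived from
the synchronous ones: fixed points and single-bit cycles carry over
directly, each syn-complex loop seeds a forward-closure/bottom-SCC test,
and a final sweep (`FR(s) ⊆ BR(s)` ⇔ `s` is in an attractor) picks up
anything the seeds missed.  A brute-force explicit-state oracle (full
state transition graph + strongly connected components) ships in the
package and is held to agree exactly with the set-based engine on every
test network.

Intended users: systems biologists and method developers who need exact
attractor sets and counts for logical models of up to ~20 nodes, with a
verifiable reference path.

## Worked example

The two-node swap network (`x1, x2` / `x2, x1`) exchanges its node values
each step:

```bash
$ boolattract --model examples/swap.bnet --counts-only
{
  "self_loop": 2,
  "simple_loop": 0,
  "syn_complex": 1,
  "asyn_complex": 0
}
```

Synchronously there are three attractors: the fixed points `00` and `11`,
plus the 2-cycle `01 ↔ 10` — a *syn-complex* loop, because its step flips
both bits at once.  Asynchronously that 2-cycle dissolves (from `01` a
single-node update reaches `11` or `00`), so only the two fixed points
survive: the counts line shows 2 shared self loops, 1 synchronous-only
complex loop and no asynchronous complex loop.

The ten-node mammalian cell-cycle logical model (Fauré et al. 2006,
`examples/mammalian_cell_cycle.bnet`) gives:

```bash
$ boolattract --model examples/mammalian_cell_cycle.bnet --counts-only
{
  "self_loop": 1,
  "simple_loop": 0,
  "syn_complex": 1,
  "asyn_complex": 1
}
```

the quiescent fixed point `0100010100` (Rb, p27 and Cdh1 on, cyclins off)
plus one cycling attractor: a synchronous complex loop of period 7 that
becomes a 112-state asynchronous complex loop.

Full reports (`--semantics sync|async|both`, default `both`) list every
attractor with its states as binary strings in declared node order; output
is byte-stable and identical between `--engine symbolic` (the set-based
engine) and `--engine brute` (the explicit oracle).  Signed interaction
graphs (`A -> B` / `A -| B` files, `--format graph`) are translated to
rules by a documented activator/inhibitor scheme (`--scheme`), and
`boolattract random --n 8 --k 2 --seed 1` emits reproducible random N-K
test networks.

The same pipeline from Python:

```python
from boolattract import parse_rules, sync_attractors, async_attractors

net = parse_rules(open("examples/swap.bnet").read())
sync_rep = sync_attractors(net)
async_rep, sync_rep = async_attractors(net, sync_rep)
print(sync_rep.counts)   # {'self_loop': 2, 'simple_loop': 0, 'syn_complex': 1, 'asyn_complex': 0}
print(len(async_rep.attractors))  # 2
```

See `docs/methods.md` for the algorithms, their assumptions and the
numerical/design choices.

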