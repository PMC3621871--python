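"""Iterative synchronous attractor detection.

Under synchronous semantics the update map F is a total function, so every
trajectory eventually enters a cycle and the attractors are exactly the
cycles of F.  Rather than walking trajectories, the detector iterates the
relation power R^k and reads off the fixed-state set
A_k = {s : F^k(s) = s}, which contains precisely the attractors whose
period divides k (divisor monotonicity: d | k implies A_d is a subset of
A_k).  Each iteration reports the newly fixed states, decomposes them into
cycles, and deletes their whole basin (backward reachable set) from the
unvisited set, so later iterations only ever see states whose attractor is
still unknown.

Termination: the unvisited set empties once k has passed the longest cycle
length (at most 2^n), or earlier when R^k repeats an already-seen power —
F^k = F^j with j < k forces every remaining unvisited state onto a cycle
(with a nonempty unvisited set this can only happen against the identity
power j = 0, i.e. F is a permutation), so the remainder is decomposed
directly.
"""
from __future__ import annotations

from .model_io import Attractor, AttractorReport, hamming, state_to_string
from .symbolic_core import (
    StateSet,
    TransitionRelation,
    backward_reachable,
    build_sync_relation,
)

__all__ = [
    "IterationCapExceeded",
    "decompose_cycles",
    "classify_sync",
    "sync_attractors",
]


class IterationCapExceeded(RuntimeError):
    """Raised when max_k iterations did not empty the unvisited set."""


def decompose_cycles(states: StateSet, R: TransitionRelation) -> list[Attractor]:
    """Partition a set of cycle states into the disjoint cycles of F.

    Every member must lie on a cycle entirely contained in ``states``;
    cycles are extracted by following the unique successor from the
    smallest unassigned state.  A successor stepping outside the set is a
    contract violation.
    """
    remaining = set(states.states())
    out: list[Attractor] = []
    while remaining:
        start = min(remaining)
        cycle = [start]
        walk = {start}
        cur = start
        while True:
            cur = R.successor(cur)
            if cur == start:
                break
            if cur not in remaining or cur in walk:
                raise ValueError(
                    f"state {state_to_string(cur, R.n)} leaves the candidate cycle set; "
                    "input states are not a union of cycles"
                )
            walk.add(cur)
            cycle.append(cur)
        remaining -= walk
        out.append(
            Attractor(states=tuple(cycle), semantics="sync", period=len(cycle))
        )
    out.sort(key=lambda a: (a.period, a.smallest))
    return out


def classify_sync(attractor: Attractor) -> str:
    """Type tag of a synchronous cycle from its step-wise Hamming distances.

    A single state is a self loop; a longer cycle is a simple loop when
    every consecutive pair (wrap-around included) differs in exactly one
    bit, and a syn-complex loop when some step flips two or more bits.
    """
    if attractor.size == 1:
        return "self_loop"
    cyc = attractor.states
    for a, b in zip(cyc, cyc[1:] + cyc[:1]):
        if hamming(a, b) != 1:
            return "syn_complex"
    return "simple_loop"


def sync_attractors(network, max_k: int | None = None) -> AttractorReport:
    """Compute all synchronous attractors of ``network`` iteratively.

    Parameters
    ----------
    network : BooleanNetwork
    max_k : int, optional
        Hard cap on the number of relation powers; defaults to 2^n, which
        is always sufficient (every cycle length is at most 2^n).  Raises
        :class:`IterationCapExceeded` if exceeded without finishing, rather
        than truncating silently.
    """
    R = build_sync_relation(network)
    n = network.n
    if max_k is None:
        max_k = 1 << n
    if max_k < 1:
        raise ValueError("max_k must be >= 1")

    unvisited = StateSet.universe(n)
    attractors: list[Attractor] = []
    # seen powers of the relation, keyed exactly; power 0 is the identity
    seen: dict[bytes, int] = {TransitionRelation.identity(n).canonical_key(): 0}
    Rk = None
    finished = False

    for k in range(1, max_k + 1):
        Rk = R if k == 1 else Rk.compose(R)
        key = Rk.canonical_key()
        if key in seen:
            # F^k equals an earlier power: every remaining state is in an
            # attractor, so decompose the rest of the unvisited set directly.
            if unvisited:
                attractors.extend(decompose_cycles(unvisited, R))
                unvisited = StateSet.empty(n)
            finished = True
            break
        seen[key] = k

        new_fixed = Rk.fixed_states() & unvisited
        if new_fixed:
            attractors.extend(decompose_cycles(new_fixed, R))
            unvisited = unvisited - backward_reachable(new_fixed, R)
        if unvisited.is_empty:
            finished = True
            break

    if not finished:
        raise IterationCapExceeded(
            f"unvisited states remain after max_k={max_k} iterations"
        )

    for att in attractors:
        att.type_tag = classify_sync(att)
    attractors.sort(key=lambda a: (a.period, a.smallest))
    report = AttractorReport(semantics="sync", n=n, attractors=attractors)
    report.validate_disjoint()
    return report
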