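"""Deriving asynchronous attractors from the synchronous ones.

Under general asynchronous semantics (one node updates per step) the
attractors are the bottom strongly connected components of the state
transition graph.  Instead of searching the whole graph, the derivation
starts from the synchronous attractors:

* a synchronous fixed point is an attractor of both semantics (self loop);
* a synchronous cycle whose consecutive states differ in exactly one bit
  has exactly one unstable node per state, so its asynchronous dynamics
  coincide with the cycle — a simple loop shared by both semantics;
* a syn-complex loop L (some step flips >= 2 bits) is never asynchronously
  closed as-is.  Its asynchronous forward closure C either is a bottom SCC
  (a new asyn-complex loop containing L), coincides with an already-found
  asyn-complex loop (L sits inside a visited attractor), or leaks.  In the
  leaking case L's states cannot be discarded as transient outright: an
  asynchronous attractor may overlap a synchronous cycle only partially,
  so those states are left for the sweep below to resolve individually.

Whatever the synchronous seeds missed is swept up afterwards: remaining
unvisited states are tested in ascending order with the bottom-SCC
criterion FR(s) is a subset of BR(s); every hit is an additional
asyn-complex loop.  A sweep miss is safe to delete together with its whole
backward closure: any state that can reach a transient state is itself
transient (an attractor state's forward closure never leaves the
attractor).  The successful branches likewise delete the asynchronous
basin of what they resolved, so each region is touched once and the
result is exactly the set of bottom SCCs.
"""
from __future__ import annotations

from .model_io import Attractor, AttractorReport, state_to_string
from .sync_attractors import classify_sync
from .symbolic_core import (
    StateSet,
    TransitionRelation,
    backward_reachable,
    build_async_relation,
    build_sync_relation,
    forward_reachable,
)

__all__ = [
    "SyncReportMismatch",
    "is_bottom_scc",
    "async_attractors",
    "containment_map",
]


class SyncReportMismatch(ValueError):
    """The supplied synchronous report is inconsistent with the network."""


def is_bottom_scc(candidate: StateSet, R_async: TransitionRelation) -> bool:
    """True iff ``candidate`` is closed and strongly connected under R_async.

    Checks image(candidate) within candidate, then strong connectivity via a
    single anchor t: if candidate is closed, FR(t) = candidate and
    candidate within BR(t) force FR(s) = candidate for every member s.
    """
    if candidate.is_empty:
        raise ValueError("candidate set must be nonempty")
    if not R_async.image(candidate).issubset(candidate):
        return False
    anchor = StateSet.from_states(candidate.n, [candidate.min_state()])
    if forward_reachable(anchor, R_async) != candidate:
        return False
    return candidate.issubset(backward_reachable(anchor, R_async))


def _check_sync_report(report: AttractorReport, R_sync: TransitionRelation) -> None:
    for att in report.attractors:
        states = StateSet.from_states(report.n, att.states)
        if R_sync.image(states) != states:
            raise SyncReportMismatch(
                f"alleged synchronous attractor starting at "
                f"{state_to_string(att.smallest, report.n)} is not closed under F"
            )


def _cycle_order(states: StateSet, R: TransitionRelation) -> tuple[int, ...]:
    """Order a deterministic cycle starting from its smallest state."""
    start = states.min_state()
    cycle = [start]
    cur = R.successor(start)
    while cur != start:
        cycle.append(cur)
        cur = R.successor(cur)
    return tuple(cycle)


def async_attractors(
    network, sync_report: AttractorReport
) -> tuple[AttractorReport, AttractorReport]:
    """Derive all asynchronous attractors from the synchronous report.

    Returns ``(async_report, classified_sync_report)``.  The synchronous
    report must be complete and correct for ``network`` (as produced by
    :func:`~boolattract.sync_attractors.sync_attractors`); each synchronous
    attractor is re-verified to be closed under F before use.
    """
    n = network.n
    R_sync = build_sync_relation(network)
    R_async = build_async_relation(network)
    _check_sync_report(sync_report, R_sync)

    unvisited = StateSet.universe(n)
    async_atts: list[Attractor] = []
    found_sets: list[frozenset[int]] = []

    def add_async(states: StateSet, type_tag: str, ordered: tuple[int, ...] | None = None):
        members = ordered if ordered is not None else tuple(states.states())
        async_atts.append(Attractor(states=members, semantics="async", type_tag=type_tag))
        found_sets.append(frozenset(members))

    # --- main resolving pass over the synchronous seeds -------------------
    sync_sorted = sorted(sync_report.attractors, key=lambda a: a.smallest)
    for att in sync_sorted:
        att.type_tag = classify_sync(att)
        L = StateSet.from_states(n, att.states)
        if att.size == 1:
            # fixed point: attractor of both semantics
            add_async(L, "self_loop")
            unvisited = unvisited - backward_reachable(L, R_async)
            continue
        if att.type_tag == "simple_loop":
            # one unstable node per state along a Hamming-1 cycle, so the
            # asynchronous closure provably equals the cycle; verify anyway
            # and fall through to the complex branch if it ever failed.
            seed = StateSet.from_states(n, [att.smallest])
            if forward_reachable(seed, R_async) == L:
                add_async(L, "simple_loop", ordered=att.states)
                unvisited = unvisited - backward_reachable(L, R_async)
                continue
        # syn-complex loop (or a simple loop that failed the closure check)
        closure = forward_reachable(L, R_async)
        closure_set = frozenset(closure.states())
        if closure_set in found_sets:
            # L lies inside an asyn-complex loop found earlier; nothing new
            continue
        if is_bottom_scc(closure, R_async):
            add_async(closure, "asyn_complex")
            unvisited = unvisited - backward_reachable(closure, R_async)
        # Otherwise the closure leaks: L is not asynchronously closed.  L may
        # still overlap an asynchronous attractor partially (some states
        # transient, others not), so nothing can be deleted wholesale here —
        # the unvisited sweep below resolves these states one by one.

    # --- checking unvisited states ----------------------------------------
    while unvisited:
        seed = StateSet.from_states(n, [unvisited.min_state()])
        fwd = forward_reachable(seed, R_async)
        bwd = backward_reachable(seed, R_async)
        if fwd.issubset(bwd):
            # s lies in an attractor: its forward closure is a bottom SCC
            add_async(fwd, "asyn_complex")
            unvisited = unvisited - backward_reachable(fwd, R_async)
        else:
            # s is transient, and so is everything that can reach it
            unvisited = unvisited - bwd

    async_atts.sort(key=lambda a: a.smallest)
    async_report = AttractorReport(semantics="async", n=n, attractors=async_atts)
    async_report.validate_disjoint()

    classified_sync = AttractorReport(
        semantics="sync",
        n=n,
        attractors=sorted(sync_report.attractors, key=lambda a: (a.period, a.smallest)),
    )
    return async_report, classified_sync


def containment_map(
    async_report: AttractorReport, sync_report: AttractorReport
) -> dict[int, list[int] | str]:
    """Which synchronous attractor(s) each asynchronous attractor contains.

    Keyed by the smallest state of each asynchronous attractor; the value is
    the list of smallest states of the synchronous attractors whose state
    sets it contains, or ``"transient-only"`` when it contains none (its
    states are all synchronous transients).  Self loops map to themselves.
    """
    out: dict[int, list[int] | str] = {}
    for a_att in async_report.attractors:
        contained = [
            s_att.smallest
            for s_att in sync_report.attractors
            if s_att.state_set <= a_att.state_set
        ]
        out[a_att.smallest] = contained if contained else "transient-only"
    return out
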