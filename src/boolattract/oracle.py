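"""Explicit-state reference implementation (the correctness authority).

Builds the full state transition graph by evaluating every update rule
state-by-state with plain Python booleans — deliberately a different code
path from the vectorised set engine — and reads the attractors off as the
bottom strongly connected components of the explicit graph (for the
deterministic synchronous graph, the bottom SCCs are exactly the cycles).
SCCs come from scipy's iterative implementation, so there is no recursion
depth hazard at 2^20 states.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph

from .model_io import Attractor, AttractorReport, BooleanNetwork
from .symbolic_core import StateCapExceeded
from .sync_attractors import classify_sync

__all__ = [
    "STATE_CAP_BITS",
    "ExplicitSTG",
    "build_stg",
    "oracle_attractors",
    "oracle_sync_attractors",
    "oracle_async_attractors",
]

STATE_CAP_BITS = 20  # 2^20 explicitly enumerated states


@dataclass
class ExplicitSTG:
    """A fully enumerated state transition graph."""

    n: int
    semantics: str  # "sync" | "async"
    successors: list[list[int]]  # index = state as integer


def build_stg(network: BooleanNetwork, semantics: str) -> ExplicitSTG:
    """Enumerate every state's successors under the chosen semantics.

    Synchronous: exactly one successor per state.  Asynchronous: one
    successor per unstable node (single-bit flips), with a self-loop at
    global fixed points.
    """
    if semantics not in ("sync", "async"):
        raise ValueError(f"unknown semantics {semantics!r}")
    n = network.n
    if n > STATE_CAP_BITS:
        raise StateCapExceeded(
            f"n={n} exceeds the explicit-state cap of {STATE_CAP_BITS} nodes; "
            "use the set-based engine"
        )
    names = network.node_names
    exprs = network.update_exprs
    size = 1 << n
    successors: list[list[int]] = []
    for s in range(size):
        env = {names[i]: bool((s >> (n - 1 - i)) & 1) for i in range(n)}
        nxt_bits = [bool(e.evaluate(env)) for e in exprs]
        if semantics == "sync":
            t = 0
            for i, bit in enumerate(nxt_bits):
                if bit:
                    t |= 1 << (n - 1 - i)
            successors.append([t])
        else:
            succ = []
            for i, bit in enumerate(nxt_bits):
                if bit != env[names[i]]:
                    succ.append(s ^ (1 << (n - 1 - i)))
            successors.append(succ if succ else [s])
    return ExplicitSTG(n=n, semantics=semantics, successors=successors)


def _bottom_scc_states(stg: ExplicitSTG) -> list[np.ndarray]:
    """State arrays of the bottom SCCs, sorted by smallest member."""
    size = 1 << stg.n
    lens = np.fromiter((len(s) for s in stg.successors), dtype=np.int64, count=size)
    rows = np.repeat(np.arange(size, dtype=np.int64), lens)
    cols = np.fromiter(
        (t for succ in stg.successors for t in succ), dtype=np.int64, count=int(lens.sum())
    )
    m = sparse.csr_matrix(
        (np.ones(rows.shape, dtype=np.int8), (rows, cols)), shape=(size, size)
    )
    n_comp, labels = csgraph.connected_components(m, directed=True, connection="strong")
    has_exit = np.zeros(n_comp, dtype=bool)
    cross = labels[rows] != labels[cols]
    has_exit[labels[rows[cross]]] = True
    out = [np.flatnonzero(labels == c) for c in range(n_comp) if not has_exit[c]]
    out.sort(key=lambda arr: int(arr[0]))
    return out


def _order_cycle(states: np.ndarray, stg: ExplicitSTG) -> tuple[int, ...]:
    start = int(states[0])
    cycle = [start]
    cur = stg.successors[start][0]
    while cur != start:
        cycle.append(int(cur))
        cur = stg.successors[cur][0]
    return tuple(cycle)


def oracle_attractors(stg: ExplicitSTG) -> AttractorReport:
    """All attractors of the explicit graph as bottom SCCs, classified."""
    attractors: list[Attractor] = []
    for comp in _bottom_scc_states(stg):
        if stg.semantics == "sync":
            cycle = _order_cycle(comp, stg)
            att = Attractor(states=cycle, semantics="sync", period=len(cycle))
            att.type_tag = classify_sync(att)
        else:
            members = set(int(s) for s in comp)
            deterministic = all(len(stg.successors[s]) == 1 for s in members)
            if len(members) == 1:
                att = Attractor(states=(int(comp[0]),), semantics="async", type_tag="self_loop")
            elif deterministic:
                att = Attractor(
                    states=_order_cycle(comp, stg), semantics="async", type_tag="simple_loop"
                )
            else:
                att = Attractor(
                    states=tuple(sorted(members)), semantics="async", type_tag="asyn_complex"
                )
        attractors.append(att)
    if stg.semantics == "sync":
        attractors.sort(key=lambda a: (a.period, a.smallest))
    else:
        attractors.sort(key=lambda a: a.smallest)
    return AttractorReport(semantics=stg.semantics, n=stg.n, attractors=attractors)


def oracle_sync_attractors(network: BooleanNetwork) -> AttractorReport:
    return oracle_attractors(build_stg(network, "sync"))


def oracle_async_attractors(network: BooleanNetwork) -> AttractorReport:
    return oracle_attractors(build_stg(network, "async"))
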