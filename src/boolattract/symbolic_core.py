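"""Set-level state-space algebra: state sets, transition relations, reachability.

The engine manipulates whole sets of states at once rather than individual
trajectories.  A :class:`StateSet` is the characteristic bit-vector of a
subset of {0,1}^n; a :class:`TransitionRelation` is a sparse Boolean matrix
over (current-state, next-state) pairs.  Image, preimage, relation
composition (which realises the k-step map F^k), fixed-state extraction and
forward/backward reachability are all bulk sparse operations.

The representation is explicit in the number of states, so the practical
width cap is n <= 20 (2^20 states); the enumeration-heavy helpers are meant
for the small sets callers expect to enumerate (attractors).
"""
from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np
from scipy import sparse

from .model_io import BooleanNetwork

__all__ = [
    "STATE_WIDTH_CAP",
    "StateCapExceeded",
    "StateSet",
    "TransitionRelation",
    "build_sync_relation",
    "build_async_relation",
    "forward_reachable",
    "backward_reachable",
    "compose",
    "fixed_states",
]

STATE_WIDTH_CAP = 20  # 2^20 states; beyond this the dense characteristic vector is impractical


class StateCapExceeded(RuntimeError):
    """The network is wider than the explicitly enumerable state space."""


def _check_width(n: int) -> None:
    if n < 1:
        raise ValueError("state width must be >= 1")
    if n > STATE_WIDTH_CAP:
        raise StateCapExceeded(
            f"n={n} exceeds the supported width cap of {STATE_WIDTH_CAP} nodes"
        )


class StateSet:
    """A subset of {0,1}^n held as a characteristic boolean vector."""

    __slots__ = ("n", "mask")

    def __init__(self, n: int, mask: np.ndarray):
        _check_width(n)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (1 << n,):
            raise ValueError(f"mask must have shape ({1 << n},)")
        self.n = n
        self.mask = mask

    # constructors ---------------------------------------------------------
    @classmethod
    def empty(cls, n: int) -> "StateSet":
        return cls(n, np.zeros(1 << n, dtype=bool))

    @classmethod
    def universe(cls, n: int) -> "StateSet":
        return cls(n, np.ones(1 << n, dtype=bool))

    @classmethod
    def from_states(cls, n: int, states: Iterable[int]) -> "StateSet":
        mask = np.zeros(1 << n, dtype=bool)
        for s in states:
            if not 0 <= s < (1 << n):
                raise ValueError(f"state {s} out of range for n={n}")
            mask[s] = True
        return cls(n, mask)

    # algebra --------------------------------------------------------------
    def _check_compatible(self, other: "StateSet") -> None:
        if not isinstance(other, StateSet) or other.n != self.n:
            raise ValueError("state sets have different widths")

    def __or__(self, other: "StateSet") -> "StateSet":
        self._check_compatible(other)
        return StateSet(self.n, self.mask | other.mask)

    def __and__(self, other: "StateSet") -> "StateSet":
        self._check_compatible(other)
        return StateSet(self.n, self.mask & other.mask)

    def __sub__(self, other: "StateSet") -> "StateSet":
        self._check_compatible(other)
        return StateSet(self.n, self.mask & ~other.mask)

    def __invert__(self) -> "StateSet":
        return StateSet(self.n, ~self.mask)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StateSet):
            return NotImplemented
        return self.n == other.n and bool(np.array_equal(self.mask, other.mask))

    __hash__ = None  # mutable-array backed

    def issubset(self, other: "StateSet") -> bool:
        self._check_compatible(other)
        return not bool(np.any(self.mask & ~other.mask))

    # queries --------------------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())

    def __bool__(self) -> bool:
        return not self.is_empty

    def __len__(self) -> int:
        return int(self.mask.sum())

    def __contains__(self, state: int) -> bool:
        return bool(self.mask[state])

    def states(self) -> list[int]:
        """Enumerate members ascending (intended for small sets)."""
        return [int(s) for s in np.flatnonzero(self.mask)]

    def __iter__(self) -> Iterator[int]:
        return iter(self.states())

    def min_state(self) -> int:
        idx = np.flatnonzero(self.mask)
        if idx.size == 0:
            raise ValueError("empty state set has no minimum")
        return int(idx[0])

    def __repr__(self) -> str:
        return f"StateSet(n={self.n}, size={len(self)})"


class TransitionRelation:
    """A relation R over {0,1}^n x {0,1}^n as a sparse boolean matrix."""

    __slots__ = ("n", "matrix")

    def __init__(self, n: int, matrix):
        _check_width(n)
        m = sparse.csr_matrix(matrix, dtype=bool)
        if m.shape != (1 << n, 1 << n):
            raise ValueError(f"relation matrix must be {1 << n} x {1 << n}")
        m.sum_duplicates()
        m.eliminate_zeros()
        m.sort_indices()
        self.n = n
        self.matrix = m

    # constructors ---------------------------------------------------------
    @classmethod
    def identity(cls, n: int) -> "TransitionRelation":
        return cls(n, sparse.identity(1 << n, dtype=bool, format="csr"))

    @classmethod
    def from_edges(cls, n: int, sources, targets) -> "TransitionRelation":
        size = 1 << n
        sources = np.asarray(sources, dtype=np.int64)
        targets = np.asarray(targets, dtype=np.int64)
        data = np.ones(sources.shape, dtype=bool)
        return cls(n, sparse.csr_matrix((data, (sources, targets)), shape=(size, size)))

    @classmethod
    def from_successors(cls, succ: np.ndarray) -> "TransitionRelation":
        size = succ.shape[0]
        n = int(size).bit_length() - 1
        return cls.from_edges(n, np.arange(size, dtype=np.int64), succ)

    # relational algebra ---------------------------------------------------
    def _check_compatible(self, other: "TransitionRelation") -> None:
        if other.n != self.n:
            raise ValueError("relations have different widths")

    def image(self, S: StateSet) -> StateSet:
        """{t : exists s in S with (s, t) in R}."""
        if S.n != self.n:
            raise ValueError("state set width does not match relation")
        sub = self.matrix[S.mask]
        mask = np.zeros(1 << self.n, dtype=bool)
        mask[sub.indices] = True
        return StateSet(self.n, mask)

    def preimage(self, S: StateSet) -> StateSet:
        """{s : exists t in S with (s, t) in R}."""
        if S.n != self.n:
            raise ValueError("state set width does not match relation")
        sub = self.matrix[:, S.mask].tocsr()
        mask = np.diff(sub.indptr) > 0
        return StateSet(self.n, mask)

    def compose(self, other: "TransitionRelation") -> "TransitionRelation":
        """Sequential composition: (s, u) iff exists t with (s,t) in self, (t,u) in other."""
        self._check_compatible(other)
        prod = self.matrix.astype(np.int64) @ other.matrix.astype(np.int64)
        return TransitionRelation(self.n, prod.astype(bool))

    def fixed_states(self) -> StateSet:
        """States with a self-transition: {s : (s, s) in R}."""
        return StateSet(self.n, self.matrix.diagonal().astype(bool))

    def restrict(self, S: StateSet) -> "TransitionRelation":
        """Edges with both endpoints inside S."""
        if S.n != self.n:
            raise ValueError("state set width does not match relation")
        d = sparse.diags(S.mask.astype(np.int8))
        kept = d @ self.matrix.astype(np.int8) @ d
        return TransitionRelation(self.n, kept.astype(bool))

    # queries --------------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TransitionRelation):
            return NotImplemented
        a, b = self.matrix, other.matrix
        return (
            self.n == other.n
            and a.nnz == b.nnz
            and bool(np.array_equal(a.indptr, b.indptr))
            and bool(np.array_equal(a.indices, b.indices))
        )

    __hash__ = None

    def canonical_key(self) -> bytes:
        """Exact byte key of the canonical CSR structure (for seen-tables)."""
        return self.matrix.indptr.tobytes() + self.matrix.indices.tobytes()

    def successors(self, state: int) -> list[int]:
        m = self.matrix
        return [int(t) for t in m.indices[m.indptr[state] : m.indptr[state + 1]]]

    def successor(self, state: int) -> int:
        succ = self.successors(state)
        if len(succ) != 1:
            raise ValueError(
                f"state {state} has {len(succ)} successors; relation is not functional there"
            )
        return succ[0]

    def is_total_function(self) -> bool:
        return bool(np.all(np.diff(self.matrix.indptr) == 1))

    @property
    def nnz(self) -> int:
        return int(self.matrix.nnz)

    def __repr__(self) -> str:
        return f"TransitionRelation(n={self.n}, edges={self.nnz})"


# ---------------------------------------------------------------------------
# building relations from networks


def _state_bit_columns(network: BooleanNetwork) -> list[np.ndarray]:
    """Per-node boolean column over all 2^n states (node 0 = leftmost bit)."""
    n = network.n
    size = 1 << n
    idx = np.arange(size, dtype=np.int64)
    return [((idx >> (n - 1 - i)) & 1).astype(bool) for i in range(n)]


def _next_bit_columns(network: BooleanNetwork) -> list[np.ndarray]:
    """Vectorised evaluation of every update rule over all states at once."""
    n = network.n
    size = 1 << n
    cols = _state_bit_columns(network)
    env = dict(zip(network.node_names, cols))
    out = []
    for expr in network.update_exprs:
        val = expr.evaluate(env)
        out.append(np.broadcast_to(np.asarray(val, dtype=bool), (size,)))
    return out


def build_sync_relation(network: BooleanNetwork) -> TransitionRelation:
    """The synchronous map as a relation: every node updates simultaneously.

    The result is a total function — each state has exactly one successor.
    """
    _check_width(network.n)
    n = network.n
    nxt = _next_bit_columns(network)
    succ = np.zeros(1 << n, dtype=np.int64)
    for i, col in enumerate(nxt):
        succ |= col.astype(np.int64) << (n - 1 - i)
    return TransitionRelation.from_successors(succ)


def build_async_relation(network: BooleanNetwork) -> TransitionRelation:
    """The general asynchronous relation: one node updates per step.

    Emits an edge s -> s^bit(i) for every node i whose update would change
    in state s; no-op updates produce no edge, except that global fixed
    points keep an explicit self-loop (so single-state attractors are
    literal loops in the graph).
    """
    _check_width(network.n)
    n = network.n
    size = 1 << n
    cur = _state_bit_columns(network)
    nxt = _next_bit_columns(network)
    sources: list[np.ndarray] = []
    targets: list[np.ndarray] = []
    stable = np.ones(size, dtype=bool)
    idx = np.arange(size, dtype=np.int64)
    for i in range(n):
        diff = nxt[i] != cur[i]
        stable &= ~diff
        src = idx[diff]
        sources.append(src)
        targets.append(src ^ (1 << (n - 1 - i)))
    fixed = idx[stable]
    sources.append(fixed)
    targets.append(fixed)
    return TransitionRelation.from_edges(n, np.concatenate(sources), np.concatenate(targets))


# ---------------------------------------------------------------------------
# reachability and iteration


def forward_reachable(seed: StateSet, R: TransitionRelation) -> StateSet:
    """All states reachable from ``seed`` (the seed itself included).

    Least fixpoint of S <- S | image(S); the frontier shrinks to empty in at
    most 2^n rounds because the reached set grows monotonically.
    """
    reached = seed
    frontier = seed
    while frontier:
        frontier = R.image(frontier) - reached
        reached = reached | frontier
    return reached


def backward_reachable(seed: StateSet, R: TransitionRelation) -> StateSet:
    """All states that can reach ``seed`` (the seed itself included)."""
    reached = seed
    frontier = seed
    while frontier:
        frontier = R.preimage(frontier) - reached
        reached = reached | frontier
    return reached


def compose(R1: TransitionRelation, R2: TransitionRelation) -> TransitionRelation:
    return R1.compose(R2)


def fixed_states(Rk: TransitionRelation) -> StateSet:
    """A_k: the states that return to themselves under the k-step relation."""
    return Rk.fixed_states()
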