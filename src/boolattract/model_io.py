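"""Boolean network models: parsing, translation, generation, reporting.

A :class:`BooleanNetwork` is an ordered list of node names with one Boolean
update expression per node.  Node order is load-bearing: the i-th declared
node owns bit position i of every state, with the first declared node
printed leftmost.  A state is held as a plain integer whose binary string
(width n, leading zeros) reads off the node values in declaration order.

The module also understands signed interaction graphs (activator/inhibitor
edge lists) together with the translation schemes that turn them into
update rules, generates seeded random N-K networks for testing, and
serialises attractor reports to a stable JSON layout.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .expr import (
    And,
    BoolExpr,
    Const,
    ExprSyntaxError,
    Not,
    Or,
    Var,
    expr_from_truth_table,
    parse_expr,
)

__all__ = [
    "ParseError",
    "ValidationError",
    "BooleanNetwork",
    "SignedInteractionGraph",
    "Attractor",
    "AttractorReport",
    "TYPE_TAGS",
    "SCHEMES",
    "state_to_string",
    "string_to_state",
    "hamming",
    "parse_rules",
    "render_rules",
    "parse_interaction_graph",
    "translate",
    "random_network",
    "write_report",
    "report_to_dict",
    "shared_counts",
]


class ParseError(ValueError):
    """An input file violated the rule or edge-list dialect."""


class ValidationError(ValueError):
    """A constructed object violated a structural invariant."""


_IDENT_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*$")

TYPE_TAGS = ("self_loop", "simple_loop", "syn_complex", "asyn_complex")
SCHEMES = ("classical", "inhibitor_priority", "combined")


def state_to_string(state: int, n: int) -> str:
    """Render a state as its binary string, first declared node leftmost."""
    return format(state, f"0{n}b")


def string_to_state(bits: str) -> int:
    return int(bits, 2)


def hamming(a: int, b: int) -> int:
    return (a ^ b).bit_count()


@dataclass(frozen=True)
class BooleanNetwork:
    """An ordered Boolean network: node names plus one update rule each."""

    node_names: tuple[str, ...]
    update_exprs: tuple[BoolExpr, ...]

    def __post_init__(self):
        if len(self.node_names) < 1:
            raise ValidationError("a network needs at least one node")
        if len(self.node_names) != len(self.update_exprs):
            raise ValidationError("one update expression required per node")
        seen = set()
        for name in self.node_names:
            if name in seen:
                raise ValidationError(f"duplicate node declaration: {name!r}")
            seen.add(name)
        for name, expr in zip(self.node_names, self.update_exprs):
            for var in expr.variables():
                if var not in seen:
                    raise ValidationError(
                        f"update rule for {name!r} references undeclared identifier {var!r}"
                    )

    @property
    def n(self) -> int:
        return len(self.node_names)

    def index(self, name: str) -> int:
        return self.node_names.index(name)

    def render(self) -> str:
        return render_rules(self)


@dataclass(frozen=True)
class SignedInteractionGraph:
    """A signed regulatory graph: activator / inhibitor edges."""

    node_names: tuple[str, ...]
    edges: tuple[tuple[str, str, str], ...]  # (source, target, "activate"|"inhibit")

    def __post_init__(self):
        declared = set(self.node_names)
        if len(declared) != len(self.node_names):
            raise ValidationError("duplicate node declaration in interaction graph")
        seen = set()
        for src, tgt, sign in self.edges:
            if sign not in ("activate", "inhibit"):
                raise ValidationError(f"unknown edge sign {sign!r}")
            if src not in declared or tgt not in declared:
                raise ValidationError(f"edge ({src!r}, {tgt!r}) has an undeclared endpoint")
            if (src, tgt, sign) in seen:
                raise ValidationError(f"duplicate edge ({src!r}, {tgt!r}, {sign!r})")
            seen.add((src, tgt, sign))

    def regulators(self, target: str) -> tuple[list[str], list[str]]:
        """Return (activators, inhibitors) of ``target`` in edge order."""
        acts = [s for s, t, sign in self.edges if t == target and sign == "activate"]
        inhs = [s for s, t, sign in self.edges if t == target and sign == "inhibit"]
        return acts, inhs


@dataclass
class Attractor:
    """A closed, inescapable set of states under one update semantics.

    For synchronous attractors ``states`` follows the cycle order starting
    from the smallest member, and ``period`` equals the cycle length.  For
    asynchronous attractors ``states`` is sorted ascending and ``period`` is
    ``None`` (a bottom SCC has no single period).
    """

    states: tuple[int, ...]
    semantics: str  # "sync" | "async"
    type_tag: str | None = None
    period: int | None = None

    @property
    def size(self) -> int:
        return len(self.states)

    @property
    def smallest(self) -> int:
        return min(self.states)

    @property
    def state_set(self) -> frozenset[int]:
        return frozenset(self.states)


@dataclass
class AttractorReport:
    """All attractors of one network under one semantics."""

    semantics: str
    n: int
    attractors: list[Attractor] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out = {tag: 0 for tag in TYPE_TAGS}
        for att in self.attractors:
            if att.type_tag not in out:
                raise ValidationError(f"attractor with invalid type tag {att.type_tag!r}")
            out[att.type_tag] += 1
        return out

    def validate_disjoint(self) -> None:
        seen: set[int] = set()
        for att in self.attractors:
            overlap = seen & att.state_set
            if overlap:
                s = state_to_string(min(overlap), self.n)
                raise ValidationError(f"attractors share state {s}")
            seen |= att.state_set

    def signature(self) -> frozenset:
        """Order-free canonical form for exact report comparison."""
        return frozenset(
            (att.type_tag, att.period, att.state_set) for att in self.attractors
        )


# ---------------------------------------------------------------------------
# rule files


def parse_rules(text: str) -> BooleanNetwork:
    """Parse a BoolNet-style rule file.

    Layout: a header line ``targets, factors`` followed by one
    ``node, expression`` line per node.  ``#`` starts a comment, blank lines
    are ignored, and both LF and CRLF line endings are accepted.
    """
    lines = text.lstrip("﻿").splitlines()
    entries: list[tuple[int, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            entries.append((lineno, line))
    if not entries:
        raise ParseError("empty rule file")
    header_no, header = entries[0]
    if not re.fullmatch(r"targets\s*,\s*factors", header, flags=re.IGNORECASE):
        raise ParseError(
            f"line {header_no}: expected header 'targets, factors', got {header!r}"
        )
    if len(entries) == 1:
        raise ParseError("rule file declares no nodes")

    names: list[str] = []
    exprs: list[BoolExpr] = []
    for lineno, line in entries[1:]:
        if "," not in line:
            raise ParseError(f"line {lineno}: expected 'node, expression'")
        name, expr_text = line.split(",", 1)
        name = name.strip()
        if not _IDENT_RE.match(name):
            raise ParseError(f"line {lineno}: invalid node name {name!r}")
        if name in names:
            raise ParseError(f"line {lineno}: duplicate node declaration {name!r}")
        try:
            expr = parse_expr(expr_text)
        except ExprSyntaxError as err:
            raise ParseError(f"line {lineno}: {err}") from err
        names.append(name)
        exprs.append(expr)

    declared = set(names)
    for name, expr in zip(names, exprs):
        for var in expr.variables():
            if var not in declared:
                raise ParseError(
                    f"update rule for {name!r} references undeclared identifier {var!r}"
                )
    return BooleanNetwork(tuple(names), tuple(exprs))


def render_rules(network: BooleanNetwork) -> str:
    lines = ["targets, factors"]
    for name, expr in zip(network.node_names, network.update_exprs):
        lines.append(f"{name}, {expr}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# signed interaction graphs

_EDGE_RE = re.compile(r"^\s*([A-Za-z_][A-Za-z0-9_.]*)\s*(->|-\|)\s*([A-Za-z_][A-Za-z0-9_.]*)\s*$")
_NODE_RE = re.compile(r"^\s*node\s+([A-Za-z_][A-Za-z0-9_.]*)\s*$")


def parse_interaction_graph(text: str) -> SignedInteractionGraph:
    """Parse an activator/inhibitor edge list.

    One edge per line: ``A -> B`` (activation) or ``A -| B`` (inhibition).
    Nodes are collected in first-appearance order; a line ``node X``
    declares a node without edges.  ``#`` starts a comment.
    """
    names: list[str] = []
    edges: list[tuple[str, str, str]] = []

    def declare(name: str) -> None:
        if name not in names:
            names.append(name)

    for lineno, raw in enumerate(text.lstrip("﻿").splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        node_m = _NODE_RE.match(line)
        if node_m:
            declare(node_m.group(1))
            continue
        edge_m = _EDGE_RE.match(line)
        if not edge_m:
            raise ParseError(f"line {lineno}: malformed edge line {line!r}")
        src, op, tgt = edge_m.groups()
        sign = "activate" if op == "->" else "inhibit"
        if (src, tgt, sign) in edges:
            raise ParseError(f"line {lineno}: duplicate edge {line!r}")
        declare(src)
        declare(tgt)
        edges.append((src, tgt, sign))
    if not names:
        raise ParseError("empty interaction graph")
    return SignedInteractionGraph(tuple(names), tuple(edges))


def translate(
    graph: SignedInteractionGraph,
    scheme: str = "classical",
    per_node: Mapping[str, str] | None = None,
) -> BooleanNetwork:
    """Build update rules from a signed graph under a translation scheme.

    For node i with activator set A_i and inhibitor set I_i:

    * ``classical``: f_i = (OR of A_i) AND NOT (OR of I_i); with no
      activators the activation term defaults to x_i (value held), with no
      inhibitors the inhibition term vanishes.
    * ``inhibitor_priority``: the inhibitors-dominate form
      f_i = NOT (OR of I_i) AND (OR of A_i), same defaults.
    * ``combined``: per-node choice between the two via ``per_node``
      (mapping node name -> scheme), defaulting to classical.

    A node with no regulators at all holds its value: f_i = x_i.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    per_node = dict(per_node or {})
    if scheme != "combined" and per_node:
        raise ValueError("per_node overrides are only valid with scheme='combined'")
    for name, sch in per_node.items():
        if name not in graph.node_names:
            raise ValidationError(f"per_node override for undeclared node {name!r}")
        if sch not in ("classical", "inhibitor_priority"):
            raise ValueError(f"invalid per-node scheme {sch!r}")

    exprs: list[BoolExpr] = []
    for name in graph.node_names:
        acts, inhs = graph.regulators(name)
        act_term: BoolExpr
        if acts:
            vars_ = tuple(Var(a) for a in acts)
            act_term = vars_[0] if len(vars_) == 1 else Or(vars_)
        else:
            act_term = Var(name)  # no activators: value held
        if not inhs:
            exprs.append(act_term)
            continue
        ivars = tuple(Var(i) for i in inhs)
        inh_term: BoolExpr = ivars[0] if len(ivars) == 1 else Or(ivars)
        node_scheme = per_node.get(name, "classical") if scheme == "combined" else scheme
        if node_scheme == "inhibitor_priority":
            exprs.append(And((Not(inh_term), act_term)))
        else:
            exprs.append(And((act_term, Not(inh_term))))
    return BooleanNetwork(graph.node_names, tuple(exprs))


# ---------------------------------------------------------------------------
# random N-K networks


def random_network(n: int, k: int, seed: int) -> BooleanNetwork:
    """Generate a seeded random N-K (Kauffman) network.

    Each node receives ``k`` distinct regulators drawn uniformly and an
    update function drawn as a uniform random truth table over them,
    redrawn while constant so that the rendered expression references all
    ``k`` regulators.  Identical ``(n, k, seed)`` yields identical networks.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 1 or k > n:
        raise ValueError(f"in-degree k={k} must satisfy 1 <= k <= n={n}")
    rng = np.random.default_rng(seed)
    names = tuple(f"x{i + 1}" for i in range(n))
    exprs: list[BoolExpr] = []
    for _ in range(n):
        regs = np.sort(rng.choice(n, size=k, replace=False))
        while True:
            table = rng.integers(0, 2, size=1 << k).astype(bool)
            if table.any() and not table.all():
                break
        exprs.append(expr_from_truth_table([names[r] for r in regs], table))
    return BooleanNetwork(names, tuple(exprs))


# ---------------------------------------------------------------------------
# reports

_TAG_ORDER = {tag: i for i, tag in enumerate(TYPE_TAGS)}


def _attractor_to_dict(att: Attractor, n: int) -> dict:
    states = [state_to_string(s, n) for s in att.states]
    entry: dict = {"type": att.type_tag, "size": att.size, "states": states}
    if att.period is not None:
        entry["period"] = att.period
    return entry


def report_to_dict(
    report: AttractorReport, network: BooleanNetwork, model_name: str = "model"
) -> dict:
    """Build the JSON-ready report object (sorted, validated)."""
    if report.n != network.n:
        raise ValidationError("report width does not match network")
    report.validate_disjoint()
    atts = sorted(
        report.attractors,
        key=lambda a: (_TAG_ORDER[a.type_tag], state_to_string(a.smallest, report.n)),
    )
    return {
        "model": model_name,
        "n_nodes": network.n,
        "node_order": list(network.node_names),
        "semantics": report.semantics,
        "attractors": [_attractor_to_dict(a, report.n) for a in atts],
        "counts": report.counts,
    }


def write_report(
    report: AttractorReport, network: BooleanNetwork, model_name: str = "model"
) -> str:
    """Serialise an attractor report as byte-stable JSON text."""
    return json.dumps(report_to_dict(report, network, model_name), indent=2) + "\n"


def shared_counts(sync_report: AttractorReport, async_report: AttractorReport) -> dict[str, int]:
    """Combined per-type counts across both semantics.

    Self loops and simple loops are shared between the semantics and counted
    once; syn-complex loops are counted from the synchronous report and
    asyn-complex loops from the asynchronous one.
    """
    sc = sync_report.counts
    ac = async_report.counts
    return {
        "self_loop": ac["self_loop"],
        "simple_loop": ac["simple_loop"],
        "syn_complex": sc["syn_complex"],
        "asyn_complex": ac["asyn_complex"],
    }
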