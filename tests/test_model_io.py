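"""Rule/graph parsing, translation schemes, generation and report output."""
import json

import pytest

from boolattract import (
    Attractor,
    AttractorReport,
    ParseError,
    ValidationError,
    parse_interaction_graph,
    parse_rules,
    random_network,
    render_rules,
    translate,
    write_report,
)
from boolattract.oracle import build_stg

from conftest import random_suite


class TestParseRules:
    def test_minimal_swap_network(self):
        net = parse_rules("targets, factors\nx1, x2\nx2, x1")
        assert net.node_names == ("x1", "x2")
        assert str(net.update_exprs[0]) == "x2"
        assert str(net.update_exprs[1]) == "x1"

    def test_one_node_negation(self):
        net = parse_rules("targets, factors\na, !a")
        assert net.n == 1
        assert str(net.update_exprs[0]) == "!a"

    def test_crlf_comments_and_whitespace(self):
        text = "# model\r\ntargets , factors\r\n x1 ,  x2 & ( x1 | !x2 ) # rule\r\nx2, 1\r\n\r\n"
        net = parse_rules(text)
        assert net.node_names == ("x1", "x2")

    @pytest.mark.parametrize(
        "text, fragment",
        [
            ("targets, factors\nx1, x9", "undeclared identifier 'x9'"),
            ("targets, factors\nx1, x1\nx1, !x1", "duplicate node"),
            ("", "empty rule file"),
            ("targets, factors\n", "declares no nodes"),
            ("x1, x2\nx2, x1", "targets, factors"),
            ("targets, factors\nx1, x2 &", "expected an operand"),
            ("targets, factors\nx1; x2", "node, expression"),
        ],
    )
    def test_parse_errors(self, text, fragment):
        with pytest.raises(ParseError) as exc:
            parse_rules(text)
        assert fragment in str(exc.value)

    def test_roundtrip_preserves_truth_tables(self):
        # render -> reparse must reproduce the update map exactly
        for seed, net in random_suite(100, max_n=8, max_k=3):
            reparsed = parse_rules(render_rules(net))
            assert reparsed.node_names == net.node_names
            orig = build_stg(net, "sync").successors
            back = build_stg(reparsed, "sync").successors
            assert orig == back, f"seed {seed}"


class TestInteractionGraph:
    def test_activation_and_inhibition(self):
        g = parse_interaction_graph("A -> B\nB -| A")
        assert g.node_names == ("A", "B")
        assert set(g.edges) == {("A", "B", "activate"), ("B", "A", "inhibit")}

    def test_self_activation_accepted(self):
        g = parse_interaction_graph("A -> A")
        assert g.edges == (("A", "A", "activate"),)

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(ParseError, match="line 1"):
            parse_interaction_graph("A => B")

    def test_explicit_node_declaration(self):
        g = parse_interaction_graph("node C\nA -> B")
        assert g.node_names == ("C", "A", "B")

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ParseError, match="duplicate"):
            parse_interaction_graph("A -> B\nA -> B")


class TestTranslate:
    def test_classical_single_activator(self):
        g = parse_interaction_graph("A -> B")
        net = translate(g, "classical")
        rules = dict(zip(net.node_names, map(str, net.update_exprs)))
        assert rules == {"A": "A", "B": "A"}  # A has no regulators: held

    def test_inhibitor_priority_formula(self):
        g = parse_interaction_graph("A -> B\nC -| B")
        net = translate(g, "inhibitor_priority")
        rules = dict(zip(net.node_names, map(str, net.update_exprs)))
        assert rules["B"] == "!C & A"

    def test_classical_formula_with_inhibitor(self):
        g = parse_interaction_graph("A -> B\nC -| B")
        net = translate(g, "classical")
        rules = dict(zip(net.node_names, map(str, net.update_exprs)))
        assert rules["B"] == "A & !C"

    def test_empty_edge_set_holds_every_node(self):
        g = parse_interaction_graph("node A\nnode B")
        for scheme in ("classical", "inhibitor_priority", "combined"):
            net = translate(g, scheme)
            assert [str(e) for e in net.update_exprs] == ["A", "B"]

    def test_combined_per_node_choice(self):
        g = parse_interaction_graph("A -> B\nC -| B\nA -> C\nB -| C")
        net = translate(g, "combined", per_node={"C": "inhibitor_priority"})
        rules = dict(zip(net.node_names, map(str, net.update_exprs)))
        assert rules["B"] == "A & !C"  # default classical
        assert rules["C"] == "!B & A"

    def test_translate_is_scheme_local(self):
        # changing an edge incident only to B changes only f_B
        g1 = parse_interaction_graph("A -> B\nB -> C\nC -| A")
        g2 = parse_interaction_graph("A -> B\nA -| B\nB -> C\nC -| A")
        n1 = translate(g1, "classical")
        n2 = translate(g2, "classical")
        for name in ("A", "C"):
            assert str(n1.update_exprs[n1.index(name)]) == str(n2.update_exprs[n2.index(name)])
        assert str(n1.update_exprs[n1.index("B")]) != str(n2.update_exprs[n2.index("B")])


class TestRandomNetwork:
    def test_fixed_seed_reproducible(self):
        a = random_network(3, 1, 7)
        b = random_network(3, 1, 7)
        assert render_rules(a) == render_rules(b)

    def test_every_node_references_k_distinct_regulators(self):
        net = random_network(5, 2, 1)
        for expr in net.update_exprs:
            assert len(set(expr.variables())) == 2

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            random_network(2, 3, 0)

    def test_distinct_seeds_differ(self):
        assert render_rules(random_network(6, 2, 0)) != render_rules(random_network(6, 2, 1))


class TestWriteReport:
    def test_singleton_self_loop_counts(self, swap_network):
        report = AttractorReport(
            semantics="sync",
            n=2,
            attractors=[Attractor(states=(0,), semantics="sync", type_tag="self_loop", period=1)],
        )
        obj = json.loads(write_report(report, swap_network, "demo"))
        assert obj["counts"] == {
            "self_loop": 1,
            "simple_loop": 0,
            "syn_complex": 0,
            "asyn_complex": 0,
        }
        assert obj["attractors"][0]["states"] == ["00"]
        assert obj["node_order"] == ["x1", "x2"]

    def test_empty_report_is_valid_json(self, swap_network):
        report = AttractorReport(semantics="async", n=2, attractors=[])
        obj = json.loads(write_report(report, swap_network, "demo"))
        assert obj["attractors"] == []
        assert set(obj["counts"].values()) == {0}

    def test_overlapping_attractors_refused(self, swap_network):
        report = AttractorReport(
            semantics="sync",
            n=2,
            attractors=[
                Attractor(states=(0,), semantics="sync", type_tag="self_loop", period=1),
                Attractor(states=(0, 3), semantics="sync", type_tag="syn_complex", period=2),
            ],
        )
        with pytest.raises(ValidationError, match="share state"):
            write_report(report, swap_network, "demo")

    def test_output_is_byte_stable(self, swap_network):
        report = AttractorReport(
            semantics="sync",
            n=2,
            attractors=[
                Attractor(states=(3,), semantics="sync", type_tag="self_loop", period=1),
                Attractor(states=(0,), semantics="sync", type_tag="self_loop", period=1),
            ],
        )
        assert write_report(report, swap_network) == write_report(report, swap_network)
        obj = json.loads(write_report(report, swap_network))
        # sorted by (type, smallest bitstring)
        assert [a["states"][0] for a in obj["attractors"]] == ["00", "11"]
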