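from pathlib import Path

import pytest

from boolattract import parse_rules, random_network

EXAMPLES = Path(__file__).resolve().parent.parent / "examples"

SWAP_RULES = "targets, factors\nx1, x2\nx2, x1\n"
NEGATION_CYCLE_RULES = "targets, factors\nx1, !x2\nx2, x1\n"
IDENTITY3_RULES = "targets, factors\nx1, x1\nx2, x2\nx3, x3\n"


@pytest.fixture
def swap_network():
    """Two-node swap: sync attractors {00}, {11} and the 2-cycle {01,10}."""
    return parse_rules(SWAP_RULES)


@pytest.fixture
def negation_cycle_network():
    """f1 = !x2, f2 = x1: a single 4-state Hamming-1 cycle."""
    return parse_rules(NEGATION_CYCLE_RULES)


@pytest.fixture
def identity3_network():
    """All nodes held: every one of the 8 states is a fixed point."""
    return parse_rules(IDENTITY3_RULES)


@pytest.fixture
def mammalian_network():
    """Ten-node mammalian cell-cycle logical model (Faure et al. 2006)."""
    return parse_rules((EXAMPLES / "mammalian_cell_cycle.bnet").read_text())


def random_suite(count, max_n=10, max_k=3, n_offset=2):
    """Deterministic family of small random N-K networks for cross-checks."""
    nets = []
    for seed in range(count):
        n = n_offset + seed % (max_n - n_offset + 1)
        k = min(1 + seed % max_k, n)
        nets.append((seed, random_network(n, k, seed)))
    return nets
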