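"""Shared fixtures and the exhaustive-enumeration oracle.

The oracle computes the exact mean inter-set edge count over *all* pairs of
independent uniform subsets by enumeration; it is deliberately naive (pure
Python loops over itertools.combinations) and independent of the package's
vectorized path, so it can adjudicate both the closed-form expectation and
the Monte-Carlo null.
"""

from __future__ import annotations

import itertools
from math import comb

import pytest

from crossnet import GeneSet, Interactome


def exhaustive_cross_mean(interactome: Interactome, a: int, b: int) -> float:
    """Exact E[#edges spanning (A, B)] over independent uniform subsets."""
    nodes = sorted(interactome.nodes)
    edges = list(interactome.edges)
    n = len(nodes)
    total = 0
    for set_a in itertools.combinations(nodes, a):
        sa = set(set_a)
        for set_b in itertools.combinations(nodes, b):
            sb = set(set_b)
            total += sum(
                1
                for u, v in edges
                if (u in sa and v in sb) or (v in sa and u in sb)
            )
    return total / (comb(n, a) * comb(n, b))


def brute_force_cross_count(interactome, members_a, members_b) -> int:
    """Reference inter-set edge count by direct edge iteration."""
    sa, sb = set(members_a), set(members_b)
    return sum(
        1
        for u, v in interactome.edges
        if (u in sa and v in sb) or (v in sa and u in sb)
    )


@pytest.fixture
def path4() -> Interactome:
    """Path graph A-B-C-D."""
    return Interactome.from_edges([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture
def triangle() -> Interactome:
    return Interactome.from_edges([("X", "Y"), ("Y", "Z"), ("X", "Z")])


@pytest.fixture
def coag_like_sets() -> tuple[GeneSet, GeneSet]:
    """Two seed sets sharing CD40 and PLAU, as in pathway/GWAS overlap."""
    a = GeneSet.from_symbols("pathway", ["F2", "F10", "PLAU", "CD40"])
    b = GeneSet.from_symbols("gwas", ["HLA-DRB1", "CD40", "PLAU"])
    return a, b
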