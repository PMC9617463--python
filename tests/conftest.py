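"""Shared fixtures: tiny hand-checkable scaffold graphs and helpers."""

import itertools
import random

import pytest

from scaffgraph.graph import Parameters, PartialSolution, ScaffoldGraph, decompose_solution


@pytest.fixture
def k2():
    """Minimal scaffold graph: one contig, no link edges."""
    return ScaffoldGraph([("a", "b")])


@pytest.fixture
def square4():
    """4-cycle: two matching edges, two weighted link edges."""
    return ScaffoldGraph([("a", "b"), ("c", "d")], [("b", "c", 1), ("d", "a", 2)])


@pytest.fixture
def bridged_k4s():
    """Two K4 cliques (two contigs each) joined by one bridge d-e."""
    g = ScaffoldGraph([("a", "b"), ("c", "d"), ("e", "f"), ("g", "h")])
    for quad in (("a", "b", "c", "d"), ("e", "f", "g", "h")):
        for x, y in itertools.combinations(quad, 2):
            if not g.has_edge(x, y):
                g.add_link_edge(x, y, 1)
    g.add_link_edge("d", "e", 5)
    return g


def random_partial_solution(g: ScaffoldGraph, seed: int,
                            accept_prob: float = 0.35) -> PartialSolution:
    """A random valid partial solution (every component stays a path/cycle)."""
    rng = random.Random(seed)
    edges = sorted(g.weight, key=sorted)
    rng.shuffle(edges)
    chosen, saturated = set(), set()
    for e in edges:
        u, v = sorted(e)
        if u in saturated or v in saturated or rng.random() >= accept_prob:
            continue
        cand = frozenset(chosen | {e})
        try:
            decompose_solution(g, PartialSolution(cand))
        except ValueError:
            continue
        chosen.add(e)
        saturated.update((u, v))
    return PartialSolution(frozenset(chosen))


def all_parameter_pairs(n_matching: int):
    """Every (sigma_p, sigma_c) within the necessary bound."""
    for sc in range(n_matching // 2 + 1):
        for sp in range(n_matching - 2 * sc + 1):
            yield Parameters(sp, sc)
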