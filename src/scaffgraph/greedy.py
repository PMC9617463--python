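"""Greedy maximum-weight scaffolding guarded by a feasibility function.

Link edges are scanned once in non-increasing weight order; an edge is
accepted iff both endpoints are still free, accepting it keeps every
component of ``S ∪ M*`` a path or a cycle, and the feasibility function
confirms that the enlarged partial solution still extends to exactly
``sigma_p`` alternating paths and ``sigma_c`` alternating cycles.  On
acceptance every other link edge incident to either endpoint is discarded
(the update step).  Because feasibility is downward monotone, the scan
terminates with a complete valid solution whenever the empty solution is
feasible — no repair phase exists or is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

from .graph import (Edge, Parameters, PartialSolution, ScaffoldGraph,
                    SolutionDecomposition, decompose_solution, edge)

__all__ = ["GreedyTrace", "InfeasibleInstanceError", "greedy_scaffold", "run_comparison"]

FeasibilityFn = Callable[[ScaffoldGraph, PartialSolution, Parameters], bool]
TieBreak = Callable[[Edge], Tuple]

ACCEPTED = "accepted"
REMOVED = "removed_incident"
REJECTED = "rejected_infeasible"


class InfeasibleInstanceError(ValueError):
    """The empty partial solution is already infeasible: no solution exists."""


def default_tie_break(e: Edge) -> Tuple[str, str]:
    a, b = sorted(e)
    return (a, b)


@dataclass
class GreedyTrace:
    """Ordered record of the scan: (edge, outcome) per considered edge,
    the final solution and the removed-edge set ``R``."""

    considered: List[Tuple[Edge, str]] = field(default_factory=list)
    solution: PartialSolution = PartialSolution()
    removed: Set[Edge] = field(default_factory=set)


def greedy_scaffold(g: ScaffoldGraph, p: Parameters, feasibility: FeasibilityFn,
                    tie_break: Optional[TieBreak] = None
                    ) -> Tuple[SolutionDecomposition, GreedyTrace]:
    """Run the greedy scan; returns the decomposed solution and its trace.

    ``feasibility`` must accept ``(g, partial_solution, parameters)``.  Ties
    among equal-weight edges are broken by ``tie_break`` (default:
    lexicographic on the sorted endpoint pair, ascending).
    """
    tb = tie_break or default_tie_break
    if not feasibility(g, PartialSolution(), p):
        raise InfeasibleInstanceError(
            f"no solution with sigma_p={p.sigma_p}, sigma_c={p.sigma_c} exists")
    order = sorted(g.weight, key=lambda e: (-g.weight[e], tb(e)))
    trace = GreedyTrace()
    chosen: Set[Edge] = set()
    # free path ends: other_end[x] = opposite free end of x's component
    other_end: Dict[str, str] = {}
    for me in g.matching_edges:
        u, v = sorted(me)
        other_end[u] = v
        other_end[v] = u
    for e in order:
        if e in trace.removed:
            trace.considered.append((e, REMOVED))
            continue
        u, v = sorted(e)
        assert u in other_end and v in other_end, "edge endpoints must be free here"
        candidate = PartialSolution(frozenset(chosen | {e}))
        if not feasibility(g, candidate, p):
            trace.considered.append((e, REJECTED))
            continue
        # accept: update components and discard incident link edges
        chosen.add(e)
        trace.considered.append((e, ACCEPTED))
        au, bv = other_end.pop(u), other_end.pop(v)
        if au == v:  # closed a cycle
            pass
        else:
            other_end[au] = bv
            other_end[bv] = au
        for x in (u, v):
            for y in g.link_neighbors(x):
                ee = edge(x, y)
                if ee not in chosen:
                    trace.removed.add(ee)
    trace.solution = PartialSolution(frozenset(chosen))
    decomposition = decompose_solution(g, trace.solution, cover_all=True)
    if (decomposition.sigma_p_of, decomposition.sigma_c_of) != (p.sigma_p, p.sigma_c):
        raise RuntimeError(
            "greedy terminated with wrong counts "
            f"({decomposition.sigma_p_of} paths, {decomposition.sigma_c_of} cycles); "
            "the feasibility function is not downward monotone")
    return decomposition, trace


def run_comparison(instances: Sequence, classes: Sequence[str] = ("complete", "cluster"),
                   with_optimum: bool = True, optimum_cap: int = 10) -> List[Dict]:
    """Score the greedy under several feasibility classes on each instance.

    ``instances`` are :class:`~scaffgraph.instances.InstanceBundle` objects.
    For class ``complete``/``cluster`` the graph is first completed into the
    class with zero-weight edges; class ``oracle`` runs on the graph as-is
    with the exhaustive feasibility.  The exact optimum (computed on the
    original graph) is attached when the instance is small enough.
    """
    from .cluster import build_cluster_structure, complete_to_class
    from .feasibility import (cluster_feasibility, complete_feasibility,
                              oracle_feasibility)
    from .oracle import brute_force_optimum

    rows: List[Dict] = []
    for bundle in instances:
        g, p = bundle.graph, bundle.params
        row: Dict = {"instance": bundle.name(), "n_matching": g.n_matching()}
        if with_optimum and g.n_matching() <= optimum_cap:
            res = brute_force_optimum(g, p, cap=optimum_cap)
            row["optimum"] = res.best_weight if res.feasible else None
        for cls in classes:
            if cls == "complete":
                gg = complete_to_class(g, "complete")
                fn = complete_feasibility(gg)
            elif cls == "cluster":
                gg = complete_to_class(g, "cluster")
                fn = cluster_feasibility(gg)
            elif cls == "oracle":
                gg = g
                fn = oracle_feasibility()
            else:
                raise ValueError(f"unknown feasibility class {cls!r}")
            dec, _ = greedy_scaffold(gg, p, fn)
            row[f"greedy_{cls}"] = dec.total_weight
            opt = row.get("optimum")
            if opt is not None and dec.total_weight > 0:
                row[f"ratio_{cls}"] = Fraction(opt) / dec.total_weight
        rows.append(row)
    return rows
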