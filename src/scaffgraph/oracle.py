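"""Exponential-time exact solvers used as ground truth on small instances.

These are deliberately simple and exhaustive: they enumerate (directly or via
an exact dynamic program over matching-edge subsets) every decomposition of
``S ∪ M*`` into alternating paths and cycles, so they can arbitrate the
polynomial-time feasibility functions and the greedy solver on any instance
small enough to enumerate.  Size caps refuse loudly rather than truncating.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Dict, FrozenSet, Iterable, Iterator, List, Optional, Set, Tuple

from .graph import (Edge, Parameters, PartialSolution, ScaffoldGraph, edge,
                    solution_is_valid)

__all__ = [
    "OracleResult",
    "OracleSizeError",
    "brute_force_feasible",
    "brute_force_optimum",
    "enumerate_solutions",
    "max_independent_set",
]

DEFAULT_CAP = 10
_DP_MAX_MATCHING = 12  # beyond this the subset DP table would be too large


class OracleSizeError(ValueError):
    """Raised instead of silently truncating when an instance exceeds the cap."""


def _require_cap(n: int, cap: int, what: str) -> None:
    if n > cap:
        raise OracleSizeError(
            f"{what}: instance has {n} matching edges, above the configured cap {cap}; "
            f"raise `cap` explicitly to force exhaustive search")


# ---------------------------------------------------------------------------
# Exhaustive enumeration by backtracking
# ---------------------------------------------------------------------------

def _initial_components(g: ScaffoldGraph, s: PartialSolution
                        ) -> Tuple[List[Tuple[Tuple[str, str], int]], int]:
    """Open path components (free-end pairs + matching-edge counts) and the
    number of cycles already present in ``s ∪ M*``."""
    incid: Dict[str, str] = {}
    for e in s.edges:
        u, v = sorted(e)
        if e not in g.weight:
            raise ValueError(f"solution edge {sorted(e)} is not a link edge")
        if u in incid or v in incid:
            raise ValueError("vertex with two incident solution edges")
        incid[u] = v
        incid[v] = u

    def trace(start: str) -> Tuple[List[str], bool]:
        seq = [start]
        v, use_m = start, True
        while True:
            nxt = g.matched_with[v] if use_m else incid.get(v)
            if nxt is None:
                return seq, False
            if nxt == start:
                return seq, True
            seq.append(nxt)
            v, use_m = nxt, not use_m

    seen: Set[str] = set()
    comps: List[Tuple[Tuple[str, str], int]] = []
    cycles0 = 0
    for v in sorted(g.vertices):
        if v in seen or v in incid:
            continue
        seq, closed = trace(v)
        if closed:
            continue
        seen.update(seq)
        comps.append(((seq[0], seq[-1]), len(seq) // 2))
    for v in sorted(g.vertices):
        if v in seen:
            continue
        seq, closed = trace(v)
        if not closed:
            raise ValueError("invalid partial solution: non-alternating component")
        seen.update(seq)
        cycles0 += 1
    return sorted(comps), cycles0


def enumerate_solutions(g: ScaffoldGraph, s: PartialSolution, p: Parameters,
                        cap: int = DEFAULT_CAP,
                        prune: Optional[Callable[[List[Edge], List], bool]] = None
                        ) -> Iterator[FrozenSet[Edge]]:
    """Yield every full solution extending ``s`` with exactly the required
    path and cycle counts, each exactly once.

    Backtracking that repeatedly takes the first open component and builds
    the complete final element (path or cycle) containing it: the element is
    grown outward from the component's first free end, then — for paths —
    from its second free end, which gives every element a unique generation
    order.  Pruning uses only necessary counting conditions, so the
    enumeration stays exhaustive.

    ``prune(chosen_edges, open_components)`` may cut subtrees (used by the
    branch-and-bound optimum; must only cut subtrees it can afford to lose).
    """
    _require_cap(g.n_matching(), cap, "enumerate_solutions")
    if not p.within_bounds(g.n_matching()):
        return
    comps0, cycles0 = _initial_components(g, s)
    if cycles0 > p.sigma_c:
        return
    # process components whose free ends touch positive-weight edges first:
    # the branch-and-bound prune then resolves the weight early (the order
    # changes only the generation sequence, never the solution set)
    pos_verts = {x for e, w in g.weight.items() if w > 0 for x in e}
    comps0.sort(key=lambda c: (not (c[0][0] in pos_verts or c[0][1] in pos_verts), c))
    chosen: List[Edge] = sorted(s.edges, key=sorted)  # yielded solutions include s

    def counts_ok(n_open: int, total_m: int, paths_done: int, cycles_done: int) -> bool:
        need_p = p.sigma_p - paths_done
        need_c = p.sigma_c - cycles_done
        if need_p < 0 or need_c < 0:
            return False
        if n_open < need_p + need_c:
            return False
        if n_open > 0 and need_p + need_c == 0:
            return False
        if total_m < need_p + 2 * need_c:
            return False
        return True

    def link(x: str, y: str) -> Optional[Edge]:
        if x != y and g.has_edge(x, y):
            e = edge(x, y)
            if e in g.weight:
                return e
        return None

    def rec(comps: List[Tuple[Tuple[str, str], int]],
            paths_done: int, cycles_done: int) -> Iterator[FrozenSet[Edge]]:
        total_m = sum(sz for _, sz in comps)
        if not counts_ok(len(comps), total_m, paths_done, cycles_done):
            return
        if not comps:
            yield frozenset(chosen)
            return
        if prune is not None and prune(chosen, comps):
            return
        (a, b), sz = comps[0]
        rest = comps[1:]

        def grow(left: str, right: str, msize: int,
                 remaining: List[Tuple[Tuple[str, str], int]],
                 left_done: bool) -> Iterator[FrozenSet[Edge]]:
            # element under construction containing comps[0]; free outer ends
            # (left, right); left grows first, cycles close before any right
            # growth so each cycle has one canonical generation order.
            owed = (p.sigma_c - cycles_done) + (p.sigma_p - paths_done) - 1
            if len(remaining) < owed:
                return  # every still-owed element needs >= 1 remaining component
            if not left_done:
                if cycles_done < p.sigma_c and msize >= 2:
                    e = link(left, right)
                    if e is not None:
                        chosen.append(e)
                        yield from rec(remaining, paths_done, cycles_done + 1)
                        chosen.pop()
                for i, ((c, d), sz2) in enumerate(remaining):
                    for near, far in ((c, d), (d, c)):
                        e = link(left, near)
                        if e is None:
                            continue
                        chosen.append(e)
                        yield from grow(far, right, msize + sz2,
                                        remaining[:i] + remaining[i + 1:], False)
                        chosen.pop()
            # stop growing left: seal or grow right
            if paths_done < p.sigma_p:
                if left_done:
                    yield from rec(remaining, paths_done + 1, cycles_done)
                else:
                    yield from grow(left, right, msize, remaining, True)
            if left_done:
                for i, ((c, d), sz2) in enumerate(remaining):
                    for near, far in ((c, d), (d, c)):
                        e = link(right, near)
                        if e is None:
                            continue
                        chosen.append(e)
                        yield from grow(left, far, msize + sz2,
                                        remaining[:i] + remaining[i + 1:], True)
                        chosen.pop()

        yield from grow(a, b, sz, rest, False)

    yield from rec(comps0, 0, cycles0)


def brute_force_feasible(g: ScaffoldGraph, s: PartialSolution, p: Parameters,
                         cap: int = DEFAULT_CAP) -> bool:
    """True iff some full solution with exactly ``(sigma_p, sigma_c)`` extends ``s``."""
    for _ in enumerate_solutions(g, s, p, cap=cap):
        return True
    return False


# ---------------------------------------------------------------------------
# Exact optimum
# ---------------------------------------------------------------------------

@dataclass
class OracleResult:
    feasible: bool
    best_weight: Optional[Fraction]
    witness: Optional[PartialSolution]
    enumeration_count: int = 0


def _optimum_subset_dp(g: ScaffoldGraph, p: Parameters) -> OracleResult:
    """Exact optimum via DP over subsets of matching edges.

    ``chain[mask][(a, b)]`` is the best weight of a single alternating path
    covering exactly the matching edges in ``mask`` with free ends ``a, b``;
    chains are assembled into partitions with exact path/cycle counts.
    Exact, and much faster than raw enumeration on dense graphs.
    """
    m_edges = sorted(g.matching_edges, key=lambda e: sorted(e))
    n = len(m_edges)
    idx = {e: i for i, e in enumerate(m_edges)}
    NEG = Fraction(-1)
    chain: List[Dict[Tuple[str, str], Fraction]] = [dict() for _ in range(1 << n)]
    chain_par: Dict[Tuple[int, str, str], Tuple[int, str, str, Edge]] = {}
    for i, e in enumerate(m_edges):
        u, v = sorted(e)
        chain[1 << i][(u, v)] = Fraction(0)
        chain[1 << i][(v, u)] = Fraction(0)
    order_masks = sorted(range(1, 1 << n), key=int.bit_count)
    for mask in order_masks:
        for (a, b), w in list(chain[mask].items()):
            for c in g.link_neighbors(b):
                j = idx[edge(c, g.matched_with[c])]
                if mask & (1 << j):
                    continue
                nm = mask | (1 << j)
                d = g.matched_with[c]
                nw = w + g.weight[edge(b, c)]
                if nw > chain[nm].get((a, d), NEG):
                    chain[nm][(a, d)] = nw
                    chain_par[(nm, a, d)] = (mask, a, b, edge(b, c))
    BestEntry = Tuple[Fraction, str, str, Optional[Edge]]  # weight, ends, chord
    best_path: List[Optional[BestEntry]] = [None] * (1 << n)
    best_cycle: List[Optional[BestEntry]] = [None] * (1 << n)
    for mask in order_masks:
        for (a, b), w in chain[mask].items():
            if best_path[mask] is None or w > best_path[mask][0]:
                best_path[mask] = (w, a, b, None)
            if mask.bit_count() >= 2 and g.has_edge(a, b):
                ec = edge(a, b)
                if ec in g.weight:
                    cw = w + g.weight[ec]
                    if best_cycle[mask] is None or cw > best_cycle[mask][0]:
                        best_cycle[mask] = (cw, a, b, ec)
    # partition DP: f[mask][(p_used, c_used)] = best weight covering mask,
    # parts taken in increasing order of their lowest matching edge
    f: List[Dict[Tuple[int, int], Fraction]] = [dict() for _ in range(1 << n)]
    f_par: Dict[Tuple[int, int, int], Tuple[int, str]] = {}  # -> (sub, kind)
    f[0][(0, 0)] = Fraction(0)
    full = (1 << n) - 1
    for mask in range(1 << n):
        if not f[mask]:
            continue
        rem = full & ~mask
        if not rem:
            continue
        low = rem & (-rem)
        sub = rem
        while sub:
            if sub & low:
                for kind, table, budget in (("P", best_path, p.sigma_p),
                                            ("C", best_cycle, p.sigma_c)):
                    entry = table[sub]
                    if entry is None:
                        continue
                    for (pu, cu), w in f[mask].items():
                        used = pu if kind == "P" else cu
                        if used >= budget:
                            continue
                        key = (pu + 1, cu) if kind == "P" else (pu, cu + 1)
                        nw = w + entry[0]
                        if nw > f[mask | sub].get(key, NEG):
                            f[mask | sub][key] = nw
                            f_par[(mask | sub, *key)] = (sub, kind)
            sub = (sub - 1) & rem
    best = f[full].get((p.sigma_p, p.sigma_c))
    if best is None:
        return OracleResult(False, None, None)
    # witness reconstruction by walking the parent pointers backwards
    edges: Set[Edge] = set()
    mask, pu, cu = full, p.sigma_p, p.sigma_c
    while mask:
        sub, kind = f_par[(mask, pu, cu)]
        entry = (best_path if kind == "P" else best_cycle)[sub]
        _, a, b, chord = entry
        if chord is not None:
            edges.add(chord)
        cm, ca, cb = sub, a, b
        while (cm, ca, cb) in chain_par:
            cm, ca, cb, link_e = chain_par[(cm, ca, cb)]
            edges.add(link_e)
        mask &= ~sub
        if kind == "P":
            pu -= 1
        else:
            cu -= 1
    witness = PartialSolution(frozenset(edges))
    return OracleResult(True, best, witness)


def _optimum_backtracking(g: ScaffoldGraph, p: Parameters, cap: int) -> OracleResult:
    """Exhaustive search with an admissible weight bound: a subtree is cut
    when its chosen weight plus the weight of every positive link edge still
    joinable (both endpoints are free ends of open components) cannot beat
    the incumbent."""
    best: Optional[Fraction] = None
    witness: Optional[FrozenSet[Edge]] = None
    count = 0
    positive = [(e, w) for e, w in g.weight.items() if w > 0]

    def bound_prune(chosen: List[Edge], comps: List) -> bool:
        if best is None:
            return False
        ends = {x for (pair, _) in comps for x in pair}
        cur = g.total_weight(chosen)
        avail = sum(w for e, w in positive if e not in chosen and all(x in ends for x in e))
        return cur + avail <= best

    for sol in enumerate_solutions(g, PartialSolution(), p, cap=cap, prune=bound_prune):
        count += 1
        w = g.total_weight(sol)
        if best is None or w > best:
            best, witness = w, sol
    if best is None:
        return OracleResult(False, None, None, count)
    return OracleResult(True, best, PartialSolution(witness), count)


def brute_force_optimum(g: ScaffoldGraph, p: Parameters,
                        cap: int = DEFAULT_CAP) -> OracleResult:
    """Maximum-weight solution with exact ``(sigma_p, sigma_c)`` counts.

    Dispatches to the subset DP when the table fits, otherwise to plain
    enumeration (viable for larger but sparse, heavily-constrained
    instances such as the hardness constructions).
    """
    _require_cap(g.n_matching(), cap, "brute_force_optimum")
    if g.n_matching() <= _DP_MAX_MATCHING:
        return _optimum_subset_dp(g, p)
    return _optimum_backtracking(g, p, cap)


# ---------------------------------------------------------------------------
# Maximum independent set
# ---------------------------------------------------------------------------

def max_independent_set(adjacency: Dict[str, Set[str]], cap: int = 20) -> int:
    """Exact maximum independent-set size by branch and bound."""
    verts = sorted(adjacency)
    if len(verts) > cap:
        raise OracleSizeError(f"max_independent_set: {len(verts)} vertices exceeds cap {cap}")

    best = 0

    def rec(cand: List[str], size: int) -> None:
        nonlocal best
        if size + len(cand) <= best:
            return
        if not cand:
            best = max(best, size)
            return
        v = cand[0]
        rec([u for u in cand[1:] if u not in adjacency[v]], size + 1)  # take v
        rec(cand[1:], size)  # skip v
    rec(verts, 0)
    return best
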