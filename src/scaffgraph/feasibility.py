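"""Feasibility functions: can a partial solution still be extended into
exactly ``sigma_p`` alternating paths and ``sigma_c`` alternating cycles?

Two polynomial-time predicates are provided:

* :func:`feasible_cluster` — a bottom-up dynamic program over the rooted
  clique tree of a connected cluster graph.  For every scope (vertex branch,
  alternating element, subclique, clique) it maintains *entry vectors*: for
  each cycle count ``i`` the set of path counts achievable by some partial
  solution of that scope, split into solution classes by how the scope can
  still interact with the rest of the graph — closeable ``C`` (a path with
  both ends free), extensible ``E`` (a free path end), frozen ``F`` (no free
  end), absorbent ``A`` (frozen, but an internal link edge can be replaced by
  an external path), plus the intermediates ``A+``/``E+`` (closeable paths
  present, remainder frozen/extensible) used while scanning a subclique.
  Vectors combine by juxtaposition, merge, closing and absorption, which act
  on path/cycle counts as convolutions with small shifts.

* :func:`feasible_complete` — a constant-time predicate on complete scaffold
  graphs using only component statistics of ``s ∪ M*`` (cycles formed, path
  components and how many of them hold a single matching edge).

Both are validated against the exhaustive oracle in the test suite; the
oracle is the contract.
"""

from __future__ import annotations

from typing import Callable, Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .cluster import (AlternatingElementView, ClusterStructure,
                      alternating_elements_of, build_cluster_structure)
from .graph import Edge, Parameters, PartialSolution, ScaffoldGraph, edge
from .oracle import _initial_components

__all__ = [
    "EntryVector",
    "ClassTable",
    "compose",
    "ClusterFeasibility",
    "feasible_cluster",
    "feasible_complete",
    "cluster_feasibility",
    "complete_feasibility",
    "oracle_feasibility",
]

ClassTable = Dict[str, "EntryVector"]


class EntryVector:
    """Per cycle count ``i`` in ``[0, sigma_c]``, the set of eligible path
    counts ``j`` — i.e. some tracked partial solution has exactly ``i``
    cycles and ``j`` paths.

    Stored as explicit integer sets: eligible path counts often form
    intervals in practice, but contiguity is an unproven optimization we do
    not assume."""

    __slots__ = ("sets",)

    def __init__(self, sets: Sequence[FrozenSet[int]]):
        self.sets: Tuple[FrozenSet[int], ...] = tuple(frozenset(s) for s in sets)

    # -- constructors ------------------------------------------------------
    @staticmethod
    def empty(sigma_c: int) -> "EntryVector":
        return EntryVector([frozenset()] * (sigma_c + 1))

    @staticmethod
    def base_empty_solution(sigma_c: int) -> "EntryVector":
        """[{∅}]: {0} at zero cycles, ∅ elsewhere."""
        return EntryVector([frozenset({0})] + [frozenset()] * sigma_c)

    @staticmethod
    def base_single_path(sigma_c: int) -> "EntryVector":
        """[{p}]: {1} at zero cycles."""
        return EntryVector([frozenset({1})] + [frozenset()] * sigma_c)

    @staticmethod
    def base_single_cycle(sigma_c: int) -> "EntryVector":
        """[{c}]: {0} at one cycle (empty everywhere if sigma_c = 0)."""
        sets = [frozenset() for _ in range(sigma_c + 1)]
        if sigma_c >= 1:
            sets[1] = frozenset({0})
        return EntryVector(sets)

    # -- basic algebra -----------------------------------------------------
    @property
    def sigma_c(self) -> int:
        return len(self.sets) - 1

    def is_empty(self) -> bool:
        return all(not s for s in self.sets)

    def union(self, *others: "EntryVector") -> "EntryVector":
        sets = [set(s) for s in self.sets]
        for o in others:
            for i, s in enumerate(o.sets):
                sets[i] |= s
        return EntryVector(sets)

    def shift_paths(self, delta: int, cap: Optional[int] = None) -> "EntryVector":
        out = []
        for s in self.sets:
            t = {j + delta for j in s if j + delta >= 0}
            if cap is not None:
                t = {j for j in t if j <= cap}
            out.append(t)
        return EntryVector(out)

    def shift_cycles(self, delta: int) -> "EntryVector":
        sets = [set() for _ in self.sets]
        for i, s in enumerate(self.sets):
            if 0 <= i + delta <= self.sigma_c:
                sets[i + delta] |= s
        return EntryVector(sets)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, EntryVector) and self.sets == other.sets

    def __repr__(self) -> str:
        return "EntryVector(" + ", ".join(
            "{" + ",".join(map(str, sorted(s))) + "}" if s else "∅" for s in self.sets) + ")"


def _convolve(vectors: Sequence[EntryVector], cap: Optional[int]) -> EntryVector:
    """Component-wise Minkowski-sum convolution over cycle indices."""
    assert vectors
    sc = vectors[0].sigma_c
    acc: List[Set[int]] = [set(s) for s in vectors[0].sets]
    for vec in vectors[1:]:
        nxt: List[Set[int]] = [set() for _ in range(sc + 1)]
        for i, si in enumerate(acc):
            if not si:
                continue
            for j, sj in enumerate(vec.sets):
                if i + j > sc or not sj:
                    continue
                for x in si:
                    for y in sj:
                        z = x + y
                        if cap is None or z <= cap:
                            nxt[i + j].add(z)
        acc = nxt
    return EntryVector(acc)


def compose(kind: str, t: int, vectors: Sequence[EntryVector],
            cap: Optional[int] = None) -> EntryVector:
    """Combine entry vectors of vertex-disjoint scopes.

    ``juxtapose``: plain convolution (paths/cycles add up).
    ``merge`` with parameter ``t``: ``t`` paths, one from each operand chain,
    become a single path — path counts shift by ``-(t-1)``.
    ``close`` with parameter ``t``: ``t`` paths close into one new cycle —
    path counts shift by ``-t``, cycle index by ``+1`` (empty result when the
    cycle budget is zero, never an exception).
    ``absorb``: one path replaces a link edge of the other solution — path
    counts shift by ``-1``.
    """
    if t < 1:
        raise ValueError("parameter t must be >= 1")
    conv = _convolve(vectors, None)
    if kind == "juxtapose":
        out = conv
    elif kind == "merge":
        out = conv.shift_paths(-(t - 1))
    elif kind == "close":
        out = conv.shift_paths(-t).shift_cycles(+1)
    elif kind == "absorb":
        out = conv.shift_paths(-1)
    else:
        raise ValueError(f"unknown composition kind {kind!r}")
    if cap is not None:
        out = out.shift_paths(0, cap)
    return out


# ---------------------------------------------------------------------------
# The cluster-graph dynamic program
# ---------------------------------------------------------------------------

_SUB_CLASSES = ("F", "A", "A+", "E", "E+")


class ClusterFeasibility:
    """One bottom-up DP run for a fixed ``(graph, structure, s, parameters)``.

    Exposes the per-scope class tables (for inspection/CLI dumps) and the
    final verdict.  Tables are recomputed from scratch per call; scopes are
    memoized within the call.
    """

    def __init__(self, g: ScaffoldGraph, cs: ClusterStructure,
                 s: PartialSolution, p: Parameters):
        if set(cs.clique_of) != g.vertices:
            raise ValueError("cluster structure does not match the graph")
        self.g = g
        self.cs = cs
        self.s = s
        self.p = p
        self.sc = p.sigma_c
        self.cap = g.n_matching()
        self.vertex_tables: Dict[str, ClassTable] = {}
        self.element_tables: Dict[Tuple[str, ...], ClassTable] = {}
        self.subclique_tables: Dict[int, ClassTable] = {}
        self.clique_tables: Dict[int, ClassTable] = {}
        self._s_bridge_child: Dict[str, List[int]] = {}
        for cid, b in cs.bridge_of.items():
            if b in s.edges:
                door = next(iter(b - {cs.upper_door[cid]}))
                self._s_bridge_child.setdefault(door, []).append(cid)

    # -- helpers -----------------------------------------------------------
    def _juxt(self, *vectors: EntryVector) -> EntryVector:
        if not vectors:
            return EntryVector.base_empty_solution(self.sc)
        return compose("juxtapose", 1, vectors, cap=self.cap)

    def _merge2(self, v1: EntryVector, v2: EntryVector) -> EntryVector:
        return compose("merge", 2, [v1, v2], cap=self.cap)

    def _close2(self, v1: EntryVector, v2: EntryVector) -> EntryVector:
        return compose("close", 2, [v1, v2], cap=self.cap)

    def _absorb(self, v1: EntryVector, v2: EntryVector) -> EntryVector:
        return compose("absorb", 1, [v1, v2], cap=self.cap)

    # -- vertex scope ------------------------------------------------------
    def compute_vertex(self, v: str) -> ClassTable:
        """Classes of ``G*(v)``: the vertex plus every branch hanging below
        it.  ``E`` solutions carry a pending path whose endpoint has been
        relocated to ``v`` through a bridge (count unchanged); ``C`` and
        ``A`` are empty since at most one edge crosses the bridge above."""
        if v in self.vertex_tables:
            return self.vertex_tables[v]
        children = self.cs.children_of_vertex.get(v, [])
        forced = self._s_bridge_child.get(v, [])
        if len(forced) > 1:
            raise ValueError(f"partial solution has two bridge edges at vertex {v!r}")
        child_tabs = {c: self.compute_clique(c) for c in children}
        empty = EntryVector.empty(self.sc)
        if not children:
            table = {"F": EntryVector.base_empty_solution(self.sc), "E": empty}
        elif forced:
            cf = forced[0]
            others = [child_tabs[c]["F"].union(child_tabs[c]["E"])
                      for c in children if c != cf]
            table = {"F": empty,
                     "E": self._juxt(child_tabs[cf]["E"], *others)}
        else:
            any_child = [child_tabs[c]["F"].union(child_tabs[c]["E"]) for c in children]
            f_vec = self._juxt(*any_child)
            e_vec = empty
            for i, c in enumerate(children):
                others = any_child[:i] + any_child[i + 1:]
                e_vec = e_vec.union(self._juxt(child_tabs[c]["E"], *others))
            table = {"F": f_vec, "E": e_vec}
        self.vertex_tables[v] = table
        return table

    # -- alternating-element scope -----------------------------------------
    def compute_alternating_element(self, elem: AlternatingElementView) -> ClassTable:
        """Classes of ``G*(e)``: the element and the branches below its
        vertices.  ``I`` is the juxtaposed frozen vector of the inner
        vertices.  A path element is closeable (``C``) when both extremities
        stay free, extensible (``E``) when exactly one does, frozen (``F``)
        when both are consumed — by extension below or by self-closing
        through the clique chord (needs >= 2 matching edges)."""
        key = elem.key()
        if key in self.element_tables:
            return self.element_tables[key]
        empty = EntryVector.empty(self.sc)
        inner_tabs = [self.compute_vertex(w)["F"] for w in elem.inner_vertices]
        i_vec = self._juxt(*inner_tabs) if inner_tabs else EntryVector.base_empty_solution(self.sc)
        if elem.is_cycle:
            table = {"C": empty, "E": empty,
                     "F": self._juxt(i_vec, EntryVector.base_single_cycle(self.sc)),
                     "I": i_vec}
        else:
            u, v = elem.extremities
            fu, eu = self.compute_vertex(u)["F"], self.compute_vertex(u)["E"]
            fv, ev = self.compute_vertex(v)["F"], self.compute_vertex(v)["E"]
            base_p = EntryVector.base_single_path(self.sc)
            c_vec = self._juxt(base_p, i_vec, fu, fv)
            e_vec = self._juxt(i_vec, eu, fv).union(self._juxt(i_vec, fu, ev))
            # both ends extended below: three paths merge into one
            f_vec = self._juxt(i_vec, eu, ev).shift_paths(-1)
            if elem.n_matching >= 2:
                closed = self._juxt(i_vec, fu, fv,
                                    EntryVector.base_single_cycle(self.sc))
                f_vec = f_vec.union(closed)
            table = {"C": c_vec, "E": e_vec, "F": f_vec, "I": i_vec}
        self.element_tables[key] = table
        return table

    # -- subclique scope ---------------------------------------------------
    def accumulate_subclique(self, element_tables: Sequence[ClassTable]
                             ) -> Dict[Tuple[int, int, int], EntryVector]:
        """Scan the elements of a subclique, composing each new element with
        the accumulated solution by at most one operation.

        The accumulated state is ``(k, ext, abs)``: ``k`` closeable paths
        (both ends free inside the clique — exact, because each later close
        or merge consumes one), whether an extensible path (exactly one free
        end) exists, and whether an absorbable link edge (added by an earlier
        merge or absorption, hence removable) exists.  Multiple extensible
        paths and dead absorbable edges are canonicalized away: every
        cardinality they could reach is also reached through a reordered
        derivation kept by these states (validated against the exhaustive
        oracle).
        """
        states: Dict[Tuple[int, int, int], EntryVector] = {
            (0, 0, 0): EntryVector.base_empty_solution(self.sc)}

        def put(d: Dict[Tuple[int, int, int], EntryVector],
                key: Tuple[int, int, int], vec: EntryVector) -> None:
            if vec.is_empty():
                return
            cur = d.get(key)
            d[key] = vec if cur is None else cur.union(vec)

        for T in element_tables:
            CT, ET, FT = T["C"], T["E"], T["F"]
            nxt: Dict[Tuple[int, int, int], EntryVector] = {}
            for (k, ext, ab), V in states.items():
                # juxtaposition with any element class
                put(nxt, (k + 1, ext, ab), self._juxt(V, CT))
                put(nxt, (k, 1, ab), self._juxt(V, ET))
                put(nxt, (k, ext, ab), self._juxt(V, FT))
                if k >= 1:
                    # merge via a stored closeable path
                    put(nxt, (k, ext, 1), self._merge2(V, CT))
                    put(nxt, (k - 1, 1, 1), self._merge2(V, ET))
                    # close a stored closeable path with the element's path
                    put(nxt, (k - 1, ext, ab), self._close2(V, CT))
                if ext:
                    # merge via the extensible path's free end
                    put(nxt, (k, 1, 1), self._merge2(V, CT))
                    put(nxt, (k, 0, 1), self._merge2(V, ET))
                if ab:
                    # absorb the element's closeable path into an absorbable edge
                    put(nxt, (k, ext, 1), self._absorb(V, CT))
            states = nxt
        return states

    @staticmethod
    def collapse_states(states: Dict[Tuple[int, int, int], EntryVector],
                        sigma_c: int) -> ClassTable:
        """Collapse accumulation states into the printable solution classes
        (frozen F, frozen-absorbent A, extensible E, and the closeable
        intermediates A+/E+ with C = A+ ∪ E+)."""
        empty = EntryVector.empty(sigma_c)
        out = {"F": empty, "A": empty, "A+": empty, "E": empty, "E+": empty}

        def add(label: str, vec: EntryVector) -> None:
            out[label] = out[label].union(vec)

        for (k, ext, ab), vec in states.items():
            if k >= 1:
                add("E+" if ext else "A+", vec)
            elif ext:
                add("E", vec)
            elif ab:
                add("A", vec)
            else:
                add("F", vec)
        out["C"] = out["A+"].union(out["E+"])
        return out

    def compute_subclique(self, c: int) -> ClassTable:
        if c in self.subclique_tables:
            return self.subclique_tables[c]
        elements, _ = alternating_elements_of(self.g, self.cs, c, self.s)
        door_elem = None
        if c != self.cs.root:
            door = self.cs.upper_door[c]
            door_elem = next(e for e in elements if door in e.vertices)
        tabs = [self.compute_alternating_element(e) for e in elements if e is not door_elem]
        table = self.collapse_states(self.accumulate_subclique(tabs), self.sc)
        self.subclique_tables[c] = table
        return table

    def _subclique_states(self, c: int, door_elem: AlternatingElementView
                          ) -> Dict[Tuple[int, int, int], EntryVector]:
        elements, _ = alternating_elements_of(self.g, self.cs, c, self.s)
        tabs = [self.compute_alternating_element(e) for e in elements
                if e.key() != door_elem.key()]
        return self.accumulate_subclique(tabs)

    # -- clique scope ------------------------------------------------------
    def compute_clique(self, c: int) -> ClassTable:
        """Classes of ``G*(c)``, tracking only whether the upper door ``d``
        ends up free (``E``) or consumed (``F``): the bridge above carries at
        most one edge, so ``C`` and ``A`` are empty at clique level.

        The element holding ``d`` is composed with the subclique states by
        at most one operation; which end of the door element the operation
        consumes decides whether ``d`` stays free."""
        if c in self.clique_tables:
            return self.clique_tables[c]
        elements, _ = alternating_elements_of(self.g, self.cs, c, self.s)
        d = self.cs.upper_door[c]
        door_elem = next(e for e in elements if d in e.vertices)
        states = self._subclique_states(c, door_elem)
        Te = self.compute_alternating_element(door_elem)
        empty = EntryVector.empty(self.sc)
        f_vec, e_vec = empty, empty

        def feed(door_cls: Dict[str, EntryVector]) -> Tuple[EntryVector, EntryVector]:
            # door_cls: vectors keyed by which door-element ends stay free:
            # "dd2" (both), "d" (only d), "d2" (only d'), "none"
            fv, ev = empty, empty
            both, only_d = door_cls.get("dd2", empty), door_cls.get("d", empty)
            only_d2, none = door_cls.get("d2", empty), door_cls.get("none", empty)
            for (k, ext, ab), V in states.items():
                # juxtaposition: free ends untouched
                ev = ev.union(self._juxt(V, both.union(only_d)))
                fv = fv.union(self._juxt(V, only_d2.union(none)))
                if k >= 1 or ext:
                    # merge a subclique free end with an element end
                    fv = fv.union(self._merge2(V, both))      # via d: d consumed
                    ev = ev.union(self._merge2(V, both))      # via d': d stays free
                    fv = fv.union(self._merge2(V, only_d))    # via d
                    fv = fv.union(self._merge2(V, only_d2))   # via d'
                if k >= 1:
                    # close the element's 2-free-end path with a closeable path
                    fv = fv.union(self._close2(V, both))
                if ab:
                    # absorb the element's 2-free-end path into an absorbable edge
                    fv = fv.union(self._absorb(V, both))
            return fv, ev

        if door_elem.is_cycle:
            fv, ev = feed({"none": Te["F"]})
        elif d in door_elem.inner_vertices:
            # d consumed inside the element: results frozen regardless of the
            # element's extremity states
            u, v = door_elem.extremities
            fv1, ev1 = feed({"dd2": Te["C"], "d": Te["E"], "none": Te["F"]})
            fv, ev = fv1.union(ev1), empty
        else:
            u, v = door_elem.extremities
            d2 = v if u == d else u
            i_vec = Te["I"]
            fd, ed = self.compute_vertex(d)["F"], self.compute_vertex(d)["E"]
            fd2, ed2 = self.compute_vertex(d2)["F"], self.compute_vertex(d2)["E"]
            e_d = self._juxt(i_vec, fd, ed2)    # d free, d' extended below
            e_d2 = self._juxt(i_vec, ed, fd2)   # d extended below, d' free
            fv, ev = feed({"dd2": Te["C"], "d": e_d, "d2": e_d2, "none": Te["F"]})
        table = {"F": fv, "E": ev}
        self.clique_tables[c] = table
        return table

    # -- verdict -----------------------------------------------------------
    def root_vector(self) -> EntryVector:
        elements, _ = alternating_elements_of(self.g, self.cs, self.cs.root, self.s)
        tabs = [self.compute_alternating_element(e) for e in elements]
        states = self.accumulate_subclique(tabs)
        self.subclique_tables[self.cs.root] = self.collapse_states(states, self.sc)
        out = EntryVector.empty(self.sc)
        for vec in states.values():
            out = out.union(vec)
        return out

    def feasible(self) -> bool:
        return self.p.sigma_p in self.root_vector().sets[self.sc]


def feasible_cluster(g: ScaffoldGraph, cs: ClusterStructure,
                     s: PartialSolution, p: Parameters) -> bool:
    """True iff ``s`` extends to exactly ``(sigma_p, sigma_c)`` on the
    connected cluster graph described by ``cs``."""
    if not p.within_bounds(g.n_matching()):
        return False
    return ClusterFeasibility(g, cs, s, p).feasible()


# ---------------------------------------------------------------------------
# Complete graphs
# ---------------------------------------------------------------------------

def feasible_complete(g: ScaffoldGraph, s: PartialSolution, p: Parameters) -> bool:
    """Constant-time feasibility on complete scaffold graphs.

    Components of ``s ∪ M*`` can only merge, close, or stay; in a complete
    graph every merge/close is available.  With ``c`` cycles formed,
    ``k = sigma_c - c`` cycles still owed, ``P`` path components of which
    ``a`` hold a single matching edge (those cannot self-close): feasible iff
    ``k >= 0``, ``P >= sigma_p + k``, surplus paths have somewhere to go
    (``sigma_p + k >= 1`` unless ``P = 0``), and after filling path slots
    with single-edge components first, the cycle slots not coverable by a
    multi-edge component can each take a *pair* of single-edge components.
    """
    if not g.is_complete():
        raise ValueError(
            "feasible_complete requires a complete graph; use complete_to_class(g, "
            "'complete') or feasible_cluster")
    comps, cycles0 = _initial_components(g, s)
    k = p.sigma_c - cycles0
    if k < 0:
        return False
    P = len(comps)
    if P < p.sigma_p + k:
        return False
    if p.sigma_p + k == 0:
        return P == 0
    a = sum(1 for _, sz in comps if sz == 1)
    b = P - a
    a_left = max(0, a - p.sigma_p)
    b_left = b - max(0, p.sigma_p - a)
    if b_left < k and a_left < 2 * (k - b_left):
        return False
    return True


# ---------------------------------------------------------------------------
# Predicate factories with the uniform (g, s, p) signature for the greedy
# ---------------------------------------------------------------------------

FeasibilityFn = Callable[[ScaffoldGraph, PartialSolution, Parameters], bool]


def cluster_feasibility(g: ScaffoldGraph,
                        cs: Optional[ClusterStructure] = None) -> FeasibilityFn:
    if cs is None:
        cs = build_cluster_structure(g)
    structure = cs

    def fn(graph: ScaffoldGraph, s: PartialSolution, p: Parameters) -> bool:
        return feasible_cluster(graph, structure, s, p)
    return fn


def complete_feasibility(g: ScaffoldGraph) -> FeasibilityFn:
    def fn(graph: ScaffoldGraph, s: PartialSolution, p: Parameters) -> bool:
        return feasible_complete(graph, s, p)
    return fn


def oracle_feasibility(cap: int = 32) -> FeasibilityFn:
    from .oracle import brute_force_feasible

    def fn(graph: ScaffoldGraph, s: PartialSolution, p: Parameters) -> bool:
        return brute_force_feasible(graph, s, p, cap=cap)
    return fn
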