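"""Connected cluster graphs: recognition, rooting, and zero-weight completion.

A *connected cluster graph* is a connected graph whose edge set splits into
``E' ∪ B`` where ``E'`` induces a disjoint union of cliques and every edge of
``B`` is a bridge.  Contracting each clique yields a tree; rooting that tree
gives every non-root clique a unique *upper door* (the vertex adjacent to its
parent clique) and every clique a set of *doors* (vertices adjacent to child
cliques).  The feasibility DP walks this rooted structure bottom-up.

Arbitrary scaffold graphs are brought into the class (or made complete) by
adding zero-weight link edges, which preserves every solution and its weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .graph import (Edge, PartialSolution, ScaffoldGraph, edge, validate_graph)

__all__ = [
    "ClusterStructure",
    "AlternatingElementView",
    "SubcliqueView",
    "NotClusterGraphError",
    "find_bridges",
    "connected_components",
    "build_cluster_structure",
    "alternating_elements_of",
    "complete_to_class",
]


class NotClusterGraphError(ValueError):
    """Input graph is not a connected cluster graph; carries a witness."""


def connected_components(g: ScaffoldGraph) -> List[Set[str]]:
    seen: Set[str] = set()
    comps: List[Set[str]] = []
    for v in sorted(g.vertices):
        if v in seen:
            continue
        stack, comp = [v], {v}
        seen.add(v)
        while stack:
            x = stack.pop()
            for y in g.neighbors(x):
                if y not in comp:
                    comp.add(y)
                    seen.add(y)
                    stack.append(y)
        comps.append(comp)
    return comps


def find_bridges(g: ScaffoldGraph) -> Set[Edge]:
    """Bridges of a connected graph by iterative DFS low-link.

    Ties (neighbour visit order) are broken by sorted vertex order so the
    DFS — and hence any diagnostics derived from it — is reproducible.
    """
    if len(connected_components(g)) != 1:
        raise ValueError("find_bridges requires a connected graph")
    disc: Dict[str, int] = {}
    low: Dict[str, int] = {}
    bridges: Set[Edge] = set()
    timer = 0
    root = min(g.vertices)
    stack: List[Tuple[str, Optional[str], int]] = [(root, None, 0)]
    neighbors = {v: sorted(g.neighbors(v)) for v in g.vertices}
    while stack:
        v, parent, i = stack.pop()
        if i == 0:
            disc[v] = low[v] = timer
            timer += 1
        if i < len(neighbors[v]):
            stack.append((v, parent, i + 1))
            u = neighbors[v][i]
            if u == parent:
                continue
            if u in disc:
                low[v] = min(low[v], disc[u])
            else:
                stack.append((u, v, 0))
        else:
            if parent is not None:
                low[parent] = min(low[parent], low[v])
                if low[v] > disc[parent]:
                    bridges.add(edge(parent, v))
    return bridges


@dataclass
class ClusterStructure:
    """Definition-style decomposition of a connected cluster graph.

    ``cliques`` maps clique id -> vertex set; ``clique_of`` inverts it.
    ``parent``/``children`` describe the rooted clique tree, ``upper_door``
    the unique vertex of a non-root clique adjacent to its parent, ``doors``
    the vertices adjacent to child cliques, and ``children_of_vertex`` the
    child cliques hanging below each door (with the bridge edge used).
    """

    cliques: Dict[int, FrozenSet[str]]
    bridges: Set[Edge]
    root: int
    clique_of: Dict[str, int]
    parent: Dict[int, int]
    children: Dict[int, List[int]]
    upper_door: Dict[int, str]
    bridge_of: Dict[int, Edge]              # non-root clique -> bridge to parent
    doors: Dict[int, Set[str]]
    children_of_vertex: Dict[str, List[int]]

    def postorder(self) -> List[int]:
        out: List[int] = []
        stack = [(self.root, False)]
        while stack:
            c, done = stack.pop()
            if done:
                out.append(c)
            else:
                stack.append((c, True))
                for ch in reversed(self.children.get(c, [])):
                    stack.append((ch, False))
        return out




def build_cluster_structure(g: ScaffoldGraph, root_policy: Optional[str] = None
                            ) -> ClusterStructure:
    """Recognize a connected cluster graph and root its clique tree.

    ``root_policy``: a vertex name whose clique becomes the root; default is
    the clique containing the lexicographically smallest vertex.  Raises
    :class:`NotClusterGraphError` with a witness non-edge when a component of
    ``G - B`` is not a clique, or when a matching edge is a bridge.
    """
    report = validate_graph(g)
    if not report.ok:
        raise ValueError("invalid scaffold graph: " + "; ".join(report.violations))
    # B contains only link bridges: a matching edge that happens to be a
    # bridge (e.g. a 2-vertex clique) belongs to its clique, not to B.  If a
    # matching bridge joins two larger components the clique check below
    # fails and completion must be run first.
    bridges = {b for b in find_bridges(g) if b not in g.matching_edges}
    # components of G - B
    clique_of: Dict[str, int] = {}
    cliques: Dict[int, FrozenSet[str]] = {}
    seen: Set[str] = set()
    for v in sorted(g.vertices):
        if v in seen:
            continue
        comp = {v}
        stack = [v]
        seen.add(v)
        while stack:
            x = stack.pop()
            for y in g.neighbors(x):
                if y not in comp and edge(x, y) not in bridges:
                    comp.add(y)
                    seen.add(y)
                    stack.append(y)
        cid = len(cliques)
        for x in comp:
            clique_of[x] = cid
        cliques[cid] = frozenset(comp)
    # each component must induce a clique via non-bridge edges
    for cid, comp in cliques.items():
        members = sorted(comp)
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                if not g.has_edge(u, v):
                    hint = ""
                    if any(b in g.matching_edges for b in find_bridges(g)):
                        hint = (" (a matching edge is a bridge here; run "
                                "complete_to_class(g, 'cluster') first)")
                    raise NotClusterGraphError(
                        f"not a connected cluster graph: vertices {u!r} and {v!r} lie in the "
                        f"same bridge-free component but are not adjacent" + hint)
    # root and orient the clique tree
    if root_policy is None:
        root_vertex = min(g.vertices)
    else:
        if root_policy not in clique_of:
            raise ValueError(f"root policy vertex {root_policy!r} not in graph")
        root_vertex = root_policy
    root = clique_of[root_vertex]
    tree_adj: Dict[int, List[Tuple[int, Edge]]] = {cid: [] for cid in cliques}
    for b in sorted(bridges, key=sorted):
        u, v = sorted(b)
        cu, cv = clique_of[u], clique_of[v]
        tree_adj[cu].append((cv, b))
        tree_adj[cv].append((cu, b))
    parent: Dict[int, int] = {}
    children: Dict[int, List[int]] = {cid: [] for cid in cliques}
    upper_door: Dict[int, str] = {}
    bridge_of: Dict[int, Edge] = {}
    doors: Dict[int, Set[str]] = {cid: set() for cid in cliques}
    children_of_vertex: Dict[str, List[int]] = {}
    order = [root]
    visited = {root}
    for c in order:
        for (d, b) in tree_adj[c]:
            if d in visited:
                continue
            visited.add(d)
            parent[d] = c
            children[c].append(d)
            u, v = sorted(b)
            door_v, upper = (u, v) if clique_of[u] == c else (v, u)
            upper_door[d] = upper
            bridge_of[d] = b
            doors[c].add(door_v)
            children_of_vertex.setdefault(door_v, []).append(d)
            order.append(d)
    if len(visited) != len(cliques):
        raise ValueError("graph is disconnected")
    return ClusterStructure(cliques=cliques, bridges=bridges, root=root,
                            clique_of=clique_of, parent=parent, children=children,
                            upper_door=upper_door, bridge_of=bridge_of, doors=doors,
                            children_of_vertex=children_of_vertex)


@dataclass
class AlternatingElementView:
    """One alternating element of a clique: a maximal piece of ``S' ∪ M*``
    inside the clique, either a path (vertex sequence, matching extremal
    edges) or a cycle."""

    vertices: Tuple[str, ...]
    is_cycle: bool
    host_clique: int

    @property
    def extremities(self) -> Tuple[str, str]:
        if self.is_cycle:
            raise ValueError("a cycle element has no extremities")
        return self.vertices[0], self.vertices[-1]

    @property
    def inner_vertices(self) -> Tuple[str, ...]:
        if self.is_cycle:
            return self.vertices
        return self.vertices[1:-1]

    @property
    def n_matching(self) -> int:
        return len(self.vertices) // 2

    def key(self) -> Tuple[str, ...]:
        return tuple(sorted(self.vertices))


@dataclass
class SubcliqueView:
    """Vertices of a clique outside the element holding its upper door."""

    vertices: FrozenSet[str]
    host_clique: int


def alternating_elements_of(g: ScaffoldGraph, cs: ClusterStructure, c: int,
                            s: PartialSolution
                            ) -> Tuple[List[AlternatingElementView], Optional[SubcliqueView]]:
    """Alternating elements of clique ``c`` under ``s``, plus the subclique.

    Elements are the components of ``(s ∩ c) ∪ M*(c)``; with ``s = ∅`` every
    matching edge of ``c`` is its own single-edge element.  The subclique
    excludes the element containing the upper door (``None`` for the root).
    Elements are listed deterministically, sorted by smallest vertex.
    """
    members = cs.cliques[c]
    incid: Dict[str, str] = {}
    for e in s.edges:
        u, v = sorted(e)
        if u in members and v in members:
            if u in incid or v in incid:
                raise ValueError(f"vertex with two incident solution edges in clique {c}")
            incid[u] = v
            incid[v] = u

    def walk(start: str) -> Tuple[List[str], bool]:
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

    elements: List[AlternatingElementView] = []
    seen: Set[str] = set()
    for v in sorted(members):
        if v in seen or v in incid:
            continue
        seq, closed = walk(v)
        assert not closed
        seen.update(seq)
        if seq[-1] < seq[0]:
            seq = list(reversed(seq))
        elements.append(AlternatingElementView(tuple(seq), False, c))
    for v in sorted(members):
        if v in seen:
            continue
        seq, closed = walk(v)
        if not closed:
            raise ValueError("non-alternating component inside clique")
        seen.update(seq)
        elements.append(AlternatingElementView(tuple(seq), True, c))
    elements.sort(key=lambda e: min(e.vertices))

    subclique: Optional[SubcliqueView] = None
    if c != cs.root:
        door = cs.upper_door[c]
        door_elem = next(e for e in elements if door in e.vertices)
        subclique = SubcliqueView(frozenset(members - set(door_elem.vertices)), c)
    return elements, subclique


def complete_to_class(g: ScaffoldGraph, target: str = "cluster") -> ScaffoldGraph:
    """Zero-weight completion of ``g`` into the target class.

    ``target='complete'`` adds every missing pair as a zero-weight link.
    ``target='cluster'`` completes each bridge-free component into a clique
    and merges the two components incident to any matching-edge bridge, so
    that no matching edge remains a bridge.  Disconnected inputs are first
    connected by a chain of zero-weight links between the lexicographically
    smallest vertices of consecutive components.  Original edges and weights
    are untouched, so any solution of ``g`` remains a solution of the output
    with identical weight.
    """
    report = validate_graph(g)
    if not report.ok:
        raise ValueError("invalid scaffold graph: " + "; ".join(report.violations))
    out = g.copy()
    comps = connected_components(out)
    if len(comps) > 1:
        anchors = sorted(min(c) for c in comps)
        for a, b in zip(anchors, anchors[1:]):
            out.add_link_edge(a, b, 0)
    if target == "complete":
        verts = sorted(out.vertices)
        for i, u in enumerate(verts):
            for v in verts[i + 1:]:
                if not out.has_edge(u, v):
                    out.add_link_edge(u, v, 0)
        return out
    if target != "cluster":
        raise ValueError(f"unknown completion target {target!r}")
    bridges = find_bridges(out)
    # components of G - B, then merge across matching-edge bridges
    comp_id: Dict[str, int] = {}
    next_id = 0
    for v in sorted(out.vertices):
        if v in comp_id:
            continue
        stack = [v]
        comp_id[v] = next_id
        while stack:
            x = stack.pop()
            for y in out.neighbors(x):
                if y not in comp_id and edge(x, y) not in bridges:
                    comp_id[y] = next_id
                    stack.append(y)
        next_id += 1
    parent = list(range(next_id))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for b in bridges:
        if b in out.matching_edges:
            u, v = sorted(b)
            parent[find(comp_id[u])] = find(comp_id[v])
    groups: Dict[int, List[str]] = {}
    for v in sorted(out.vertices):
        groups.setdefault(find(comp_id[v]), []).append(v)
    for members in groups.values():
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                if not out.has_edge(u, v):
                    out.add_link_edge(u, v, 0)
    return out
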