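"""Deterministic instance generators.

* :func:`construction_sparse` — the independent-set reduction producing
  sparse bipartite scaffold graphs whose alternating girth equals a chosen
  ``ell >= 3``: one matching edge per input edge, padding matching edges per
  input vertex, and one alternating *vertex-cycle* of exactly ``ell``
  matching edges per input vertex.  A size-``k`` independent set corresponds
  exactly to a collection of ``k`` vertex-cycles plus length-one paths.
* :func:`construction_polyapx` — the S-reduction from maximum independent
  set: a 6-vertex clique per input edge, a 4-cycle per input vertex, and a
  weight-one *long vertex-cycle* per input vertex, giving optimum weight
  equal to the maximum independent-set size at ``(sigma_p, sigma_c) =
  (0, |V|+|E|)``.
* :func:`grid_2xk` — the 2×k grid on which greedy's ratio is unbounded under
  an adversarial weighting.
* :func:`tightness_witness` — a fixed connected cluster graph on cliques
  {a..f}, {g,h}, {i,j,k,l}, {m,n,o,p} where greedy (taking the weight-one
  edge ``ac`` first) scores 1 while the optimum scores 5 — the ratio-5
  witness.
* :func:`random_instance` — seeded random families (connected cluster /
  complete / subcubic triangle-free sources) used as test fixtures.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .graph import Parameters, PartialSolution, ScaffoldGraph, edge

__all__ = [
    "InstanceBundle",
    "construction_sparse",
    "construction_polyapx",
    "grid_2xk",
    "tightness_witness",
    "random_instance",
    "random_subcubic_trianglefree",
    "random_feasible_parameters",
    "cluster_shape_family",
    "long_vertex_cycle",
]


@dataclass
class InstanceBundle:
    """A generated scaffold graph with parameters and provenance."""

    graph: ScaffoldGraph
    params: Parameters
    provenance: Dict = field(default_factory=dict)

    def name(self) -> str:
        gen = self.provenance.get("generator", "instance")
        seed = self.provenance.get("seed")
        return f"{gen}" + (f"[seed={seed}]" if seed is not None else "")

    def params_for_cycles(self, k: int) -> Parameters:
        """For girth-``ell`` reduction instances: the parameter pair that
        forces ``k`` vertex-cycles and length-one paths elsewhere."""
        ell = self.provenance.get("ell")
        if ell is None:
            raise ValueError("params_for_cycles applies to construction_sparse bundles")
        return Parameters(sigma_p=self.graph.n_matching() - ell * k, sigma_c=k)


def _graph_girth(G: nx.Graph) -> float:
    """Length of the shortest cycle (inf if forest); BFS from every vertex."""
    best = float("inf")
    for src in G.nodes:
        dist = {src: 0}
        parent = {src: None}
        queue = [src]
        while queue:
            nxt: List = []
            for x in queue:
                for y in G.adj[x]:
                    if y not in dist:
                        dist[y] = dist[x] + 1
                        parent[y] = x
                        nxt.append(y)
                    elif parent[x] != y and parent[y] != x:
                        best = min(best, dist[x] + dist[y] + 1)
            queue = nxt
    return best


def construction_sparse(G: nx.Graph, ell: int = 3) -> InstanceBundle:
    """Girth-``ell`` hardness reduction from a subcubic input of girth > ell.

    Per input edge ``e_i`` a matching edge; per input vertex ``v_t``,
    ``ell - deg(v_t)`` padding matching edges; the matching edges of ``v_t``
    (shared + padding) are wired into an alternating cycle with all link
    edges running between the ``u``-side and the ``ub``-side, so the output
    is bipartite and no two same-side vertices are adjacent.  All weights
    are zero (the reduction is a decision-problem device).
    """
    if any(G.degree[v] > 3 for v in G.nodes):
        bad = next(v for v in G.nodes if G.degree[v] > 3)
        raise ValueError(f"input must be subcubic: vertex {bad!r} has degree {G.degree[bad]}")
    if ell < 3:
        raise ValueError("ell must be >= 3")
    if _graph_girth(G) <= ell:
        raise ValueError(f"input girth must exceed ell={ell}")
    nodes = sorted(G.nodes, key=str)
    edges = sorted(tuple(sorted(map(str, e))) for e in G.edges)
    g = ScaffoldGraph()
    shared: Dict[Tuple[str, str], Tuple[str, str]] = {}
    for i, (a, b) in enumerate(edges, 1):
        mu, mv = f"u{i}", f"ub{i}"
        g.add_matching_edge(mu, mv)
        shared[(a, b)] = (mu, mv)
    for t, v in enumerate(nodes, 1):
        deg = G.degree[v]
        pads = []
        for j in range(1, ell - deg + 1):
            mu, mv = f"u{t}.{j}", f"ub{t}.{j}"
            g.add_matching_edge(mu, mv)
            pads.append((mu, mv))
        incident = [shared[tuple(sorted((str(v), str(w))))] for w in sorted(G.adj[v], key=str)]
        cycle = pads + incident
        assert len(cycle) == ell
        for (u1, ub1), (u2, ub2) in zip(cycle, cycle[1:] + cycle[:1]):
            g.add_link_edge(ub1, u2, 0)
    return InstanceBundle(
        graph=g,
        params=Parameters(sigma_p=g.n_matching(), sigma_c=0),
        provenance={"generator": f"construction_sparse(ell={ell})",
                    "ell": ell,
                    "source_nodes": [str(v) for v in nodes],
                    "source_edges": edges})


def construction_polyapx(G: nx.Graph) -> InstanceBundle:
    """Poly-APX-hardness S-reduction from maximum independent set.

    Weight zero everywhere except the closing edge ``v^t_2 - ub^t_j`` of each
    long vertex-cycle (and, for an isolated vertex, the link
    ``vb^t_1 - vb^t_2`` of its forced 4-cycle), so that picking the long
    vertex-cycle of ``v_t`` — possible exactly for an independent set —
    contributes weight one.
    """
    nodes = sorted(G.nodes, key=str)
    edges = sorted(tuple(sorted(map(str, e))) for e in G.edges)
    t_of = {v: t for t, v in enumerate((str(v) for v in nodes), 1)}
    g = ScaffoldGraph()
    for i, (a, b) in enumerate(edges, 1):
        ta, tb = t_of[a], t_of[b]
        clique = [f"u{ta}.{i}", f"ub{ta}.{i}", f"u{tb}.{i}", f"ub{tb}.{i}", f"e{i}", f"eb{i}"]
        g.add_matching_edge(clique[0], clique[1])
        g.add_matching_edge(clique[2], clique[3])
        g.add_matching_edge(clique[4], clique[5])
        for x, y in itertools.combinations(clique, 2):
            if not g.has_edge(x, y):
                g.add_link_edge(x, y, 0)
    for v in nodes:
        t = t_of[str(v)]
        v1, vb1, v2, vb2 = f"v{t}.1", f"vb{t}.1", f"v{t}.2", f"vb{t}.2"
        g.add_matching_edge(v1, vb1)
        g.add_matching_edge(v2, vb2)
        deg = G.degree[v]
        g.add_link_edge(vb1, vb2, 1 if deg == 0 else 0)
        g.add_link_edge(v1, v2, 0)
        if deg:
            a_t = [i for i, (a, b) in enumerate(edges, 1) if str(v) in (a, b)]
            for i, j in zip(a_t, a_t[1:]):
                g.add_link_edge(f"ub{t}.{i}", f"u{t}.{j}", 0)
            g.add_link_edge(v1, f"u{t}.{a_t[0]}", 0)
            g.add_link_edge(v2, f"ub{t}.{a_t[-1]}", 1)
    return InstanceBundle(
        graph=g,
        params=Parameters(sigma_p=0, sigma_c=len(nodes) + len(edges)),
        provenance={"generator": "construction_polyapx",
                    "source_nodes": [str(v) for v in nodes],
                    "source_edges": edges})


def long_vertex_cycle(bundle: InstanceBundle, v: str) -> Set[str]:
    """Vertex set of the long vertex-cycle of source vertex ``v``."""
    nodes = bundle.provenance["source_nodes"]
    edges = bundle.provenance["source_edges"]
    t = nodes.index(v) + 1
    verts = {f"v{t}.1", f"vb{t}.1", f"v{t}.2", f"vb{t}.2"}
    for i, (a, b) in enumerate(edges, 1):
        if v in (a, b):
            verts |= {f"u{t}.{i}", f"ub{t}.{i}"}
    return verts


def grid_2xk(k: int, adversarial_weights: bool = False) -> InstanceBundle:
    """The 2×k grid: matching edges are the verticals ``x_i y_i``.

    With ``adversarial_weights`` the forced solution after taking ``x1 x2``
    is worth 1 while the optimum is worth ``k-1``: weight one on ``x1 x2``
    and on every edge of the optimal solution, zero on the rest.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    w = max(2, len(str(k)))
    x = [f"x{i:0{w}d}" for i in range(1, k + 1)]
    y = [f"y{i:0{w}d}" for i in range(1, k + 1)]
    g = ScaffoldGraph()
    for xi, yi in zip(x, y):
        g.add_matching_edge(xi, yi)
    for i in range(k - 1):  # i = ell-1, ell 1-based
        ell = i + 1
        wx = wy = 1
        if adversarial_weights:
            wx = 1 if (ell % 2 == 0 or ell == 1) else 0   # S_opt: even ell; plus x1x2
            wy = 1 if ell % 2 == 1 else 0                 # S_opt: odd ell
        g.add_link_edge(x[i], x[i + 1], wx)
        g.add_link_edge(y[i], y[i + 1], wy)
    return InstanceBundle(
        graph=g, params=Parameters(sigma_p=1, sigma_c=0),
        provenance={"generator": f"grid_2xk(k={k}, adversarial={adversarial_weights})",
                    "k": k})


_TIGHTNESS_CLIQUES = {
    "C1": (("a", "b", "c", "d", "e", "f"), (("a", "b"), ("c", "d"), ("e", "f"))),
    "C2": (("g", "h"), (("g", "h"),)),
    "C3": (("i", "j", "k", "l"), (("i", "j"), ("k", "l"))),
    "C4": (("m", "n", "o", "p"), (("m", "n"), ("o", "p"))),
}
_TIGHTNESS_BRIDGES = (("a", "g"), ("c", "i"), ("j", "m"))
_TIGHTNESS_OPT = (("a", "e"), ("b", "d"), ("c", "i"), ("j", "k"), ("m", "o"))


def tightness_witness() -> InstanceBundle:
    """The ratio-5 tightness witness for the greedy on cluster graphs.

    A connected cluster graph on cliques {a..f}, {g,h}, {i,j,k,l}, {m,n,o,p}
    (8 matching edges) joined by the bridges a-g, c-i, j-m, with
    ``(sigma_p, sigma_c) = (3, 0)``.  Weight 1 sits on ``ac`` and on the five
    edges of the designated optimal solution {ae, bd, ci, jk, mo}; all other
    link edges weigh 0.  Under the default tie-break the greedy accepts
    ``ac`` first; every remaining weight-one edge is then either incident to
    a saturated vertex or infeasible, so the greedy finishes at weight 1
    while the optimum is 5.  The exact bridge placement and optimum were
    fixed by computer search among the configurations consistent with this
    clique and weight scheme, and are verified by exhaustive enumeration.
    """
    heavy = {edge(u, v) for u, v in _TIGHTNESS_OPT} | {edge("a", "c")}
    g = ScaffoldGraph()
    for verts, mm in _TIGHTNESS_CLIQUES.values():
        for u, v in mm:
            g.add_matching_edge(u, v)
        for u, v in itertools.combinations(verts, 2):
            if not g.has_edge(u, v):
                g.add_link_edge(u, v, 1 if edge(u, v) in heavy else 0)
    for u, v in _TIGHTNESS_BRIDGES:
        g.add_link_edge(u, v, 1 if edge(u, v) in heavy else 0)
    return InstanceBundle(
        graph=g, params=Parameters(sigma_p=3, sigma_c=0),
        provenance={"generator": "tightness_witness",
                    "optimal_solution": sorted(map(tuple, _TIGHTNESS_OPT)),
                    "greedy_trap_edge": ("a", "c")})


def random_subcubic_trianglefree(seed: int, n_vertices: int = 6,
                                 girth_above: int = 3) -> nx.Graph:
    """Random graph with max degree 3 and girth > ``girth_above``, by
    rejection sampling over random edge insertions."""
    rng = random.Random(seed)
    G = nx.Graph()
    G.add_nodes_from(f"v{i}" for i in range(1, n_vertices + 1))
    pairs = list(itertools.combinations(sorted(G.nodes), 2))
    rng.shuffle(pairs)
    for a, b in pairs:
        if G.degree[a] >= 3 or G.degree[b] >= 3:
            continue
        G.add_edge(a, b)
        if _graph_girth(G) <= girth_above:
            G.remove_edge(a, b)
    return G


def random_instance(kind: str, seed: int, n_matching: Optional[int] = None,
                    max_weight: int = 10) -> InstanceBundle:
    """Seeded random scaffold-graph families.

    ``cluster``: a random clique tree — clique sizes even with 1–4 matching
    edges each (2–8 vertices), intra-clique edges complete, one bridge
    between random vertices of child and parent cliques — with integer
    weights i.i.d. uniform on ``[0, max_weight]`` on every link edge.
    ``complete``: complete graph on ``2 n`` vertices with a random perfect
    matching and i.i.d. integer weights.
    ``subcubic_trianglefree``: a Construction-1 scaffold graph built from a
    random subcubic triangle-free source (provenance records the source).
    Deterministic given ``seed``.
    """
    rng = random.Random(f"{kind}:{seed}")
    if n_matching is None:
        n_matching = rng.randint(4, 8)
    if kind == "cluster":
        counts: List[int] = []
        remaining = n_matching
        while remaining:
            c = rng.randint(1, min(4, remaining))
            counts.append(c)
            remaining -= c
        g = ScaffoldGraph()
        clique_verts: List[List[str]] = []
        for ci, cnt in enumerate(counts):
            verts = [f"c{ci:02d}v{j:02d}" for j in range(2 * cnt)]
            shuffled = verts[:]
            rng.shuffle(shuffled)
            for a, b in zip(shuffled[::2], shuffled[1::2]):
                g.add_matching_edge(a, b)
            for a, b in itertools.combinations(verts, 2):
                if not g.has_edge(a, b):
                    g.add_link_edge(a, b, rng.randint(0, max_weight))
            if ci > 0:
                parent = rng.randrange(ci)
                door = rng.choice(clique_verts[parent])
                upper = rng.choice(verts)
                g.add_link_edge(door, upper, rng.randint(0, max_weight))
            clique_verts.append(verts)
        prov = {"generator": "random_cluster", "seed": seed,
                "clique_matching_counts": counts}
    elif kind == "complete":
        verts = [f"v{j:02d}" for j in range(2 * n_matching)]
        shuffled = verts[:]
        rng.shuffle(shuffled)
        g = ScaffoldGraph()
        for a, b in zip(shuffled[::2], shuffled[1::2]):
            g.add_matching_edge(a, b)
        for a, b in itertools.combinations(verts, 2):
            if not g.has_edge(a, b):
                g.add_link_edge(a, b, rng.randint(0, max_weight))
        prov = {"generator": "random_complete", "seed": seed}
    elif kind == "subcubic_trianglefree":
        src = random_subcubic_trianglefree(seed, n_vertices=rng.randint(3, 6))
        bundle = construction_sparse(src, ell=3)
        bundle.provenance.update({"generator": "random_subcubic_trianglefree", "seed": seed})
        return bundle
    else:
        raise ValueError(f"unknown random instance kind {kind!r}")
    p = Parameters(sigma_p=max(1, n_matching - 2), sigma_c=0)
    return InstanceBundle(graph=g, params=p, provenance=prov)


def cluster_shape_family(max_cliques: int = 3,
                         matching_sizes: Sequence[int] = (1, 2, 3),
                         door_positions: Sequence[int] = (0, -1)
                         ) -> Iterable[InstanceBundle]:
    """Every rooted clique-tree shape with up to ``max_cliques`` cliques of
    the given per-clique matching-edge counts, over a small set of bridge
    attachment points (vertex indices within each clique, negative = from
    the end).  Weights are the link index modulo 3, so optima are nontrivial
    but deterministic.  Used to validate the feasibility DP exhaustively.
    """
    def build(sizes: Sequence[int], tree: Sequence[Tuple[int, int]],
              attach: Sequence[Tuple[int, int]]) -> Optional[InstanceBundle]:
        g = ScaffoldGraph()
        verts: List[List[str]] = []
        w = 0
        for ci, cnt in enumerate(sizes):
            vs = [f"c{ci}v{j}" for j in range(2 * cnt)]
            verts.append(vs)
            for a, b in zip(vs[::2], vs[1::2]):
                g.add_matching_edge(a, b)
            for a, b in itertools.combinations(vs, 2):
                if not g.has_edge(a, b):
                    g.add_link_edge(a, b, w % 3)
                    w += 1
        for (pi, ci), (dp_, up) in zip(tree, attach):
            door = verts[pi][dp_ % len(verts[pi])]
            upper = verts[ci][up % len(verts[ci])]
            g.add_link_edge(door, upper, w % 3)
            w += 1
        return InstanceBundle(
            graph=g, params=Parameters(sum(sizes), 0),
            provenance={"generator": "cluster_shape_family", "sizes": list(sizes),
                        "tree": list(tree), "attach": list(attach)})

    for n_cliques in range(1, max_cliques + 1):
        trees: List[List[Tuple[int, int]]]
        if n_cliques == 1:
            trees = [[]]
        elif n_cliques == 2:
            trees = [[(0, 1)]]
        else:
            trees = [[(0, 1), (1, 2)], [(0, 1), (0, 2)]]  # chain and star
        for sizes in itertools.product(matching_sizes, repeat=n_cliques):
            for tree in trees:
                for attach in itertools.product(
                        itertools.product(door_positions, door_positions),
                        repeat=len(tree)):
                    bundle = build(sizes, tree, attach)
                    if bundle is not None:
                        yield bundle


def random_feasible_parameters(g: ScaffoldGraph, seed: int,
                               feasibility) -> Parameters:
    """Uniformly pick a feasible ``(sigma_p, sigma_c)`` for ``g``."""
    rng = random.Random(seed)
    n = g.n_matching()
    empty = PartialSolution()
    options = [Parameters(sp, sc)
               for sc in range(n // 2 + 1)
               for sp in range(n - 2 * sc + 1)]
    feasible = [p for p in options if feasibility(g, empty, p)]
    if not feasible:
        raise ValueError("no feasible parameter pair exists")
    return rng.choice(feasible)
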