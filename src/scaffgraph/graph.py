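"""Scaffold-graph data model, validation, solution decomposition and I/O.

A *scaffold graph* is a simple loopless graph ``G*`` together with a perfect
matching ``M*`` and a weight function on the non-matching ("link") edges.
Vertices model contig extremities, matching edges model contigs, and a link
edge ``uv`` carries the confidence that extremity ``v`` follows extremity
``u`` in the genome.  A solution of the scaffolding problem is a set ``S`` of
link edges such that ``S ∪ M*`` decomposes into exactly ``sigma_p``
alternating paths (linear chromosomes) and ``sigma_c`` alternating cycles
(circular chromosomes); path/cycle edges alternate between matching and link
edges and the extremal edges of a path are matching edges.  A matching edge
untouched by ``S`` counts as an alternating path of length one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

__all__ = [
    "Edge",
    "ScaffoldGraph",
    "Parameters",
    "PartialSolution",
    "SolutionDecomposition",
    "ValidationReport",
    "edge",
    "validate_graph",
    "decompose_solution",
    "alternating_girth",
    "solution_is_valid",
    "read_graph_tsv",
    "write_graph_tsv",
    "read_solution",
    "write_solution",
]

Edge = FrozenSet[str]
Weight = Fraction


def edge(u: str, v: str) -> Edge:
    """Unordered vertex pair; the canonical edge identity everywhere."""
    if u == v:
        raise ValueError(f"loop edge {u!r}-{v!r} is not allowed")
    return frozenset((u, v))


def _sorted_pair(e: Edge) -> Tuple[str, str]:
    a, b = sorted(e)
    return a, b


def as_weight(value: Union[int, float, str, Fraction]) -> Weight:
    """Coerce a user-supplied weight to an exact non-negative rational."""
    w = Fraction(value) if not isinstance(value, float) else Fraction(str(value))
    if w < 0:
        raise ValueError(f"negative weight {value!r}: weights must be non-negative")
    return w


@dataclass(frozen=True)
class Parameters:
    """Required numbers of alternating paths and alternating cycles.

    ``sigma_p`` is the number of linear chromosomes sought, ``sigma_c`` the
    number of circular ones.  ``sigma_p + 2*sigma_c <= |M*|`` is necessary for
    feasibility since a cycle consumes at least two matching edges and a path
    at least one.
    """

    sigma_p: int
    sigma_c: int

    def __post_init__(self) -> None:
        if self.sigma_p < 0 or self.sigma_c < 0:
            raise ValueError("sigma_p and sigma_c must be non-negative")

    def within_bounds(self, n_matching: int) -> bool:
        return self.sigma_p + 2 * self.sigma_c <= n_matching


@dataclass(frozen=True)
class PartialSolution:
    """A set of chosen link edges whose union with ``M*`` is a disjoint
    collection of alternating paths and cycles."""

    edges: FrozenSet[Edge] = frozenset()

    @staticmethod
    def from_pairs(pairs: Iterable[Tuple[str, str]]) -> "PartialSolution":
        return PartialSolution(frozenset(edge(u, v) for u, v in pairs))

    def __or__(self, e: Edge) -> "PartialSolution":
        return PartialSolution(self.edges | {e})

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, e: Edge) -> bool:
        return e in self.edges


class ScaffoldGraph:
    """Simple loopless graph with a perfect matching and weighted link edges."""

    def __init__(
        self,
        matching_edges: Iterable[Tuple[str, str]] = (),
        link_edges: Union[Mapping[Tuple[str, str], Union[int, float, str, Fraction]],
                          Iterable[Tuple[str, str, Union[int, float, str, Fraction]]]] = (),
    ) -> None:
        self.matching_edges: Set[Edge] = set()
        self.weight: Dict[Edge, Weight] = {}
        self.matched_with: Dict[str, str] = {}
        self._adj: Dict[str, Set[str]] = {}
        for u, v in matching_edges:
            self.add_matching_edge(u, v)
        items = link_edges.items() if isinstance(link_edges, Mapping) else (
            ((u, v), w) for u, v, w in link_edges)
        for (u, v), w in items:
            self.add_link_edge(u, v, w)

    # -- construction ------------------------------------------------------
    def add_matching_edge(self, u: str, v: str) -> None:
        e = edge(u, v)
        if e in self.matching_edges or e in self.weight:
            raise ValueError(f"duplicate edge {sorted(e)}")
        for x in (u, v):
            if x in self.matched_with:
                raise ValueError(f"vertex {x!r} would be in two matching edges")
        self.matching_edges.add(e)
        self.matched_with[u] = v
        self.matched_with[v] = u
        self._adj.setdefault(u, set()).add(v)
        self._adj.setdefault(v, set()).add(u)

    def add_link_edge(self, u: str, v: str, w: Union[int, float, str, Fraction] = 0) -> None:
        e = edge(u, v)
        if e in self.matching_edges or e in self.weight:
            raise ValueError(f"duplicate edge {sorted(e)}")
        self.weight[e] = as_weight(w)
        self._adj.setdefault(u, set()).add(v)
        self._adj.setdefault(v, set()).add(u)

    def copy(self) -> "ScaffoldGraph":
        g = ScaffoldGraph()
        g.matching_edges = set(self.matching_edges)
        g.weight = dict(self.weight)
        g.matched_with = dict(self.matched_with)
        g._adj = {v: set(nb) for v, nb in self._adj.items()}
        return g

    # -- queries -----------------------------------------------------------
    @property
    def vertices(self) -> Set[str]:
        return set(self._adj)

    @property
    def link_edges(self) -> Set[Edge]:
        return set(self.weight)

    def all_edges(self) -> Set[Edge]:
        return self.matching_edges | set(self.weight)

    def n_matching(self) -> int:
        return len(self.matching_edges)

    def neighbors(self, v: str) -> Set[str]:
        return self._adj.get(v, set())

    def link_neighbors(self, v: str) -> List[str]:
        return [u for u in self._adj.get(v, set()) if edge(u, v) in self.weight]

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._adj.get(u, set())

    def is_complete(self) -> bool:
        n = len(self._adj)
        return all(len(nb) == n - 1 for nb in self._adj.values())

    def total_weight(self, edges: Iterable[Edge]) -> Weight:
        return sum((self.weight[e] for e in edges), Fraction(0))

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, ScaffoldGraph)
                and self.matching_edges == other.matching_edges
                and self.weight == other.weight)

    def __repr__(self) -> str:
        return (f"ScaffoldGraph(|V|={len(self._adj)}, |M*|={len(self.matching_edges)}, "
                f"links={len(self.weight)})")


@dataclass
class ValidationReport:
    ok: bool
    violations: List[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def validate_graph(g: ScaffoldGraph) -> ValidationReport:
    """Diagnostic check of the scaffold-graph invariants.

    Reports (rather than raises) every violation: odd order, unmatched
    vertices, overlap between matching and link edges, weights outside the
    link-edge set.  Most structural violations are already unrepresentable in
    :class:`ScaffoldGraph`, which this function double-checks.
    """
    violations: List[str] = []
    if len(g.vertices) % 2 == 1:
        violations.append("odd number of vertices: no perfect matching possible")
    for v in sorted(g.vertices):
        if v not in g.matched_with:
            violations.append(f"vertex {v!r} is not covered by the matching")
    for e in g.matching_edges:
        if e in g.weight:
            violations.append(f"edge {_sorted_pair(e)} is both matching and link")
    for e, w in g.weight.items():
        if w < 0:
            violations.append(f"link edge {_sorted_pair(e)} has negative weight {w}")
    seen = {}
    for e in g.matching_edges:
        for v in e:
            if seen.setdefault(v, e) != e:
                violations.append(f"vertex {v!r} lies in two matching edges")
    return ValidationReport(not violations, violations)


@dataclass
class SolutionDecomposition:
    """Connected components of ``S ∪ M*`` as explicit vertex sequences."""

    paths: List[Tuple[str, ...]]
    cycles: List[Tuple[str, ...]]
    total_weight: Weight

    @property
    def sigma_p_of(self) -> int:
        return len(self.paths)

    @property
    def sigma_c_of(self) -> int:
        return len(self.cycles)

    @property
    def cardinality(self) -> int:
        return len(self.paths) + len(self.cycles)


def _check_partial(g: ScaffoldGraph, s: PartialSolution) -> Dict[str, List[str]]:
    """Link-adjacency of the partial solution; raises on structural errors."""
    incid: Dict[str, List[str]] = {}
    for e in s.edges:
        if e not in g.weight:
            raise ValueError(f"solution edge {_sorted_pair(e)} is not a link edge of the graph")
        u, v = _sorted_pair(e)
        for x, y in ((u, v), (v, u)):
            incid.setdefault(x, []).append(y)
            if len(incid[x]) > 1:
                raise ValueError(f"vertex {x!r} is incident to two solution edges")
    return incid


def decompose_solution(g: ScaffoldGraph, s: PartialSolution,
                       cover_all: bool = True) -> SolutionDecomposition:
    """Decompose ``s ∪ M*`` into alternating paths and cycles.

    With ``cover_all`` every matching edge untouched by ``s`` is emitted as a
    length-one path, so the decomposition covers all of ``M*`` and the number
    of link edges used equals ``|M*| - sigma_p_of`` whenever no cycles are
    double counted.  Paths start and end with a matching edge by
    construction; cycles are rotated so the lexicographically smallest vertex
    comes first, followed by its smaller neighbour, making output canonical.
    """
    incid = _check_partial(g, s)
    touched = set(incid)
    seen: Set[str] = set()
    paths: List[Tuple[str, ...]] = []
    cycles: List[Tuple[str, ...]] = []

    def walk(start: str) -> Tuple[Tuple[str, ...], bool]:
        # Alternate matching edge / solution link edge, starting with matching.
        seq = [start]
        v, use_matching = start, True
        while True:
            if use_matching:
                nxt: Optional[str] = g.matched_with[v]
            else:
                cand = incid.get(v, [])
                nxt = cand[0] if cand else None
            if nxt is None:
                return tuple(seq), False
            if nxt == start:
                return tuple(seq), True
            seq.append(nxt)
            v, use_matching = nxt, not use_matching

    # path components: start from a vertex with no solution edge (free end)
    for start in sorted(g.vertices):
        if start in seen or start in touched:
            continue
        if not cover_all and g.matched_with[start] not in touched:
            continue
        seq, closed = walk(start)
        assert not closed, "free-end walk must terminate at a free end"
        if seq[-1] < seq[0]:
            seq = tuple(reversed(seq))
        seen.update(seq)
        paths.append(seq)
    # cycle components: every remaining touched vertex lies on a cycle
    for start in sorted(g.vertices):
        if start in seen or start not in touched:
            continue
        seq, closed = walk(start)
        if not closed:
            raise ValueError(f"component through {start!r} is not alternating")
        # canonical rotation: smallest vertex first, smaller neighbour second
        i = seq.index(min(seq))
        seq = seq[i:] + seq[:i]
        if len(seq) > 2 and seq[-1] < seq[1]:
            seq = (seq[0],) + tuple(reversed(seq[1:]))
        seen.update(seq)
        cycles.append(tuple(seq))
    paths.sort()
    cycles.sort()
    return SolutionDecomposition(paths, cycles, g.total_weight(s.edges))


def solution_is_valid(g: ScaffoldGraph, s: PartialSolution, p: Parameters) -> bool:
    """True iff ``s`` decomposes ``(G*, M*)`` into exactly ``p.sigma_p``
    alternating paths and ``p.sigma_c`` alternating cycles."""
    d = decompose_solution(g, s, cover_all=True)
    return d.sigma_p_of == p.sigma_p and d.sigma_c_of == p.sigma_c


def alternating_girth(g: ScaffoldGraph, cap: Optional[int] = None) -> Union[int, float]:
    """Matching-edge count of the smallest alternating cycle, ``inf`` if none.

    Exhaustive DFS over alternating closed walks, pruned by the best cycle
    found so far; exact on the sparse instances this package generates.
    """
    best = cap if cap is not None else float("inf")
    order = {v: i for i, v in enumerate(sorted(g.vertices))}

    def dfs(start: str, v: str, used: Set[str], length: int) -> None:
        nonlocal best
        # v is the "exit" endpoint after traversing a matching edge
        for u in g.link_neighbors(v):
            if u == start and length >= 2:
                best = min(best, length)
                continue
            if u in used or order[u] < order[start]:
                continue
            w = g.matched_with[u]
            if w in used or length + 1 >= best:
                continue
            used.add(u)
            used.add(w)
            dfs(start, w, used, length + 1)
            used.discard(u)
            used.discard(w)

    for a in sorted(g.vertices, key=order.get):
        b = g.matched_with[a]
        if order[b] < order[a]:
            continue
        dfs(a, b, {a, b}, 1)
    return best if best != float("inf") else float("inf")


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_graph_tsv(path_or_lines: Union[str, Iterable[str]]) -> ScaffoldGraph:
    """Read the scaffold-graph TSV dialect.

    One edge per line, ``u<TAB>v<TAB>kind[<TAB>weight]`` with kind ``M``
    (matching) or ``L`` (link, weight required); ``#`` starts a comment.
    Duplicate pairs and negative weights are rejected.
    """
    if isinstance(path_or_lines, str):
        with open(path_or_lines, "r", encoding="utf-8") as fh:
            lines = fh.readlines()
    else:
        lines = list(path_or_lines)
    g = ScaffoldGraph()
    for no, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"line {no}: expected u<TAB>v<TAB>kind[<TAB>weight]")
        u, v, kind = parts[0], parts[1], parts[2]
        if not u or not v or any(ch.isspace() for ch in u + v):
            raise ValueError(f"line {no}: vertex names must be non-empty, no whitespace")
        if kind == "M":
            g.add_matching_edge(u, v)
        elif kind == "L":
            if len(parts) < 4:
                raise ValueError(f"line {no}: link edge requires a weight")
            g.add_link_edge(u, v, parts[3])
        else:
            raise ValueError(f"line {no}: unknown edge kind {kind!r}")
    return g


def write_graph_tsv(g: ScaffoldGraph, path: Optional[str] = None) -> str:
    out = ["# scaffold graph: u\tv\tkind\t[weight]"]
    for e in sorted(g.matching_edges, key=_sorted_pair):
        u, v = _sorted_pair(e)
        out.append(f"{u}\t{v}\tM")
    for e in sorted(g.weight, key=_sorted_pair):
        u, v = _sorted_pair(e)
        out.append(f"{u}\t{v}\tL\t{g.weight[e]}")
    text = "\n".join(out) + "\n"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def write_solution(d: SolutionDecomposition, path: Optional[str] = None) -> str:
    out = [("P " + " ".join(p)) for p in d.paths]
    out += [("C " + " ".join(c)) for c in d.cycles]
    out.append(f"# sigma_p={d.sigma_p_of} sigma_c={d.sigma_c_of} weight={d.total_weight}")
    text = "\n".join(out) + "\n"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def read_solution(path_or_lines: Union[str, Iterable[str]]) -> PartialSolution:
    """Read a solution text file back into the set of its link edges.

    Link edges are every second edge along each listed element (the extremal
    edges of paths are matching edges and are skipped)."""
    if isinstance(path_or_lines, str):
        with open(path_or_lines, "r", encoding="utf-8") as fh:
            lines = fh.readlines()
    else:
        lines = list(path_or_lines)
    edges: Set[Edge] = set()
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        kind, *verts = line.split()
        if kind not in ("P", "C"):
            raise ValueError(f"unknown element kind {kind!r}")
        for i in range(1, len(verts) - 1, 2):
            edges.add(edge(verts[i], verts[i + 1]))
        if kind == "C" and len(verts) >= 2:
            edges.add(edge(verts[-1], verts[0]))
    return PartialSolution(frozenset(edges))
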