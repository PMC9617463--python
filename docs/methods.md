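# Methods

## Problem

A *scaffold graph* `(G*, M*, ω)` models the contig-ordering stage of genome
assembly: vertices are contig extremities, the perfect matching `M*` pairs
the two extremities of each contig, and a non-matching ("link") edge `uv`
with weight `ω(uv) ≥ 0` records the paired-read evidence that extremity `v`
follows extremity `u` in the genome.  A genome with `σp` linear and `σc`
circular chromosomes corresponds to a set `S` of link edges such that
`S ∪ M*` decomposes into exactly `σp` alternating paths and `σc` alternating
cycles — edges alternate between `M*` and `S`, path extremal edges lie in
`M*`, and a matching edge untouched by `S` counts as a length-one path.
The optimization problem asks for such an `S` of maximum total weight.
Every full solution uses exactly `|M*| − σp` link edges (each path of `k`
contigs uses `k−1` links, each cycle `k`), a structural law asserted
throughout the test suite.

## Greedy algorithm

`greedy_scaffold` scans link edges once in non-increasing weight order
(ties: lexicographic on the sorted endpoint pair) and accepts an edge iff
(i) both endpoints are free, (ii) the components of `S ∪ M*` remain paths
and cycles, and (iii) a *feasibility function* confirms that `S ∪ {e}` still
extends to exactly `(σp, σc)`.  On acceptance all other link edges at the
two endpoints are discarded.  Feasibility is downward monotone (dropping an
edge from a feasible set stays feasible), so when the empty set is feasible
the scan necessarily terminates with a complete valid solution and no repair
phase is needed; the implementation still verifies the final counts and
would fail loudly on a non-monotone guard.

Known behaviour, all reproduced computationally in the tests: the ratio
optimum/greedy is at most 3 on complete graphs and at most 5 on connected
cluster graphs; ratio 5 is attained by the shipped tightness witness; and on
2×k grids an adversarial weighting forces ratio `k−1`, so no constant bound
exists for general sparse graphs.

## Feasibility on complete graphs

On a complete graph only the component statistics of `S ∪ M*` matter:
`c` cycles already closed, `P` path components, of which `a` hold a single
matching edge and `b = P − a` hold at least two.  Components can only merge,
close, or stay.  With `k = σc − c` cycles still owed, feasibility is:

* `k ≥ 0` and `P ≥ σp + k` (components never split);
* `σp + k ≥ 1` unless `P = 0` (leftover components must merge somewhere);
* after filling path slots with single-contig components first
  (`a₁ = max(0, a − σp)` singles and `b₁ = b − max(0, σp − a)` multis
  remain), every cycle slot not covered by a multi-contig component takes a
  *pair* of singles: if `b₁ < k` then `a₁ ≥ 2(k − b₁)`.

The pairing condition is needed because a single matching edge can never
close into a cycle alone (a 2-vertex cycle would need a doubled edge).  A
simpler count-only predicate (`m_paths ≥ σp + 2k`) misses this: chaining
three contigs into one path and leaving one untouched satisfies the counts
for `(σp, σc) = (0, 2)` yet is infeasible.  The predicate is validated
against the exhaustive oracle over all parameter pairs and random partial
solutions on complete graphs with up to six matching edges.

## Feasibility on connected cluster graphs

A connected cluster graph splits as `E(G*) = E′ ∪ B`: `E′` induces disjoint
cliques, every `b ∈ B` is a bridge, and contracting cliques yields a tree.
A matching edge that happens to be a graph bridge is treated as a 2-vertex
clique of `E′`, never as a `B`-edge; only when a matching bridge joins two
larger components is the instance outside the class (completion then merges
the two sides into one clique).  The tree is rooted at the clique holding
the lexicographically smallest vertex (any root is valid; this one is
deterministic); each non-root clique has a unique *upper door* adjacent to
its parent.

The DP walks the rooted tree bottom-up over four scope types — vertex
branch `G*(v)`, alternating element `G*(e)`, subclique, clique — and stores
*entry vectors*: for each cycle count `i ∈ [0, σc]` the set of path counts
achievable by a partial solution of the scope consistent with the initiating
set `S` (base cases: empty solution `{0}` at `i=0`; one path `{1}` at `i=0`;
one cycle `{0}` at `i=1`).  Sets are explicit; eligible path counts often
form intervals, but contiguity is not assumed.  Vectors combine by four operations,
convolutions over the cycle index with small shifts: juxtaposition (no
shift), merge of `t` paths into one (paths `−(t−1)`), closing `t` paths into
a cycle (paths `−t`, cycles `+1` — the empty vector when `σc` leaves no
budget), and absorption of a path into a removable link edge (paths `−1`).

Scope rules:

* **Vertex** `v`: leaf ⇒ frozen = empty-solution base.  Otherwise frozen
  juxtaposes any child-clique class; extensible picks one child whose
  extensible solution is merged through the bridge — the path's endpoint
  relocates to `v` and the count is unchanged (the element level later
  charges the `−1` when the pending path fuses with `v`'s element).  A
  bridge edge in `S` forces the extensible case; two `S`-bridges at one
  vertex are rejected.
* **Element** `e` (component of `(S ∩ clique) ∪ M*`): a cycle element is
  frozen, juxtaposing the inner vertices' frozen vectors with the cycle
  base.  A path element with extremities `u, v` is closeable when both
  stay free, extensible when exactly one is consumed from below, frozen
  when both are — or when the element self-closes through the clique chord,
  which requires at least two matching edges (a single contig has no chord).
* **Subclique / root accumulation**: elements are composed one at a time,
  each step applying at most one cross operation between the accumulated
  solution and the new element.  The accumulated state is `(k, ext, abs)`:
  the exact number `k` of closeable paths (each later merge/close/absorb
  consumes one, so presence alone is not enough), plus saturating flags for
  an extensible path and an absorbable edge.  Extensible multiplicity and
  absorbable-edge lifetime do not need exact tracking: any solution using
  two extensible paths, or absorbing into an edge that later sits on a
  cycle, is reachable at the same cardinality by a reordered derivation the
  state machine keeps (e.g. merging the two extensible paths at their own
  steps, or splicing before closing).  These canonicalizations — and every
  transition — are contracted to the exhaustive oracle, which arbitrates
  all reconstruction ambiguity: the suite checks boolean and *set-level*
  equality of the root vector against full enumeration, order-invariance of
  the accumulation under element permutations, and downward monotonicity.
* **Clique**: only the upper door's fate survives the bridge, so the clique
  table has frozen (door consumed) and extensible (door free) classes; the
  door element is composed with the accumulated subclique states by at most
  one operation, and which element end the operation touches decides the
  class.

The per-call cost is `O(|V| · σc² · k_max²)` with `k_max` bounded by the
largest clique's matching count; tables are memoized within a call and
recomputed across calls.

## Exact oracles

`enumerate_solutions` backtracks over the components of `S ∪ M*`, building
the complete final element containing the first open component before
recursing, growing first from one designated end (cycles close only in that
phase), which yields every solution exactly once — the 4-cycle instance's
solution counts are asserted by hand.  `brute_force_feasible` is this
enumeration with early exit.  `brute_force_optimum` uses an exact dynamic
program over matching-edge subsets (best single-chain weight per subset and
end pair, then a partition DP with exact path/cycle counts and witness
reconstruction) up to 12 matching edges, and above that branch-and-bound
enumeration whose admissible bound sums the positive link weights still
joinable; components adjacent to positive weight are processed first so the
bound binds early.  Both optimum routes are cross-checked against each
other on small instances.  Size caps refuse loudly and are raised
explicitly for the structured reduction instances.

## Instance generators

* `construction_sparse(G, ℓ)` (independent-set reduction, girth `ℓ ≥ 3`):
  one matching edge per edge of the subcubic input `G` (girth > `ℓ`), and
  `ℓ − deg(v)` padding matching edges per vertex `v`, wired into one
  alternating *vertex-cycle* of exactly `ℓ` matching edges per vertex, with
  all link edges running between the `u`- and `ub`-sides (bipartite).
  The padding count `ℓ − deg` is exactly what gives every vertex-cycle
  `ℓ` matching edges; the reduction equivalence `k` cycles ⇔ independent
  set of size `k` is verified exhaustively.
* `construction_polyapx(G)` (S-reduction from maximum independent set): a
  6-vertex clique per edge, a 4-cycle per vertex, and a weight-one *long
  vertex-cycle* per vertex; optimum weight at `(σp, σc) = (0, |V|+|E|)`
  equals the maximum independent-set size.  The weight-one edge is the
  closing edge `v₂–ūⱼ` of each long vertex-cycle; for an isolated vertex
  the long cycle degenerates to its 4-cycle, which gets the weight-one edge
  instead — that cycle is forced in any `σp = 0` solution, matching the
  fact that an isolated vertex lies in every maximum independent set.
* `grid_2xk(k)`: the 2×k grid with vertical matching edges; the adversarial
  weighting puts weight 1 on `x1x2` and on the optimum, 0 elsewhere, so the
  greedy (which takes `x1x2` first under the default tie-break) scores 1
  against `k−1`.
* `tightness_witness()`: cliques `{a..f}, {g,h}, {i,j,k,l}, {m,n,o,p}` with
  bridges `a–g`, `c–i`, `j–m`, `(σp, σc) = (3, 0)`, weight 1 on `ac` and on
  the designated optimum `{ae, bd, ci, jk, mo}`.  Only the cliques, the
  parameters and the weight scheme are fixed a priori; the bridge
  placement and optimum were found by computer search over configurations
  consistent with that scheme such that after `ac` every
  remaining weight-one edge is incident-blocked or infeasible, and the
  1-versus-5 outcome is verified by computation, which is the property the
  witness exists to certify.
* `random_instance`: seeded families used as fixtures — connected cluster
  graphs (random clique trees, 1–4 matching edges per clique, one bridge
  per child between uniformly chosen vertices), complete graphs with a
  random perfect matching, and subcubic triangle-free sources by rejection
  sampling.  Link weights are i.i.d. integers uniform on `[0, 10]`,
  matching the acceptance protocol; all generators are deterministic given
  their seed.

## What the synthetic data does and does not show

The random families exercise the combinatorial structure the algorithms
operate on (clique trees, bridges, weight ties, partial solutions) at sizes
where the exhaustive oracle can certify every answer (≤ 6–8 matching
edges for the equivalence suites).  They do not emulate read-mapping noise,
repeat-induced edge ambiguity, or the size and sparsity of real assembly
graphs, so passing these suites certifies algorithmic correctness and the
theorem-backed ratio bounds at desk scale, not genome-scale accuracy or
runtime.  Building scaffold graphs from read alignments, and any
sequence-level output, are out of scope.

## Numerical and design choices

* Weights are exact rationals (`fractions.Fraction`); no floating-point
  comparisons occur anywhere in the solvers, so ties and ratio checks are
  exact.  Negative weights are rejected at construction and parse time.
* Vertices are opaque strings; contig pairing exists only through `M*`.
* Deterministic tie-breaks everywhere: edge scan order, DFS neighbour
  order, element order (sorted by smallest vertex), canonical cycle
  rotation in output.
* Completion adds zero-weight links only: each bridge-free component is
  completed to a clique, components joined by a matching bridge are merged
  first, disconnected components are pre-chained through their smallest
  vertices.  Any solution of the input remains a solution of the
  completion with the same weight, so the optimum never decreases.
* The ratio suites use 200 instances with 4–8 matching edges and a feasible
  parameter pair drawn uniformly per instance; the DP-correctness suite
  uses every clique-tree shape with up to three cliques of 2/4/6 vertices
  plus 500 random instances, all parameter pairs, and sampled partial
  solutions.  These sizes keep every expected value certifiable by
  exhaustive search.

## Known limitations

* The feasibility DP requires the connected cluster class; block graphs and
  sparser classes are not implemented (the CLI exposes `cluster`,
  `complete` and `oracle` guards only).
* The oracles are exponential and refuse beyond their caps; the subset DP
  is limited to 12 matching edges, and the branch-and-bound is practical
  only on structured sparse instances.
* The subclique accumulation tracks the closeable-path count exactly, so
  its table size grows with the largest clique's matching count — a
  constant-factor cost on the class-based formulation, accepted in exchange
  for oracle-exact bookkeeping.
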