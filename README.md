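# scaffgraph

Greedy genome scaffolding on connected cluster graphs: maximum-weight
alternating path/cycle covers of a scaffold graph under a perfect matching.

## The problem

After contig assembly, paired-read evidence about which contig extremities
are adjacent is summarized in a *scaffold graph* `(G*, M*, ω)`: vertices are
contig extremities, the perfect matching `M*` pairs the two extremities of
each contig, and each non-matching *link* edge `uv` carries a confidence
weight `ω(uv) ≥ 0`.  Scaffolding with `σp` linear and `σc` circular
chromosomes means choosing link edges `S` so that `S ∪ M*` decomposes into
exactly `σp` alternating paths and `σc` alternating cycles (edges alternate
between `M*` and `S`; path extremal edges are matching edges), maximizing
`ω(S)`.  Every full solution uses exactly `|M*| − σp` link edges.

The package is for people studying scaffolding algorithms: it implements

* the greedy scan that considers link edges in decreasing weight order and
  keeps an edge whenever a *feasibility function* confirms the partial
  solution still extends to exactly `(σp, σc)`;
* a constant-time feasibility predicate for complete scaffold graphs and a
  polynomial dynamic program for *connected cluster graphs* (cliques joined
  by bridges, the clique contraction being a tree) — with these guards the
  greedy is a 3-approximation on complete and a 5-approximation on cluster
  graphs, and the ratio 5 is tight;
* zero-weight completion of arbitrary scaffold graphs into either class;
* exact exponential-time oracles (feasibility, optimum, maximum independent
  set) that certify every polynomial component on small instances;
* generators for the hardness constructions (independent-set reductions
  with prescribed alternating girth, the Poly-APX-hardness S-reduction),
  the adversarial 2×k grid, the ratio-5 tightness witness, and seeded
  random instance families.

## Worked example

The tightness witness is a connected cluster graph on cliques
`{a..f}, {g,h}, {i,j,k,l}, {m,n,o,p}` (8 contigs) asking for 3 linear
chromosomes.  Weight 1 sits on the trap edge `ac` and on the five edges of
an optimal solution; everything else weighs 0:

```sh
$ scaffgraph generate tightness -o witness.tsv
wrote witness.tsv (sigma_p=3, sigma_c=0)

$ scaffgraph greedy witness.tsv --sigma-p 3 --sigma-c 0 --class cluster
P d c a b e f
P g h
P l k i j m n o p
# sigma_p=3 sigma_c=0 weight=1

$ scaffgraph exact witness.tsv --sigma-p 3 --sigma-c 0
optimum weight: 5
```

The greedy grabs `ac` first (highest weight, first in tie-break order) and
is then locked out of every other weight-one edge, finishing three paths of
total weight 1, while exhaustive search finds a weight-5 solution — the
worst case of the factor-5 guarantee, realized exactly.

The same objects are available as a library:

```python
from scaffgraph import (tightness_witness, cluster_feasibility,
                        greedy_scaffold, brute_force_optimum)

bundle = tightness_witness()
dec, trace = greedy_scaffold(bundle.graph, bundle.params,
                             cluster_feasibility(bundle.graph))
print(dec.total_weight)                                        # 1
print(brute_force_optimum(bundle.graph, bundle.params).best_weight)  # 5
```

Other entry points: `scaffgraph validate|girth|decompose|complete` for
inspection and class completion, `scaffgraph feasible|tables` for the
feasibility functions and their DP tables, `scaffgraph generate` for the
instance families, and `scaffgraph compare` for greedy-vs-optimum suites.
See `docs/methods.md` for the model, the DP state, and the design choices.

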