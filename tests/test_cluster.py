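"""Cluster-graph recognition, rooting, elements, and zero-weight completion."""

import itertools

import pytest

from scaffgraph.cluster import (NotClusterGraphError, alternating_elements_of,
                                build_cluster_structure, complete_to_class,
                                find_bridges)
from scaffgraph.graph import (Parameters, PartialSolution, ScaffoldGraph, edge,
                              validate_graph)
from scaffgraph.oracle import brute_force_optimum


def path4_graph():
    """Path on 4 vertices (2 matching edges at the ends, 1 link in between)."""
    return ScaffoldGraph([("a", "b"), ("c", "d")], [("b", "c", 1)])


class TestFindBridges:
    def test_bridge_between_cliques(self, bridged_k4s):
        assert find_bridges(bridged_k4s) == {edge("d", "e")}

    def test_k4_has_no_bridges(self):
        g = ScaffoldGraph([("a", "b"), ("c", "d")])
        for x, y in itertools.combinations("abcd", 2):
            if not g.has_edge(x, y):
                g.add_link_edge(x, y, 0)
        assert find_bridges(g) == set()

    def test_path_is_all_bridges(self):
        g = path4_graph()
        assert find_bridges(g) == {edge("a", "b"), edge("b", "c"), edge("c", "d")}

    def test_disconnected_input_rejected(self):
        g = ScaffoldGraph([("a", "b"), ("c", "d")])
        with pytest.raises(ValueError, match="connected"):
            find_bridges(g)


class TestBuildClusterStructure:
    def test_two_cliques_one_bridge(self, bridged_k4s):
        cs = build_cluster_structure(bridged_k4s)
        assert len(cs.cliques) == 2
        assert cs.bridges == {edge("d", "e")}
        child = next(c for c in cs.cliques if c != cs.root)
        assert cs.upper_door[child] == "e"
        assert cs.doors[cs.root] == {"d"}

    def test_default_root_holds_smallest_vertex(self, bridged_k4s):
        cs = build_cluster_structure(bridged_k4s)
        assert "a" in cs.cliques[cs.root]
        cs2 = build_cluster_structure(bridged_k4s, root_policy="h")
        assert "h" in cs2.cliques[cs2.root]

    def test_square_is_not_a_cluster_graph(self, square4):
        with pytest.raises(NotClusterGraphError, match="not adjacent"):
            build_cluster_structure(square4)

    def test_two_vertex_clique_matching_edge_is_not_a_bridge_of_B(self):
        # a pendant contig: its matching edge is a graph bridge but belongs
        # to its own 2-vertex clique, not to the bridge set B
        g = ScaffoldGraph([("a", "b"), ("c", "d")], [("b", "c", 1)])
        cs = build_cluster_structure(g)
        assert len(cs.cliques) == 2
        assert cs.bridges == {edge("b", "c")}

    def test_pendant_contig_across_bridges_is_its_own_clique(self):
        # a 2-vertex clique between two K4s: valid as-is, both its incident
        # link edges are bridges
        g = ScaffoldGraph([("a", "b"), ("c", "d"), ("e", "f"), ("g", "h"), ("x", "y")])
        for quad in (("a", "b", "c", "d"), ("e", "f", "g", "h")):
            for p, q in itertools.combinations(quad, 2):
                if not g.has_edge(p, q):
                    g.add_link_edge(p, q, 1)
        g.add_link_edge("d", "x", 1)
        g.add_link_edge("y", "e", 1)
        cs = build_cluster_structure(g)
        assert frozenset(("x", "y")) in set(cs.cliques.values())
        assert len(cs.cliques) == 3

    def test_matching_bridge_between_triangles_needs_completion(self):
        # contig c-d straddles two triangle components: the matching edge is
        # a bridge between non-trivial parts, so the class is only reached
        # after completion (which merges the two sides into one clique)
        g = ScaffoldGraph([("a", "b"), ("c", "d"), ("e", "f")],
                          [("a", "c", 1), ("b", "c", 1), ("d", "e", 1), ("d", "f", 1)])
        with pytest.raises(NotClusterGraphError, match="complete_to_class"):
            build_cluster_structure(g)
        completed = complete_to_class(g, "cluster")
        cs = build_cluster_structure(completed)
        assert len(cs.cliques) == 1  # merged into a single K6

    def test_clique_layout_of_tightness_witness(self):
        from scaffgraph.instances import tightness_witness
        cs = build_cluster_structure(tightness_witness().graph)
        families = sorted(tuple(sorted(v)) for v in cs.cliques.values())
        assert families == [tuple("abcdef"), tuple("ghij")[:2],
                            tuple("ijkl"), tuple("mnop")]


class TestAlternatingElements:
    def test_empty_solution_gives_single_edge_elements(self, bridged_k4s):
        cs = build_cluster_structure(bridged_k4s)
        elems, sub = alternating_elements_of(bridged_k4s, cs, cs.root, PartialSolution())
        assert sorted(e.vertices for e in elems) == [("a", "b"), ("c", "d")]
        assert all(not e.is_cycle and e.n_matching == 1 for e in elems)
        assert sub is None  # root has no upper door

    def test_subclique_excludes_upper_door_element(self, bridged_k4s):
        cs = build_cluster_structure(bridged_k4s)
        child = next(c for c in cs.cliques if c != cs.root)
        s = PartialSolution.from_pairs([("f", "g")])
        elems, sub = alternating_elements_of(bridged_k4s, cs, child, s)
        door_elem = next(e for e in elems if cs.upper_door[child] in e.vertices)
        assert sub.vertices == cs.cliques[child] - set(door_elem.vertices)

    def test_solution_edges_chain_into_one_element(self, bridged_k4s):
        cs = build_cluster_structure(bridged_k4s)
        s = PartialSolution.from_pairs([("b", "c")])
        elems, _ = alternating_elements_of(bridged_k4s, cs, cs.root, s)
        assert len(elems) == 1
        assert elems[0].vertices == ("a", "b", "c", "d")
        assert elems[0].inner_vertices == ("b", "c")

    def test_cycle_element_detected(self, bridged_k4s):
        cs = build_cluster_structure(bridged_k4s)
        s = PartialSolution.from_pairs([("b", "c"), ("a", "d")])
        elems, _ = alternating_elements_of(bridged_k4s, cs, cs.root, s)
        assert len(elems) == 1 and elems[0].is_cycle


class TestCompletion:
    def test_complete_graph_unchanged(self):
        g = ScaffoldGraph([("a", "b"), ("c", "d")])
        for x, y in itertools.combinations("abcd", 2):
            if not g.has_edge(x, y):
                g.add_link_edge(x, y, 2)
        assert complete_to_class(g, "complete") == g

    def test_square_completes_to_k4(self, square4):
        done = complete_to_class(square4, "cluster")
        assert done.is_complete()
        assert done.weight[edge("a", "c")] == 0 and done.weight[edge("b", "d")] == 0
        # original weights untouched
        assert done.weight[edge("b", "c")] == 1 and done.weight[edge("a", "d")] == 2
        build_cluster_structure(done)

    def test_cluster_graph_round_trips_identically(self, bridged_k4s):
        assert complete_to_class(bridged_k4s, "cluster") == bridged_k4s

    def test_disconnected_components_get_chained(self):
        g = ScaffoldGraph([("a", "b"), ("c", "d")])
        done = complete_to_class(g, "cluster")
        assert validate_graph(done).ok
        build_cluster_structure(done)
        assert all(w == 0 for w in done.weight.values())

    def test_completion_never_decreases_optimum(self, square4):
        p = Parameters(1, 0)
        before = brute_force_optimum(square4, p).best_weight
        for target in ("cluster", "complete"):
            after = brute_force_optimum(complete_to_class(square4, target), p).best_weight
            assert after >= before

    def test_completion_is_robust_on_random_instances(self):
        from scaffgraph.instances import random_instance
        for seed in range(12):
            g = random_instance("cluster", 40 + seed, n_matching=5).graph
            # drop some link edges to leave the class, then re-complete
            victims = sorted(g.weight, key=sorted)[::3]
            for e in victims:
                del g.weight[e]
                u, v = sorted(e)
                g._adj[u].discard(v)
                g._adj[v].discard(u)
            done = complete_to_class(g, "cluster")
            build_cluster_structure(done)  # must not raise
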