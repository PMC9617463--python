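"""Feasibility: entry-vector algebra, the cluster DP, the complete-graph
predicate — all contracted to the exhaustive oracle."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scaffgraph.cluster import build_cluster_structure
from scaffgraph.feasibility import (ClusterFeasibility, EntryVector, compose,
                                    feasible_cluster, feasible_complete)
from scaffgraph.graph import Parameters, PartialSolution
from scaffgraph.instances import random_instance
from scaffgraph.oracle import brute_force_feasible

from conftest import all_parameter_pairs, random_partial_solution

SC = 2  # cycle budget used for the algebra tests


def vec(*rows):
    return EntryVector([frozenset(r) for r in rows])


class TestEntryVectorBases:
    def test_empty_solution_base(self):
        assert EntryVector.base_empty_solution(SC) == vec({0}, (), ())

    def test_single_path_base(self):
        assert EntryVector.base_single_path(SC) == vec({1}, (), ())

    def test_single_cycle_base(self):
        assert EntryVector.base_single_cycle(SC) == vec((), {0}, ())

    def test_single_cycle_base_vanishes_without_cycle_budget(self):
        assert EntryVector.base_single_cycle(0).is_empty()


class TestCompose:
    def test_juxtapose_identity(self):
        v = vec({1, 3}, {0}, {2})
        assert compose("juxtapose", 1, [v, EntryVector.base_empty_solution(SC)]) == v

    def test_merge_two_single_paths(self):
        p = EntryVector.base_single_path(SC)
        assert compose("merge", 2, [p, p]) == vec({1}, (), ())

    def test_close_two_single_paths(self):
        p = EntryVector.base_single_path(SC)
        assert compose("close", 2, [p, p]) == vec((), {0}, ())

    def test_close_with_zero_cycle_budget_gives_empty_sets(self):
        p = EntryVector.base_single_path(0)
        assert compose("close", 2, [p, p]).is_empty()

    def test_absorb_drops_one_path(self):
        v = vec({2, 3}, (), ())
        c = EntryVector.base_single_path(SC)
        assert compose("absorb", 1, [v, c]) == vec({2, 3}, (), ())

    def test_negative_path_counts_are_discarded(self):
        p = EntryVector.base_single_path(SC)
        assert compose("merge", 4, [p, p]).is_empty()

    small_vectors = st.lists(
        st.frozensets(st.integers(min_value=0, max_value=4), max_size=3),
        min_size=SC + 1, max_size=SC + 1).map(EntryVector)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=small_vectors, b=small_vectors, c=small_vectors)
    def test_juxtapose_commutative_and_associative(self, a, b, c):
        ab = compose("juxtapose", 1, [a, b])
        ba = compose("juxtapose", 1, [b, a])
        assert ab == ba
        left = compose("juxtapose", 1, [ab, c])
        right = compose("juxtapose", 1, [a, compose("juxtapose", 1, [b, c])])
        assert left == right


class TestClusterDP:
    def test_single_contig(self, k2):
        cs = build_cluster_structure(k2)
        assert feasible_cluster(k2, cs, PartialSolution(), Parameters(1, 0))
        assert not feasible_cluster(k2, cs, PartialSolution(), Parameters(0, 1))

    def test_path_through_bridge(self, bridged_k4s):
        cs = build_cluster_structure(bridged_k4s)
        assert feasible_cluster(bridged_k4s, cs, PartialSolution(), Parameters(1, 0))

    def test_oracle_equivalence_on_random_instances(self):
        """Primary contract: DP == exhaustive search, all parameter pairs,
        empty and random partial solutions."""
        for seed in range(25):
            rng = random.Random(seed)
            g = random_instance("cluster", 4000 + seed,
                                n_matching=rng.randint(2, 6)).graph
            cs = build_cluster_structure(g)
            sols = [PartialSolution(),
                    random_partial_solution(g, seed * 7 + 1),
                    random_partial_solution(g, seed * 7 + 2, accept_prob=0.6)]
            for s in sols:
                for p in all_parameter_pairs(g.n_matching()):
                    assert feasible_cluster(g, cs, s, p) == \
                        brute_force_feasible(g, s, p), (seed, sorted(map(sorted, s.edges)), p)

    def test_forced_bridge_edges_respected(self):
        for seed in range(10):
            g = random_instance("cluster", 5000 + seed, n_matching=5).graph
            cs = build_cluster_structure(g)
            bridges = sorted(cs.bridges, key=sorted)
            if not bridges:
                continue
            s = PartialSolution(frozenset(bridges[:1]))
            for p in all_parameter_pairs(5):
                assert feasible_cluster(g, cs, s, p) == brute_force_feasible(g, s, p)

    def test_downward_monotonicity(self):
        """If s ∪ {e} is feasible then s is feasible (same witness)."""
        for seed in range(8):
            g = random_instance("cluster", 6000 + seed, n_matching=5).graph
            cs = build_cluster_structure(g)
            s = random_partial_solution(g, seed, accept_prob=0.5)
            if not s.edges:
                continue
            smaller = PartialSolution(frozenset(sorted(s.edges, key=sorted)[1:]))
            for p in all_parameter_pairs(5):
                if feasible_cluster(g, cs, s, p):
                    assert feasible_cluster(g, cs, smaller, p)

    def test_element_order_invariance(self):
        """The accumulated subclique table must not depend on the order in
        which alternating elements are scanned."""
        from scaffgraph.cluster import alternating_elements_of
        for seed in (0, 3, 11):
            g = random_instance("cluster", 8000 + seed, n_matching=5).graph
            cs = build_cluster_structure(g)
            dp = ClusterFeasibility(g, cs, PartialSolution(),
                                    Parameters(0, g.n_matching() // 2))
            elements, _ = alternating_elements_of(g, cs, cs.root, PartialSolution())
            tabs = [dp.compute_alternating_element(e) for e in elements]
            rng = random.Random(seed)
            reference = None
            for _ in range(4):
                order = tabs[:]
                rng.shuffle(order)
                states = dp.accumulate_subclique(order)
                total = EntryVector.empty(dp.sc)
                for v in states.values():
                    total = total.union(v)
                if reference is None:
                    reference = total
                else:
                    assert total == reference

    def test_eligible_sets_match_enumerated_solution_counts(self):
        """Set-level contract: root vector row i equals the exact set of
        path counts among full solutions with i cycles."""
        from scaffgraph.oracle import enumerate_solutions
        for seed in range(6):
            g = random_instance("cluster", 900 + seed, n_matching=4).graph
            cs = build_cluster_structure(g)
            n = g.n_matching()
            dp = ClusterFeasibility(g, cs, PartialSolution(), Parameters(0, n // 2))
            rv = dp.root_vector()
            for i in range(n // 2 + 1):
                truth = set()
                for sp in range(n - 2 * i + 1):
                    for _ in enumerate_solutions(g, PartialSolution(), Parameters(sp, i)):
                        truth.add(sp)
                        break
                assert set(rv.sets[i]) == truth


class TestScopeTables:
    def test_leaf_vertex_table(self, bridged_k4s):
        """A vertex without children: frozen = the empty solution, no
        extensible solutions."""
        cs = build_cluster_structure(bridged_k4s)
        dp = ClusterFeasibility(bridged_k4s, cs, PartialSolution(), Parameters(1, 1))
        t = dp.compute_vertex("b")  # no child cliques hang below b
        assert t["F"] == EntryVector.base_empty_solution(1)
        assert t["E"].is_empty()

    def test_single_matching_edge_element_table(self, bridged_k4s):
        """A childless single-contig element is closeable with one path and
        nothing else."""
        from scaffgraph.cluster import alternating_elements_of
        cs = build_cluster_structure(bridged_k4s)
        dp = ClusterFeasibility(bridged_k4s, cs, PartialSolution(), Parameters(1, 1))
        elems, _ = alternating_elements_of(bridged_k4s, cs, cs.root, PartialSolution())
        elem = next(e for e in elems if e.vertices == ("a", "b"))
        t = dp.compute_alternating_element(elem)
        assert t["C"] == EntryVector.base_single_path(1)
        assert t["E"].is_empty() and t["F"].is_empty()

    def test_leaf_two_vertex_clique_table(self, bridged_k4s):
        """For a pendant contig clique the door is always a free path end:
        extensible {1}, frozen empty."""
        g = bridged_k4s.copy()
        g.add_matching_edge("y", "z")
        g.add_link_edge("h", "y", 0)
        cs = build_cluster_structure(g)
        dp = ClusterFeasibility(g, cs, PartialSolution(), Parameters(2, 0))
        leaf = next(c for c in cs.cliques if cs.cliques[c] == frozenset({"y", "z"}))
        t = dp.compute_clique(leaf)
        assert t["E"].sets[0] == {1}
        assert t["F"].is_empty()


class TestCompletePredicate:
    def test_requires_complete_graph(self, bridged_k4s):
        with pytest.raises(ValueError, match="complete"):
            feasible_complete(bridged_k4s, PartialSolution(), Parameters(1, 0))

    def test_three_contigs_one_cycle_one_path(self):
        g = random_instance("complete", 1, n_matching=3).graph
        assert feasible_complete(g, PartialSolution(), Parameters(1, 1))

    def test_two_contigs_cycle_counts(self):
        g = random_instance("complete", 2, n_matching=2).graph
        assert feasible_complete(g, PartialSolution(), Parameters(0, 1))
        assert not feasible_complete(g, PartialSolution(), Parameters(0, 2))

    def test_single_edge_component_cannot_close_alone(self):
        """A path holding one matching edge can never become a cycle by
        itself — the statistics must see it."""
        g = random_instance("complete", 3, n_matching=4).graph
        verts = sorted(g.vertices)
        # chain three contigs into one path, leave one untouched
        chain = []
        free = set(verts)
        import itertools
        ms = sorted(g.matching_edges, key=sorted)
        (a1, a2), (b1, b2), (c1, c2), _ = [tuple(sorted(e)) for e in ms]
        s = PartialSolution.from_pairs([(a2, b1), (b2, c1)])
        assert not feasible_complete(g, s, Parameters(0, 2))
        assert brute_force_feasible(g, s, Parameters(0, 2)) is False

    def test_oracle_equivalence_exhaustive(self):
        """Contract: predicate == exhaustive search on complete graphs up to
        six matching edges, over all parameters and random partials."""
        for seed in range(30):
            rng = random.Random(seed)
            g = random_instance("complete", 3000 + seed,
                                n_matching=rng.randint(1, 5)).graph
            sols = [PartialSolution(), random_partial_solution(g, seed + 1)]
            for s in sols:
                for p in all_parameter_pairs(g.n_matching()):
                    assert feasible_complete(g, s, p) == \
                        brute_force_feasible(g, s, p), (seed, p)
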