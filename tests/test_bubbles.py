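"""Bounded-branching shortest paths and bubble enumeration."""

from __future__ import annotations

import itertools
import random

import networkx as nx
import pytest

from repeatdbg.bubbles import (
    BubbleQuery,
    EnumerationStats,
    bounded_branching_shortest_paths,
    brute_force_bubbles,
    enumerate_all_bubbles,
    enumerate_bubbles_from,
    feasible,
    spell_bubble,
    spell_path,
)
from repeatdbg.graph import CompressedGraph, alternating_cycle, branching_vertices, build_graph, compress

from conftest import random_digraph, validate_bubble

INF = float("inf")


def dp_oracle(g: nx.DiGraph, s, beta: int, t) -> float:
    """Min path weight using <= beta branching vertices, by exhaustive search.

    The source is never counted; the final vertex is (matching the DP's
    bookkeeping, where the endpoint-exclusion adjustment happens later).
    """
    br = branching_vertices(g)
    best = INF if t != s else 0
    for path in nx.all_simple_paths(g, s, t):
        count = sum(1 for v in path[1:] if v in br)
        if count <= beta:
            w = sum(g.edges[u, v]["weight"] for u, v in zip(path, path[1:]))
            best = min(best, w)
    return best


class TestBoundedDP:
    def test_line_graph(self):
        g = nx.DiGraph()
        g.add_edge("s", "a", weight=1)
        g.add_edge("a", "t", weight=1)
        tab = bounded_branching_shortest_paths(g, "s", 0)
        assert tab.distance(0, "t") == 2

    def test_branching_vertex_consumes_budget(self):
        g = nx.DiGraph()
        g.add_edge("s", "v", weight=1)
        g.add_edge("x", "v", weight=1)  # makes v branching
        g.add_edge("v", "t", weight=1)
        tab = bounded_branching_shortest_paths(g, "s", 1)
        assert tab.distance(0, "t") == INF
        assert tab.distance(1, "t") == 2

    def test_source_distance_zero_for_all_budgets(self):
        g = random_digraph(7)
        tab = bounded_branching_shortest_paths(g, 0, 5)
        for beta in range(6):
            assert tab.distance(beta, 0) == 0

    def test_negative_weight_rejected(self):
        g = nx.DiGraph()
        g.add_edge("s", "t", weight=-1)
        with pytest.raises(ValueError):
            bounded_branching_shortest_paths(g, "s", 2)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_oracle(self, seed):
        g = random_digraph(seed, n_max=8, p=0.3)
        tab = bounded_branching_shortest_paths(g, 0, g.number_of_nodes())
        for t in g.nodes:
            for beta in range(g.number_of_nodes() + 1):
                assert tab.distance(beta, t) == dp_oracle(g, 0, beta, t), (t, beta)

    @pytest.mark.parametrize("seed", range(20))
    def test_unconstrained_budget_equals_dijkstra(self, seed):
        g = random_digraph(seed, n_max=12, p=0.3)
        n = g.number_of_nodes()
        tab = bounded_branching_shortest_paths(g, 0, n)
        dist = nx.single_source_dijkstra_path_length(g, 0)
        for v in g.nodes:
            assert tab.distance(n, v) == dist.get(v, INF)

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_in_budget(self, seed):
        g = random_digraph(seed)
        n = g.number_of_nodes()
        tab = bounded_branching_shortest_paths(g, 0, n)
        for v in g.nodes:
            ds = [tab.distance(beta, v) for beta in range(n + 1)]
            assert all(a >= b for a, b in zip(ds, ds[1:]))


class TestFeasible:
    def test_same_vertex_trivially_feasible(self, diamond):
        assert feasible(diamond, "a", "a", 0, 0, 0, 0)

    def test_disconnected_endpoints_infeasible(self):
        g = nx.DiGraph()
        g.add_edge("a", "b", weight=1)
        g.add_edge("c", "d", weight=1)
        assert not feasible(g, "a", "c", 10, 10, 5, 5)

    def test_diamond_midpoints_meet_at_target(self, diamond):
        assert feasible(diamond, "a", "b", 1, 1, 0, 0)

    def test_branching_endpoint_charges_pending_unit(self):
        # u2 is branching and must be traversed to reach the only common
        # target, which costs one unit the zero budget does not have
        g = nx.DiGraph()
        g.add_edge("u1", "t", weight=1)
        g.add_edge("u2", "t", weight=1)
        g.add_edge("x", "u2", weight=1)
        g.add_edge("u2", "y", weight=1)  # u2: out-degree 2 -> branching
        assert not feasible(g, "u1", "u2", 5, 5, 0, 0)
        assert feasible(g, "u1", "u2", 5, 5, 0, 1)


class TestEnumeration:
    def test_single_path_yields_nothing(self):
        g = nx.DiGraph()
        g.add_edge("s", "a", weight=1)
        g.add_edge("a", "t", weight=1)
        assert list(enumerate_bubbles_from(g, BubbleQuery("s", 5, 5, 2))) == []

    def test_diamond_single_bubble(self, diamond):
        out = list(enumerate_bubbles_from(diamond, BubbleQuery("s", 2, 2, 0)))
        assert len(out) == 1
        bub = out[0]
        assert {bub.path1, bub.path2} == {("s", "a", "t"), ("s", "b", "t")}
        assert (bub.len1, bub.len2) == (2, 2)

    def test_fan_three_bubbles(self, fan):
        out = list(enumerate_bubbles_from(fan, BubbleQuery("s", 2, 2, 0)))
        assert len(out) == 3

    def test_alternating_cycle_has_no_bubbles(self):
        for x in (2, 3, 6):
            assert list(enumerate_all_bubbles(alternating_cycle(x), 10, 10, 5)) == []

    def test_stacked_diamonds_two_bubbles(self):
        g = nx.DiGraph()
        arcs = [("s", "a"), ("s", "b"), ("a", "m"), ("b", "m"),
                ("m", "c"), ("m", "d"), ("c", "t"), ("d", "t")]
        for u, v in arcs:
            g.add_edge(u, v, weight=1)
        assert len(list(enumerate_all_bubbles(g, 4, 4, 5))) == 2

    def test_budget_gates_branching_bubble(self):
        # 'a' is branching (extra in-arc), so the bubble needs b >= 1
        g = nx.DiGraph()
        for u, v in [("s", "a"), ("s", "c"), ("a", "t"), ("c", "t"), ("x", "a")]:
            g.add_edge(u, v, weight=1)
        assert list(enumerate_bubbles_from(g, BubbleQuery("s", 2, 2, 0))) == []
        assert len(list(enumerate_bubbles_from(g, BubbleQuery("s", 2, 2, 1)))) == 1

    @pytest.mark.parametrize("seed", range(60))
    def test_equals_brute_force_and_no_barren_calls(self, seed):
        """Set equality with the exhaustive oracle; INV: zero barren calls."""
        g = random_digraph(seed)
        n = g.number_of_nodes()
        rng = random.Random(seed + 1000)
        a1 = rng.choice([3, 5, 8])
        a2 = a1 + rng.choice([0, 2, 4])
        for b in (0, 1, 2, n):
            q = BubbleQuery(0, a1, a2, b)
            stats = EnumerationStats()
            fast = list(enumerate_bubbles_from(g, q, stats=stats))
            assert stats.barren == 0
            for bub in fast:
                validate_bubble(bub, g, q)
            assert {x.key() for x in fast} == {
                x.key() for x in brute_force_bubbles(g, q)
            }
            assert len({x.key() for x in fast}) == len(fast), "duplicates"

    @pytest.mark.parametrize("seed", range(15))
    def test_monotone_in_budget_and_alpha(self, seed):
        g = random_digraph(seed)
        n = g.number_of_nodes()
        prev: set = set()
        for b in (0, 1, 2, n):
            cur = {x.key() for x in enumerate_bubbles_from(g, BubbleQuery(0, 6, 6, b))}
            assert prev <= cur
            prev = cur
        # at b >= |V| the budget is vacuous
        unconstrained = {
            x.key() for x in brute_force_bubbles(g, BubbleQuery(0, 6, 6, n))
        }
        assert prev == unconstrained
        small = {x.key() for x in enumerate_bubbles_from(g, BubbleQuery(0, 3, 4, 2))}
        large = {x.key() for x in enumerate_bubbles_from(g, BubbleQuery(0, 4, 6, 2))}
        assert small <= large

    def test_work_limit_truncates_stream(self):
        g = random_digraph(2, n_max=12, p=0.4)
        q = BubbleQuery(0, 8, 8, g.number_of_nodes())
        full = list(enumerate_bubbles_from(g, q))
        stats = EnumerationStats()
        capped = list(enumerate_bubbles_from(g, q, stats=stats, max_steps=3))
        assert len(capped) <= len(full)
        if len(capped) < len(full):
            assert stats.truncated

    def test_all_sources_covers_every_branching_source(self):
        g = nx.DiGraph()
        arcs = [("s", "a"), ("s", "b"), ("a", "t"), ("b", "t"),
                ("t", "c"), ("t", "d"), ("c", "u"), ("d", "u")]
        for u, v in arcs:
            g.add_edge(u, v, weight=1)
        out = list(enumerate_all_bubbles(g, 4, 4, 2))
        assert {bub.source for bub in out} == {"s", "t"}


class TestSpelling:
    def test_single_arc_path(self):
        g = nx.DiGraph()
        g.add_edge("ACT", "CTGA", weight=2)
        cg = CompressedGraph(3, g)
        assert spell_path(["ACT", "CTGA"], cg) == "ACTGA"

    def test_inconsistent_overlap_raises(self):
        g = nx.DiGraph()
        g.add_edge("ACTG", "CTGA", weight=2)  # labels do not overlap by k-1
        cg = CompressedGraph(3, g)
        with pytest.raises(ValueError):
            spell_path(["ACTG", "CTGA"], cg)

    def test_spelled_length_identity_on_real_bubbles(self):
        """len(seq) = len(label(s)) + weighted path length, per path."""
        reads = ["AAGGCTTCAGGAC", "AAGGCTACAGGAC"]  # SNP bubble
        cg = compress(build_graph(reads, 4))
        out = list(enumerate_all_bubbles(cg, 20, 20, 2))
        assert out, "expected at least one bubble from the SNP pair"
        for bub in out:
            s1, s2 = spell_bubble(bub, cg)
            assert len(s1) == len(bub.path1[0]) + bub.len1
            assert len(s2) == len(bub.path2[0]) + bub.len2
            assert s1 != s2
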