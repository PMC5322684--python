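"""Shared fixtures and validators for the test suite."""

from __future__ import annotations

import itertools
import random

import networkx as nx
import pytest

from repeatdbg.graph import _nx_of, branching_vertices


@pytest.fixture
def diamond() -> nx.DiGraph:
    g = nx.DiGraph()
    for u, v in [("s", "a"), ("s", "b"), ("a", "t"), ("b", "t")]:
        g.add_edge(u, v, weight=1)
    return g


@pytest.fixture
def fan() -> nx.DiGraph:
    g = nx.DiGraph()
    for x in "abc":
        g.add_edge("s", x, weight=1)
        g.add_edge(x, "t", weight=1)
    return g


def random_digraph(seed: int, n_max: int = 12, p: float = 0.25) -> nx.DiGraph:
    """Seeded random weighted digraph used by the oracle batteries."""
    rng = random.Random(seed)
    n = rng.randint(4, n_max)
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u, v in itertools.permutations(range(n), 2):
        if rng.random() < p:
            g.add_edge(u, v, weight=rng.randint(1, 3))
    return g


def random_reads(seed: int, n_reads: int = 6, len_range=(8, 20)) -> list[str]:
    rng = random.Random(seed)
    return [
        "".join(rng.choice("ACGT") for _ in range(rng.randint(*len_range)))
        for _ in range(n_reads)
    ]


def validate_bubble(bub, g, query) -> None:
    """Check every structural invariant of an emitted bubble."""
    G = _nx_of(g)
    br = branching_vertices(G)
    assert bub.path1[0] == bub.path2[0] == bub.source == query.source
    assert bub.path1[-1] == bub.path2[-1] == bub.target
    assert bub.target != bub.source
    for path in (bub.path1, bub.path2):
        assert len(path) == len(set(path)), "path revisits a vertex"
        for u, v in zip(path, path[1:]):
            assert G.has_edge(u, v)
    assert not (set(bub.path1[1:-1]) & set(bub.path2[1:-1])), "shared internal vertex"
    assert bub.path1[1] != bub.path2[1], "first arcs must differ"
    for path, length, count in (
        (bub.path1, bub.len1, bub.branch1),
        (bub.path2, bub.len2, bub.branch2),
    ):
        w = sum(G.edges[u, v].get("weight", 1) for u, v in zip(path, path[1:]))
        assert w == length
        assert sum(1 for v in path[1:-1] if v in br) == count
        assert count <= query.b
    assert bub.len1 <= bub.len2, "canonical form is shorter path first"
    assert bub.len1 <= query.alpha1 and bub.len2 <= query.alpha2
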