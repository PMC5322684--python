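"""Enumeration of bubbles with bounded branching in weighted digraphs.

An (s, t, alpha1, alpha2, b)-bubble is a pair of internally vertex-disjoint
s-to-t paths whose weighted lengths are at most alpha1 (shorter path) and
alpha2 (longer path), each containing at most b branching vertices — the
endpoints s and t are not counted.  On a compressed de Bruijn graph a
bubble is the signature of an alternative-splicing event (the two isoform
paths), and the branching bound b is what lets the search skip
repeat-associated tangles, which are branching-dense: a true AS bubble is
typically branching-sparse even when the surrounding region is not.

The enumerator recursively partitions the solution space by the next arc of
one partially built path, and only descends into subspaces certified
non-empty by a feasibility oracle, so the work is output-sensitive (the
delay between consecutive bubbles is polynomial).  The oracle is a dynamic
program computing, from a source u, the shortest-path length to every
vertex using at most beta branching vertices, for beta = 0..b: entering a
branching vertex consumes one unit of budget, the source consumes none.
Within one budget layer the values propagate along non-branching vertices
to a fixpoint (a Dijkstra pass seeded with the layer's branching-vertex
values).  The vertex-disjointness requirement can be dropped inside the
oracle: if two witness paths to a common target first intersect at t*,
their prefixes up to t* are internally disjoint and satisfy every monotone
constraint, so feasibility is exact and no recursive call is barren.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass
from typing import Iterator, Sequence

import networkx as nx

from .graph import CompressedGraph, _nx_of, branching_vertices

INF = float("inf")


@dataclass
class BubbleQuery:
    """Search parameters: source vertex, length bounds, branching budget.

    ``alpha1 <= alpha2``; the shorter path of a reported bubble is bounded
    by alpha1 and the longer by alpha2.  ``b`` bounds the number of
    branching vertices strictly between s and t on each path (default 5,
    the production setting of the repeat-avoiding enumerator).
    """

    source: object
    alpha1: float
    alpha2: float
    b: int = 5

    def __post_init__(self) -> None:
        if self.alpha1 > self.alpha2:
            raise ValueError("alpha1 must be <= alpha2 (shorter path first)")
        if self.alpha1 < 0 or self.b < 0:
            raise ValueError("alpha1 and b must be non-negative")


@dataclass(frozen=True)
class Bubble:
    """A pair of internally vertex-disjoint s-t paths, shorter path first.

    Lengths are weighted path lengths; ``branch1``/``branch2`` count
    branching vertices strictly between source and target.  ``seq1``/
    ``seq2`` carry spelled nucleotide sequences on labelled graphs.
    """

    source: object
    target: object
    path1: tuple
    path2: tuple
    len1: float
    len2: float
    branch1: int
    branch2: int
    seq1: str | None = None
    seq2: str | None = None

    def key(self) -> tuple:
        return (self.path1, self.path2)


@dataclass
class BoundedDistanceTable:
    """d[beta][t]: shortest length from ``source`` to t with <= beta branching."""

    source: object
    b: int
    layers: list[dict]
    branching: frozenset

    def distance(self, beta: int, t) -> float:
        if beta < 0:
            return INF
        beta = min(beta, self.b)
        return self.layers[beta].get(t, INF)


@dataclass
class EnumerationStats:
    """Instrumentation of one enumeration run (for testing INV and limits)."""

    calls: int = 0
    barren: int = 0  # recursive calls whose subtree emitted nothing
    emitted: int = 0
    truncated: bool = False  # stopped by the work limit


class _WorkLimit(Exception):
    pass


def _adjacency(G: nx.DiGraph, weight: str = "weight"):
    succ: dict = {}
    pred: dict = {}
    for v in G.nodes:
        succ[v] = {}
        pred[v] = {}
    for u, v, data in G.edges(data=True):
        w = data.get(weight, 1)
        if w < 0:
            raise ValueError(f"negative arc weight on ({u!r}, {v!r})")
        succ[u][v] = w
        pred[v][u] = w
    return succ, pred


def _bounded_dp(
    succ: dict,
    pred: dict,
    source,
    b: int,
    branching: set,
    removed: set,
    blocked_out: set,
) -> list[dict]:
    """Layered DP over budgets 0..b, skipping ``removed`` vertices.

    ``blocked_out`` vertices keep their own distances but contribute no
    outgoing arcs (used to freeze a finished path at its endpoint).  The
    number of layers is capped at the number of active branching vertices
    plus one: no simple path can spend more budget than that, so the top
    layer already equals the unconstrained distance.
    """
    b = min(b, sum(1 for v in branching if v not in removed))

    def relax_layer(dist: dict) -> None:
        # fixpoint over non-branching heads within the current budget layer
        heap = [(d, repr(v), v) for v, d in dist.items()]
        heapq.heapify(heap)
        while heap:
            d, _, u = heapq.heappop(heap)
            if d > dist.get(u, INF):
                continue
            if u in blocked_out:
                continue
            for v, w in succ[u].items():
                if v in removed or v in branching or v == u:
                    continue
                nd = d + w
                if nd < dist.get(v, INF):
                    dist[v] = nd
                    heapq.heappush(heap, (nd, repr(v), v))

    layer0 = {source: 0}
    relax_layer(layer0)
    layers = [layer0]
    for _ in range(b):
        prevl = layers[-1]
        cur = dict(prevl)
        for t in branching:
            if t in removed or t == source:
                continue
            best = prevl.get(t, INF)
            for v, w in pred[t].items():
                if v in removed or v == t or v in blocked_out:
                    continue
                dv = prevl.get(v, INF)
                if dv + w < best:
                    best = dv + w
            if best < INF:
                cur[t] = best
        relax_layer(cur)
        layers.append(cur)
    return layers


def bounded_branching_shortest_paths(
    g, s, b: int, *, branching: set | None = None, weight: str = "weight"
) -> BoundedDistanceTable:
    """Shortest paths from ``s`` using at most ``b`` branching vertices.

    Implements the budgeted recurrence: d[0, s] = 0 and d[0, t] = w(s, t)
    for non-branching out-neighbours of s; at larger budgets a branching
    target is reached from the previous layer (entering it costs one unit)
    while non-branching targets relax within the layer.  The source is
    never counted as branching.  ``b`` is capped at |V|.  Arc weights must
    be non-negative.
    """
    G = _nx_of(g)
    if s not in G:
        raise ValueError(f"source {s!r} not in graph")
    if b < 0:
        raise ValueError("b must be >= 0")
    b = min(b, G.number_of_nodes())
    if branching is None:
        branching = branching_vertices(G)
    succ, pred = _adjacency(G, weight)
    layers = _bounded_dp(succ, pred, s, b, set(branching), set(), set())
    # layers may be capped at the branching count; distance() clamps beta
    return BoundedDistanceTable(s, len(layers) - 1, layers, frozenset(branching))


def feasible(
    g,
    u1,
    u2,
    rem_len1: float,
    rem_len2: float,
    rem_b1: int,
    rem_b2: int,
    *,
    branching: set | None = None,
    weight: str = "weight",
) -> bool:
    """Can two paths from u1 and u2 meet within the remaining budgets?

    True iff some target t admits extensions with lengths within
    (rem_len1, rem_len2) and branching counts within (rem_b1, rem_b2),
    where a branching t is granted one extra unit on each side (the
    endpoint t is not counted in a closed bubble), and a branching u_i is
    charged one unit whenever its path must still extend (t != u_i), since
    u_i then becomes an internal vertex.  Vertex-disjointness is
    deliberately dropped (prefix argument) without loss of exactness.
    """
    G = _nx_of(g)
    if branching is None:
        branching = branching_vertices(G)
    succ, pred = _adjacency(G, weight)
    return _feasible(
        succ, pred, set(branching), set(), set(),
        u1, u2, rem_len1, rem_len2, rem_b1, rem_b2,
    )


def _feasible(
    succ, pred, branching, removed, blocked_out,
    u1, u2, L1a, L2a, B1, B2, L1b=None, L2b=None,
) -> bool:
    """Oracle over one or two (length-bound) assignments.

    (L1a, L2a) and optionally (L1b, L2b) are alternative assignments of the
    remaining length budgets to the two paths (the alpha bounds apply to
    the sorted final lengths, so either pairing may certify feasibility).
    """
    if max(L1a, L1b if L1b is not None else -1) < 0:
        return False
    if max(L2a, L2b if L2b is not None else -1) < 0:
        return False
    if B1 < 0 or B2 < 0:
        return False
    pend1 = 1 if u1 in branching else 0
    pend2 = 1 if u2 in branching else 0
    n_active = len(succ) - len(removed)
    d1 = _bounded_dp(succ, pred, u1, min(B1 + 1, n_active), branching, removed, blocked_out)
    d2 = _bounded_dp(succ, pred, u2, min(B2 + 1, n_active), branching, removed, blocked_out)
    top1, top2 = len(d1) - 1, len(d2) - 1
    for t in d1[top1]:
        extra = 1 if t in branching else 0
        b1_eff = B1 + extra - (pend1 if t != u1 else 0)
        b2_eff = B2 + extra - (pend2 if t != u2 else 0)
        if b1_eff < 0 or b2_eff < 0:
            continue
        dd1 = d1[min(b1_eff, top1)].get(t, INF)
        dd2 = d2[min(b2_eff, top2)].get(t, INF)
        if dd2 == INF:
            continue
        if dd1 <= L1a and dd2 <= L2a:
            return True
        if L1b is not None and dd1 <= L1b and dd2 <= L2b:
            return True
    return False


def _make_bubble(source, target, pathA, pathB, lenA, lenB, brA, brB) -> Bubble:
    a = (lenA, tuple(map(repr, pathA)))
    b = (lenB, tuple(map(repr, pathB)))
    if a <= b:
        return Bubble(source, target, tuple(pathA), tuple(pathB), lenA, lenB, brA, brB)
    return Bubble(source, target, tuple(pathB), tuple(pathA), lenB, lenA, brB, brA)


def enumerate_bubbles_from(
    g,
    query: BubbleQuery,
    *,
    stats: EnumerationStats | None = None,
    max_steps: int | None = None,
    weight: str = "weight",
) -> Iterator[Bubble]:
    """Stream all (s, *, alpha1, alpha2, b)-bubbles rooted at query.source.

    Each bubble is emitted exactly once, in canonical (shorter-path-first)
    form, in a deterministic order.  The recursion extends the partial path
    whose accumulated length is smaller (ties: path 1) and descends only
    into subspaces certified non-empty by the feasibility oracle, so the
    enumeration is output-sensitive.  Mirror duplicates are avoided at the
    root by pairing the two distinct first arcs in a fixed order.
    ``max_steps`` bounds the number of recursive calls; when it is reached
    the stream ends early with ``stats.truncated`` set (the production
    behaviour of halting complex regions on a timeout).
    """
    G = _nx_of(g)
    s = query.source
    if s not in G:
        raise ValueError(f"source {s!r} not in graph")
    alpha1, alpha2, b = query.alpha1, query.alpha2, query.b
    branching = set(branching_vertices(G))
    succ, pred = _adjacency(G, weight)
    st = stats if stats is not None else EnumerationStats()

    removed: set = set()
    blocked_out: set = set()

    def oracle(u1, u2, l1, l2, b1, b2) -> bool:
        return _feasible(
            succ, pred, branching, removed, blocked_out,
            u1, u2,
            alpha1 - l1, alpha2 - l2, b - b1, b - b2,
            alpha2 - l1, alpha1 - l2,
        )

    def rec(u1, u2, path1, path2, l1, l2, b1, b2, frozen1, frozen2):
        st.calls += 1
        if max_steps is not None and st.calls > max_steps:
            raise _WorkLimit
        emitted_before = st.emitted
        if frozen1:
            i = 2
        elif frozen2:
            i = 1
        else:
            i = 1 if l1 <= l2 else 2
        if i == 1:
            ui, uo = u1, u2
            li, bi = l1, b1
            pi = path1
        else:
            ui, uo = u2, u1
            li, bi = l2, b2
            pi = path2
        frozen_other = frozen2 if i == 1 else frozen1
        add_br = 1 if ui in branching else 0
        for v in sorted(succ[ui], key=repr):
            if v == ui or v in removed:
                continue
            w = succ[ui][v]
            new_len = li + w
            new_br = bi + add_br
            if v == uo:
                # closing arc: t = uo, not counted as branching
                if new_br > b:
                    continue
                if i == 1:
                    lens, brs = (new_len, l2), (new_br, b2)
                    pA, pB = path1 + [v], path2
                else:
                    lens, brs = (l1, new_len), (b1, new_br)
                    pA, pB = path1, path2 + [v]
                lo, hi = sorted(lens)
                if lo <= alpha1 and hi <= alpha2:
                    st.emitted += 1
                    yield _make_bubble(s, v, pA, pB, lens[0], lens[1], brs[0], brs[1])
                continue
            if new_br > b or new_len > alpha2:
                continue
            removed.add(ui)
            args = (
                (v, u2, path1 + [v], path2, new_len, l2, new_br, b2, frozen1, frozen2)
                if i == 1
                else (u1, v, path1, path2 + [v], l1, new_len, b1, new_br, frozen1, frozen2)
            )
            nu1, nu2, _, _, nl1, nl2, nb1, nb2 = args[:8]
            if oracle(nu1, nu2, nl1, nl2, nb1, nb2):
                yield from rec(*args)
            removed.discard(ui)
        # subspace using no further arc of path i: its endpoint is the target
        if not frozen_other:
            blocked_out.add(ui)
            if oracle(u1, u2, l1, l2, b1, b2):
                if i == 1:
                    yield from rec(u1, u2, path1, path2, l1, l2, b1, b2, True, frozen2)
                else:
                    yield from rec(u1, u2, path1, path2, l1, l2, b1, b2, frozen1, True)
            blocked_out.discard(ui)
        if st.emitted == emitted_before:
            st.barren += 1

    first_arcs = [v for v in sorted(succ[s], key=repr) if v != s]
    removed.add(s)
    try:
        for v1, v2 in itertools.combinations(first_arcs, 2):
            w1, w2 = succ[s][v1], succ[s][v2]
            if oracle(v1, v2, w1, w2, 0, 0):
                yield from rec(v1, v2, [s, v1], [s, v2], w1, w2, 0, 0, False, False)
    except _WorkLimit:
        st.truncated = True
    finally:
        removed.discard(s)


def enumerate_all_bubbles(
    g,
    alpha1: float,
    alpha2: float,
    b: int = 5,
    *,
    max_steps_per_source: int | None = None,
    stats: EnumerationStats | None = None,
    weight: str = "weight",
) -> Iterator[Bubble]:
    """Bubbles from every admissible source (out-degree >= 2), streamed.

    A bubble's source is its first vertex, so the per-source streams are
    disjoint and no deduplication is needed.  ``max_steps_per_source``
    bounds the work spent on any one source, mirroring the per-region
    timeout used in practice on repeat-dense graphs.
    """
    G = _nx_of(g)
    for s in sorted(G.nodes, key=repr):
        if G.out_degree(s) < 2:
            continue
        src_stats = EnumerationStats()
        q = BubbleQuery(s, alpha1, alpha2, b)
        yield from enumerate_bubbles_from(
            g, q, stats=src_stats, max_steps=max_steps_per_source, weight=weight
        )
        if stats is not None:
            stats.calls += src_stats.calls
            stats.barren += src_stats.barren
            stats.emitted += src_stats.emitted
            stats.truncated = stats.truncated or src_stats.truncated


def brute_force_bubbles(g, query: BubbleQuery, *, weight: str = "weight") -> set[Bubble]:
    """Exhaustive ground-truth enumeration on small graphs (|V| <= 30).

    Enumerates every simple path from the source by DFS, then every pair of
    internally vertex-disjoint paths sharing an endpoint, filtered by the
    sorted length bounds and per-path branching budgets.
    """
    G = _nx_of(g)
    if G.number_of_nodes() > 30:
        raise ValueError("brute force is limited to graphs with <= 30 vertices")
    s = query.source
    alpha1, alpha2, b = query.alpha1, query.alpha2, query.b
    branching = branching_vertices(G)
    succ, _ = _adjacency(G, weight)

    # all simple paths from s with weight <= alpha2 and <= b branching
    # vertices strictly after s, allowing the final vertex to be branching
    # without charge (it may serve as the uncounted target t).
    paths: list[tuple[list, float, int]] = []

    def dfs(path, length, br_internal):
        u = path[-1]
        if len(path) >= 2:
            paths.append((list(path), length, br_internal))
        for v, w in succ[u].items():
            if v in path:
                continue
            if length + w > alpha2:
                continue
            extra = 1 if u in branching and len(path) >= 2 else 0
            if br_internal + extra > b:
                continue
            path.append(v)
            dfs(path, length + w, br_internal + extra)
            path.pop()

    dfs([s], 0.0, 0)
    by_target: dict = {}
    for path, length, br in paths:
        by_target.setdefault(path[-1], []).append((path, length, br))
    out: set[Bubble] = set()
    for t, plist in by_target.items():
        for (p1, l1, br1), (p2, l2, br2) in itertools.combinations(plist, 2):
            if set(p1[1:-1]) & set(p2[1:-1]):
                continue
            if p1[1] == p2[1]:  # same first arc: not internally disjoint
                continue
            lo, hi = sorted((l1, l2))
            if lo > alpha1 or hi > alpha2:
                continue
            if br1 > b or br2 > b:
                continue
            out.add(_make_bubble(s, t, p1, p2, l1, l2, br1, br2))
    return out


def spell_path(path: Sequence[str], g: CompressedGraph) -> str:
    """Spell the nucleotide sequence of a unitig path, merging k-1 overlaps."""
    k = g.k
    seq = path[0]
    for label in path[1:]:
        if seq[-(k - 1):] != label[: k - 1]:
            raise ValueError(
                f"inconsistent overlap between consecutive unitigs near {label[:k]!r}"
            )
        seq += label[k - 1:]
    return seq


def spell_bubble(bubble: Bubble, g: CompressedGraph) -> tuple[str, str]:
    """Spelled sequences of the two bubble paths on a compressed graph.

    Each spelled length equals len(label(source)) + weighted path length.
    """
    if len(bubble.path1) < 2 or len(bubble.path2) < 2:
        raise ValueError("a bubble path must contain at least one arc")
    return spell_path(bubble.path1, g), spell_path(bubble.path2, g)
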