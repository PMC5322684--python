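"""Directed de Bruijn graphs over the DNA alphabet.

A de Bruijn graph (DBG) of order ``k`` has one vertex per distinct k-mer of
the input reads and an arc ``(u, v)`` whenever the (k+1)-mer ``u + v[-1]``
occurs in some read (so arcs are supported by actual read context, and carry
an occurrence count).  An arc ``(u, v)`` is *compressible* when
``out_degree(u) == 1`` and ``in_degree(v) == 1``: every walk through ``u``
must continue to ``v``, so the arc can be contracted without information
loss.  Contracting every compressible arc yields the *compressed* (unitig)
graph whose vertices carry nucleotide labels of length >= k.

The number of compressible arcs, gamma, is the topological statistic used
throughout this package to characterise repeat-associated subgraphs: graphs
built from many low-divergence copies of the same sequence have few
compressible arcs relative to their size, while graphs built from unrelated
sequences are almost entirely compressible.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)

DNA_ALPHABET = "ACGT"
_VALID_RUN = re.compile(r"[ACGT]+")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def clean_fragments(read: str) -> list[str]:
    """Split a read into maximal runs over {A,C,G,T} (uppercased).

    Characters outside the alphabet (N, IUPAC codes, ...) act as breaks;
    each run is treated downstream as an independent read fragment.
    """
    return _VALID_RUN.findall(read.upper())


@dataclass
class DeBruijnGraph:
    """k-mer graph with per-vertex and per-arc occurrence counts.

    ``g`` is a :class:`networkx.DiGraph` whose nodes are k-mer strings with a
    ``cov`` attribute (occurrence count in the reads) and whose edges carry a
    ``cov`` attribute (occurrence count of the supporting (k+1)-mer).
    """

    k: int
    g: nx.DiGraph

    @property
    def n_vertices(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_arcs(self) -> int:
        return self.g.number_of_edges()

    def vertex_coverage(self, v: str) -> int:
        return self.g.nodes[v]["cov"]

    def arc_coverage(self, u: str, v: str) -> int:
        return self.g.edges[u, v]["cov"]

    def copy(self) -> "DeBruijnGraph":
        return DeBruijnGraph(self.k, self.g.copy())


@dataclass
class CompressedGraph:
    """Unitig graph obtained by contracting all compressible arcs.

    Nodes are unitig label strings (length >= k); a label spells the ordered
    run of original k-mers it replaces.  Edge attribute ``weight`` is the
    number of nucleotides appended when traversing the arc, i.e.
    ``len(label(head)) - (k - 1)``.
    """

    k: int
    g: nx.DiGraph

    @property
    def unitigs(self) -> list[str]:
        return list(self.g.nodes)

    def origin(self, label: str) -> list[str]:
        """Ordered list of original k-mers spelled by a unitig label."""
        return spelled_kmers(label, self.k)

    def arc_weight(self, u: str, v: str) -> int:
        return self.g.edges[u, v]["weight"]


@dataclass
class GraphStats:
    """Summary statistics of a (de Bruijn) graph.

    ``gamma`` is the number of compressible arcs; ``boundary_rigid`` (when
    reads are supplied) counts the boundary-rigid (k-1)-mers, which stand in
    one-to-one correspondence with compressible arcs on read-derived graphs.
    """

    gamma: int
    n_vertices: int
    n_arcs: int
    n_branching: int
    boundary_rigid: int | None = None


def spelled_kmers(label: str, k: int) -> list[str]:
    return [label[i : i + k] for i in range(len(label) - k + 1)]


def _nx_of(g) -> nx.DiGraph:
    return g.g if isinstance(g, (DeBruijnGraph, CompressedGraph)) else g


def build_graph(
    reads: Iterable[str], k: int, *, add_reverse_complement: bool = False
) -> DeBruijnGraph:
    """Build the de Bruijn graph of order ``k`` from a collection of reads.

    Vertices are all distinct k-mers of the reads; an arc ``(u, v)`` is
    present iff the (k+1)-mer ``u + v[-1]`` occurs in some read.  Coverages
    count occurrences.  With ``add_reverse_complement`` the reverse
    complement of every read (fragment) is added before construction,
    for use on non-strand-specific libraries.

    Raises ``ValueError`` for k < 2.  An empty result (no read reaches
    length k) is returned as an empty graph with a warning.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    kmer_cov: dict[str, int] = {}
    arc_cov: dict[tuple[str, str], int] = {}
    n_frag = 0
    for read in reads:
        for frag in clean_fragments(read):
            frags = [frag]
            if add_reverse_complement:
                frags.append(reverse_complement(frag))
            for f in frags:
                if len(f) < k:
                    continue
                n_frag += 1
                for i in range(len(f) - k + 1):
                    km = f[i : i + k]
                    kmer_cov[km] = kmer_cov.get(km, 0) + 1
                for i in range(len(f) - k):
                    arc = (f[i : i + k], f[i + 1 : i + k + 1])
                    arc_cov[arc] = arc_cov.get(arc, 0) + 1
    g = nx.DiGraph()
    for km, cov in kmer_cov.items():
        g.add_node(km, cov=cov)
    for (u, v), cov in arc_cov.items():
        g.add_edge(u, v, cov=cov)
    if not g:
        logger.warning("no read fragment of length >= k=%d; empty graph", k)
    return DeBruijnGraph(k, g)


def compressible_arcs(g) -> set[tuple]:
    """Arcs ``(u, v)`` with out-degree(u) == 1 and in-degree(v) == 1.

    Self-loops are never compressible (contracting one is undefined).
    Accepts a :class:`DeBruijnGraph`, :class:`CompressedGraph`, or any
    :class:`networkx.DiGraph`.
    """
    G = _nx_of(g)
    return {
        (u, v)
        for u, v in G.edges
        if u != v and G.out_degree(u) == 1 and G.in_degree(v) == 1
    }


def gamma(g) -> int:
    """Number of compressible arcs (the repeat-characterisation statistic)."""
    return len(compressible_arcs(g))


def branching_vertices(g) -> set:
    """Vertices with in-degree >= 2 or out-degree >= 2.

    A self-loop contributes one to both degrees.
    """
    G = _nx_of(g)
    return {v for v in G.nodes if G.in_degree(v) >= 2 or G.out_degree(v) >= 2}


def boundary_rigid_kmers(reads: Iterable[str], k: int) -> set[str]:
    """(k-1)-mers that always occur in one fixed single-symbol context.

    A (k-1)-mer is *boundary rigid* when every one of its occurrences in the
    reads is preceded by the same symbol and followed by the same symbol.
    Occurrences at read (fragment) boundaries, which lack a predecessor or a
    successor, disqualify the (k-1)-mer: such an occurrence contributes no
    (k+1)-mer context on one side, mirroring a missing arc in the graph.
    On read-derived graphs these stand in one-to-one correspondence with
    compressible arcs.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    kk = k - 1
    context: dict[str, tuple[str, str]] = {}
    dead: set[str] = set()
    for read in reads:
        for f in clean_fragments(read):
            n = len(f)
            if n < kk:
                continue
            for i in range(n - kk + 1):
                sub = f[i : i + kk]
                if sub in dead:
                    continue
                if i == 0 or i + kk == n:
                    dead.add(sub)
                    context.pop(sub, None)
                    continue
                ctx = (f[i - 1], f[i + kk])
                prev = context.get(sub)
                if prev is None:
                    context[sub] = ctx
                elif prev != ctx:
                    dead.add(sub)
                    del context[sub]
    return set(context)


def prune(g: DeBruijnGraph, abs_cutoff: int, rel_cutoff: float) -> DeBruijnGraph:
    """Coverage-based graph cleaning with an absolute and a relative cut-off.

    First removes vertices with coverage < ``abs_cutoff`` (with their
    incident arcs).  Then, at every branching out-neighbourhood (and
    symmetrically every branching in-neighbourhood), removes arcs whose
    coverage divided by the summed coverage of the sibling arcs is below
    ``rel_cutoff`` (both directions evaluated on the post-absolute graph,
    removals applied together).  Finally deletes isolated vertices.  The
    absolute rule targets sequencing errors in general; the relative one,
    spurious minor arcs next to highly covered ones.
    """
    if abs_cutoff < 0:
        raise ValueError("abs_cutoff must be >= 0")
    if not (0 <= rel_cutoff < 1):
        raise ValueError("rel_cutoff must be in [0, 1)")
    G = g.g.copy()
    G.remove_nodes_from([v for v, d in G.nodes(data=True) if d["cov"] < abs_cutoff])
    if rel_cutoff > 0:
        doomed = set()
        for v in G.nodes:
            out = list(G.out_edges(v, data="cov"))
            if len(out) >= 2:
                total = sum(c for _, _, c in out)
                doomed.update((a, b) for a, b, c in out if c / total < rel_cutoff)
            inc = list(G.in_edges(v, data="cov"))
            if len(inc) >= 2:
                total = sum(c for _, _, c in inc)
                doomed.update((a, b) for a, b, c in inc if c / total < rel_cutoff)
        G.remove_edges_from(doomed)
    G.remove_nodes_from([v for v in G.nodes if G.degree(v) == 0])
    if not G:
        logger.warning("pruning removed the whole graph")
    return DeBruijnGraph(g.k, G)


def _compressible_chains(G: nx.DiGraph) -> tuple[list[list], set[tuple]]:
    """Partition vertices into maximal chains of compressible arcs.

    Returns the chains and the set of arcs contracted inside them.  A cycle
    made entirely of compressible arcs becomes one chain whose closing arc
    is *not* contracted (it survives as a self-loop; self-loops are never
    contracted).  Chain order is deterministic: open chains in graph node
    order, then cycles by smallest member.
    """
    succ_c: dict = {}
    pred_c: dict = {}
    for u, v in G.edges:
        if u != v and G.out_degree(u) == 1 and G.in_degree(v) == 1:
            succ_c[u] = v
            pred_c[v] = u
    chains: list[list] = []
    contracted: set[tuple] = set()
    visited: set = set()
    for s in G.nodes:
        if s in succ_c and s not in pred_c:
            chain = [s]
            cur = s
            while cur in succ_c:
                nxt = succ_c[cur]
                contracted.add((cur, nxt))
                chain.append(nxt)
                cur = nxt
            chains.append(chain)
            visited.update(chain)
    for s in sorted(v for v in G.nodes if v not in visited and v in succ_c):
        if s in visited:
            continue
        chain = [s]
        cur = succ_c[s]
        while cur != s:
            contracted.add((chain[-1], cur))
            chain.append(cur)
            cur = succ_c[cur]
        chains.append(chain)
        visited.update(chain)
    chains.extend([v] for v in G.nodes if v not in visited)
    return chains, contracted


def compress(g: DeBruijnGraph | CompressedGraph | nx.DiGraph):
    """Contract every compressible arc, yielding the unitig graph.

    Maximal chains of compressible arcs are merged into single vertices;
    the operation is order-independent (contraction is confluent), so a
    linear-time chain compaction is used rather than arc-by-arc
    contraction.  For :class:`DeBruijnGraph` / :class:`CompressedGraph`
    inputs the merged vertex carries the chain's spelled label and the
    result is a :class:`CompressedGraph` with arc weights
    ``len(label(head)) - (k - 1)``.  A plain :class:`networkx.DiGraph`
    (abstract weighted digraph) is compacted structurally: merged nodes are
    tuples of original nodes and an arc's weight is the weight of the
    entering arc plus the weights contracted inside the head chain, which
    coincides with the label arithmetic on sequence graphs.
    """
    labeled = isinstance(g, (DeBruijnGraph, CompressedGraph))
    G = _nx_of(g)
    chains, contracted = _compressible_chains(G)

    cg = nx.DiGraph()
    node_of: dict = {}
    internal_weight: dict = {}
    if labeled:
        k = g.k
        for chain in chains:
            label = "".join([chain[0]] + [v[k - 1 :] for v in chain[1:]])
            covs = [G.nodes[v].get("cov") for v in chain]
            mean_cov = (
                sum(covs) / len(covs) if all(c is not None for c in covs) else None
            )
            cg.add_node(label, cov=mean_cov, n_members=len(chain))
            for v in chain:
                node_of[v] = label
    else:
        for chain in chains:
            node = chain[0] if len(chain) == 1 else tuple(chain)
            cg.add_node(node)
            for v in chain:
                node_of[v] = node
    for chain in chains:
        w = sum(
            G.edges[a, b].get("weight", 1) for a, b in zip(chain, chain[1:])
        )
        internal_weight[node_of[chain[0]]] = w
    for u, v in G.edges:
        if (u, v) in contracted:
            continue
        hu, hv = node_of[u], node_of[v]
        w = G.edges[u, v].get("weight", 1) + internal_weight[hv]
        cg.add_edge(hu, hv, weight=w)
    if labeled:
        return CompressedGraph(g.k, cg)
    return cg


def alternating_cycle(x: int) -> nx.DiGraph:
    """The R(x) gadget: a cycle on 2x vertices with alternating arc directions.

    Even vertices ``v0, v2, ...`` each have arcs to their two odd cycle
    neighbours, so they are sources of out-degree 2 and the odd vertices are
    sinks of in-degree 2.  None of the 2x arcs is compressible, making R(x)
    the canonical fixture of a maximally incompressible (repeat-like)
    subgraph.
    """
    if x < 2:
        raise ValueError("x must be >= 2 (smaller x would create parallel arcs)")
    g = nx.DiGraph()
    n = 2 * x
    g.add_nodes_from(range(n))
    for i in range(x):
        g.add_edge(2 * i, (2 * i + 1) % n, weight=1)
        g.add_edge(2 * i, (2 * i - 1) % n, weight=1)
    return g


def graph_stats(g, reads: Iterable[str] | None = None) -> GraphStats:
    """Compute gamma, size, branching count and (optionally) rigidity."""
    G = _nx_of(g)
    rigid = None
    if reads is not None:
        k = g.k if isinstance(g, DeBruijnGraph) else None
        if k is None:
            raise ValueError("boundary rigidity needs a DeBruijnGraph with k")
        rigid = len(boundary_rigid_kmers(reads, k))
    return GraphStats(
        gamma=gamma(G),
        n_vertices=G.number_of_nodes(),
        n_arcs=G.number_of_edges(),
        n_branching=len(branching_vertices(G)),
        boundary_rigid=rigid,
    )
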