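"""Readers and writers for the standard formats the toolkit touches.

FASTA/FASTQ parsing is delegated to Biopython (plain or gzip-compressed
files, detected by extension); qualities are ignored.  Compressed graphs
are serialised as GFA 1.0 with unitig labels on S-lines and a ``(k-1)M``
overlap CIGAR on L-lines.  Abstract weighted digraphs round-trip through a
three-column TSV edge list (tail, head, weight).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
from Bio import SeqIO

from .graph import CompressedGraph


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _sequence_format(path) -> str:
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    suffix = Path(name).suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    return "fasta"


def read_sequences(path) -> Iterator[tuple[str, str]]:
    """Yield ``(id, sequence)`` pairs from FASTA/FASTQ, plain or gzipped."""
    fmt = _sequence_format(path)
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq).upper()


def read_reads(paths: Iterable) -> list[str]:
    """Read the sequences of one or more FASTA/FASTQ files."""
    reads: list[str] = []
    for path in paths:
        reads.extend(seq for _, seq in read_sequences(path))
    return reads


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(records: Iterable[tuple[str, str]], path) -> None:
    """Write records with constant dummy qualities (the toolkit ignores them)."""
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_gfa(cg: CompressedGraph, path) -> None:
    """Serialise a compressed graph as GFA 1.0.

    Unitigs are named ``u0, u1, ...`` in node order; each S-line carries the
    spelled label, each L-line a ``(k-1)M`` overlap.
    """
    names = {label: f"u{i}" for i, label in enumerate(cg.g.nodes)}
    overlap = cg.k - 1
    with _open_text(path, "wt") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for label, name in names.items():
            fh.write(f"S\t{name}\t{label}\n")
        for u, v in cg.g.edges:
            fh.write(f"L\t{names[u]}\t+\t{names[v]}\t+\t{overlap}M\n")


def read_gfa(path) -> CompressedGraph:
    """Load a GFA 1.0 file written by :func:`write_gfa`.

    Only forward-orientation links with a uniform ``xM`` overlap are
    supported; k is recovered as overlap + 1.
    """
    seqs: dict[str, str] = {}
    links: list[tuple[str, str, int]] = []
    with _open_text(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "S":
                seqs[fields[1]] = fields[2]
            elif fields[0] == "L":
                if fields[2] != "+" or fields[4] != "+":
                    raise ValueError("only forward-orientation links supported")
                if not fields[5].endswith("M"):
                    raise ValueError(f"unsupported overlap CIGAR {fields[5]!r}")
                links.append((fields[1], fields[3], int(fields[5][:-1])))
    overlaps = {ov for _, _, ov in links}
    if len(overlaps) > 1:
        raise ValueError(f"non-uniform overlaps in GFA: {sorted(overlaps)}")
    overlap = overlaps.pop() if overlaps else (min(map(len, seqs.values())) - 1 if seqs else 0)
    k = overlap + 1
    g = nx.DiGraph()
    for name, seq in seqs.items():
        g.add_node(seq, cov=None, n_members=len(seq) - k + 1)
    for a, b, _ in links:
        g.add_edge(seqs[a], seqs[b], weight=len(seqs[b]) - overlap)
    return CompressedGraph(k, g)


def read_edge_list(path) -> nx.DiGraph:
    """Read an abstract weighted digraph from TSV (tail, head, weight).

    A missing third column defaults the weight to 1.  Lines starting with
    ``#`` are ignored.
    """
    g = nx.DiGraph()
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            w = float(parts[2]) if len(parts) > 2 else 1.0
            if w < 0:
                raise ValueError("negative arc weight")
            if w == int(w):
                w = int(w)
            g.add_edge(parts[0], parts[1], weight=w)
    return g


def write_edge_list(g: nx.DiGraph, path) -> None:
    with _open_text(path, "wt") as fh:
        for u, v, w in g.edges(data="weight", default=1):
            fh.write(f"{u}\t{v}\t{w}\n")
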