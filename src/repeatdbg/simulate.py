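"""Desk-scale synthetic scenarios with the statistical structure of
repeat-troubled RNA-seq assembly.

Two scenario generators are provided.  The *repeat-pair* scenario emulates
the classic chimera mechanism: two transcripts A·R1·B and C·R2·D each
carry one member of a low-divergence repeat family; their copies collapse
in the assembly graph, connecting the unique flanks of both genes, and the
assembler may emit the chimeras A·R·D / C·R·B.  A configurable number of
repeat-free background transcripts represents the rest of the
transcriptome (in real assemblies chimeras are ~1% of mostly repeat-free
transcripts, which is what makes a topology-based flag informative).

The *drowned-bubble* scenario plants an exon-skipping event (inclusion
isoform E1·E2·E3 versus exclusion E1·E3) whose variable region is
repeat-free, but whose flanking introns — present in the data through a
pre-mRNA read fraction — carry several repeat-family copies.  The repeat
copies create a branching-dense tangle around the event: unbounded bubble
enumeration wanders into it, while a small branching budget b recovers the
event directly.

Reads are uniform-start substrings with optional per-base substitution
errors; pre-mRNA records are sampled at a fixed global fraction.  All
generators are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np

from . import bubbles as bb
from .graph import DeBruijnGraph, build_graph, compress
from .repeats import RepeatModelParams, _decode, simulate_family

OK, CHIMERIC, TRUNCATED = "ok", "chimeric", "truncated"

_ACGT_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE2IDX = np.zeros(256, dtype=np.int64)
for _j, _b in enumerate(b"ACGT"):
    _BASE2IDX[_b] = _j


@dataclass
class ScenarioSpec:
    """Study conditions for the synthetic scenarios.

    Defaults mirror the regime the repeat model targets: 300 nt unique
    flanks, a repeat family of 8 copies of length 300 at 2% divergence,
    75 bp reads at 30x mean depth without sequencing errors, a 15%
    pre-mRNA read fraction, and k = 21 for downstream graphs.
    """

    unique_len: int = 300
    repeat_params: RepeatModelParams = field(
        default_factory=lambda: RepeatModelParams(m=8, n=300, alpha=0.02)
    )
    read_len: int = 75
    coverage: float = 30.0
    err_rate: float = 0.0
    premrna_frac: float = 0.15
    seed: int = 0
    k: int = 21
    n_background: int = 18
    skipped_exon_len: int = 100

    def __post_init__(self) -> None:
        if not (0 <= self.premrna_frac <= 1):
            raise ValueError("premrna_frac must be in [0, 1]")
        if self.read_len < self.k:
            raise ValueError("read_len must be >= k")


@dataclass
class PlantedEvent:
    """Ground truth of a planted exon-skipping event."""

    inclusion_id: str
    exclusion_id: str
    inclusion_seq: str
    exclusion_seq: str
    skipped_exon: str


@dataclass
class LabelledSet:
    """FASTA-ready records with ground-truth labels.

    ``sequences`` are the records to be assessed (the 'assembly');
    ``read_sources`` are the molecules reads are drawn from — true
    transcripts plus, when ``premrna`` marks them, unspliced precursors.
    """

    sequences: list[tuple[str, str]]
    labels: dict[str, str]
    truth_events: list[PlantedEvent]
    read_sources: list[tuple[str, str]]
    premrna: set[str] = field(default_factory=set)


def _random_seq(rng, n: int) -> str:
    return _decode(rng.integers(0, 4, size=n))


def make_repeat_pair_scenario(spec: ScenarioSpec) -> LabelledSet:
    """Two repeat-sharing transcripts, their chimeras, and background.

    True transcripts t_ARB = A·R1·B and t_CRD = C·R2·D (labelled ok) carry
    copies R1, R2 of one repeat family.  The chimeric records follow the
    path an assembler would take through the collapsed repeat: they switch
    copies at a shared k-length anchor (at alpha = 0 this degenerates to
    A·R·D and C·R·B).  ``n_background`` additional repeat-free transcripts
    of length 2·unique_len are labelled ok; reads are drawn from the ok
    transcripts only (chimeras are assembly artifacts, not molecules).
    """
    ss = np.random.SeedSequence(spec.seed)
    s_blocks, s_family, s_bg = ss.spawn(3)
    rng = np.random.default_rng(s_blocks)
    ul = spec.unique_len
    A, B, C, D = (_random_seq(rng, ul) for _ in range(4))
    fam = simulate_family(replace(spec.repeat_params, seed=s_family))
    r1, r2 = fam.copies[0], fam.copies[1]
    p = _shared_anchor(r1, r2, spec.k)
    records = [
        ("t_ARB", A + r1 + B),
        ("t_CRD", C + r2 + D),
        ("chimera_AD", A + r1[:p] + r2[p:] + D),
        ("chimera_CB", C + r2[:p] + r1[p:] + B),
    ]
    labels = {"t_ARB": OK, "t_CRD": OK, "chimera_AD": CHIMERIC, "chimera_CB": CHIMERIC}
    bg_rng = np.random.default_rng(s_bg)
    for i in range(spec.n_background):
        name = f"bg_{i}"
        records.append((name, _random_seq(bg_rng, 2 * ul)))
        labels[name] = OK
    read_sources = [(n, s) for n, s in records if labels[n] == OK]
    return LabelledSet(records, labels, [], read_sources)


def _shared_anchor(r1: str, r2: str, k: int) -> int:
    """Copy-switch position: a k-window where both copies agree, searched
    outward from the midpoint; falls back to the midpoint."""
    n = len(r1)
    mid = max(0, n // 2 - k // 2)
    offsets = sorted(range(n - k + 1), key=lambda i: abs(i - mid))
    for i in offsets:
        if r1[i : i + k] == r2[i : i + k]:
            return i + k // 2
    return n // 2


def make_drowned_bubble(
    spec: ScenarioSpec, n_flanking_repeats: int | None = None
) -> tuple[LabelledSet, PlantedEvent]:
    """Exon-skipping event surrounded by repeat-laden introns.

    The gene is E1 · I1 · E2 · I2 · E3 with unique exons (E2 of
    ``skipped_exon_len``); each intron holds ``n_flanking_repeats`` copies
    of the repeat family (default: half the family each) separated by
    short unique spacers.  Isoforms E1·E2·E3 (inclusion) and E1·E3
    (exclusion) are the ok records and mRNA read sources; the unspliced
    precursor contributes reads at ``premrna_frac``.
    """
    if n_flanking_repeats is None:
        n_flanking_repeats = max(1, spec.repeat_params.m // 2)
    if n_flanking_repeats < 1:
        raise ValueError("n_flanking_repeats must be >= 1")
    m_needed = 2 * n_flanking_repeats
    params = replace(spec.repeat_params, m=max(spec.repeat_params.m, m_needed))
    ss = np.random.SeedSequence(spec.seed)
    s_blocks, s_family = ss.spawn(2)
    rng = np.random.default_rng(s_blocks)
    fam = simulate_family(replace(params, seed=s_family))
    ul = spec.unique_len
    e1, e3 = _random_seq(rng, ul), _random_seq(rng, ul)
    e2 = _random_seq(rng, spec.skipped_exon_len)
    spacer_len = 50

    def intron(copies: list[str]) -> str:
        parts = [_random_seq(rng, spacer_len)]
        for c in copies:
            parts.append(c)
            parts.append(_random_seq(rng, spacer_len))
        return "".join(parts)

    i1 = intron(fam.copies[:n_flanking_repeats])
    i2 = intron(fam.copies[n_flanking_repeats : 2 * n_flanking_repeats])
    inclusion = e1 + e2 + e3
    exclusion = e1 + e3
    premrna = e1 + i1 + e2 + i2 + e3
    records = [("isoform_inclusion", inclusion), ("isoform_exclusion", exclusion)]
    labels = {"isoform_inclusion": OK, "isoform_exclusion": OK}
    event = PlantedEvent(
        "isoform_inclusion", "isoform_exclusion", inclusion, exclusion, e2
    )
    read_sources = records + [("premrna", premrna)]
    return (
        LabelledSet(records, labels, [event], read_sources, premrna={"premrna"}),
        event,
    )


def simulate_reads(ls: LabelledSet, spec: ScenarioSpec) -> list[str]:
    """Uniform-start reads with substitution errors from a labelled set.

    The read count is ``coverage * total_source_length / read_len``.  A
    fraction ``premrna_frac`` of reads is drawn from the pre-mRNA records
    (when present), the rest from the mRNA records; within each class the
    source molecule is chosen proportionally to its length, the start
    uniformly.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(4)[3])
    rl = spec.read_len
    mrna = [(n, s) for n, s in ls.read_sources if n not in ls.premrna]
    pre = [(n, s) for n, s in ls.read_sources if n in ls.premrna]
    for name, seq in ls.read_sources:
        if len(seq) < rl:
            raise ValueError(f"source {name!r} shorter than the read length")
    total = sum(len(s) for _, s in ls.read_sources)
    n_reads = int(round(spec.coverage * total / rl))
    n_pre = int(round(spec.premrna_frac * n_reads)) if pre else 0
    reads: list[str] = []
    for pool, count in ((pre, n_pre), (mrna, n_reads - n_pre)):
        if not pool or count <= 0:
            continue
        lens = np.array([len(s) - rl + 1 for _, s in pool], dtype=float)
        probs = lens / lens.sum()
        choices = rng.choice(len(pool), size=count, p=probs)
        for idx in choices:
            seq = pool[idx][1]
            start = rng.integers(0, len(seq) - rl + 1)
            read = seq[start : start + rl]
            if spec.err_rate > 0:
                arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
                hit = rng.random(rl) < spec.err_rate
                if hit.any():
                    # substitute with one of the three other bases, uniformly
                    off = rng.integers(1, 4, size=rl)
                    arr[hit] = _ACGT_CODES[(_BASE2IDX[arr[hit]] + off[hit]) % 4]
                    read = arr.tobytes().decode()
            reads.append(read)
    return reads


def graph_from_scenario(ls: LabelledSet, spec: ScenarioSpec) -> DeBruijnGraph:
    """Reads -> de Bruijn graph, the standard first pipeline step."""
    return build_graph(simulate_reads(ls, spec), spec.k)


def find_planted_bubble(
    ls: LabelledSet,
    event: PlantedEvent,
    spec: ScenarioSpec,
    b: int = 5,
    *,
    alpha2: int | None = None,
    max_steps_per_source: int | None = 500,
) -> bb.Bubble | None:
    """End-to-end recovery of a planted exon-skipping event.

    Builds the graph from simulated reads, compresses it, and enumerates
    bubbles with alpha1 = alpha2 = the inclusion-isoform length by default
    (path lengths on the compressed graph include the whole final unitig,
    so the bound must cover the shared downstream exon; intron-length
    detours still exceed it).  Returns the first bubble whose two spelled
    sequences are substrings of the two isoforms and whose longer path
    contains the skipped exon, or None.  ``max_steps_per_source`` bounds
    the work per source, as the production enumerator does with timeouts.
    """
    g = graph_from_scenario(ls, spec)
    cg = compress(g)
    if alpha2 is None:
        alpha2 = len(event.inclusion_seq)
    stream = bb.enumerate_all_bubbles(
        cg, alpha2, alpha2, b, max_steps_per_source=max_steps_per_source
    )
    for bubble in stream:
        try:
            s1, s2 = bb.spell_bubble(bubble, cg)
        except ValueError:
            continue
        long_seq, short_seq = (s1, s2) if len(s1) >= len(s2) else (s2, s1)
        if (
            event.skipped_exon in long_seq
            and long_seq in event.inclusion_seq
            and short_seq in event.exclusion_seq
        ):
            return bubble
    return None
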