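"""Topology-based confidence scoring of assembled transcripts.

Each transcript is mapped back onto the de Bruijn graph of the reads by
looking up its k-mers.  A k-mer is flagged ``branching`` if it is a
branching vertex of the graph, ``simple`` if present but non-branching,
and ``absent`` if missing (pruned or never sequenced).  The Branching
Measure B(t) of a transcript is the maximum proportion of branching k-mers
over all windows of w consecutive k-mers, after discarding a fraction of
the flags at each end (assembly ends are unreliable and would otherwise
dominate).  B(t) in [0, 1]; a high value means the transcript traverses a
branching-dense — typically repeat-induced — region where the assembler
had to guess among many paths, so the transcript is low-confidence
(chimeras and mis-extensions concentrate there).  Only the graph topology
is used: no read mapping, no coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import DeBruijnGraph, branching_vertices, reverse_complement

logger = logging.getLogger(__name__)

BRANCHING, SIMPLE, ABSENT = "branching", "simple", "absent"


@dataclass
class TranscriptMapping:
    """Per-k-mer flags of one transcript mapped onto the graph."""

    transcript_id: str
    flags: list[str]  # one of BRANCHING / SIMPLE / ABSENT per k-mer

    @property
    def n_absent(self) -> int:
        return sum(f == ABSENT for f in self.flags)


@dataclass
class BranchingProfile:
    """Windowed Branching Measure of one transcript.

    ``B`` is None when the trimmed region is empty.  ``window_start`` is
    the 1-based flag position (after trimming) of the maximising window.
    """

    transcript_id: str
    w: int
    B: float | None
    window_start: int | None
    trim_frac: float
    n_absent: int = 0
    length: int | None = None


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float | None


def map_transcript(
    g: DeBruijnGraph,
    transcript: str,
    transcript_id: str = "",
    *,
    check_reverse_complement: bool = False,
    _branching: set | None = None,
) -> TranscriptMapping:
    """Flag every k-mer of ``transcript`` against the graph.

    With ``check_reverse_complement`` a k-mer absent on the given strand is
    also looked up as its reverse complement (for graphs built with the
    reverse-complement option).  Raises ``ValueError`` if the transcript is
    shorter than k.
    """
    k = g.k
    transcript = transcript.upper()
    if len(transcript) < k:
        raise ValueError(
            f"transcript {transcript_id!r} is shorter than k={k} "
            f"({len(transcript)} nt)"
        )
    branching = _branching if _branching is not None else branching_vertices(g)
    nodes = g.g
    flags = []
    for i in range(len(transcript) - k + 1):
        km = transcript[i : i + k]
        if km not in nodes and check_reverse_complement:
            km = reverse_complement(km)
        if km not in nodes:
            flags.append(ABSENT)
        elif km in branching:
            flags.append(BRANCHING)
        else:
            flags.append(SIMPLE)
    return TranscriptMapping(transcript_id, flags)


def branching_measure(
    mapping: TranscriptMapping, w: int = 100, trim_frac: float = 0.10
) -> BranchingProfile:
    """Maximum windowed proportion of branching k-mers.

    ``floor(trim_frac * L)`` flags are discarded from each end (L = number
    of flags); a window of ``w`` flags then slides over the trimmed region
    (if the region is shorter than w, it forms a single window).  Absent
    k-mers count as non-branching in the proportion but are tallied in
    ``n_absent``: absence reflects pruning or sequencing gaps, not
    topological complexity.
    """
    if w < 1:
        raise ValueError("w must be >= 1")
    if not (0 <= trim_frac < 0.5):
        raise ValueError("trim_frac must be in [0, 0.5)")
    L = len(mapping.flags)
    cut = int(trim_frac * L)
    region = mapping.flags[cut : L - cut]
    if not region:
        logger.warning(
            "transcript %r: trimmed region is empty, B undefined",
            mapping.transcript_id,
        )
        return BranchingProfile(
            mapping.transcript_id, w, None, None, trim_frac,
            mapping.n_absent, L,
        )
    ind = np.fromiter((f == BRANCHING for f in region), dtype=int)
    ww = min(w, len(region))
    csum = np.concatenate([[0], np.cumsum(ind)])
    counts = csum[ww:] - csum[:-ww]
    best = int(np.argmax(counts))
    return BranchingProfile(
        mapping.transcript_id,
        w,
        float(counts[best]) / ww,
        best + 1,
        trim_frac,
        mapping.n_absent,
        L,
    )


def score_assembly(
    g: DeBruijnGraph,
    transcripts,
    w: int = 100,
    trim_frac: float = 0.10,
    *,
    check_reverse_complement: bool = False,
) -> pd.DataFrame:
    """One Branching-Measure profile per transcript record.

    ``transcripts`` is an iterable of ``(id, sequence)`` pairs (e.g. from
    :func:`repeatdbg.io.read_sequences`).  Records that fail to map (too
    short) are logged and skipped; scoring is deterministic.
    """
    branching = branching_vertices(g)
    rows = []
    for tid, seq in transcripts:
        try:
            mapping = map_transcript(
                g, seq, tid,
                check_reverse_complement=check_reverse_complement,
                _branching=branching,
            )
        except ValueError as exc:
            logger.warning("skipping %r: %s", tid, exc)
            continue
        prof = branching_measure(mapping, w=w, trim_frac=trim_frac)
        rows.append(
            {
                "transcript_id": tid,
                "length": len(seq),
                "B": prof.B,
                "window_start": prof.window_start,
                "w": w,
                "trim_frac": trim_frac,
                "n_absent": mapping.n_absent,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "length", "B", "window_start", "w",
            "trim_frac", "n_absent",
        ],
    )


def evaluate_flagging(profiles: pd.DataFrame, labels: dict) -> RocCurve:
    """ROC of B(t) as a chimera flag (higher B => predicted chimeric).

    ``labels`` maps transcript id to ``"chimeric"`` or ``"ok"`` (any
    non-chimeric label counts as negative); every labelled id must be
    present in ``profiles``.  AUC by trapezoidal integration; with a
    single class the AUC is undefined and reported as None.
    """
    from sklearn.metrics import auc as sk_auc
    from sklearn.metrics import roc_curve as sk_roc_curve

    scored = profiles.set_index("transcript_id")["B"]
    missing = [tid for tid in labels if tid not in scored.index]
    if missing:
        raise ValueError(f"labelled transcripts missing from profiles: {missing}")
    ids = [tid for tid in labels if not pd.isna(scored[tid])]
    dropped = len(labels) - len(ids)
    if dropped:
        logger.warning("dropping %d transcripts with undefined B", dropped)
    y = np.array([1 if labels[tid] == "chimeric" else 0 for tid in ids])
    scores = np.array([scored[tid] for tid in ids], dtype=float)
    if len(set(y)) < 2:
        logger.warning("single-class labels: AUC undefined")
        return RocCurve(np.array([]), np.array([]), np.array([]), None)
    fpr, tpr, thr = sk_roc_curve(y, scores, drop_intermediate=False)
    return RocCurve(thr, fpr, tpr, float(sk_auc(fpr, tpr)))
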