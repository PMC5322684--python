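"""The uniform model for high copy-number, low-divergence repeats.

A repeat family S(m, n, alpha) consists of m copies of length n derived
from a uniformly random ancestor s0: independently at every position of
every copy, the ancestral symbol is kept with probability 1 - alpha and
otherwise replaced by one of the three other symbols, uniformly.  Indels
are excluded by the model.  The family emulates, e.g., a recent
transposable-element invasion (many copies, divergence of a few percent).

The quantity of interest is the number of boundary-rigid (k-1)-mers of the
family — equivalently, the number of compressible arcs of its de Bruijn
graph.  For unrelated random sequences essentially every interior
(k-1)-mer is boundary rigid (about m(n-k+2) of them, provided
m(n-k+2) <= 4^(k-1)), whereas for a repeat family the count collapses as m
grows: shared (k-1)-mers accumulate conflicting mutated contexts.  The
analytic upper bound on the expected count, conditional on a copy's window
being at Hamming distance d from the ancestral window, is

    Pr[rigid | d] <= (1 - (2a - 4/3 a^2) (1-a)^(k-1-d) (a/3)^d)^(m-1)

with a = alpha, summed over d and scaled by (n-k-1) m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .graph import boundary_rigid_kmers

_IDX2BASE = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class RepeatModelParams:
    """Parameters of the uniform repeat model.

    m: number of copies (>= 1); n: copy length (>= 1); alpha: per-position
    mutation probability in [0, 3/4]; seed: RNG seed (one generator per
    family, copies drawn in order, positions vectorised per copy).
    """

    m: int
    n: int
    alpha: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError("m and n must be >= 1")
        if not (0.0 <= self.alpha <= 0.75):
            raise ValueError(f"alpha must be in [0, 3/4], got {self.alpha}")


@dataclass
class RepeatFamily:
    ancestor: str
    copies: list[str]
    params: RepeatModelParams

    def hamming_to_ancestor(self) -> list[int]:
        a = np.frombuffer(self.ancestor.encode(), dtype="S1")
        return [
            int((np.frombuffer(c.encode(), dtype="S1") != a).sum())
            for c in self.copies
        ]


@dataclass
class RigidBound:
    """Eq.-style upper bounds on the expected boundary-rigid count.

    ``summed`` is (n-k-1) * m * sum_d of the conditional bound — the form
    used in all experiments.  ``closed`` is the printed exponential
    approximation exp(-(m-1)(2a - 4/3 a^2) / (a/3)^(k-1)) scaled the same
    way; it is reproduced verbatim (including the divisor in the exponent)
    and is NaN at alpha = 0, where the expression is undefined.
    """

    summed: float
    closed: float


@dataclass
class RigidityExperiment:
    """One cell of the gamma-vs-model experiment."""

    k: int
    m: int
    n: int
    alpha: float
    model: str  # "repeat" or "random"
    observed_rigid: float  # mean over replicates
    expected_random: int  # m (n - k + 2)
    analytic_bound: float
    replicates: int

    @property
    def ratio(self) -> float:
        return self.observed_rigid / self.expected_random


def _decode(arr: np.ndarray) -> str:
    return _IDX2BASE[arr].tobytes().decode()


def random_sequences(m: int, n: int, seed=None) -> list[str]:
    """m independent uniform sequences over {A,C,G,T}^n."""
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    rng = np.random.default_rng(seed)
    return [_decode(rng.integers(0, 4, size=n)) for _ in range(m)]


def simulate_family(params: RepeatModelParams) -> RepeatFamily:
    """Draw a repeat family S(m, n, alpha), deterministic given the seed."""
    rng = np.random.default_rng(params.seed)
    s0 = rng.integers(0, 4, size=params.n)
    copies = []
    for _ in range(params.m):
        mutate = rng.random(params.n) < params.alpha
        # offset 1..3 from the ancestral symbol = uniform over the other 3
        offset = rng.integers(1, 4, size=params.n)
        copy = np.where(mutate, (s0 + offset) % 4, s0)
        copies.append(_decode(copy))
    return RepeatFamily(_decode(s0), copies, params)


def estimate_alpha(families: "RepeatFamily | Sequence[RepeatFamily]") -> float:
    """Unbiased estimate of alpha: mean Hamming distance to ancestor over n."""
    if isinstance(families, RepeatFamily):
        families = [families]
    dists, total = 0, 0
    for fam in families:
        dists += sum(fam.hamming_to_ancestor())
        total += fam.params.m * fam.params.n
    return dists / total


def rigid_probability_bound(k: int, d: int, m: int, alpha: float) -> float:
    """Conditional upper bound on Pr[a (k-1)-mer is boundary rigid].

    The condition is that the copy's (k-1)-window sits at Hamming distance d
    from the ancestral window; the bound is
    (1 - (2a - 4/3 a^2)(1-a)^(k-1-d)(a/3)^d)^(m-1).
    """
    if not (0 <= d <= k - 1):
        raise ValueError("d must be in [0, k-1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0.0 <= alpha <= 0.75):
        raise ValueError("alpha must be in [0, 3/4]")
    p = (2 * alpha - 4.0 / 3.0 * alpha**2) * (1 - alpha) ** (k - 1 - d) * (
        alpha / 3.0
    ) ** d
    return (1 - p) ** (m - 1)


def expected_rigid_bound(k: int, n: int, m: int, alpha: float) -> RigidBound:
    """Both printed forms of the bound on E[# boundary-rigid (k-1)-mers]."""
    if k >= n:
        raise ValueError("requires k < n")
    summed = (n - k - 1) * m * sum(
        rigid_probability_bound(k, d, m, alpha) for d in range(k)
    )
    if alpha == 0:
        closed = float("nan")
    else:
        exponent = -(m - 1) * (2 * alpha - 4.0 / 3.0 * alpha**2) / (alpha / 3.0) ** (
            k - 1
        )
        closed = (n - k - 1) * m * math.exp(exponent)
    return RigidBound(summed=summed, closed=closed)


def observed_rigid_count(sequences: Sequence[str], k: int) -> int:
    """Empirical boundary-rigid (k-1)-mer count of a set of sequences."""
    return len(boundary_rigid_kmers(sequences, k))


def gamma_experiment(
    grid: Sequence[RepeatModelParams],
    k: int,
    replicates: int = 10,
    seed: int = 0,
    include_random_control: bool = True,
) -> pd.DataFrame:
    """Average boundary-rigid counts over replicate families for each cell.

    For every parameter set the mean observed count is reported next to the
    random-sequence reference value m(n-k+2) and the summed analytic bound.
    With ``include_random_control`` a matching row of unrelated uniform
    sequences is added per cell; its ratio stays near 1 in the
    m(n-k+2) <= 4^(k-1) regime while the repeat-family ratio decays with m.
    """
    ss = np.random.SeedSequence(seed)
    rows: list[RigidityExperiment] = []
    for cell in grid:
        children = ss.spawn(2 * replicates)
        fam_counts = []
        rnd_counts = []
        for r in range(replicates):
            fam_seed = children[2 * r]
            params = RepeatModelParams(cell.m, cell.n, cell.alpha, seed=fam_seed)
            fam = simulate_family(params)
            fam_counts.append(observed_rigid_count(fam.copies, k))
            if include_random_control:
                rnd = random_sequences(cell.m, cell.n, seed=children[2 * r + 1])
                rnd_counts.append(observed_rigid_count(rnd, k))
        expected_random = cell.m * (cell.n - k + 2)
        bound = expected_rigid_bound(k, cell.n, cell.m, cell.alpha).summed
        rows.append(
            RigidityExperiment(
                k, cell.m, cell.n, cell.alpha, "repeat",
                float(np.mean(fam_counts)), expected_random, bound, replicates,
            )
        )
        if include_random_control:
            rows.append(
                RigidityExperiment(
                    k, cell.m, cell.n, cell.alpha, "random",
                    float(np.mean(rnd_counts)), expected_random, bound, replicates,
                )
            )
    df = pd.DataFrame([vars(r) for r in rows])
    df["ratio"] = df["observed_rigid"] / df["expected_random"]
    return df
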