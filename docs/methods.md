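# Methods

## Graph model

`build_graph` constructs the strand-specific de Bruijn graph of order k:
vertices are the distinct k-mers of the reads; an arc (u, v) requires the
supporting (k+1)-mer u·v[k] to occur in a read, and both vertices and arcs
carry occurrence counts. Requiring (k+1)-mer support (rather than mere
(k−1)-overlap between present k-mers) keeps arcs evidence-based and makes
the arc set exactly what the boundary-rigidity correspondence describes.
Characters outside {A,C,G,T} split a read into independent fragments. An
optional flag adds the reverse complement of every read for
non-strand-specific libraries; the default stays with the directed formal
object.

**Compressible arcs and compaction.** An arc (u, v) with out-degree(u) = 1
and in-degree(v) = 1 is compressible; self-loops are never compressible
and never contracted (contracting a self-loop is undefined and would spin
on homopolymers). `compress` merges maximal chains of compressible arcs
in linear time. Contraction is confluent — the result is independent of
the order in which individual arcs are contracted — so chain compaction is
equivalent to arc-by-arc contraction; the test suite checks this against a
naive reference that contracts arcs in lexicographic tail order. A cycle
consisting entirely of compressible arcs collapses to one vertex with a
self-loop. Arc weights in the compressed graph are
`len(label(head)) − (k−1)`, the nucleotides appended when traversing the
arc; for abstract (unlabelled) digraphs the same quantity is computed as
the entering arc's weight plus the weights contracted inside the head
chain.

**Boundary rigidity.** A (k−1)-mer is boundary rigid when every occurrence
has the same single predecessor symbol and the same single successor
symbol; occurrences at read (fragment) boundaries disqualify it, because a
boundary occurrence supplies no (k+1)-mer context on one side and the
corresponding arc is missing. With this convention each boundary-rigid
(k−1)-mer ŝ yields the compressible arc (a·ŝ, ŝ·c) and distinct ŝ yield
distinct arcs, so `|boundary_rigid_kmers| ≤ γ` always, with equality
whenever no (k−1)-mer recurs in two different contexts. The correspondence
is therefore exact with overwhelming probability on random read sets (the
regime in which it is asserted and tested) but can be broken
adversarially: in {AACTG, GGCTT} with k = 3, `CT` occurs in two contexts
and both flanking arcs are compressible while `CT` is not rigid. The
package treats γ as the primary statistic and reports both.

**Pruning.** `prune(g, abs_cutoff, rel_cutoff)` removes vertices with
coverage below the absolute cut-off, then — evaluating both directions on
that intermediate graph and applying all removals together — deletes arcs
whose coverage is below `rel_cutoff` times the summed coverage of their
sibling arcs at any branching in/out-neighbourhood, then drops isolated
vertices. The relative rule is this package's reconstruction (coverage
fraction against siblings); the thresholds are fully configurable and
recorded in outputs. Defaults (0, 0) are the identity.

## Repeat model S(m, n, α)

A uniform ancestor s₀ of length n; m copies mutate each position
independently with probability α (α ≤ 3/4), substituting uniformly among
the three other bases. Indels are excluded by construction and no option
reintroduces them. One seeded NumPy generator per family draws the
ancestor first, then copies in order (per copy: mutation mask, then
substitution offsets), making families bit-reproducible.

The analytic machinery evaluates the conditional bound
`Pr[rigid | d] ≤ (1 − (2α − 4/3·α²)(1−α)^(k−1−d)(α/3)^d)^(m−1)` and the
expected-count bound in two forms: the **summed** form
`(n−k−1)·m·Σ_{d=0}^{k−1} Pr[rigid | d]`, which is what every experiment
and test uses, and the printed **closed** exponential form, reproduced
verbatim even though its exponent divides by `(α/3)^(k−1)` where the
multiplicative structure of the preceding inequality would multiply — we
treat that as a typesetting artifact of the source derivation and expose
both rather than silently "fixing" one. The closed form is undefined
(NaN) at α = 0. The summed form also carries no weighting by Pr[d_H = d];
it is deliberately a loose upper envelope (at α = 0.02, k = 21 it exceeds
the trivial maximum m(n−k+2)), and the experiments use it only as the
stated bound, never as an estimate.

`gamma_experiment` reports, per parameter cell, the mean boundary-rigid
count over replicate families next to the random-sequence reference value
m(n−k+2) and the summed bound. At α = 0 all copies equal the ancestor and
the normalised ratio is exactly (n−k)/(m(n−k+2)) ≈ 1/m; at small α > 0
the ratio decays monotonically in m while unrelated random sequences stay
near 1 — the contrast that makes γ a usable repeat signature. Note the
maximum achievable ratio is (n−k)/(n−k+2) (≈ 0.946 at n = 50, k = 15),
not 1, because the two terminal (k−1)-mers of each sequence lack one
flank.

## Bounded-branching shortest paths

`bounded_branching_shortest_paths` computes d[β, t], the shortest length
from s to t using at most β branching vertices, for β = 0..b. The source
is never counted; the target is. Layer β = 0 seeds d[0, s] = 0 and relaxes
along arcs whose head is non-branching (a Dijkstra pass, since
non-branching chains may need within-layer fixpoint propagation on general
graphs). Each subsequent layer first settles branching targets from the
completed previous layer (entering one consumes a budget unit), then runs
the same within-layer pass for non-branching targets. Budgets are capped
at the number of branching vertices plus the implicit |V| cap — no simple
path can spend more — so the top layer equals the unconstrained Dijkstra
distance, which the tests assert on seeded random digraphs alongside an
exhaustive simple-path oracle and monotonicity in β. Weights must be
non-negative; zero weights are allowed (cycle removal never increases
length or branching count, so walk relaxation and simple-path semantics
agree).

## Bubble enumeration

An (s, t, α₁, α₂, b)-bubble is a pair of internally vertex-disjoint s→t
paths; branching counts exclude both endpoints. Endpoint exclusion is
forced by the objects themselves: t has in-degree ≥ 2 in every closed
bubble, so counting it would make b = 0 vacuous, and the DP already
excludes s. The α bounds apply to the *sorted* lengths: the shorter path
must fit α₁, the longer α₂ (α₁ ≤ α₂), matching the shorter-first
canonical form in which bubbles are reported. Canonical ordering is by
(length, vertex key); it also eliminates (π₁,π₂)/(π₂,π₁) mirror
duplicates, which the enumerator additionally avoids at the root by
pairing the two distinct first arcs out of s in a fixed order.

The recursion keeps two partial paths with endpoints u₁, u₂ in a shrinking
graph (discovered internal vertices removed). At each step it extends the
endpoint with the smaller accumulated length (ties: path 1; a frozen path
is never extended), partitioning the current solution subspace by the next
arc — an arc into the other endpoint closes and emits a bubble — plus one
subspace in which the extended path ends where it stands (its endpoint
becomes the target and its out-arcs are removed). A subspace is entered
only when the feasibility oracle certifies it non-empty (invariant INV),
which the tests instrument: zero recursive calls may come up empty.

The oracle runs the budgeted DP from both endpoints in the current graph
and asks for a common target t with d₁[β₁, t] ≤ remaining length₁ and
d₂[β₂, t] ≤ remaining length₂, under either assignment of (α₁, α₂) to the
two paths. Budgets are adjusted at the boundary cases: a branching target
is granted one extra unit (t is uncounted in a closed bubble), and a
branching endpoint uᵢ is charged one pending unit whenever its path must
still extend (t ≠ uᵢ), since uᵢ then becomes internal — without the
pending charge the oracle can certify subspaces whose only witnesses
overspend, breaking INV. Vertex-disjointness is dropped inside the
oracle: if two witness paths first intersect at t\*, their prefixes up to
t\* are internally disjoint and satisfy every monotone constraint, so
feasibility remains exact.

`enumerate_all_bubbles` unions the per-source streams over all vertices of
out-degree ≥ 2 (a bubble's source is its first vertex, so streams are
disjoint). An optional per-source step limit truncates pathologically
complex regions — the practical regime on repeat-dense graphs — with
truncation flagged in the run's statistics. `brute_force_bubbles` (DFS
over all simple path pairs, guarded to ≤ 30 vertices) is the independent
oracle used throughout the tests.

## Branching Measure

`map_transcript` flags each transcript k-mer as branching, simple, or
absent against the read graph. `branching_measure` discards
⌊trim_frac·L⌋ flags from each end (default 10%; assembly ends are
unreliable), slides a window of w flags (default w = 100; the window size
is a free parameter, always recorded in output) and returns the maximum
branching proportion, with the 1-based start of the maximising window.
Absent k-mers count as non-branching in the proportion — absence reflects
pruning or sequencing gaps, not topological complexity — but are tallied
separately so callers can filter on them. Windows are measured in flag
(k-mer) positions, not nucleotides. With proper trim fractions (< 0.5 per
side) a non-empty flag list can never be trimmed to nothing; only an empty
mapping yields an undefined B, reported as missing. ROC/AUC evaluation of
B(t) against chimera labels uses scikit-learn's `roc_curve`/`auc`
(trapezoidal, no intermediate-point dropping); all-tied scores give AUC
0.5 and single-class labels give an undefined AUC.

## Synthetic scenarios

**Repeat-pair (chimera) benchmark.** Unique flanks A, B, C, D (300 nt) and
two copies R₁, R₂ of one family (defaults S(8, 300, 0.02), using the
first two copies); true transcripts A·R₁·B and C·R₂·D. Chimeric records
follow the path an assembler would take through the collapsed repeat:
A·R₁[:p]·R₂[p:]·D and the converse, switching copies at a k-length window
where the copies agree (searched outward from the midpoint; at α = 0 this
is literally A·R·D). Reads (75 bp, 30× mean depth, uniform starts,
substitution errors only — matching the repeat model's exclusion of
indels) are drawn from the true transcripts only: chimeras are artifacts
to be scored, not molecules. Because every repeat-crossing transcript —
true or chimeric — traverses the same collapsed region, the two true
repeat carriers score essentially the same B as the chimeras; this is the
measure's inherent false-positive class, and discrimination comes from
the population structure: 18 repeat-free background transcripts
(2×300 nt) emulate the dominant repeat-free majority of a real
transcriptome, where chimeras are on the order of 1% of records. On
pooled scores over 10 seeds the AUC is ≈ 0.95: chimeras outrank all
background, tying only with the two repeat-carrying true transcripts per
seed.

**Drowned-bubble benchmark.** A gene E1·I1·E2·I2·E3 with unique exons
(E1, E3 300 nt; skipped exon E2 100 nt) and introns carrying half the
repeat family each, separated by 50 nt unique spacers. The inclusion
(E1·E2·E3) and exclusion (E1·E3) isoforms are the mRNA read sources; the
unspliced precursor contributes a fixed global fraction of reads
(default 15%, within the 5–15% range realistic for common extraction
protocols; per-gene correlation of precursor and mRNA expression is
simplified away at this scale). The intron repeats collapse into a
branching-dense tangle flanking the event while the event's own two paths
stay branching-sparse. `find_planted_bubble` runs the full pipeline
(reads → graph → compaction → enumeration) with α₁ = α₂ defaulting to the
inclusion-isoform length — on a compressed graph a path's length includes
the entire final unitig, so the bound must cover the shared downstream
exon; intron-length detours still exceed it — and b = 5 (the production
default for the branching budget), with a 500-step per-source work limit.
Recovery is declared when a bubble's two spelled sequences are substrings
of the two isoforms and the longer one contains the skipped exon. At
b = 5 the event is recovered in 10/10 seeds; with the budget removed and
the same small work limit (and α large enough to admit intron paths, the
regime that motivates bounding b), recovery collapses to a minority of
seeds — the enumeration spends its budget inside the tangle.

**What the generators do not emulate.** No indels, no position-dependent
error profiles, no paired-end structure, no expression heterogeneity, no
repeat subfamily tree structure or length variation among copies, and
read sampling is uniform rather than fragment-size driven. Passing these
benchmarks therefore demonstrates the algorithmic claims — the topology
signature, the rescue effect of bounding b, and the ranking power of
B(t) under collapsed repeats — not performance on real libraries, where
error removal, strand issues and richer repeat structure intervene.

## Numerical and engineering choices

- Sequences are discussed 1-based and closed-interval in documentation;
  internal storage is 0-based Python slicing.
- All stochastic components accept explicit seeds; child streams derive
  from `numpy.random.SeedSequence` spawning, so adding experiments never
  reshuffles existing ones.
- Graph containers are `networkx.DiGraph` wrapped in thin dataclasses
  (`DeBruijnGraph`, `CompressedGraph`); the enumerator converts to plain
  adjacency dictionaries internally for speed.
- Deterministic iteration everywhere: neighbours and sources are sorted
  by their representation before iteration, so streams are reproducible
  across runs and platforms.
- GFA 1.0 output uses S-lines with full unitig labels and L-lines with a
  `(k−1)M` overlap; the reader accepts only this forward-orientation
  subset and recovers k from the overlap.

## Known limitations

- The rigidity/γ bijection is probabilistic, not universal (see above);
  γ is the robust quantity.
- `brute_force_bubbles` is exponential and guarded to tiny graphs; it
  exists as an oracle, not an API.
- The Branching Measure flags complexity, not error: a correctly
  assembled transcript through a genuine repeat scores high (by design,
  these are its false positives), and a chimera joined outside any
  complex region scores low.
- Identifying repeat-associated subgraphs directly (minimising γ over
  large connected subgraphs) is NP-complete and deliberately out of
  scope; only the characterisation statistics are provided.
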