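# repeatdbg

Repeat-aware de Bruijn graph analysis for short-read RNA-seq assembly:
a formal repeat model with its graph-topological signature, a
branching-bounded bubble enumerator for calling alternative-splicing (AS)
events without getting lost in repeat-induced tangles, and a
topology-only confidence score for assembled transcripts.

## Who this is for

Developers and users of de novo transcriptome assemblers and local
(variant-calling) assemblers who need to reason about what high
copy-number, low-divergence repeats — typically transposable elements
carried into RNA-seq data by unspliced introns — do to a de Bruijn graph
(DBG), and how to work around them without a reference genome or a repeat
database.

## The model and the statistics

**Graphs.** For a read set *R* and order *k*, the DBG has a vertex for
every distinct k-mer of *R* and an arc (u, v) whenever the (k+1)-mer
u·v[k] occurs in a read. An arc is **compressible** when
d⁺(u) = 1 and d⁻(v) = 1; contracting all compressible arcs yields the
compressed (unitig) graph. γ denotes the number of compressible arcs.
A (k−1)-mer is **boundary rigid** when every occurrence in the reads has
the same predecessor symbol and the same successor symbol; on
read-derived graphs boundary-rigid (k−1)-mers correspond one-to-one with
compressible arcs.

**Repeat model.** S(m, n, α) draws a uniform ancestor s₀ ∈ {A,C,G,T}ⁿ and
m copies that keep each position with probability 1−α, otherwise
substitute uniformly among the three other bases (no indels). For
unrelated random sequences essentially all m(n−k+2) interior (k−1)-mers
are boundary rigid (when m(n−k+2) ≤ 4^(k−1)); for a repeat family the
normalised count collapses as m grows — repeats are recognisable as
subgraphs with **few compressible arcs**. The package evaluates the
analytic bound
Pr[rigid | d] ≤ (1 − (2α − 4/3·α²)(1−α)^(k−1−d)(α/3)^d)^(m−1),
summed over d and scaled by (n−k−1)·m.

**Bubbles.** An (s, t, α₁, α₂, b)-bubble is a pair of internally
vertex-disjoint s→t paths with weighted lengths ≤ α₁, α₂ and at most *b*
branching vertices each (endpoints uncounted). Bounding *b* is what lets
the enumerator recover AS events that are "drowned" next to repeat
tangles: the event's two isoform paths are branching-sparse even when
their surroundings are not. The enumerator recursively partitions the
solution space by the next arc of one partial path and descends only into
subspaces certified non-empty by a dynamic program that computes
shortest-path lengths under a branching budget in O(b·|E|).

**Branching Measure.** A transcript *t* mapped back onto the read DBG
gets one flag per k-mer (branching / simple / absent); B(t) is the
maximum proportion of branching flags in any window of *w* flags after
trimming 10% of flags from each end. High B(t) marks transcripts that
crossed a branching-dense (repeat-induced) region where the assembler had
to guess — where chimeras live.

## Worked example

```python
import repeatdbg as rd

# Two transcripts sharing a repeat family copy, plus background
spec = rd.ScenarioSpec(seed=0)           # 300 nt flanks, S(8, 300, 0.02), 75 bp reads
ls = rd.make_repeat_pair_scenario(spec)
g = rd.build_graph(rd.simulate_reads(ls, spec), spec.k)

stats = rd.graph_stats(g)
print(stats.gamma, stats.n_branching)    # 11946 8

df = rd.score_assembly(g, ls.sequences)  # Branching Measure per record
print(df.set_index("transcript_id").loc[
    ["t_ARB", "chimera_AD", "bg_0"], "B"].round(3))
# transcript_id
# t_ARB         0.04
# chimera_AD    0.04
# bg_0          0.00

roc = rd.evaluate_flagging(df, ls.labels)
print(round(roc.auc, 3))                 # 0.95
```

The repeat-sharing transcripts and the chimeras all traverse the
collapsed repeat (B = 0.04: four branching k-mers in the densest
100-k-mer window), while repeat-free background transcripts score 0 — so
ranking by B(t) flags the chimeras ahead of all background, with the two
repeat-carrying true transcripts as the expected near-ties (AUC 0.95).

Enumerating a planted exon-skipping event drowned next to intron repeats:

```python
spec = rd.ScenarioSpec(seed=7)
ls, event = rd.make_drowned_bubble(spec)
bub = rd.find_planted_bubble(ls, event, spec, b=5)
print(bub.len1, bub.len2, bub.branch1, bub.branch2)  # 19 119 0 1
```

The two paths differ by exactly the 100 nt skipped exon and stay within
the branching budget; with the budget removed and the same small work
limit, the enumeration wanders into the repeat tangle instead.

A CLI mirrors the library (`repeatdbg build-graph | graph-stats |
simulate-repeats | rigidity-experiment | enumerate-bubbles |
branching-measure | simulate-scenario | evaluate-flagging`).

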