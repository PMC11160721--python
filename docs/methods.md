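# Methods

## The problem

A clonal family is the set of B-cell receptor sequences descending from one
VDJ recombination event. Given a sample of heavy-chain sequences, clonal
assignment partitions them into families. The methods compared here span
the two regimes used in practice: junction-based rules that need a germline
reference for V/J annotation, and a reference-free phylogenetic rule
(Poisson tree processes) that consumes only the sequences.

## Repertoire simulation

**Germline.** Synthetic references carry i.i.d. uniform-random sequences:
44 V genes of 300 nt, 27 D of 20 nt, 6 J of 50 nt by default (the human
functional gene counts and typical segment lengths). Random sequences are
sufficient because every downstream consumer only needs the genes to be
distinguishable; no codon structure or allele nomenclature is modeled.
User references can be supplied as FASTA with `>NAME|SEGMENT` headers.

**Recombination.** A family's naive sequence is `V + np1 + D + np2 + J`
with V, D, J sampled uniformly and the N/P insertion lengths geometric on
{0, 1, …} with mean 5 per junction (a realistic amount of junctional
addition; fixed lengths, e.g. 6, are available and used for the
degraded-reference scenario). Exonuclease trimming is not modeled. The
junction window runs from the last 6 nt of V to the first 6 nt of J —
synthetic genes carry no conserved anchor residues, so the window is
positional; it always contains `np1 + D + np2`.

**Family sizes and trees.** Leaf counts are geometric on {1, 2, …} with
success probability 1/mean (a family has at least its founding cell).
Lineage trees are Yule (uniform pure-birth): the root splits at time zero,
each subsequent split waits Exp(1/k) at k lineages, and all branches extend
to a common end time, giving an ultrametric tree that is rescaled to unit
root-to-tip depth.

**SHM.** "Mutation rate per position" is interpreted as the expected number
of substitutions per site along any root-to-tip path: unit-depth branch
lengths are multiplied by the rate, and each mutable site receives a
Poisson-distributed number of events per branch, each to a uniformly chosen
different base. This is exactly Jukes–Cantor, so the expected tip-to-naive
divergence is `(3/4)(1 − exp(−4r/3))` — 4.8% at r = 0.05, which keeps rates
≤ 0.05 inside the ~5% divergence regime seen between real antibodies and
their germline precursors, and makes rates comparable across tree shapes.
`region="junction"` restricts mutable sites to the junction window;
positions outside it are conserved exactly.

**Seeding.** One master seed; family *i* uses the substream
`SeedSequence(master, spawn_key=(i,))`, so enlarging a repertoire never
perturbs existing families. Benchmark cells use
`SeedSequence(master, spawn_key=(configuration, replicate))`.

**What the generator does not emulate.** Context-dependent SHM hotspots,
indel SHM, exonuclease trimming, sequencing error, isotypes and light
chains. Consequences worth keeping in mind: uniform SHM puts *fewer*
mutations into the junction than hotspot-biased SHM would, so
junction-based methods oversplit somewhat later (in rate) here than they do
on hotspot-aware simulations; and identical family sizes cluster tightly
around the geometric mean. Passing tests therefore demonstrate correctness
of the algorithms and the direction of the method ranking, not quantitative
error rates on real repertoires.

## Annotation

`align` mode scores each germline gene against the read at every ungapped
offset and keeps the best V and J; a record is unannotated when the best V
identity falls below 0.8. Ungapped scoring is deliberate: when the
reference carries indels relative to the true germline (the degraded-
"fake"-reference scenario: 3 deletions + 3 insertions of size 1–4 and
20–40 point mutations per V gene), the frame shift collapses the match
score and annotation fails — the behavior the benchmark is designed to
expose. A gapped aligner would hide it. `oracle` mode passes the
simulator's ground-truth calls through and isolates clustering error from
annotation error.

## Clustering rules

* **Identical junction**: equality on (V call, J call, junction string).
* **Threshold**: within each (V, J, junction length) group, single-linkage
  agglomeration on junction Hamming distance normalized by junction length,
  cut at 0.15 by default. Nucleotide (not amino-acid) distance is used;
  grouping by junction length is required for Hamming distance to be
  defined. Single linkage means families stay whole as long as a chain of
  ≤-threshold neighbours exists.
* **Fuzzy clonotyping**: clusters of identical junctions, merged largest-
  first (ties lexicographic) into the first group holding any junction
  variant within `max_mismatch` (default 1) positions; V/J calls unused.
  The merge order is fixed purely for determinism.

Unannotated records always surface as singleton clusters rather than being
dropped, so evaluation can account for them.

## Poisson-tree-process delimitation

The rooted binary tree (NJ from pairwise Hamming distances, midpoint-
rooted; an externally built tree may be substituted) is partitioned into a
recombination process — a connected edge set containing the root — and
within-clone subtrees. Branch lengths in each process are i.i.d.
exponential. With per-subtree rates (multi-rate) or one shared within-clone
rate (single-rate), the maximized log-likelihood of n branches summing to s
is `h(n, s) = n ln(n/s) − n`; empty branch sets (singleton tips hanging off
recombination edges) contribute zero likelihood and zero parameters. Model
selection minimizes `AIC = 2k − 2 lnL` over all delimitations *and* the
one-process null model; AIC ties resolve to fewer parameters (the null).
Selecting by raw likelihood instead would always favour the most oversplit
delimitation, since each extra subtree brings a free rate parameter.

**Exact searches.** Minimizing AIC equals maximizing `lnL − k`. In
multi-rate mode each within-clone subtree contributes a local, separable
term (`h − 1`), leaving only the recombination term `h(n₀, s₀)` coupled
through the global count n₀ and sum s₀; the dynamic program therefore
propagates, per node and per recombination-edge count, the Pareto frontier
of (s₀, separable score) pairs — an exact algorithm whose cost grows with
frontier size. In single-rate mode all non-recombination branches pool, so
the objective depends only on (n₀, s₀); it is convex in s₀ at fixed n₀,
hence optimized at the minimum or maximum attainable s₀, which a
knapsack-style min/max DP tracks exactly at any tree size.

**Scale.** The multi-rate Pareto DP is used up to 40 tips (well past the
≤ 12-tip regime where exhaustive enumeration is feasible as an oracle);
above that a multi-start search is used: for a *fixed* recombination rate
the objective is edge-separable and a linear-time DP applies, and the rate
is re-estimated from each solution (each such iteration cannot decrease the
true objective). Across every tree where both were run (up to ~70 tips,
SHM 0.01–0.2) the multi-start search reproduced the exact optimum.

**Minimum branch length.** Branches below a floor are raised to it; with a
floor near zero, clusters of identical sequences produce arbitrarily large
exponential densities and the delimitation shatters into spurious clones.
The repertoire pipeline therefore floors branches at 1/L (alignment length
L — the smallest observable nonzero distance), which is also how the
species-delimitation tools handle their minimum branch length. With this
floor the pipeline recovers all 16 families at SHM 0.01 (F1 = 1.0).

**Unequal lengths.** Repertoire-wide distance matrices end-pad sequences
with an always-mismatching sentinel. Lengths are identical within a family
(no indel SHM), so padding only affects between-family distances, which
junctional length differences genuinely separate. One tree is built per
repertoire, consistent with the method's reference-free premise.

## Evaluation

For sequence x: TP/TN/FP/FN count the *other* sequences by (same/different
true family) × (same/different inferred cluster); precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 = 2TP/(2TP+FP+FN); the seven quantities are
averaged over evaluated sequences to one value per simulation. Sequences a
method failed to return are first re-added as singleton clusters; under the
standard protocol sequences in inferred singleton clusters are then
excluded (dropping sequences of *true* singleton families is a separate
flag, off by default). 0/0 ratios score 1 — a correctly isolated sequence
is not an error. The median of an even-sized list is the mean of the two
central values. These conventions matter only at the margins; the ranking
of methods is insensitive to them.

## Ancestral reconstruction

Per inferred cluster with > 2 members: NJ tree from the member sequences;
rooting at the midpoint of the longest tip-to-tip path (two-tip trees are
split at the path midpoint directly), or — as the "unrooted" convention —
at the parent node of the lexicographically first tip, which fixes which
basal node an unrooted reconstruction is read from. Root states are
reconstructed per site by Fitch parsimony (unit-cost Sankoff, valid for
polytomies; ties resolved A < C < G < T) or by marginal ML under
Jukes–Cantor with the tree's branch lengths. Parsimony is the default:
the simulator mutates under Jukes–Cantor mechanics, so a GTR-style model
would add parameters without information. Clusters are matched to true
families by majority vote (ties to the smaller family id) and scored by
Hamming distance to that family's naive sequence.

## Benchmark grid and problem sizes

The default grid is 6 SHM rates {0.001, 0.005, 0.01, 0.05, 0.1, 0.2} × 4
mean leaf counts — 24 configurations. The leaf means {2, 5, 10, 25} and the
default of 5 replicates per cell are this package's choices. The main setup
uses 16 clonal families (10/20/50 supported). The shipped analyses
(acceptance script, trend tests) run 16 families × mean 10 leaves × 3–5
replicates per condition — small enough for a desk run, large enough that
the method ranking and divergence statistics are stable across seeds.

## Known limitations

* The multi-rate search above 40 tips is a multi-start heuristic; it has
  matched the exact DP everywhere tested but carries no optimality proof.
* NJ on Hamming distances replaces maximum-likelihood tree inference;
  branch lengths are not substitution-model corrected, which slightly
  compresses deep branches at high SHM.
* The simulator's uniform SHM understates junction mutation load relative
  to hotspot-biased models; absolute F1 values at a given rate are
  therefore optimistic for junction-based methods.
* The fuzzy-clonotyping and threshold rules are transparent
  re-implementations of the published *rules*, not of any tool's code;
  engine-specific behaviors (alignment heuristics, abundance weighting)
  are out of scope.
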