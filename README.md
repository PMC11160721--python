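# clonefam

Simulation-based benchmarking of **B-cell clonal family assignment**.

After VDJ recombination, every B-cell lineage ("clonal family") descends
from one recombined heavy-chain sequence and diversifies by somatic
hypermutation (SHM). Repertoire analysis — clonal expansion, selection,
naive-ancestor inference — first requires grouping the sequenced receptors
into these families. `clonefam` simulates repertoires with known clonal
structure and measures how well different grouping strategies recover it,
including a phylogenetic strategy that needs **no germline reference** and
is therefore applicable to non-model organisms.

## What is implemented

**Simulator** — synthetic (or user-supplied) V/D/J germline references;
recombination `V + np1 + D + np2 + J` with geometric N/P insertion lengths;
geometric family sizes; Yule lineage trees rescaled to unit root-to-tip
depth; SHM as Poisson substitution events per site under Jukes–Cantor
mechanics, so a rate *r* yields expected divergence
`(3/4)(1 − e^(−4r/3))` from the naive ancestor. A junction-only SHM mode
and a degraded-reference mode (V genes perturbed with indels and 20–40
point mutations) reproduce the benchmark's stress scenarios.

**Assignment methods** (all consume AIRR-style rearrangement tables):

| method | rule |
|---|---|
| `cluster_identical_junction` | same V call, J call and byte-identical junction |
| `cluster_junction_threshold` | single-linkage clustering on normalized junction Hamming distance within (V, J, length) groups, cut at a threshold (default 0.15) |
| `cluster_cdr3_fuzzy` | identical-junction clonotypes merged when junctions differ at ≤ *k* positions |
| `assign_ptp` | reference-free: NJ tree from pairwise distances → midpoint root → Poisson-tree-process delimitation |

**Poisson tree processes.** The rooted tree is split into a *recombination*
process (a connected edge set containing the root, rate λ₀) and
*within-clone* subtrees (one exponential rate each in multi-rate mode, one
shared rate in single-rate mode). For *n* branches summing to *s* the
maximized exponential log-likelihood is `n·ln(n/s) − n`; the delimitation
minimizing `AIC = 2k − 2·lnL` (including the one-process null model) is
selected by exact dynamic programming, with an independent brute-force
enumerator used as a test oracle.

**Evaluation** — the per-sequence TP/TN/FP/FN scheme: for each sequence,
other sequences are classified by same/different true family × same/different
inferred cluster; precision, recall and F1 are averaged over sequences.
Missing sequences re-enter as singletons; discerned singletons can be
dropped (the standard protocol). Family counts and the MSE of the median
family size are also reported.

**Ancestral reconstruction** — per inferred family (> 2 members): NJ tree,
midpoint or fixed-basal rooting, root-state reconstruction by Fitch
parsimony or marginal ML under Jukes–Cantor, scored by Hamming distance to
the true naive sequence.

## Worked example

```python
import clonefam as cf

ref = cf.generate_synthetic_germline(seed=101)          # 44 V / 27 D / 6 J
rep = cf.simulate_repertoire(ref, n_clones=16, mean_leaves=10,
                             shm_rate=0.05, seed=1)
rec = cf.repertoire_to_records(rep)
truth = cf.partition_from_records(rec)
ann = cf.annotate_sequences(rec, mode="oracle")

for name, part in [
    ("identical-junction", cf.cluster_identical_junction(ann)),
    ("junction-threshold", cf.cluster_junction_threshold(ann, 0.15)),
    ("cdr3-fuzzy",         cf.cluster_cdr3_fuzzy(ann, 1)),
    ("ptp (multi-rate)",   cf.assign_ptp(rec)),
]:
    m = cf.summarize(truth, part)
    print(f"{name:20s} families={m.n_families_inferred:3d} "
          f"precision={m.mean_precision:.3f} recall={m.mean_recall:.3f} "
          f"F1={m.mean_f1:.3f}")
```

Output:

```
identical-junction   families= 27  precision=1.000  recall=0.460  F1=0.555
junction-threshold   families= 13  precision=1.000  recall=1.000  F1=1.000
cdr3-fuzzy           families= 30  precision=1.000  recall=0.461  F1=0.565
ptp (multi-rate)     families= 14  precision=1.000  recall=0.979  F1=0.985
```

At 5% SHM (the upper end of biologically realistic divergence — these 165
sequences sit on average 4.7% away from their naive ancestors), grouping by
*identical* junctions shatters the 16 true families into 27 clusters
(recall 0.46), and fuzzy clonotyping behaves similarly. Threshold-based
junction clustering recovers the families essentially perfectly, and the
reference-free tree delimitation comes close (F1 0.985) while consuming
nothing but the raw sequences. (Counts below 16 reflect dropped
singletons.)

The same stages are available from the shell:

```bash
clonefam simulate --n-clones 16 --mean-leaves 10 --shm-rate 0.05 --seed 1 --out-dir sim/
clonefam assign --method ptp --in sim/truth.tsv --out assigned.tsv
clonefam evaluate --truth sim/truth.tsv --inferred assigned.tsv
clonefam benchmark --out-dir results/   # full grid
```

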