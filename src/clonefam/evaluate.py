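"""Per-sequence scoring of an inferred partition against ground truth.

For every sequence x the other sequences are classified relative to x:

* TP — same true family, placed in the same inferred cluster;
* TN — different true family, placed in a different cluster;
* FP — different true family, placed in the same cluster;
* FN — same true family, placed in a different cluster.

Precision, recall and F1 follow the usual formulas; each of the seven
quantities is averaged over all evaluated sequences to give one value per
simulation.  Sequences a method failed to return are first re-added as
singleton clusters; when singleton dropping is on (the default protocol),
sequences sitting in inferred singleton clusters are then excluded from the
averages, and family counts are taken after the same filtering.  A sequence
whose counts are all zero against zero (a correctly isolated true singleton)
scores precision = recall = F1 = 1 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .assign import Partition


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    sequence_id: str
    tp: int
    tn: int
    fp: int
    fn: int


@dataclass(frozen=True)
class MetricsSummary:
    mean_tp: float
    mean_tn: float
    mean_fp: float
    mean_fn: float
    mean_precision: float
    mean_recall: float
    mean_f1: float
    n_sequences_evaluated: int
    n_families_true: int
    n_families_inferred: int
    n_singletons_removed: int
    n_missing_as_singletons: int


def _ratio(num: int, den: int) -> float:
    """0/0 convention: a correctly isolated sequence is not penalized."""
    return 1.0 if den == 0 else num / den


def confusion_counts(truth: Partition, inferred: Partition, sequence_id: str,
                     evaluated_ids: Iterable[str] | None = None) -> ConfusionCounts:
    """Confusion counts for one sequence over ``evaluated_ids`` (defaults to
    all ids in the truth partition); the sequence itself is excluded from
    all four counts."""
    ids = set(evaluated_ids) if evaluated_ids is not None else set(truth.assignment)
    if sequence_id not in truth.assignment or sequence_id not in inferred.assignment:
        raise EvaluationError(f"sequence {sequence_id!r} missing from a partition")
    fam = truth.assignment[sequence_id]
    clu = inferred.assignment[sequence_id]
    tp = tn = fp = fn = 0
    for other in ids:
        if other == sequence_id:
            continue
        same_fam = truth.assignment[other] == fam
        same_clu = inferred.assignment[other] == clu
        tp += same_fam and same_clu
        fn += same_fam and not same_clu
        fp += same_clu and not same_fam
        tn += not same_fam and not same_clu
    return ConfusionCounts(sequence_id, tp, tn, fp, fn)


def sequence_prf(counts: ConfusionCounts) -> tuple[float, float, float]:
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    recall = _ratio(counts.tp, counts.tp + counts.fn)
    f1 = _ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn)
    return precision, recall, f1


def _with_missing_as_singletons(inferred: Partition, all_ids: Sequence[str]) -> tuple[Partition, int]:
    assignment = dict(inferred.assignment)
    missing = [sid for sid in all_ids if sid not in assignment]
    for sid in missing:
        assignment[sid] = f"missing_{sid}"
    return Partition(assignment, inferred.method, inferred.params), len(missing)


def summarize(
    truth: Partition,
    inferred: Partition,
    drop_inferred_singletons: bool = True,
    drop_true_singletons: bool = False,
) -> MetricsSummary:
    """Average the seven per-sequence quantities into one summary.

    ``inferred`` may cover only a subset of the truth ids; missing ids are
    added back as singleton clusters first (and counted).  With
    ``drop_inferred_singletons`` (the standard protocol) sequences in
    inferred size-1 clusters are then removed from the evaluated set.
    """
    all_ids = sorted(truth.assignment)
    inferred, n_missing = _with_missing_as_singletons(inferred, all_ids)
    extra = set(inferred.assignment) - set(all_ids)
    if extra:
        raise EvaluationError(f"inferred partition contains unknown ids: {sorted(extra)[:3]}")

    fam = np.array([truth.assignment[s] for s in all_ids])
    clu = np.array([inferred.assignment[s] for s in all_ids])
    keep = np.ones(len(all_ids), dtype=bool)
    if drop_inferred_singletons:
        labels, counts = np.unique(clu, return_counts=True)
        single = set(labels[counts == 1])
        keep &= ~np.isin(clu, list(single)) if single else keep
    if drop_true_singletons:
        labels, counts = np.unique(fam, return_counts=True)
        single = set(labels[counts == 1])
        if single:
            keep &= ~np.isin(fam, list(single))
    n_removed = int((~keep).sum())
    fam_k, clu_k = fam[keep], clu[keep]
    n_eval = len(fam_k)
    if n_eval == 0:
        raise EvaluationError("no evaluable sequences after singleton filtering")

    # vectorized pair counting over the evaluated set
    fam_sizes = {f: c for f, c in zip(*np.unique(fam_k, return_counts=True))}
    clu_sizes = {c: n for c, n in zip(*np.unique(clu_k, return_counts=True))}
    both: dict[tuple[str, str], int] = {}
    for f, c in zip(fam_k, clu_k):
        both[(f, c)] = both.get((f, c), 0) + 1

    tps = np.array([both[(f, c)] - 1 for f, c in zip(fam_k, clu_k)], dtype=float)
    fns = np.array([fam_sizes[f] - 1 for f in fam_k], dtype=float) - tps
    fps = np.array([clu_sizes[c] - 1 for c in clu_k], dtype=float) - tps
    tns = (n_eval - 1) - tps - fns - fps

    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tps + fps == 0, 1.0, tps / np.maximum(tps + fps, 1e-300))
        recall = np.where(tps + fns == 0, 1.0, tps / np.maximum(tps + fns, 1e-300))
        f1 = np.where(2 * tps + fps + fns == 0, 1.0,
                      2 * tps / np.maximum(2 * tps + fps + fns, 1e-300))

    return MetricsSummary(
        mean_tp=float(tps.mean()), mean_tn=float(tns.mean()),
        mean_fp=float(fps.mean()), mean_fn=float(fns.mean()),
        mean_precision=float(precision.mean()), mean_recall=float(recall.mean()),
        mean_f1=float(f1.mean()),
        n_sequences_evaluated=n_eval,
        n_families_true=len(set(fam_k)),
        n_families_inferred=len(set(clu_k)),
        n_singletons_removed=n_removed,
        n_missing_as_singletons=n_missing,
    )


def median_family_size(partition: Partition, drop_singletons: bool = True) -> float:
    sizes = [s for s in partition.cluster_sizes() if s > 1 or not drop_singletons]
    if not sizes:
        raise EvaluationError("no families left after singleton filtering")
    return float(np.median(sizes))


def mse_median_family_size(pairs: Iterable[tuple[float, float]]) -> float:
    """Mean over simulations of (true median size − inferred median size)²."""
    pairs = list(pairs)
    if not pairs:
        raise EvaluationError("no simulations provided")
    return float(np.mean([(t - i) ** 2 for t, i in pairs]))


def count_families(partition: Partition, drop_singletons: bool = False) -> int:
    return sum(1 for s in partition.cluster_sizes() if s > 1 or not drop_singletons)
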