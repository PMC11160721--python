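"""Ancestral (naive) sequence reconstruction and its evaluation.

For every inferred clonal family of more than two sequences a
neighbor-joining tree is built from the member sequences, rooted either at
the midpoint of the longest tip-to-tip path or — mimicking reading the
reconstruction off an unrooted tree — at the basal node adjacent to the
lexicographically first tip.  The ancestral sequence at the root is then
reconstructed per site, either by Fitch parsimony (deterministic tie-break:
fixed base priority A < C < G < T among minimal-cost states) or by marginal
maximum likelihood under the Jukes–Cantor model with the tree's branch
lengths.  The Hamming distance between the reconstruction and the true
naive sequence of the majority-matched family measures how clonal
assignment errors propagate into this downstream inference.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

from .assign import Partition
from .simulate import NUCLEOTIDES, Repertoire, array_to_seq, seq_to_array

Method = Literal["fitch", "ml_jc"]
Rooting = Literal["midpoint", "unrooted"]


@dataclass(frozen=True)
class ReconstructionResult:
    cluster_id: str
    true_family_id: str | None
    inferred_ancestor: str
    hamming_to_truth: int | None
    normalized_distance: float | None
    rooting: str
    n_sequences: int


def hamming(a: str, b: str) -> int:
    """Number of differing positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    return int(np.count_nonzero(seq_to_array(a) != seq_to_array(b)))


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root a tree halfway between its two most distant tips.

    Total branch length is conserved; the two root-to-extreme-tip distances
    are equal.  Two-tip trees are handled directly (the root splits the
    single path in half).
    """
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValueError("midpoint rooting needs >= 2 tips")
    if len(tips) == 2:
        a, b = tips
        total = (a.length or 0.0) + (b.length or 0.0)
        if tree.parent is None and len(tree.children) == 2:
            half = total / 2.0
            return TreeNode.read([f"({a.name}:{half},{b.name}:{half});"])
    return tree.copy().root_at_midpoint(reset=True)


def _root_at_first_tip(tree: TreeNode) -> TreeNode:
    """Deterministic stand-in for reading an unrooted tree: re-root at the
    parent of the lexicographically first tip."""
    t = tree.copy()
    first = min(t.tips(), key=lambda tip: tip.name)
    parent = first.parent
    if parent is None or parent.parent is None:
        return t
    return t.root_at(parent, reset=True)


_BASE_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}


def _tip_rows(tree: TreeNode, tip_sequences: Mapping[str, str]) -> dict[str, np.ndarray]:
    names = [t.name for t in tree.tips()]
    if set(names) != set(tip_sequences):
        raise ValueError("tree tips and sequence labels do not match")
    lengths = {len(s) for s in tip_sequences.values()}
    if len(lengths) != 1:
        raise ValueError("tip sequences must have equal length")
    return {n: seq_to_array(tip_sequences[n]) for n in names}


def _fitch_root_states(tree: TreeNode, tip_sequences: Mapping[str, str]) -> np.ndarray:
    """Per-site minimal substitution cost per root state (Sankoff with unit
    costs, valid for polytomies), returning the cost matrix (4, L)."""
    rows = _tip_rows(tree, tip_sequences)
    L = len(next(iter(rows.values())))
    costs: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            row = rows[node.name]
            c = np.full((4, L), np.inf)
            for b, i in _BASE_INDEX.items():
                c[i, row == ord(b)] = 0.0
            costs[id(node)] = c
        else:
            total = np.zeros((4, L))
            for child in node.children:
                cc = costs[id(child)]
                # unit substitution cost: min over child states of cc + [state != parent]
                best_any = cc.min(axis=0)
                total += np.minimum(cc, best_any + 1.0)
            costs[id(node)] = total
    return costs[id(tree)]


def _jc_transition(b: float) -> np.ndarray:
    same = 0.25 + 0.75 * np.exp(-4.0 * b / 3.0)
    diff = (1.0 - same) / 3.0
    return np.full((4, 4), diff) + np.eye(4) * (same - diff)


def _ml_jc_root_posteriors(tree: TreeNode, tip_sequences: Mapping[str, str]) -> np.ndarray:
    """Per-site root state likelihoods under Jukes–Cantor (Felsenstein
    pruning), shape (4, L)."""
    rows = _tip_rows(tree, tip_sequences)
    L = len(next(iter(rows.values())))
    partial: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            row = rows[node.name]
            p = np.zeros((4, L))
            for b, i in _BASE_INDEX.items():
                p[i, row == ord(b)] = 1.0
            partial[id(node)] = p
        else:
            p = np.ones((4, L))
            for child in node.children:
                P = _jc_transition(child.length or 0.0)
                p *= P @ partial[id(child)]
            partial[id(node)] = p
    return 0.25 * partial[id(tree)]


def reconstruct_ancestor(tree: TreeNode, tip_sequences: Mapping[str, str],
                         method: Method = "fitch") -> str:
    """Reconstruct the root sequence; ties resolved by base priority
    A < C < G < T."""
    if method == "fitch":
        scores = -_fitch_root_states(tree, tip_sequences)  # higher is better
    elif method == "ml_jc":
        scores = _ml_jc_root_posteriors(tree, tip_sequences)
    else:
        raise ValueError(f"unknown reconstruction method {method!r}")
    # argmax returns the first (lowest-priority-index) maximum: A < C < G < T
    best = np.argmax(scores, axis=0)
    return array_to_seq(np.array([ord(NUCLEOTIDES[i]) for i in best], dtype=np.uint8))


def fitch_parsimony_score(tree: TreeNode, tip_sequences: Mapping[str, str]) -> int:
    """Minimal total substitution count over the tree (all sites)."""
    costs = _fitch_root_states(tree, tip_sequences)
    return int(costs.min(axis=0).sum())


def evaluate_reconstruction(
    rep: Repertoire,
    partition: Partition,
    rooting: Rooting = "midpoint",
    method: Method = "fitch",
    min_cluster_size: int = 3,
) -> list[ReconstructionResult]:
    """Reconstruct an ancestor for every inferred cluster of more than two
    sequences and compare it to the naive sequence of the true family
    matched by majority vote (ties toward the smaller family id).

    Clusters whose matched naive length differs from the reconstruction
    length are reported with a None distance.
    """
    from .ptp import build_nj_tree, pairwise_distance_matrix

    seq_by_id: dict[str, str] = {}
    family_of: dict[str, str] = {}
    naive_of: dict[str, str] = {}
    for fam in rep.families:
        naive_of[fam.family_id] = fam.event.naive_sequence
        for sid, seq in fam.tip_sequences.items():
            seq_by_id[sid] = seq
            family_of[sid] = fam.family_id

    results: list[ReconstructionResult] = []
    clusters: dict[str, list[str]] = {}
    for sid, cid in partition.assignment.items():
        clusters.setdefault(str(cid), []).append(str(sid))
    for cid in sorted(clusters):
        members = sorted(clusters[cid])
        if len(members) < min_cluster_size:
            continue
        votes = Counter(family_of[m] for m in members)
        top = max(votes.values())
        matched = min(f for f, v in votes.items() if v == top)
        records = pd.DataFrame({"sequence_id": members,
                                "sequence": [seq_by_id[m] for m in members]})
        tree = build_nj_tree(pairwise_distance_matrix(records))
        rooted = midpoint_root(tree) if rooting == "midpoint" else _root_at_first_tip(tree)
        tip_seqs = {m: seq_by_id[m] for m in members}
        ancestor = reconstruct_ancestor(rooted, tip_seqs, method=method)
        truth = naive_of[matched]
        if len(truth) == len(ancestor):
            d = hamming(ancestor, truth)
            nd = d / len(truth)
        else:
            d, nd = None, None
        results.append(ReconstructionResult(cid, matched, ancestor, d, nd,
                                            rooting, len(members)))
    return results
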