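"""Reference-free clonal assignment by Poisson tree processes (PTP).

A rooted binary tree built from the sequences is partitioned into a
*recombination* process — a connected set of edges containing the root,
analogous to speciation in species delimitation — and *within-clone*
(coalescent/SHM) processes, the maximal subtrees hanging below it.  Branch
lengths within each process are modeled as i.i.d. exponential; the
recombination process has its own rate, and the within-clone processes share
one rate (single-rate, classic PTP) or carry one rate each (multi-rate,
mPTP-style).  For a set of n branches summing to s the maximized exponential
log-likelihood is n·ln(n/s) − n.  Model selection — including against the
null model in which all branches form a single process — is by the Akaike
Information Criterion, AIC = 2k − 2·lnL; the delimitation with the smallest
AIC is returned, ties going to the model with fewer parameters.

A delimitation is encoded by the set of nodes that root the within-clone
subtrees: an antichain of internal nodes (no node an ancestor of another,
root excluded).  Tips not covered by any such subtree sit directly on
recombination edges and are singleton clones whose (empty) within-clone
process contributes zero log-likelihood and zero parameters.

Searching all delimitations exactly:

* multi-rate — minimizing AIC equals maximizing lnL − (#parameters), and the
  per-subtree rate parameters make the within-clone side fully decomposable
  (each chosen subtree contributes its local term minus 1).  The
  recombination term n·ln(n/s) − n couples the global edge count n and
  length sum s, so the dynamic program propagates, per node and per
  recombination-edge count, the Pareto frontier of (length sum s, best
  decomposable score c): only points with minimal s for their c can win.
  The frontier DP is exact; its cost grows with frontier size, so above
  ``exact_max_tips`` a multi-start search over the recombination rate is
  used instead (for a fixed rate the objective is edge-decomposable and a
  plain DP applies; candidate rates are refined by expectation/maximization
  style iteration, which monotonically improves the true score).
* single-rate — all non-recombination branches pool into one exponential, so
  lnL depends only on (n, s) of the recombination set; for fixed n it is
  convex in s, hence maximized at the minimal or maximal attainable s.  A
  knapsack-style DP tracking min/max s per edge count is exact at any size.

:func:`brute_force_delimit` enumerates every delimitation and exists as an
independent oracle for tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .assign import Partition
from .simulate import seq_to_array

Mode = Literal["multi_rate", "single_rate"]


class DelimitationError(ValueError):
    pass


@dataclass(frozen=True)
class Delimitation:
    """A PTP solution on a rooted tree.

    ``clusters`` are the tip-label sets of the within-clone subtrees plus the
    singleton tips attached directly to recombination edges; under the null
    model there is a single cluster holding every tip.
    """

    clusters: tuple[frozenset[str], ...]
    recombination_rate: float | None
    within_rates: tuple[float, ...]
    log_likelihood: float
    n_params: int
    aic: float
    mode: str
    null_model: bool = False

    def to_partition(self) -> Partition:
        return delimitation_to_partition(self)


def delimitation_to_partition(delim: Delimitation) -> Partition:
    assignment: dict[str, str] = {}
    for i, cluster in enumerate(sorted(delim.clusters, key=lambda c: sorted(c)[0])):
        for sid in cluster:
            assignment[sid] = f"ptp{i}"
    return Partition(assignment, method=f"ptp-{delim.mode}")


def pairwise_distance_matrix(records: pd.DataFrame, pad: bool = False) -> DistanceMatrix:
    """Normalized Hamming distance matrix over the sequences, with taxa
    ordered lexicographically by sequence_id.

    Sequences must have equal length unless ``pad=True``, in which case
    shorter sequences are end-padded with a sentinel that mismatches every
    base.  Within a simulated clonal family lengths are always identical
    (hypermutation introduces no indels), so padding only affects
    between-family distances, which junctional length differences genuinely
    separate.
    """
    df = records.sort_values("sequence_id")
    ids = [str(s) for s in df["sequence_id"]]
    lengths = df["sequence"].str.len().unique()
    if len(lengths) != 1 and not pad:
        raise DelimitationError(f"sequences must have equal length, saw {sorted(lengths)}")
    max_len = int(lengths.max())
    mat = np.zeros((len(ids), max_len), dtype=np.uint8)  # 0 = padding sentinel
    for i, s in enumerate(df["sequence"]):
        mat[i, :len(s)] = seq_to_array(s)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        d[i, i + 1:] = np.mean(mat[i + 1:] != mat[i], axis=1)
    d = d + d.T
    return DistanceMatrix(d, ids)


def build_nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; negative branch lengths clamped to zero."""
    if dm.shape[0] < 2:
        raise DelimitationError("need >= 2 taxa to build a tree")
    if dm.shape[0] == 2:
        d = float(dm[0, 1])
        a, b = dm.ids
        return TreeNode.read([f"({a}:{d / 2},{b}:{d / 2});"])
    return nj(dm, neg_as_zero=True)


def mle_exp_rate(branch_lengths: Iterable[float]) -> tuple[float | None, float]:
    """Exponential MLE for a branch set: rate n/Σb and log-likelihood
    n·ln(rate) − rate·Σb.  The empty set contributes (None, 0.0) — the
    zero-parameter convention for singleton clones."""
    b = [float(x) for x in branch_lengths]
    if not b:
        return None, 0.0
    if min(b) <= 0:
        raise DelimitationError("branch lengths must be positive (clamp first)")
    n, s = len(b), sum(b)
    rate = n / s
    return rate, n * math.log(rate) - rate * s


def _h(n: int, s: float) -> float:
    """Maximized exponential log-likelihood of n branches summing to s."""
    if n == 0:
        return 0.0
    return n * math.log(n / s) - n


def _prepare_tree(tree: TreeNode, min_branch: float) -> TreeNode:
    t = tree.copy()
    lengths = [node.length or 0.0 for node in t.traverse(include_self=False)]
    if not lengths or max(lengths) <= 0.0:
        raise DelimitationError("tree has no positive branch lengths")
    for node in t.traverse(include_self=False):
        node.length = max(node.length or 0.0, min_branch)
    for node in t.non_tips(include_self=True):
        if len(node.children) != 2:
            raise DelimitationError(
                f"delimitation requires a binary rooted tree; node has {len(node.children)} children")
    return t


def _subtree_info(t: TreeNode):
    """Per node: tip set, number of edges strictly below, their length sum."""
    tips: dict[int, frozenset[str]] = {}
    n_edges: dict[int, int] = {}
    s_edges: dict[int, float] = {}
    for node in t.postorder(include_self=True):
        if node.is_tip():
            tips[id(node)] = frozenset([node.name])
            n_edges[id(node)] = 0
            s_edges[id(node)] = 0.0
        else:
            tips[id(node)] = frozenset().union(*(tips[id(c)] for c in node.children))
            n_edges[id(node)] = sum(n_edges[id(c)] + 1 for c in node.children)
            s_edges[id(node)] = sum(s_edges[id(c)] + c.length for c in node.children)
    return tips, n_edges, s_edges


def _delim_from_roots(t: TreeNode, roots: set[int], tips, n_edges, s_edges,
                      mode: Mode) -> Delimitation:
    """Score the delimitation whose within-clone subtrees are rooted at the
    nodes with ids in ``roots`` (must be an antichain of internal nodes)."""
    clusters: list[frozenset[str]] = []
    within: list[tuple[int, float]] = []
    spec_n, spec_s = 0, 0.0

    def walk(node: TreeNode) -> None:
        nonlocal spec_n, spec_s
        for child in node.children:
            spec_n += 1
            spec_s += child.length
            if id(child) in roots:
                clusters.append(tips[id(child)])
                within.append((n_edges[id(child)], s_edges[id(child)]))
            elif child.is_tip():
                clusters.append(tips[id(child)])
                within.append((0, 0.0))
            else:
                walk(child)

    walk(t)
    lnl = _h(spec_n, spec_s)
    rates: list[float] = []
    if mode == "multi_rate":
        n_params = 1
        for n, s in within:
            lnl += _h(n, s)
            if n > 0:
                n_params += 1
                rates.append(n / s)
    else:
        nc = sum(n for n, _ in within)
        sc = sum(s for _, s in within)
        lnl += _h(nc, sc)
        n_params = 1 + (1 if nc > 0 else 0)
        if nc > 0:
            rates.append(nc / sc)
    return Delimitation(tuple(clusters), spec_n / spec_s if spec_n else None,
                        tuple(rates), lnl, n_params, 2 * n_params - 2 * lnl, mode)


def _null_delimitation(t: TreeNode, tips, n_edges, s_edges, mode: Mode) -> Delimitation:
    root_id = id(t)
    n, s = n_edges[root_id], s_edges[root_id]
    lnl = _h(n, s)
    return Delimitation((tips[root_id],), None, (n / s,), lnl, 1, 2 - 2 * lnl,
                        mode, null_model=True)


# ---------------------------------------------------------------------------
# exact multi-rate search: Pareto-frontier dynamic program
# ---------------------------------------------------------------------------

def _coal_score(node_id, n_edges, s_edges) -> float:
    """Decomposable score of declaring a within-clone subtree here:
    local exponential lnL minus 1 for its rate parameter (0 for tips)."""
    n = n_edges[node_id]
    if n == 0:
        return 0.0
    return _h(n, s_edges[node_id]) - 1.0


def _pareto_dp(t: TreeNode, n_edges, s_edges):
    """Per node, per recombination-edge count k below it: Pareto frontier of
    (recombination length sum s, within-clone score c), each entry carrying a
    backpointer describing the within-clone roots chosen below."""

    def prune(entries: dict[float, tuple[float, tuple]]) -> dict[float, tuple[float, tuple]]:
        # keep only entries not dominated by (smaller-or-equal s, larger c)
        items = sorted(entries.items())
        best_c = -math.inf
        out = {}
        for s, (c, bp) in items:
            if c > best_c:
                out[s] = (c, bp)
                best_c = c
        return out

    table: dict[int, dict[int, dict[float, tuple[float, tuple]]]] = {}
    for node in t.postorder(include_self=True):
        nid = id(node)
        if node.is_tip():
            table[nid] = {0: {0.0: (0.0, ("leaf",))}}
            continue
        entries: dict[int, dict[float, tuple[float, tuple]]] = {}
        if node.parent is not None:  # option: within-clone subtree rooted here
            entries[0] = {0.0: (_coal_score(nid, n_edges, s_edges), ("coal", nid))}
        a, b = node.children
        fa, fb = table[id(a)], table[id(b)]
        for ka, fra in fa.items():
            for kb, frb in fb.items():
                k = ka + kb + 2
                dest = entries.setdefault(k, {})
                for sa, (ca, bpa) in fra.items():
                    for sb, (cb, bpb) in frb.items():
                        s = sa + sb + a.length + b.length
                        c = ca + cb
                        cur = dest.get(s)
                        if cur is None or c > cur[0]:
                            dest[s] = (c, ("split", bpa, bpb))
        table[nid] = {k: prune(fr) for k, fr in entries.items()}
        # release child tables
        del table[id(a)], table[id(b)]
    return table[id(t)]


def _collect_roots(bp: tuple, roots: set[int]) -> None:
    if bp[0] == "coal":
        roots.add(bp[1])
    elif bp[0] == "split":
        _collect_roots(bp[1], roots)
        _collect_roots(bp[2], roots)


def _multi_rate_exact(t: TreeNode, tips, n_edges, s_edges) -> Delimitation:
    frontier = _pareto_dp(t, n_edges, s_edges)
    best_score, best_bp = -math.inf, None
    for k, fr in frontier.items():
        for s, (c, bp) in fr.items():
            score = _h(k, s) - 1.0 + c  # -1 for the recombination rate
            if score > best_score:
                best_score, best_bp = score, bp
    roots: set[int] = set()
    _collect_roots(best_bp, roots)
    return _delim_from_roots(t, roots, tips, n_edges, s_edges, "multi_rate")


# ---------------------------------------------------------------------------
# large-tree multi-rate search: fixed-rate DP with multi-start refinement
# ---------------------------------------------------------------------------

def _fixed_rate_dp(t: TreeNode, n_edges, s_edges, lam: float) -> set[int]:
    """Best within-clone roots when the recombination rate is fixed at
    ``lam``: every recombination edge of length b scores ln(lam) − lam·b,
    making the objective fully edge-decomposable."""
    log_lam = math.log(lam)
    score: dict[int, float] = {}
    choice: dict[int, bool] = {}  # True = within-clone subtree rooted here
    for node in t.postorder(include_self=True):
        nid = id(node)
        if node.is_tip():
            score[nid], choice[nid] = 0.0, True
            continue
        a, b = node.children
        split = (score[id(a)] + score[id(b)]
                 + 2 * log_lam - lam * (a.length + b.length))
        if node.parent is None:
            score[nid], choice[nid] = split, False
        else:
            coal = _coal_score(nid, n_edges, s_edges)
            choice[nid] = coal >= split
            score[nid] = max(coal, split)
    roots: set[int] = set()

    def walk(node: TreeNode) -> None:
        for child in node.children:
            if child.is_tip():
                continue
            if choice[id(child)]:
                roots.add(id(child))
            else:
                walk(child)

    walk(t)
    return roots


def _multi_rate_search(t: TreeNode, tips, n_edges, s_edges,
                       n_starts: int = 24, max_iter: int = 50) -> Delimitation:
    root_id = id(t)
    E, S = n_edges[root_id], s_edges[root_id]
    lo = 2.0 / S
    hi = E / (S * 1e-3)
    starts = np.geomspace(lo, hi, n_starts)
    best: Delimitation | None = None
    seen: set[frozenset[int]] = set()
    for lam0 in starts:
        lam = float(lam0)
        for _ in range(max_iter):
            roots = _fixed_rate_dp(t, n_edges, s_edges, lam)
            key = frozenset(roots)
            delim = _delim_from_roots(t, roots, tips, n_edges, s_edges, "multi_rate")
            if best is None or delim.aic < best.aic - 1e-12:
                best = delim
            if delim.recombination_rate is None:
                break
            new_lam = delim.recombination_rate
            if key in seen or abs(new_lam - lam) <= 1e-12 * lam:
                seen.add(key)
                break
            seen.add(key)
            lam = new_lam
    return best


# ---------------------------------------------------------------------------
# exact single-rate search: min/max recombination length sum per edge count
# ---------------------------------------------------------------------------

def _single_rate_exact(t: TreeNode, tips, n_edges, s_edges) -> Delimitation:
    NEG, POS = -math.inf, math.inf
    # per node: k -> (min_s, bp_min, max_s, bp_max)
    table: dict[int, dict[int, tuple[float, tuple, float, tuple]]] = {}
    for node in t.postorder(include_self=True):
        nid = id(node)
        if node.is_tip():
            table[nid] = {0: (0.0, ("leaf",), 0.0, ("leaf",))}
            continue
        entries: dict[int, tuple[float, tuple, float, tuple]] = {}
        if node.parent is not None:
            entries[0] = (0.0, ("coal", nid), 0.0, ("coal", nid))
        a, b = node.children
        for ka, (mna, bpmna, mxa, bpmxa) in table[id(a)].items():
            for kb, (mnb, bpmnb, mxb, bpmxb) in table[id(b)].items():
                k = ka + kb + 2
                add = a.length + b.length
                mn, bpmn = mna + mnb + add, ("split", bpmna, bpmnb)
                mx, bpmx = mxa + mxb + add, ("split", bpmxa, bpmxb)
                cur = entries.get(k)
                if cur is None:
                    entries[k] = (mn, bpmn, mx, bpmx)
                else:
                    cmn, cbpmn, cmx, cbpmx = cur
                    if mn < cmn:
                        cmn, cbpmn = mn, bpmn
                    if mx > cmx:
                        cmx, cbpmx = mx, bpmx
                    entries[k] = (cmn, cbpmn, cmx, cbpmx)
        table[nid] = entries
        del table[id(a)], table[id(b)]

    root_id = id(t)
    E, S = n_edges[root_id], s_edges[root_id]
    best_score, best_bp = -math.inf, None
    for k, (mn, bpmn, mx, bpmx) in table[root_id].items():
        for s, bp in ((mn, bpmn), (mx, bpmx)):
            # pooled within-clone branches: the remaining E-k edges
            lnl = _h(k, s) + _h(E - k, S - s)
            n_params = 1 + (1 if E - k > 0 else 0)
            score = lnl - n_params
            if score > best_score + 1e-15:
                best_score, best_bp = score, bp
    roots: set[int] = set()
    _collect_roots(best_bp, roots)
    return _delim_from_roots(t, roots, tips, n_edges, s_edges, "single_rate")


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def ptp_delimit(tree: TreeNode, mode: Mode = "multi_rate",
                min_branch: float = 1e-8,
                exact_max_tips: int = 40) -> Delimitation:
    """Poisson-tree-process delimitation of a rooted binary tree.

    Returns the smallest-AIC model among all delimitations and the null
    model; ties prefer the null model (fewest parameters).  ``multi_rate``
    uses the exact Pareto DP up to ``exact_max_tips`` tips and the
    multi-start fixed-rate search beyond; ``single_rate`` is exact at any
    size.
    """
    t = _prepare_tree(tree, min_branch)
    if t.count(tips=True) < 2:
        raise DelimitationError("need >= 2 tips")
    tips, n_edges, s_edges = _subtree_info(t)
    null = _null_delimitation(t, tips, n_edges, s_edges, mode)
    if mode == "multi_rate":
        if t.count(tips=True) <= exact_max_tips:
            best = _multi_rate_exact(t, tips, n_edges, s_edges)
        else:
            best = _multi_rate_search(t, tips, n_edges, s_edges)
    elif mode == "single_rate":
        best = _single_rate_exact(t, tips, n_edges, s_edges)
    else:
        raise DelimitationError(f"unknown mode {mode!r}")
    if null.aic <= best.aic + 1e-12:
        return null
    return best


def _enumerate_root_sets(node: TreeNode) -> list[set[int]]:
    """All ways to choose within-clone roots in the subtree below ``node``,
    given the edge above ``node`` is a recombination edge."""
    if node.is_tip():
        return [set()]
    options: list[set[int]] = []
    if node.parent is not None:
        options.append({id(node)})
    a, b = node.children
    for ra in _enumerate_root_sets(a):
        for rb in _enumerate_root_sets(b):
            options.append(ra | rb)
    return options


def brute_force_delimit(tree: TreeNode, mode: Mode = "multi_rate",
                        min_branch: float = 1e-8,
                        max_tips: int = 12) -> Delimitation:
    """Exhaustive-enumeration oracle: scores every delimitation (plus the
    null model) and returns the smallest-AIC one.  Refuses trees with more
    than ``max_tips`` tips."""
    t = _prepare_tree(tree, min_branch)
    if t.count(tips=True) > max_tips:
        raise DelimitationError(f"brute force limited to {max_tips} tips")
    if t.count(tips=True) < 2:
        raise DelimitationError("need >= 2 tips")
    tips, n_edges, s_edges = _subtree_info(t)
    best = _null_delimitation(t, tips, n_edges, s_edges, mode)
    for roots in _enumerate_root_sets(t):
        delim = _delim_from_roots(t, roots, tips, n_edges, s_edges, mode)
        if delim.aic < best.aic - 1e-12:
            best = delim
    return best


def assign_ptp(records: pd.DataFrame, mode: Mode = "multi_rate",
               min_branch: float | None = None, tree: TreeNode | None = None,
               exact_max_tips: int = 40) -> Partition:
    """Full reference-free pipeline: distance matrix → NJ tree → midpoint
    root → PTP delimitation → partition.  An externally built tree may be
    supplied instead of the NJ stand-in.

    When ``min_branch`` is None it defaults to 1/L for alignment length L —
    the smallest observable nonzero distance (one substitution).  Branches
    shorter than that are artifacts of identical or near-identical
    sequences; clamping them any lower lets the exponential densities of
    tight clusters grow without bound and drives spurious oversplitting.
    """
    from .ancestral import midpoint_root

    ids = [str(s) for s in records["sequence_id"]]
    if min_branch is None:
        min_branch = 1.0 / max(len(s) for s in records["sequence"])
    if len(ids) == 1:
        return Partition({ids[0]: "ptp0"}, method=f"ptp-{mode}")
    if tree is None:
        dm = pairwise_distance_matrix(records, pad=True)
        tree = build_nj_tree(dm)
    rooted = midpoint_root(tree)
    delim = ptp_delimit(rooted, mode=mode, min_branch=min_branch,
                        exact_max_tips=exact_max_tips)
    return delim.to_partition()
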