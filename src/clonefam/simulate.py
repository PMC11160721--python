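"""Ground-truth B-cell repertoire simulation.

Each clonal family is founded by one VDJ recombination event: a uniformly
sampled V, D and J gene joined with non-templated N/P nucleotides at the two
junctions (no exonuclease trimming).  The family then expands along a random
Yule lineage tree, rescaled to unit root-to-tip depth, and somatic
hypermutation (SHM) is applied down the tree under Jukes–Cantor mechanics:
on a branch of length ``b`` (unit-depth length times the SHM rate) every
mutable site receives a Poisson(``b``) number of substitution events, each to
a uniformly chosen different base.  The per-position SHM rate is therefore
the expected number of substitutions per site on any root-to-tip path, which
makes rates comparable across tree shapes and reproduces the Jukes–Cantor
expected divergence (3/4)(1 - exp(-4r/3)).

In ``region="junction"`` mode only the junction window mutates, leaving the
V, D and J templated positions outside the window untouched — a stripped-down
scenario that isolates how junction-focused clustering methods respond to
junction diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from skbio import TreeNode

from .germline import GermlineReference, NUCLEOTIDES

_NT_TO_INT = {b: i for i, b in enumerate(NUCLEOTIDES)}
_INT_TO_NT = np.frombuffer(NUCLEOTIDES.encode(), dtype=np.uint8)

RegionMode = Literal["whole", "junction"]

#: Number of V-end / J-start nucleotides included in the junction window on
#: top of np1 + D + np2.  Synthetic genes carry no codon anchors, so the
#: window is defined positionally rather than from conserved residues.
DEFAULT_JUNCTION_FLANK = 6


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


@dataclass(frozen=True)
class RecombinationEvent:
    """One VDJ recombination: the founding event of a clonal family."""

    v_name: str
    d_name: str
    j_name: str
    np1: str
    np2: str
    naive_sequence: str
    junction_start: int
    junction_end: int

    @property
    def junction(self) -> str:
        return self.naive_sequence[self.junction_start:self.junction_end]


@dataclass(frozen=True)
class ClonalFamily:
    """A recombination event, its lineage tree and the observed tip sequences."""

    family_id: str
    event: RecombinationEvent
    tree: TreeNode
    tip_sequences: dict[str, str]
    shm_rate: float


@dataclass(frozen=True)
class Repertoire:
    families: tuple[ClonalFamily, ...]
    config: dict

    @property
    def n_sequences(self) -> int:
        return sum(len(f.tip_sequences) for f in self.families)


def sample_leaf_count(mean_leaves: float, rng: np.random.Generator) -> int:
    """Draw a family size from a geometric distribution on {1, 2, ...} with
    mean ``mean_leaves`` (success probability 1/mean)."""
    if mean_leaves < 1:
        raise ValueError(f"mean_leaves must be >= 1, got {mean_leaves}")
    return int(rng.geometric(1.0 / mean_leaves))


def _sample_np_length(np_mean_len: float, np_fixed_len: int | None,
                      rng: np.random.Generator) -> int:
    if np_fixed_len is not None:
        return int(np_fixed_len)
    if np_mean_len <= 0:
        return 0
    # geometric on {0, 1, ...} with the given mean
    return int(rng.geometric(1.0 / (np_mean_len + 1.0))) - 1


def sample_recombination(
    ref: GermlineReference,
    np_mean_len: float = 5.0,
    rng: np.random.Generator | None = None,
    np_fixed_len: int | None = None,
    junction_flank: int = DEFAULT_JUNCTION_FLANK,
) -> RecombinationEvent:
    """Sample a recombination event: uniform V/D/J choice plus N/P insertions.

    N/P insertion lengths are geometric on {0, 1, ...} with mean
    ``np_mean_len`` per junction (default 5, a realistic total amount of
    junctional addition), or fixed when ``np_fixed_len`` is given.  The naive
    sequence is V + np1 + D + np2 + J with no trimming; the junction window
    spans the last ``junction_flank`` nt of V through the first
    ``junction_flank`` nt of J.
    """
    rng = np.random.default_rng() if rng is None else rng
    v = ref.v_genes[int(rng.integers(0, len(ref.v_genes)))]
    d = ref.d_genes[int(rng.integers(0, len(ref.d_genes)))]
    j = ref.j_genes[int(rng.integers(0, len(ref.j_genes)))]
    np1 = "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, _sample_np_length(np_mean_len, np_fixed_len, rng)))
    np2 = "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, _sample_np_length(np_mean_len, np_fixed_len, rng)))
    naive = v.sequence + np1 + d.sequence + np2 + j.sequence
    junction_start = max(0, len(v.sequence) - junction_flank)
    junction_end = min(len(naive), len(v.sequence) + len(np1) + len(d.sequence) + len(np2) + junction_flank)
    return RecombinationEvent(v.name, d.name, j.name, np1, np2, naive,
                              junction_start, junction_end)


def sample_family_tree(n_leaves: int, rng: np.random.Generator,
                       tip_prefix: str = "S") -> TreeNode:
    """Sample a Yule (pure-birth) lineage tree with ``n_leaves`` tips,
    rescaled so every root-to-tip path has length exactly 1.0."""
    if n_leaves < 1:
        raise ValueError(f"n_leaves must be >= 1, got {n_leaves}")
    if n_leaves == 1:
        tip = TreeNode(name=f"{tip_prefix}1", length=1.0)
        root = TreeNode(children=[tip])
        return root

    root = TreeNode()
    birth: dict[int, float] = {id(root): 0.0}
    # the root splits at time 0; each of its lineages is a candidate to split
    active: list[TreeNode] = []
    for _ in range(2):
        child = TreeNode(parent=None)
        root.append(child)
        birth[id(child)] = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_leaves:
        k = len(active)
        t += rng.exponential(1.0 / k)
        node = active.pop(int(rng.integers(0, k)))
        node.length = t - birth[id(node)]
        for _ in range(2):
            child = TreeNode()
            node.append(child)
            birth[id(child)] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / n_leaves)
    for i, node in enumerate(active):
        node.length = t_end - birth[id(node)]
    for i, tip in enumerate(root.tips()):
        tip.name = f"{tip_prefix}{i + 1}"
    # rescale to unit depth
    for node in root.traverse(include_self=False):
        node.length = node.length / t_end
    root.length = None
    return root


def _mutate_array(arr: np.ndarray, branch: float, mutable: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Poisson substitution events on mutable sites, each to a uniformly
    chosen different base (Jukes–Cantor mechanics)."""
    out = arr.copy()
    if branch <= 0:
        return out
    n_events = rng.poisson(branch, size=mutable.sum())
    idx = np.flatnonzero(mutable)
    for pos, k in zip(idx[n_events > 0], n_events[n_events > 0]):
        base = out[pos]
        for _ in range(int(k)):
            choices = [b for b in _INT_TO_NT if b != base]
            base = choices[int(rng.integers(0, 3))]
        out[pos] = base
    return out


def apply_shm(
    naive: str,
    tree: TreeNode,
    shm_rate: float,
    rng: np.random.Generator,
    region: RegionMode = "whole",
    window: tuple[int, int] | None = None,
) -> dict[str, str]:
    """Evolve ``naive`` down ``tree`` (unit-depth branch lengths multiplied by
    ``shm_rate``) and return the tip sequences keyed by tip name.

    In ``region="junction"`` mode only positions inside ``window``
    (0-based half-open) are mutable.
    """
    if shm_rate < 0:
        raise ValueError(f"shm_rate must be >= 0, got {shm_rate}")
    arr = seq_to_array(naive)
    mutable = np.ones(len(arr), dtype=bool)
    if region == "junction":
        if window is None:
            raise ValueError("junction-only mode requires a window")
        lo, hi = window
        if not (0 <= lo <= hi <= len(arr)):
            raise ValueError(f"window {window} outside sequence of length {len(arr)}")
        mutable[:] = False
        mutable[lo:hi] = True
    elif region != "whole":
        raise ValueError(f"unknown region mode {region!r}")

    tips: dict[str, str] = {}

    def _descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            branch = (child.length or 0.0) * shm_rate
            child_seq = _mutate_array(seq, branch, mutable, rng)
            if child.is_tip():
                tips[child.name] = array_to_seq(child_seq)
            else:
                _descend(child, child_seq)

    _descend(tree, arr)
    if not tree.children:  # degenerate single-node tree
        tips[tree.name] = naive
    return tips


def simulate_family(
    ref: GermlineReference,
    family_id: str,
    mean_leaves: float,
    shm_rate: float,
    rng: np.random.Generator,
    region: RegionMode = "whole",
    np_mean_len: float = 5.0,
    np_fixed_len: int | None = None,
    junction_flank: int = DEFAULT_JUNCTION_FLANK,
) -> ClonalFamily:
    n_leaves = sample_leaf_count(mean_leaves, rng)
    event = sample_recombination(ref, np_mean_len, rng, np_fixed_len, junction_flank)
    tree = sample_family_tree(n_leaves, rng, tip_prefix=f"{family_id}_S")
    window = (event.junction_start, event.junction_end)
    tips = apply_shm(event.naive_sequence, tree, shm_rate, rng,
                     region=region, window=window if region == "junction" else None)
    return ClonalFamily(family_id, event, tree, tips, shm_rate)


def simulate_repertoire(
    ref: GermlineReference,
    n_clones: int = 16,
    mean_leaves: float = 10.0,
    shm_rate: float = 0.01,
    region: RegionMode = "whole",
    seed: int | None = None,
    np_mean_len: float = 5.0,
    np_fixed_len: int | None = None,
    junction_flank: int = DEFAULT_JUNCTION_FLANK,
) -> Repertoire:
    """Simulate a repertoire of exactly ``n_clones`` clonal families.

    Per-family random substreams are derived from the master seed by family
    index, so increasing ``n_clones`` never perturbs earlier families.
    """
    if n_clones < 1:
        raise ValueError(f"n_clones must be >= 1, got {n_clones}")
    families = []
    for i in range(n_clones):
        sub = np.random.SeedSequence(entropy=seed if seed is not None else 0,
                                     spawn_key=(i,))
        rng = np.random.default_rng(sub)
        families.append(simulate_family(
            ref, f"F{i + 1}", mean_leaves, shm_rate, rng, region=region,
            np_mean_len=np_mean_len, np_fixed_len=np_fixed_len,
            junction_flank=junction_flank))
    config = dict(n_clones=n_clones, mean_leaves=mean_leaves, shm_rate=shm_rate,
                  region=region, seed=seed, np_mean_len=np_mean_len,
                  np_fixed_len=np_fixed_len, junction_flank=junction_flank)
    return Repertoire(tuple(families), config)


def divergence_stats(rep: Repertoire) -> tuple[dict[str, float], float]:
    """Mean per-site Hamming divergence of tips from their naive ancestor.

    Returns (per-family means, overall mean over all sequences).
    """
    if not rep.families:
        raise ValueError("empty repertoire")
    per_family: dict[str, float] = {}
    total, n_seq = 0.0, 0
    for fam in rep.families:
        naive = seq_to_array(fam.event.naive_sequence)
        divs = [
            float(np.mean(seq_to_array(s) != naive)) for s in fam.tip_sequences.values()
        ]
        per_family[fam.family_id] = float(np.mean(divs))
        total += sum(divs)
        n_seq += len(divs)
    return per_family, total / n_seq


def jc_expected_divergence(rate: float) -> float:
    """Jukes–Cantor expected per-site divergence after ``rate`` expected
    substitutions per site: (3/4)(1 - exp(-4 rate / 3))."""
    return 0.75 * (1.0 - np.exp(-4.0 * rate / 3.0))
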