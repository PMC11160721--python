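import numpy as np
import pytest

from clonefam import generate_synthetic_germline, repertoire_to_records, simulate_repertoire


@pytest.fixture(scope="session")
def germline():
    """Small but realistic synthetic reference (full human-like gene counts)."""
    return generate_synthetic_germline(seed=101)


@pytest.fixture(scope="session")
def tiny_germline():
    return generate_synthetic_germline(n_v=4, n_d=3, n_j=2, seed=7)


@pytest.fixture(scope="session")
def small_repertoire(germline):
    """16 families, mean 5 leaves, SHM 0.01 — the workhorse fixture."""
    return simulate_repertoire(germline, n_clones=16, mean_leaves=5,
                               shm_rate=0.01, seed=11)


@pytest.fixture(scope="session")
def small_records(small_repertoire):
    return repertoire_to_records(small_repertoire)


def random_binary_tree(rng, n_tips, min_len=0.02, max_len=1.0, prefix="t"):
    """Random rooted binary tree with uniform branch lengths, via recursive
    random splits of the tip set."""
    from skbio import TreeNode

    labels = [f"{prefix}{i}" for i in range(n_tips)]

    def build(names):
        if len(names) == 1:
            return TreeNode(name=names[0],
                            length=float(rng.uniform(min_len, max_len)))
        k = int(rng.integers(1, len(names)))
        node = TreeNode(length=float(rng.uniform(min_len, max_len)))
        node.extend([build(names[:k]), build(names[k:])])
        return node

    root = TreeNode()
    k = int(rng.integers(1, n_tips)) if n_tips > 1 else 1
    if n_tips == 1:
        root.append(build(labels))
    else:
        root.extend([build(labels[:k]), build(labels[k:])])
    return root
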