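import math

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from clonefam import (
    assign_ptp,
    brute_force_delimit,
    build_nj_tree,
    delimitation_to_partition,
    mle_exp_rate,
    pairwise_distance_matrix,
    partition_from_records,
    ptp_delimit,
    repertoire_to_records,
    simulate_repertoire,
)
from clonefam.ptp import DelimitationError

from conftest import random_binary_tree


class TestDistanceMatrix:
    def test_identical_sequences_zero(self):
        df = pd.DataFrame({"sequence_id": ["a", "b"], "sequence": ["ACGT", "ACGT"]})
        dm = pairwise_distance_matrix(df)
        assert dm[0, 1] == 0.0

    def test_half_different(self):
        df = pd.DataFrame({"sequence_id": ["a", "b"], "sequence": ["AAAA", "AATT"]})
        assert pairwise_distance_matrix(df)[0, 1] == 0.5

    def test_matches_double_loop(self, small_records):
        sub = small_records[small_records["sequence"].str.len()
                            == small_records["sequence"].str.len().iloc[0]].head(12)
        dm = pairwise_distance_matrix(sub)
        seqs = dict(zip(sub["sequence_id"], sub["sequence"]))
        for i in dm.ids:
            for j in dm.ids:
                expected = np.mean([a != b for a, b in zip(seqs[i], seqs[j])])
                assert dm[i, j] == pytest.approx(expected)

    def test_unequal_lengths_rejected_without_padding(self):
        df = pd.DataFrame({"sequence_id": ["a", "b"], "sequence": ["ACGT", "ACG"]})
        with pytest.raises(DelimitationError):
            pairwise_distance_matrix(df)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # three-point formulas: x+y=d_ab, x+z=d_ac, y+z=d_bc
        from skbio import DistanceMatrix

        d_ab, d_ac, d_bc = 0.4, 0.6, 0.8
        dm = DistanceMatrix([[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]],
                            ["a", "b", "c"])
        tree = build_nj_tree(dm)
        dist = {t.name: tree.distance(t) + 0 for t in tree.tips()}
        assert tree.distance(tree.find("a")) + tree.distance(tree.find("b")) == pytest.approx(d_ab)
        assert tree.find("a").length == pytest.approx((d_ab + d_ac - d_bc) / 2)

    def test_additive_matrix_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:4):2); patristic distances are additive
        from skbio import DistanceMatrix

        truth = TreeNode.read(["((a:1,b:2):1,(c:3,d:4):2);"])
        ids = ["a", "b", "c", "d"]
        mat = [[truth.find(i).distance(truth.find(j)) for j in ids] for i in ids]
        tree = build_nj_tree(DistanceMatrix(mat, ids))
        for i in ids:
            for j in ids:
                got = tree.find(i).distance(tree.find(j))
                assert got == pytest.approx(mat[ids.index(i)][ids.index(j)])
        # topology: {a,b} vs {c,d} split present
        names = {frozenset(t.name for t in n.tips()) for n in tree.non_tips()}
        assert frozenset({"a", "b"}) in names or frozenset({"c", "d"}) in names

    def test_newick_round_trip(self):
        rng = np.random.default_rng(0)
        tree = random_binary_tree(rng, 6)
        back = TreeNode.read([str(tree)])
        assert {t.name for t in back.tips()} == {t.name for t in tree.tips()}
        for t in tree.tips():
            assert back.find(t.name).length == pytest.approx(t.length)

    def test_too_few_taxa(self):
        from skbio import DistanceMatrix

        with pytest.raises(DelimitationError):
            build_nj_tree(DistanceMatrix([[0.0]], ["a"]))


class TestExponentialMLE:
    @pytest.mark.parametrize("branches, rate, lnl", [
        ([1, 1, 1], 1.0, -3.0),
        ([0.5, 1.5], 1.0, -2.0),
        ([2], 0.5, math.log(0.5) - 1),
    ])
    def test_closed_forms(self, branches, rate, lnl):
        got_rate, got_lnl = mle_exp_rate(branches)
        assert got_rate == pytest.approx(rate)
        assert got_lnl == pytest.approx(lnl)

    def test_empty_set_convention(self):
        assert mle_exp_rate([]) == (None, 0.0)

    def test_rate_recovery_large_sample(self):
        rng = np.random.default_rng(12)
        lam = 3.7
        draws = rng.exponential(1 / lam, 10_000)
        rate, _ = mle_exp_rate(draws)
        assert abs(rate - lam) / lam < 0.05


def two_cluster_tree():
    """Two tight 3-tip clades on long stems: an unambiguous 2-clone tree."""
    return TreeNode.read([
        "(((a1:0.01,a2:0.01):0.01,a3:0.02):0.5,"
        "((b1:0.01,b2:0.01):0.01,b3:0.02):0.5);"
    ])


class TestDelimitation:
    def test_two_separated_clusters_beat_null(self):
        delim = ptp_delimit(two_cluster_tree(), "multi_rate")
        assert not delim.null_model
        sets = {frozenset(c) for c in delim.clusters}
        assert sets == {frozenset({"a1", "a2", "a3"}), frozenset({"b1", "b2", "b3"})}
        null = brute_force_delimit(two_cluster_tree(), "multi_rate")
        assert delim.aic == pytest.approx(null.aic)  # oracle picks the same model

    def test_homogeneous_tree_prefers_null(self):
        tree = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1);"])
        delim = ptp_delimit(tree, "multi_rate")
        assert delim.null_model and len(delim.clusters) == 1
        assert brute_force_delimit(tree, "multi_rate").null_model

    def test_aic_identity(self):
        for mode in ("multi_rate", "single_rate"):
            d = ptp_delimit(two_cluster_tree(), mode)
            assert d.aic == pytest.approx(2 * d.n_params - 2 * d.log_likelihood)

    def test_clusters_partition_tips(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            tree = random_binary_tree(rng, int(rng.integers(4, 10)))
            delim = ptp_delimit(tree, "multi_rate")
            tips = [t.name for t in tree.tips()]
            covered = [name for c in delim.clusters for name in c]
            assert sorted(covered) == sorted(tips)

    @pytest.mark.parametrize("mode", ["multi_rate", "single_rate"])
    def test_dp_equals_exhaustive_enumeration(self, mode):
        """The defining oracle property: on 60 random trees of up to 8 tips
        the DP matches brute-force enumeration to 1e-9 in log-likelihood."""
        rng = np.random.default_rng(42)
        for i in range(60):
            n = int(rng.integers(2, 9))
            tree = random_binary_tree(rng, n, min_len=0.01, max_len=1.5)
            dp = ptp_delimit(tree, mode)
            oracle = brute_force_delimit(tree, mode)
            assert dp.log_likelihood == pytest.approx(oracle.log_likelihood, abs=1e-9)
            assert dp.aic == pytest.approx(oracle.aic, abs=1e-9)
            assert {frozenset(c) for c in dp.clusters} == \
                {frozenset(c) for c in oracle.clusters}

    def test_heuristic_matches_exact_on_midsize_trees(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            tree = random_binary_tree(rng, 20, min_len=0.01, max_len=1.0)
            exact = ptp_delimit(tree, "multi_rate", exact_max_tips=40)
            heur = ptp_delimit(tree, "multi_rate", exact_max_tips=1)
            assert heur.aic == pytest.approx(exact.aic, abs=1e-6)

    def test_brute_force_refuses_large_trees(self):
        rng = np.random.default_rng(8)
        with pytest.raises(DelimitationError):
            brute_force_delimit(random_binary_tree(rng, 20))

    def test_min_branch_clamping_handles_zero_branches(self):
        tree = TreeNode.read(["((a:0,b:0):0.5,(c:0,d:0):0.5);"])
        delim = ptp_delimit(tree, "multi_rate", min_branch=1e-4)
        assert delim.log_likelihood == delim.log_likelihood  # finite

    def test_all_zero_tree_rejected(self):
        tree = TreeNode.read(["((a:0,b:0):0,(c:0,d:0):0);"])
        with pytest.raises(DelimitationError):
            ptp_delimit(tree, "multi_rate")


class TestPartitionConversion:
    def test_null_model_single_cluster(self):
        tree = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1);"])
        part = delimitation_to_partition(ptp_delimit(tree, "multi_rate"))
        assert len(part.as_sets()) == 1

    def test_two_cluster_example(self):
        part = delimitation_to_partition(ptp_delimit(two_cluster_tree(), "multi_rate"))
        assert part.as_sets() == frozenset({
            frozenset({"a1", "a2", "a3"}), frozenset({"b1", "b2", "b3"})})


class TestRepertoirePipeline:
    def test_reference_free_full_coverage(self, small_records):
        part = assign_ptp(small_records)
        assert set(part.assignment) == {str(s) for s in small_records["sequence_id"]}

    def test_low_shm_closer_to_truth_than_high_shm(self, germline):
        def count_error(shm, seed):
            rep = simulate_repertoire(germline, n_clones=10, mean_leaves=5,
                                      shm_rate=shm, seed=seed)
            rec = repertoire_to_records(rep)
            part = assign_ptp(rec)
            return abs(len(part.as_sets()) - 10)

        low = np.mean([count_error(0.01, s) for s in (1, 2, 3)])
        high = np.mean([count_error(0.2, s) for s in (1, 2, 3)])
        assert low < high
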