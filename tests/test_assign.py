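import numpy as np
import pandas as pd
import pytest

from clonefam import (
    annotate_sequences,
    cluster_cdr3_fuzzy,
    cluster_identical_junction,
    cluster_junction_threshold,
    partition_from_records,
    perturb_v_genes,
    repertoire_to_records,
    simulate_repertoire,
)


def records_from(rows):
    df = pd.DataFrame(rows)
    for col in ("v_call", "j_call", "junction"):
        if col not in df:
            df[col] = None
    return df


def brute_force_partition(records, related):
    """Transitive closure of a pairwise 'clonally related' predicate —
    the independent grouping oracle."""
    ids = [str(s) for s in records["sequence_id"]]
    rows = {str(r.sequence_id): r for r in records.itertuples()}
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in ids:
        for j in ids:
            if i < j and related(rows[i], rows[j]):
                parent[find(i)] = find(j)
    clusters = {}
    for i in ids:
        clusters.setdefault(find(i), set()).add(i)
    return frozenset(frozenset(c) for c in clusters.values())


def is_annotated(row):
    return row.v_call is not None and row.junction is not None


class TestAnnotate:
    def test_oracle_mode_passes_truth_through(self, small_records):
        ann = annotate_sequences(small_records, mode="oracle")
        assert (ann["junction"] == small_records["junction"]).all()

    def test_oracle_mode_requires_truth(self):
        df = pd.DataFrame({"sequence_id": ["a"], "sequence": ["ACGT"]})
        with pytest.raises(ValueError):
            annotate_sequences(df, mode="oracle")

    def test_align_mode_recovers_calls_without_mutation(self, germline):
        rep = simulate_repertoire(germline, n_clones=8, mean_leaves=3,
                                  shm_rate=0.0, seed=21)
        rec = repertoire_to_records(rep)
        ann = annotate_sequences(rec, germline, mode="align")
        assert (ann["v_call"] == rec["v_call"]).all()
        assert (ann["j_call"] == rec["j_call"]).all()

    def test_align_against_perturbed_reference_drops_records(self, germline):
        # a degraded reference assembly: indels break ungapped alignment
        fake = perturb_v_genes(germline, seed=5)
        rep = simulate_repertoire(germline, n_clones=8, mean_leaves=3,
                                  shm_rate=0.05, seed=22)
        rec = repertoire_to_records(rep)
        ann = annotate_sequences(rec, fake, mode="align")
        assert ann["v_call"].isna().sum() > 0


class TestIdenticalJunction:
    def test_recovers_truth_without_mutation(self, germline):
        rep = simulate_repertoire(germline, n_clones=10, mean_leaves=4,
                                  shm_rate=0.0, seed=31)
        rec = repertoire_to_records(rep)
        part = cluster_identical_junction(annotate_sequences(rec, mode="oracle"))
        assert part.as_sets() == partition_from_records(rec).as_sets()

    def test_single_junction_mutation_splits(self):
        df = records_from([
            {"sequence_id": "a", "v_call": "V1", "j_call": "J1", "junction": "AAAA"},
            {"sequence_id": "b", "v_call": "V1", "j_call": "J1", "junction": "AAAT"},
        ])
        assert len(cluster_identical_junction(df).as_sets()) == 2

    def test_matches_brute_force_pairwise_grouping(self, small_records):
        ann = annotate_sequences(small_records.head(30), mode="oracle")
        part = cluster_identical_junction(ann)
        oracle = brute_force_partition(
            ann,
            lambda r1, r2: (r1.v_call == r2.v_call and r1.j_call == r2.j_call
                            and r1.junction == r2.junction),
        )
        assert part.as_sets() == oracle

    def test_unannotated_become_singletons(self):
        df = records_from([
            {"sequence_id": "a", "v_call": "V1", "j_call": "J1", "junction": "AAAA"},
            {"sequence_id": "b", "v_call": None, "j_call": None, "junction": None},
        ])
        sets = cluster_identical_junction(df).as_sets()
        assert frozenset({"b"}) in sets


class TestJunctionThreshold:
    def test_two_of_twenty_links(self):
        j1 = "A" * 20
        j2 = "T" * 2 + "A" * 18  # distance 0.10 <= 0.15
        df = records_from([
            {"sequence_id": "a", "v_call": "V1", "j_call": "J1", "junction": j1},
            {"sequence_id": "b", "v_call": "V1", "j_call": "J1", "junction": j2},
        ])
        assert len(cluster_junction_threshold(df, 0.15).as_sets()) == 1

    def test_four_of_twenty_does_not_link(self):
        j1 = "A" * 20
        j2 = "T" * 4 + "A" * 16  # distance 0.20 > 0.15
        df = records_from([
            {"sequence_id": "a", "v_call": "V1", "j_call": "J1", "junction": j1},
            {"sequence_id": "b", "v_call": "V1", "j_call": "J1", "junction": j2},
        ])
        assert len(cluster_junction_threshold(df, 0.15).as_sets()) == 2

    def test_maximal_threshold_merges_vj_length_groups(self, small_records):
        ann = annotate_sequences(small_records, mode="oracle")
        part = cluster_junction_threshold(ann, 1.0)
        oracle = brute_force_partition(
            ann,
            lambda r1, r2: (r1.v_call == r2.v_call and r1.j_call == r2.j_call
                            and len(r1.junction) == len(r2.junction)),
        )
        assert part.as_sets() == oracle

    def test_matches_brute_force_single_linkage(self, germline):
        rep = simulate_repertoire(germline, n_clones=6, mean_leaves=5,
                                  shm_rate=0.1, seed=33)
        ann = annotate_sequences(repertoire_to_records(rep), mode="oracle").head(30)
        threshold = 0.15

        def related(r1, r2):
            if (r1.v_call != r2.v_call or r1.j_call != r2.j_call
                    or len(r1.junction) != len(r2.junction)):
                return False
            d = sum(a != b for a, b in zip(r1.junction, r2.junction)) / len(r1.junction)
            return d <= threshold

        part = cluster_junction_threshold(ann, threshold)
        assert part.as_sets() == brute_force_partition(ann, related)

    def test_monotone_in_threshold(self, germline):
        rep = simulate_repertoire(germline, n_clones=8, mean_leaves=5,
                                  shm_rate=0.1, seed=34)
        ann = annotate_sequences(repertoire_to_records(rep), mode="oracle")
        counts = [len(cluster_junction_threshold(ann, t).as_sets())
                  for t in (0.0, 0.05, 0.15, 0.3, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_threshold(self, small_records):
        with pytest.raises(ValueError):
            cluster_junction_threshold(small_records, 1.5)


class TestCdr3Fuzzy:
    def test_zero_mismatch_is_identity_clustering_ignoring_vj(self):
        df = records_from([
            {"sequence_id": "a", "v_call": "V1", "j_call": "J1", "junction": "AAAA"},
            {"sequence_id": "b", "v_call": "V2", "j_call": "J2", "junction": "AAAA"},
            {"sequence_id": "c", "v_call": "V1", "j_call": "J1", "junction": "AAAT"},
        ])
        sets = cluster_cdr3_fuzzy(df, 0).as_sets()
        assert sets == frozenset({frozenset({"a", "b"}), frozenset({"c"})})

    def test_chain_merge_with_largest_first_order(self):
        df = records_from([
            {"sequence_id": s, "junction": j}
            for s, j in [("a", "AAAA"), ("b", "AAAT"), ("c", "AATT")]
        ])
        sets = cluster_cdr3_fuzzy(df, 1).as_sets()
        assert sets == frozenset({frozenset({"a", "b", "c"})})

    def test_oversplits_at_high_shm(self, germline):
        rep = simulate_repertoire(germline, n_clones=16, mean_leaves=5,
                                  shm_rate=0.1, seed=35)
        ann = annotate_sequences(repertoire_to_records(rep), mode="oracle")
        part = cluster_cdr3_fuzzy(ann, 1)
        assert len(part.as_sets()) > 16


class TestPartitionInvariants:
    @pytest.mark.parametrize("method", ["identical", "threshold", "fuzzy"])
    def test_true_partition_over_all_ids(self, small_records, method):
        ann = annotate_sequences(small_records, mode="oracle")
        part = {
            "identical": cluster_identical_junction,
            "threshold": cluster_junction_threshold,
            "fuzzy": cluster_cdr3_fuzzy,
        }[method](ann)
        ids = {str(s) for s in small_records["sequence_id"]}
        assert set(part.assignment) == ids
        covered = [m for c in part.clusters() for m in c]
        assert sorted(covered) == sorted(ids)
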