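import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from famsurvey.expression import (
    cluster_profiles,
    collapse_probes,
    differential_vs_reference,
    hormone_response,
    presence_filter,
)

from conftest import make_matrix
from oracles import complete_linkage_partition


class TestCollapseProbes:
    def _probe_matrix(self):
        # p1/p2 both measure gA; p2 has the higher mean
        values = [[100.0, 200.0], [300.0, 400.0], [10.0, 20.0]]
        return make_matrix(
            values, ["a", "b"], [1, 1], index=["p1", "p2", "p3"]
        )

    def test_higher_mean_probe_wins(self):
        probemap = pd.DataFrame(
            {"probe_id": ["p1", "p2", "p3"], "gene_id": ["gA", "gA", "gB"]}
        )
        collapsed, dropped = collapse_probes(self._probe_matrix(), probemap)
        assert list(collapsed.values.loc["gA"]) == [300.0, 400.0]
        assert dropped == []

    def test_shared_probe_duplicated_to_both_genes(self):
        probemap = pd.DataFrame(
            {"probe_id": ["p1", "p1"], "gene_id": ["gA", "gB"]}
        )
        collapsed, _ = collapse_probes(self._probe_matrix(), probemap)
        assert (collapsed.values.loc["gA"] == collapsed.values.loc["gB"]).all()

    def test_probeless_genes_reported(self):
        probemap = pd.DataFrame({"probe_id": ["p1"], "gene_id": ["gA"]})
        _, dropped = collapse_probes(
            self._probe_matrix(), probemap, universe=["gA", "gC", "gD"]
        )
        assert dropped == ["gC", "gD"]

    def test_idempotent_on_gene_level_matrix(self):
        probemap = pd.DataFrame(
            {"probe_id": ["p1", "p2", "p3"], "gene_id": ["gA", "gA", "gB"]}
        )
        collapsed, _ = collapse_probes(self._probe_matrix(), probemap)
        identity = pd.DataFrame(
            {"probe_id": list(collapsed.values.index), "gene_id": list(collapsed.values.index)}
        )
        again, _ = collapse_probes(collapsed, identity)
        assert again.values.equals(collapsed.values)

    def test_empty_probemap_rejected(self):
        with pytest.raises(ValueError):
            collapse_probes(self._probe_matrix(), pd.DataFrame())

    def test_synthetic_dropped_count(self, dataset):
        collapsed, dropped = collapse_probes(
            dataset.developmental,
            dataset.probemap,
            universe=sorted(dataset.truth.family_gene_ids),
        )
        assert set(dropped) == dataset.truth.no_probe_genes
        for a, b in dataset.truth.shared_probe_pairs:
            assert (collapsed.values.loc[a] == collapsed.values.loc[b]).all()


class TestPresenceFilter:
    def test_one_present_flag_suffices(self):
        m = make_matrix(
            [[10, 10, 10]], ["a", "b", "c"], [1, 1, 1],
            flags=[["A", "P", "A"]], index=["g1"]
        )
        expressed, never = presence_filter(m)
        assert expressed == ["g1"] and never == []

    def test_absent_or_marginal_everywhere(self):
        m = make_matrix(
            [[10, 10], [10, 10]], ["a", "b"], [1, 1],
            flags=[["A", "M"], ["P", "P"]], index=["g1", "g2"]
        )
        expressed, never = presence_filter(m)
        assert never == ["g1"] and expressed == ["g2"]

    def test_missing_flags_fallback(self):
        m = make_matrix([[10, 10]], ["a", "b"], [1, 1], index=["g1"])
        expressed, never = presence_filter(m)
        assert expressed == ["g1"] and never == []


class TestClustering:
    def test_identical_profiles_merge_first_at_zero(self):
        m = make_matrix(
            [[8, 16], [8, 16], [100, 1]], ["a", "b"], [1, 1]
        )
        groups = cluster_profiles(m, 2)
        assert groups.linkage_matrix[0, 2] == 0.0
        assert groups.labels["g0"] == groups.labels["g1"] != groups.labels["g2"]

    def test_three_gene_merge_order_hand_traced(self):
        # log2 profiles: g0=(0,0), g1=(1,0), g2=(5,0); complete linkage merges
        # g0,g1 (d=1) first, then the pair with g2 at max(4,5)=5
        m = make_matrix([[1, 1], [2, 1], [32, 1]], ["a", "b"], [1, 1])
        groups = cluster_profiles(m, 1)
        Z = groups.linkage_matrix
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(5.0)

    def test_too_many_groups_rejected(self):
        m = make_matrix([[1, 1], [2, 1]], ["a", "b"], [1, 1])
        with pytest.raises(ValueError):
            cluster_profiles(m, 3)

    def test_labels_invariant_under_row_permutation(self):
        rng = np.random.default_rng(2)
        X = rng.lognormal(3, 1, size=(20, 6))
        m = make_matrix(X, list("abcdef"), [1] * 6)
        ref = cluster_profiles(m, 4).labels
        perm = rng.permutation(20)
        m2 = make_matrix(X[perm], list("abcdef"), [1] * 6,
                         index=[f"g{i}" for i in perm])
        got = cluster_profiles(m2, 4).labels
        ref_partition = sorted(
            sorted(g for g, l in ref.items() if l == lab) for lab in set(ref.values())
        )
        got_partition = sorted(
            sorted(g for g, l in got.items() if l == lab) for lab in set(got.values())
        )
        assert ref_partition == got_partition

    def test_matches_naive_oracle_small_matrices(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = int(rng.integers(5, 30))
            X = rng.lognormal(3, 0.8, size=(n, 5))
            k = int(rng.integers(2, min(6, n)))
            m = make_matrix(X, list("abcde"), [1] * 5)
            labels = cluster_profiles(m, k).labels
            got = sorted(
                sorted(int(g[1:]) for g, l in labels.items() if l == lab)
                for lab in set(labels.values())
            )
            want = sorted(sorted(c) for c in complete_linkage_partition(np.log2(X), k))
            assert got == want


class TestDifferentialExpression:
    def test_exact_twofold_is_not_called(self):
        m = make_matrix(
            [[100, 100, 200, 200]], ["ref", "t"], [2, 2], index=["g1"]
        )
        (r,) = differential_vs_reference(m, "ref")
        assert r.fold_change == pytest.approx(2.0) and r.direction == "ns"

    def test_planted_fourfold_genes_recovered(self, dataset):
        truth = dataset.truth
        collapsed, _ = collapse_probes(dataset.developmental, dataset.probemap)
        results = differential_vs_reference(collapsed, truth.reference_condition)
        calls = {(r.gene_id, r.condition): r.direction for r in results}
        planted = [
            (g, stage, d)
            for stage, items in truth.de_genes.items()
            for (g, d) in items
        ]
        hit = sum(1 for g, stage, d in planted if calls.get((g, stage)) == d)
        assert hit / len(planted) >= 0.9

    def test_single_replicate_rejected(self):
        m = make_matrix([[100, 100, 200]], ["ref", "t"], [2, 1], index=["g1"])
        with pytest.raises(ValueError):
            differential_vs_reference(m, "ref")

    def test_missing_reference_rejected(self):
        m = make_matrix([[1, 1, 2, 2]], ["a", "b"], [2, 2])
        with pytest.raises(ValueError):
            differential_vs_reference(m, "nope")

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.lognormal(5, 1, size=(30, 6))
        m1 = make_matrix(X, ["ref", "t1", "t2"], [2, 2, 2])
        m2 = make_matrix(X * 7.3, ["ref", "t1", "t2"], [2, 2, 2])
        r1 = differential_vs_reference(m1, "ref")
        r2 = differential_vs_reference(m2, "ref")
        for a, b in zip(r1, r2):
            assert a.fold_change == pytest.approx(b.fold_change)
            assert a.p_value == pytest.approx(b.p_value)
            assert a.direction == b.direction


class TestHormoneResponse:
    def test_missing_control_rejected(self):
        m = make_matrix([[1, 1, 2, 2]], ["NAA", "GA3"], [2, 2])
        with pytest.raises(ValueError):
            hormone_response(m, "CK")

    def test_planted_overlap_structure_recovered(self, dataset):
        truth = dataset.truth
        collapsed, _ = collapse_probes(dataset.hormone, dataset.probemap)
        by_treatment, overlap = hormone_response(collapsed)
        # calls match the planted responders per treatment
        for treatment, planted in truth.hormone_responders.items():
            got = {r.gene_id: r.direction for r in by_treatment[treatment]
                   if r.direction != "ns"}
            assert got == dict(planted)
        # overlap partition equals the planted multi-treatment structure
        counts = {}
        for planted in truth.hormone_responders.values():
            for g, _ in planted:
                counts[g] = counts.get(g, 0) + 1
        for k in (1, 2, 3):
            assert overlap[k] == sorted(g for g, c in counts.items() if c == k)

    def test_null_gene_not_called(self):
        m = make_matrix(
            [[100, 101, 99, 100, 100, 102, 101, 99]],
            ["CK", "NAA", "GA3", "KT"], [2, 2, 2, 2], index=["g1"]
        )
        by_treatment, overlap = hormone_response(m)
        assert all(
            r.direction == "ns" for rows in by_treatment.values() for r in rows
        )
        assert all(not genes for genes in overlap.values())
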