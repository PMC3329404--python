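import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from famsurvey.coexpression import (
    build_network,
    correlation_pvalue,
    extract_class_subnetwork,
    pearson,
    permutation_threshold,
    variability_filter,
)
from famsurvey.expression import collapse_probes

from conftest import make_matrix
from oracles import standard_error_naive


class TestPearson:
    def test_perfect_and_inverse(self):
        x = [1.0, 2.0, 3.0, 5.0]
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # covariance 4, each variance 5 -> r = 4/5
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_short_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2])


class TestCorrelationPvalue:
    def test_zero_correlation(self):
        assert correlation_pvalue(0.0, 24) == pytest.approx(1.0)

    def test_perfect_correlation(self):
        assert correlation_pvalue(1.0, 10) == 0.0
        assert correlation_pvalue(-1.0, 10) == 0.0

    def test_strong_correlation_tail(self):
        # r=0.8, n=24 -> t = 0.8*sqrt(22)/0.6 ~ 6.25
        p = correlation_pvalue(0.8, 24)
        t = 0.8 * math.sqrt(22) / math.sqrt(1 - 0.64)
        assert p == pytest.approx(2 * stats.t.sf(t, 22), rel=1e-12)
        assert p < 1e-5

    def test_monotone_in_magnitude(self):
        ps = [correlation_pvalue(r, 24) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert ps == sorted(ps, reverse=True)

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x, y = rng.normal(size=(2, 20))
            r = pearson(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic)
            assert correlation_pvalue(r, 20) == pytest.approx(ref.pvalue, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            correlation_pvalue(0.5, 2)


class TestPermutationThreshold:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(200, 12)))
        t1, _, _ = permutation_threshold(m, n_sample_genes=100, seed=4)
        t2, _, _ = permutation_threshold(m, n_sample_genes=100, seed=4)
        assert t1 == t2

    def test_alpha_bounds_rejected(self):
        m = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 6)))
        for bad in (0.0, 0.6, 1.0):
            with pytest.raises(ValueError):
                permutation_threshold(m, n_sample_genes=10, alpha=bad)

    def test_smaller_alpha_larger_threshold(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(400, 24)))
        t_loose, _, _ = permutation_threshold(m, 300, alpha=0.01, seed=1)
        t_tight, _, _ = permutation_threshold(m, 300, alpha=0.001, seed=1)
        assert t_tight >= t_loose

    def test_planted_modules_heavier_observed_tail(self):
        rng = np.random.default_rng(6)
        latent = rng.normal(size=12)
        module = latent + rng.normal(0, 0.2, size=(50, 12))
        noise = rng.normal(size=(150, 12))
        m = pd.DataFrame(np.vstack([module, noise]))
        _, null, observed = permutation_threshold(m, 200, seed=2)
        ks = stats.ks_2samp(observed, null.values)
        assert ks.statistic > 0 and ks.pvalue < 1e-6
        assert np.mean(observed > 0.8) > np.mean(null.values > 0.8)

    def test_null_invariants(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(size=(100, 10)))
        _, null, _ = permutation_threshold(m, 50, seed=0)
        assert null.n_pairs == 50 * 49 // 2
        assert np.all(np.abs(null.values) <= 1.0)


class TestVariabilityFilter:
    def test_constant_gene_excluded(self):
        m = make_matrix([[500.0] * 4], ["a", "b", "c", "d"], [1] * 4, index=["g1"])
        assert variability_filter(m, ["g1"]) == []

    def test_threshold_is_strict(self):
        # condition means engineered so SE == 500 exactly: sd = 1000, n = 4
        base = 5000.0
        vals = [base - 1000, base - 1000, base + 1000, base + 1000]
        m = make_matrix([vals], ["a", "b", "c", "d"], [1] * 4, index=["g1"])
        se = standard_error_naive(vals)
        assert se == pytest.approx(1000 * math.sqrt(4 / 3) / 2, rel=1e-12)
        assert variability_filter(m, ["g1"], se_threshold=se) == []
        assert variability_filter(m, ["g1"], se_threshold=se * 0.999) == ["g1"]

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(12)
        X = rng.lognormal(6, 1, size=(20, 8))
        m = make_matrix(X, list("abcdefgh"), [1] * 8)
        means = m.condition_means()
        for gene in means.index:
            se = standard_error_naive(means.loc[gene])
            in_set = gene in variability_filter(m, list(means.index), se_threshold=500)
            assert in_set == (se > 500)

    def test_replicates_averaged_before_se(self):
        # two replicates per condition; SE uses condition means
        m = make_matrix(
            [[100, 300, 1000, 3000]], ["a", "b"], [2, 2], index=["g1"]
        )
        means = m.condition_means()
        assert list(means.loc["g1"]) == [200.0, 2000.0]

    def test_single_condition_rejected(self):
        m = make_matrix([[1, 2]], ["a"], [2], index=["g1"])
        with pytest.raises(ValueError):
            variability_filter(m, ["g1"])


class TestBuildNetwork:
    def _matrix(self, seed=0, n=60, p=12):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(size=(n, p)), index=[f"g{i}" for i in range(n)]
        )

    def test_threshold_bounds_rejected(self):
        m = self._matrix()
        for bad in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError):
                build_network(m, ["g0"], bad)

    def test_unknown_seed_rejected(self):
        with pytest.raises(ValueError):
            build_network(self._matrix(), ["nope"], 0.8)

    def test_isolated_seed_contributes_nothing(self):
        m = self._matrix(seed=3)
        network = build_network(m, ["g0"], 0.999)
        assert network.edges == []

    def test_all_edges_respect_threshold_postcondition(self):
        m = self._matrix(seed=5)
        network = build_network(m, [f"g{i}" for i in range(10)], 0.5)
        assert all(e.pcc >= network.threshold_used for e in network.edges)
        assert all(e.p_value < 0.05 for e in network.edges)
        keys = {tuple(sorted((e.gene_a, e.gene_b))) for e in network.edges}
        assert len(keys) == len(network.edges)

    def test_planted_module_edges_recovered(self, dataset):
        truth = dataset.truth
        collapsed, _ = collapse_probes(dataset.developmental, dataset.probemap)
        log_means = np.log2(collapsed.condition_means())
        threshold, _, _ = permutation_threshold(log_means, 1000, 0.001, seed=17)
        candidates = [g for g in sorted(truth.family_gene_ids) if g in log_means.index]
        seeds = variability_filter(collapsed, candidates)
        network = build_network(log_means, seeds, threshold)
        edge_set = {tuple(sorted((e.gene_a, e.gene_b))) for e in network.edges}
        mod = truth.module_of
        genes_in_matrix = set(log_means.index)
        within = {
            tuple(sorted((s, g)))
            for s in seeds if s in mod
            for g in mod
            if g != s and mod[g] == mod[s] and g in genes_in_matrix
        }
        cross = {
            tuple(sorted((s, g)))
            for s in seeds if s in mod
            for g in mod
            if mod[g] != mod[s] and g in genes_in_matrix
        }
        recall = len(within & edge_set) / len(within)
        false_rate = len(cross & edge_set) / len(cross)
        assert recall >= 0.9
        assert false_rate <= 0.01
        # module partition recovered via connected components among module genes
        g = network.to_networkx().subgraph([n for n in mod if n in genes_in_matrix])
        import networkx as nx

        comp_label = {}
        for i, comp in enumerate(nx.connected_components(g)):
            for node in comp:
                comp_label[node] = i
        nodes = sorted(comp_label)
        ari = adjusted_rand_score(
            [mod[n] for n in nodes], [comp_label[n] for n in nodes]
        )
        assert ari >= 0.9


class TestClassSubnetworks:
    def _network(self):
        m = pd.DataFrame(
            np.vstack([
                np.tile([1.0, 5.0, 2.0, 8.0, 3.0], (4, 1))
                + np.random.default_rng(0).normal(0, 0.01, size=(4, 5)),
            ]),
            index=["f1", "m1", "m2", "h1"],
        )
        classes = {"m1": "MADS-box", "m2": "MADS-box", "h1": "histone"}
        return build_network(m, ["f1"], 0.5, node_classes=classes)

    def test_class_selection(self):
        sub = extract_class_subnetwork(self._network(), {"MADS-box"})
        assert set(sub.nodes) == {"f1", "m1", "m2"}

    def test_empty_selection_family_only(self):
        sub = extract_class_subnetwork(self._network(), set())
        assert set(sub.nodes) == {"f1"}
        assert sub.edges == []

    def test_subnetwork_never_larger(self):
        network = self._network()
        sub = extract_class_subnetwork(network, {"histone"})
        assert len(sub.nodes) <= len(network.nodes)
        assert len(sub.edges) <= len(network.edges)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            extract_class_subnetwork(self._network(), {"made-up"})
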