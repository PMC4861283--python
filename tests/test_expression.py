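"""RPKM, filters, correlation graphs, expression clustering, sample hclust."""

import numpy as np
import pandas as pd
import pytest
from helpers import average_linkage_oracle
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from oleofinder.expression import (ExpressionMatrix, cluster_expression,
                                   correlation_graph, expressed_filter,
                                   rpkm, sample_hclust, upregulated)
from oleofinder.simulate import (STAGES, SimulationConfig,
                                 simulate_expression)


class TestRPKM:
    def test_definition(self):
        assert rpkm(10, 1000, 10**6) == pytest.approx(10.0)
        assert rpkm(0, 1000, 10**6) == 0.0

    def test_sum_identity(self, rng):
        # when counts sum to the library, sum(rpkm * length) = 1e9
        lengths = rng.integers(300, 10000, size=50)
        counts = rng.integers(0, 1000, size=50)
        lib = counts.sum()
        vals = rpkm(counts, lengths, lib)
        assert (vals * lengths).sum() == pytest.approx(1e9, rel=1e-12)

    def test_scaling_invariance(self):
        assert rpkm(10, 500, 10**6) == pytest.approx(rpkm(30, 500, 3 * 10**6))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            rpkm(-1, 100, 100)


def tiny_matrix(values, n_rep=2):
    """values: gene -> per (stage, rep) abundance array of len 7*n_rep."""
    sample_ids, stage, order, rep = [], [], [], []
    for si, s in enumerate(STAGES):
        for r in range(1, n_rep + 1):
            sample_ids.append(f"{s}_r{r}")
            stage.append(s)
            order.append(si)
            rep.append(r)
    vals = pd.DataFrame(values, index=sample_ids).T
    samples = pd.DataFrame({"stage": stage, "stage_order": order,
                            "replicate": rep}, index=sample_ids)
    return ExpressionMatrix(values=vals, samples=samples)


class TestExpressedFilter:
    def test_all_zero_gene_excluded(self):
        m = tiny_matrix({"dead": np.zeros(14), "live": np.full(14, 5.0)})
        assert expressed_filter(m, min_rpkm=1.0) == {"live"}

    def test_single_replicate_expression_insufficient_when_strict(self):
        vals = np.zeros(14)
        vals[0] = 5.0  # stage 1, replicate 1 only
        m = tiny_matrix({"g": vals})
        assert expressed_filter(m, min_rpkm=1.0,
                                require_both_replicates=True) == set()
        assert expressed_filter(m, min_rpkm=1.0,
                                require_both_replicates=False) == {"g"}

    def test_planted_fraction_recovered_at_zero_noise(self):
        values = {}
        for i in range(40):
            level = 5.0 if i < 25 else 0.2
            values[f"g{i:02d}"] = np.full(14, level)
        m = tiny_matrix(values)
        kept = expressed_filter(m, min_rpkm=1.0)
        assert len(kept) == 25


class TestUpregulated:
    def test_window_peak_vs_overall_mean(self):
        prof = [1, 1, 1, 4, 1, 1, 1]
        assert upregulated(prof, [3], fold=2.0)        # 4 >= 2 * 10/7
        assert not upregulated(prof, [1], fold=2.0)

    def test_constant_profile_boundary(self):
        prof = [3.0] * 7
        assert upregulated(prof, [3, 4, 5], fold=1.0)
        assert not upregulated(prof, [3, 4, 5], fold=2.0)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            upregulated([1, 2, 3], [], fold=1.0)

    @given(st.lists(st.floats(0.1, 100), min_size=7, max_size=7),
           st.floats(1.0, 3.0), st.floats(0.0, 2.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_fold(self, prof, fold, extra):
        window = [3, 4, 5]
        if upregulated(prof, window, fold=fold + extra):
            assert upregulated(prof, window, fold=fold)


class TestCorrelationGraph:
    def test_proportional_profiles_edge_weight_one(self):
        profs = pd.DataFrame({"s1": [1.0, 2.0], "s2": [2.0, 4.0],
                              "s3": [3.0, 6.0], "s4": [5.0, 10.0]},
                             index=["a", "b"])
        g = correlation_graph(profs, threshold=0.7)
        assert g["a"]["b"]["weight"] == pytest.approx(1.0)

    def test_threshold_is_strict(self):
        profs = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 7)),
                             index=list("abcd"))
        g = correlation_graph(profs, threshold=1.0)
        assert g.number_of_edges() == 0

    def test_anticorrelated_pair_connected(self):
        x = np.array([1.0, 5.0, 2.0, 7.0, 3.0, 6.0, 4.0])
        profs = pd.DataFrame([x, -0.9 * x + 10], index=["a", "b"])
        g = correlation_graph(profs, threshold=0.7)
        assert g.has_edge("a", "b")

    def test_constant_profiles_skipped_with_warning(self):
        profs = pd.DataFrame([[1.0] * 7, [1, 2, 3, 4, 5, 6, 7]],
                             index=["flat", "ok"])
        with pytest.warns(UserWarning, match="constant"):
            g = correlation_graph(profs)
        assert g.number_of_edges() == 0 and "flat" in g

    def test_invariant_to_positive_affine_transform(self, rng):
        base = rng.normal(size=(10, 7))
        p1 = pd.DataFrame(base, index=[f"g{i}" for i in range(10)])
        p2 = p1 * 3.7 + 11.0
        g1 = correlation_graph(p1)
        g2 = correlation_graph(p2)
        assert set(g1.edges) == set(g2.edges)


class TestClusterExpression:
    def test_zero_noise_recovers_archetypes_exactly(self):
        cfg = SimulationConfig(seed=5, n_genes_expr=160, sigma_gene=0.0,
                               sigma_rep=0.0)
        em, truth = simulate_expression(cfg)
        part, profiles = cluster_expression(em)
        labels = part.labels()
        genes = list(truth.cluster_label_by_gene)
        ari = adjusted_rand_score(
            [truth.cluster_label_by_gene[g] for g in genes],
            [labels[g] for g in genes])
        assert ari == pytest.approx(1.0)
        assert profiles.shape[1] == len(STAGES)

    def test_noisy_recovery_and_cluster_ordering(self):
        cfg = SimulationConfig(seed=5, n_genes_expr=400)
        em, truth = simulate_expression(cfg)
        part, _ = cluster_expression(em)
        labels = part.labels()
        genes = list(truth.cluster_label_by_gene)
        ari = adjusted_rand_score(
            [truth.cluster_label_by_gene[g] for g in genes],
            [labels[g] for g in genes])
        assert ari >= 0.9
        sizes = [len(c) for c in part.clusters]
        assert sizes == sorted(sizes, reverse=True)


class TestSampleHclust:
    def test_identical_samples_merge_at_zero(self):
        vals = pd.DataFrame(
            {"s1": [1.0, 5.0, 2.0], "s2": [1.0, 5.0, 2.0],
             "s3": [9.0, 1.0, 7.0]}, index=["g1", "g2", "g3"])
        samples = pd.DataFrame(
            {"stage": ["a", "a", "b"], "stage_order": [0, 0, 1],
             "replicate": [1, 2, 1]}, index=["s1", "s2", "s3"])
        m = ExpressionMatrix(values=vals, samples=samples)
        link, labels, newick = sample_hclust(m)
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert newick.endswith(";") and "s3" in newick

    def test_merge_sequence_matches_bruteforce_oracle(self, rng):
        n_samples = 6
        vals = pd.DataFrame(
            rng.lognormal(2.0, 1.0, size=(40, n_samples)),
            index=[f"g{i}" for i in range(40)],
            columns=[f"s{i}" for i in range(n_samples)])
        samples = pd.DataFrame(
            {"stage": [f"st{i}" for i in range(n_samples)],
             "stage_order": range(n_samples),
             "replicate": 1}, index=vals.columns)
        m = ExpressionMatrix(values=vals, samples=samples)
        link, labels, _ = sample_hclust(m)

        logm = np.log2(vals.to_numpy().T + 1.0)
        dist = 1.0 - np.corrcoef(logm)
        np.fill_diagonal(dist, 0.0)
        merges = average_linkage_oracle(dist)

        # compare each merge's member sets and heights
        n = n_samples
        members = {i: frozenset([i]) for i in range(n)}
        for step, (a, b, h, _) in enumerate(link):
            got = members[int(a)] | members[int(b)]
            members[n + step] = got
            oa, ob, oh = merges[step]
            assert got == oa | ob
            assert h == pytest.approx(oh, rel=1e-9)
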