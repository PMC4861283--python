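"""Synthetic-data generator: determinism, planted truth, marginals."""

import numpy as np
import pytest
from scipy import stats

from oleofinder.orthology import DEFAULT_PANEL, classify_og
from oleofinder.simulate import (ARCHETYPES, DEFAULT_COMPOSITION, STAGES,
                                 SimulationConfig, SimulationTruth,
                                 simulate_counts_de, simulate_expression,
                                 simulate_family, simulate_og_table,
                                 simulate_promoters, toy_ontology)


class TestConfig:
    def test_bad_probability_vector_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            SimulationConfig(composition_probs={"shared": 0.5})

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma_gene"):
            SimulationConfig(sigma_gene=-0.1)

    def test_archetype_shape_checked(self):
        with pytest.raises(ValueError, match="archetype_table"):
            SimulationConfig(n_clusters=5)

    def test_archetypes_are_separable_at_the_07_threshold(self):
        c = np.corrcoef(ARCHETYPES)
        np.fill_diagonal(c, 0.0)
        assert np.abs(c).max() < 0.7


class TestOGTable:
    def test_empty_case(self):
        ogs, truth = simulate_og_table(SimulationConfig(n_ogs=0))
        assert ogs == [] and truth.og_class_by_id == {}

    def test_truth_class_matches_composition(self, small_config):
        ogs, truth = simulate_og_table(small_config)
        for og in ogs:
            expect = truth.og_class_by_id[og.og_id]
            assert classify_og(og, DEFAULT_PANEL) == expect

    def test_gene_ids_globally_unique(self, small_config):
        ogs, _ = simulate_og_table(small_config)
        genes = [g for og in ogs for _, g in og.members]
        assert len(genes) == len(set(genes))

    def test_class_frequencies_within_binomial_bounds(self):
        cfg = SimulationConfig(seed=1, n_ogs=500)
        _, truth = simulate_og_table(cfg)
        n = cfg.n_ogs
        counts: dict = {}
        for cls in truth.og_class_by_id.values():
            counts[cls] = counts.get(cls, 0) + 1
        for cls, p in cfg.composition_probs.items():
            lo = stats.binom.ppf(0.005, n, p)
            hi = stats.binom.ppf(0.995, n, p)
            assert lo <= counts.get(cls, 0) <= hi, cls

    def test_chi2_goodness_of_fit_at_scale(self):
        cfg = SimulationConfig(seed=2, n_ogs=5000)
        _, truth = simulate_og_table(cfg)
        classes = sorted(DEFAULT_COMPOSITION)
        obs = np.array([sum(1 for c in truth.og_class_by_id.values()
                            if c == cls) for cls in classes])
        exp = np.array([DEFAULT_COMPOSITION[c] * cfg.n_ogs for c in classes])
        _, p = stats.chisquare(obs, exp)
        assert p > 0.001


class TestExpression:
    def test_zero_noise_profiles_equal_archetypes(self):
        cfg = SimulationConfig(seed=0, n_genes_expr=80, sigma_gene=0.0,
                               sigma_rep=0.0, sigma_offset=0.0)
        em, truth = simulate_expression(cfg)
        log2 = np.log2(em.values.to_numpy())
        for i, gene in enumerate(em.values.index):
            c = truth.cluster_label_by_gene[gene]
            expect = np.repeat(ARCHETYPES[c], 2)
            assert np.allclose(log2[i], expect, atol=1e-9)

    def test_two_replicates_per_stage(self, small_config):
        em, _ = simulate_expression(small_config)
        meta = em.samples
        per_stage = meta.groupby("stage")["replicate"].count()
        assert (per_stage == 2).all()
        assert len(em.stages) == len(STAGES)

    def test_deterministic_for_fixed_seed(self, small_config):
        em1, t1 = simulate_expression(small_config)
        em2, t2 = simulate_expression(small_config)
        assert em1.values.equals(em2.values)
        assert t1.cluster_label_by_gene == t2.cluster_label_by_gene


class TestCountsDE:
    def test_three_accessions_four_stages(self, small_config):
        counts, libs, _ = simulate_counts_de(small_config)
        assert sorted(counts) == ["HO1", "LO1", "LO2"]
        for acc in counts:
            assert list(counts[acc].columns) == \
                ["15DAF", "25DAF", "35DAF", "55DAF"]

    def test_library_totals_near_nominal(self):
        cfg = SimulationConfig(seed=8, n_genes_de=1000, n_de_genes=0)
        counts, libs, _ = simulate_counts_de(cfg)
        for acc in counts:
            for stage in counts[acc].columns:
                total = counts[acc][stage].sum()
                assert total == pytest.approx(cfg.lib_size, rel=0.05)

    def test_null_config_plants_nothing(self):
        cfg = SimulationConfig(seed=8, n_de_genes=0, n_genes_de=200)
        _, _, truth = simulate_counts_de(cfg)
        assert not any(truth.de_gene_flags.values())

    def test_planted_flags_recorded(self, small_config):
        _, _, truth = simulate_counts_de(small_config)
        assert sum(truth.de_gene_flags.values()) == small_config.n_de_genes


class TestPromoters:
    def test_planted_positions_recorded_and_sorted(self, small_config):
        records, truth = simulate_promoters(small_config)
        assert len(records) == small_config.n_promoters
        for gene, seq in records:
            pos = truth.motif_positions_by_promoter[gene]
            assert pos == sorted(pos)
            assert len(seq) == small_config.promoter_length

    def test_impossible_packing_rejected(self):
        cfg = SimulationConfig(promoter_length=40,
                               planted_motifs_per_promoter=3, n_promoters=1)
        with pytest.raises(ValueError, match="non-overlapping"):
            simulate_promoters(cfg)

    def test_short_promoter_rejected_by_config(self):
        with pytest.raises(ValueError, match="shorter than the motif"):
            SimulationConfig(promoter_length=10)


class TestFamily:
    def test_additive_distances_at_zero_noise(self):
        from oleofinder.phylo import neighbor_joining, path_length_matrix
        cfg = SimulationConfig(seed=21, distance_noise=0.0)
        fam, _ = simulate_family(cfg)
        dm = fam["distances"]
        tree = neighbor_joining(dm)
        pm = path_length_matrix(tree, dm.labels)
        assert np.abs(pm.values - dm.values).max() <= 1e-9

    def test_leaves_carry_species_tags(self):
        cfg = SimulationConfig(seed=21)
        fam, _ = simulate_family(cfg)
        species = {n.name.split("_")[0] for n in fam["tree"].leaves()}
        assert species <= set(DEFAULT_PANEL.species)

    def test_truth_serialises(self, tmp_path, small_config):
        _, truth = simulate_og_table(small_config)
        text = truth.to_json(tmp_path / "truth.json")
        assert (tmp_path / "truth.json").read_text().startswith("{")
        assert "og_class_by_id" in text


def test_toy_ontology_is_dag_with_slim_layer():
    ont = toy_ontology()
    assert len(ont.slim) == 8
    for term in ont.slim:
        assert ont.ancestors(term) == {"GO:0008150"}
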