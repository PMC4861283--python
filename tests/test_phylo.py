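"""Distances, neighbor joining, bootstrap, duplication labels, newick."""

import numpy as np
import pytest
from helpers import random_additive_tree

from oleofinder.phylo import (DistanceMatrix, bipartitions,
                              bootstrap_support, label_duplications,
                              midpoint_root, neighbor_joining,
                              path_length_matrix, protein_distance,
                              read_newick, write_newick)
from oleofinder.simulate import SimulationConfig, simulate_family


class TestProteinDistance:
    def test_identical_sequences(self):
        dm = protein_distance([("a", "MKV"), ("b", "MKV")], model="p")
        assert dm.values[0, 1] == 0.0

    def test_p_distance_definition(self):
        dm = protein_distance([("a", "AAAAAAAAAA"), ("b", "CCAAAAAAAA")],
                              model="p")
        assert dm.values[0, 1] == pytest.approx(0.2)

    def test_poisson_correction(self):
        dm = protein_distance([("a", "AAAAAAAAAA"), ("b", "CCAAAAAAAA")],
                              model="poisson")
        assert dm.values[0, 1] == pytest.approx(-np.log(0.8), rel=1e-12)

    def test_pairwise_gap_deletion(self):
        dm = protein_distance([("a", "A-AAA"), ("b", "ACAAC")], model="p")
        # 4 comparable sites, 1 mismatch
        assert dm.values[0, 1] == pytest.approx(0.25)

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(ValueError, match="no comparable sites"):
            protein_distance([("a", "A--"), ("b", "-AA")], model="p")


class TestNeighborJoining:
    def test_hand_built_four_taxon_tree(self):
        labels = ("A", "B", "C", "D")
        d = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert bipartitions(tree) == {frozenset({"A", "B"})}
        # additive reconstruction: path lengths equal the input
        pm = path_length_matrix(tree, labels)
        assert np.allclose(pm.values, d, atol=1e-9)
        # leaf edges 1,2,3,4 and internal edge 1 (read off the branches)
        leaf_len = {n.name: n.length for n in tree.postorder() if n.is_leaf}
        assert leaf_len == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0,
                                          "D": 4.0})

    def test_three_taxa_closed_form(self):
        labels = ("x", "y", "z")
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        lens = {n.name: n.length for n in tree.children}
        assert lens == pytest.approx({"x": 1.0, "y": 3.0, "z": 5.0})

    @pytest.mark.parametrize("n_taxa", [4, 6, 9, 12])
    def test_random_additive_matrices_reconstructed(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        for _ in range(5):
            labels, dist = random_additive_tree(rng, n_taxa)
            tree = neighbor_joining(DistanceMatrix(labels, dist))
            pm = path_length_matrix(tree, labels)
            assert np.abs(pm.values - dist).max() <= 1e-9

    def test_invariant_to_taxon_order(self, rng):
        labels, dist = random_additive_tree(rng, 8)
        tree1 = neighbor_joining(DistanceMatrix(labels, dist))
        perm = rng.permutation(len(labels))
        labels2 = [labels[i] for i in perm]
        tree2 = neighbor_joining(
            DistanceMatrix(labels2, dist[np.ix_(perm, perm)]))
        assert bipartitions(tree1) == bipartitions(tree2)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="3 taxa"):
            neighbor_joining(DistanceMatrix(("a", "b"),
                                            np.array([[0.0, 1], [1, 0]])))


class TestBootstrap:
    def test_clean_signal_full_support(self, rng):
        # identical duplicated column blocks: resampling keeps the signal
        block = {"a1": "AAAA", "a2": "AAAC", "b1": "TTTT", "b2": "TTTG"}
        records = [(k, v * 30) for k, v in block.items()]
        tree = bootstrap_support(records, n_reps=50, seed=1, model="p")
        supports = [n.support for n in tree.postorder()
                    if not n.is_leaf and n.support is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_replicate_support_binary(self, rng):
        labels, dist = random_additive_tree(rng, 6)
        # build an alignment-free check via simulate_family instead
        cfg = SimulationConfig(seed=2, family_seq_len=120)
        fam, _ = simulate_family(cfg)
        tree = bootstrap_support(fam["alignment"], n_reps=1, seed=3)
        sup = [n.support for n in tree.postorder()
               if not n.is_leaf and n.support is not None]
        assert set(sup) <= {0.0, 100.0}

    def test_long_internal_branch_high_support(self):
        tree = read_newick(
            "((A_f_1:0.1,A_f_2:0.1):1.0,(B_f_1:0.1,B_f_2:0.1):1.0);")
        from oleofinder.simulate import _evolve_alignment
        rng = np.random.default_rng(5)
        records = _evolve_alignment(tree, 300, rng)
        boot = bootstrap_support(records, n_reps=100, seed=6)
        split = frozenset({"A_f_1", "A_f_2"})
        for node in boot.postorder():
            if not node.is_leaf and node is not boot and \
                    node.leaf_names() in (split,):
                assert node.support >= 95.0
                break
        else:
            pytest.fail("planted bipartition not found in bootstrap tree")


class TestDuplications:
    def test_species_overlap_rule_minimal(self):
        tree = read_newick("((gma_1:1,ath_1:1):1,(gma_2:1,ath_2:1):1);")
        tree, n_dup = label_duplications(tree)
        assert n_dup == 1
        assert tree.event == "duplication"
        assert all(c.event == "speciation" for c in tree.children)

    def test_congruent_tree_no_duplications(self):
        tree = read_newick("((gma_1:1,ath_1:1):1,osa_1:2);")
        _, n_dup = label_duplications(tree)
        assert n_dup == 0

    def test_unparseable_leaf_rejected(self):
        tree = read_newick("((gma_1:1,nounderscore:1):1,osa_1:2);")
        with pytest.raises(ValueError, match="species tag"):
            label_duplications(tree)

    def test_simulated_family_truth_recovered_via_nj(self):
        cfg = SimulationConfig(seed=9, family_dup_rate=0.8,
                               family_loss_rate=0.1, distance_noise=0.0)
        fam, truth = simulate_family(cfg, family_id="famX")
        true_tree = fam["tree"]
        nj = neighbor_joining(fam["distances"])
        # root the NJ tree on the true root split, then compare labels
        side = true_tree.children[0].leaf_names()
        rooted = _root_on_split(nj, side)
        rooted, _ = label_duplications(rooted)
        got = sorted(sorted(n.leaf_names()) for n in rooted.postorder()
                     if n.event == "duplication")
        assert got == sorted(truth.duplication_nodes_by_family["famX"])

    def test_dup_rate_zero_congruent_with_species_tree(self):
        cfg = SimulationConfig(seed=4, family_dup_rate=0.0,
                               family_loss_rate=0.0)
        fam, truth = simulate_family(cfg, family_id="f0")
        assert fam["n_duplications"] == 0
        _, n_dup = label_duplications(fam["tree"])
        assert n_dup == 0


def _root_on_split(tree, side):
    """Root an unrooted NJ tree on the edge with the given leaf split."""
    from oleofinder.phylo import _adjacency, _reroot_on_edge
    adj, objs = _adjacency(tree)
    all_leaves = tree.leaf_names()
    target = min(side, all_leaves - side,
                 key=lambda s: (len(s), tuple(sorted(s))))

    def leafset(u, parent):
        node = objs[u]
        if node.is_leaf:
            return frozenset([node.name])
        out = frozenset()
        for v, _, _ in adj[u]:
            if v != parent:
                out |= leafset(v, u)
        return out

    for u in adj:
        for v, w, _ in adj[u]:
            below = leafset(v, u)
            canon = min(below, all_leaves - below,
                        key=lambda s: (len(s), tuple(sorted(s))))
            if canon == target:
                return _reroot_on_edge(adj, objs, u, v, w / 2.0, w)
    raise AssertionError("split not present in tree")


class TestMidpointRoot:
    def test_midpoint_of_caterpillar(self):
        tree = read_newick("((a:1,b:1):1,(c:1,d:5):1);")
        rooted = midpoint_root(tree)
        # longest path: d..a or d..b = 5+1+1+1 = 8; midpoint at 4 from d
        sides = sorted(len(c.leaf_names()) for c in rooted.children)
        assert sides == [1, 3]
        pm = path_length_matrix(rooted)
        i, j = pm.labels.index("a"), pm.labels.index("d")
        assert pm.values[i, j] == pytest.approx(8.0)


class TestNewick:
    def test_parse_two_leaf(self):
        t = read_newick("(A:1,B:2):0;")
        assert {n.name: n.length for n in t.leaves()} == {"A": 1.0, "B": 2.0}

    def test_round_trip_random_tree(self, rng):
        labels, dist = random_additive_tree(rng, 20)
        tree = neighbor_joining(DistanceMatrix(labels, dist))
        text = write_newick(tree)
        back = read_newick(text)
        assert bipartitions(back) == bipartitions(tree)
        pm1 = path_length_matrix(tree, labels)
        pm2 = path_length_matrix(back, labels)
        assert np.abs(pm1.values - pm2.values).max() <= 1e-9

    def test_support_serialised_as_internal_label(self):
        t = read_newick("((A:1,B:1)87:2,C:3);")
        internal = [n for n in t.postorder() if not n.is_leaf and n is not t]
        assert internal[0].support == 87.0
        assert "87" in write_newick(t)

    def test_malformed_newick_reports_position(self):
        with pytest.raises(ValueError, match="position"):
            read_newick("((A:1,B:2;")
        with pytest.raises(ValueError, match="';'"):
            read_newick("(A,B)")
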