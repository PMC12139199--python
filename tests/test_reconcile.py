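"""LCA mapping, min dup+loss rooting and GD detection against brute force."""

import numpy as np
import pytest

from riceshift.reconcile import (
    SpeciesIndex,
    count_dup_loss,
    detect_duplications,
    lca_map,
    root_gene_tree,
    summarize_gd,
)
from riceshift.simulate import simulate_gene_trees
from riceshift.trees import parse_newick

from oracles import (
    all_unrooted_topologies,
    oracle_best_rooting,
    oracle_lca,
    oracle_reconcile,
    random_gene_topology,
    root_topology_on_edge,
)


class TestLcaMap:
    def test_single_leaf_maps_to_species_leaf(self, four_taxon_species):
        S = SpeciesIndex(four_taxon_species)
        gt = parse_newick("(A|g1,B|g2);")
        assert lca_map(gt.children[0], S).taxon == "A"

    def test_full_span_maps_to_root(self, four_taxon_species):
        S = SpeciesIndex(four_taxon_species)
        gt = parse_newick("((A|g1,D|g2),(B|g3,C|g4));")
        assert S.label_of(lca_map(gt, S)) == "root"

    def test_subspecies_pair_maps_to_mrca_not_root(self):
        sp = parse_newick("(((indica1,indica2),(japonica1,japonica2))sativa,out);", leaf_delimiter=None)
        S = SpeciesIndex(sp)
        gt = parse_newick("(indica1|g1,japonica1|g2);")
        assert S.label_of(lca_map(gt, S)) == "sativa"

    def test_unknown_taxon_named_in_error(self, four_taxon_species):
        S = SpeciesIndex(four_taxon_species)
        gt = parse_newick("(A|g1,Z|g2);")
        with pytest.raises(KeyError, match="Z"):
            lca_map(gt, S)

    def test_matches_brute_force_on_random_clades(self, four_taxon_species):
        S = SpeciesIndex(four_taxon_species)
        rng = np.random.default_rng(7)
        taxa = ["A", "B", "C", "D"]
        for _ in range(200):
            gt = random_gene_topology(rng, taxa, int(rng.integers(2, 8)))
            ours = lca_map(gt, S)
            theirs, _ = oracle_lca({l.taxon for l in gt.leaves()}, four_taxon_species)
            assert ours is theirs


class TestRooting:
    def test_congruent_tree_rerooted_to_zero_dups(self, four_taxon_species):
        S = SpeciesIndex(four_taxon_species)
        # same unrooted topology as the species tree, rooted inside (A,B)
        gt = parse_newick("(A|g1,(B|g2,(C|g3,D|g4)));")
        rooted = root_gene_tree(gt, S)
        assert count_dup_loss(rooted, S) == (0, 0)

    def test_two_copies_root_between_them(self, four_taxon_species):
        S = SpeciesIndex(four_taxon_species)
        copy = "(((A|g{0},B|g{1}),C|g{2}),D|g{3})"
        gt = parse_newick(f"({copy.format(1,2,3,4)},{copy.format(5,6,7,8)});")
        rooted = root_gene_tree(gt, S)
        dups, losses = count_dup_loss(rooted, S)
        assert (dups, losses) == (1, 0)
        sides = {frozenset(l.gene_id for l in c.leaves()) for c in rooted.children}
        assert sides == {
            frozenset({"g1", "g2", "g3", "g4"}),
            frozenset({"g5", "g6", "g7", "g8"}),
        }

    def test_rooting_score_matches_exhaustive_oracle(self, four_taxon_species):
        """On random 7-leaf trees the chosen rooting achieves the score of
        an oracle that tries every branch."""

        S = SpeciesIndex(four_taxon_species)
        rng = np.random.default_rng(11)
        taxa = ["A", "B", "C", "D"]
        for _ in range(100):
            gt = random_gene_topology(rng, taxa, 7)
            rooted = root_gene_tree(gt, S)
            dups, losses = count_dup_loss(rooted, S)
            # oracle: enumerate rootings of the same unrooted topology
            from riceshift.reconcile import enumerate_rootings

            scores = []
            for cand in enumerate_rootings(gt):
                d, l, _ = oracle_reconcile(cand, four_taxon_species)
                scores.append(d + l)
            assert dups + losses == min(scores)


class TestDetect:
    def test_single_copy_congruent_tree_no_events(self, four_taxon_species):
        S = SpeciesIndex(four_taxon_species)
        gt = parse_newick("(((A|g1,B|g2)100,C|g3)100,D|g4)100;")
        assert detect_duplications(gt, S) == []

    def test_simple_duplication_at_mrca(self):
        sp = parse_newick("(A,B);", leaf_delimiter=None)
        S = SpeciesIndex(sp)
        gt = parse_newick("((A|g1,B|g2)100,(A|g3,B|g4)100)100;")
        (event,) = detect_duplications(gt, S)
        assert event.species_node == S.label_of(S.root)
        assert event.shared_species == {"A", "B"}

    def test_low_support_node_rejected(self):
        sp = parse_newick("(A,B);", leaf_delimiter=None)
        S = SpeciesIndex(sp)
        gt = parse_newick("((A|g1,B|g2)100,(A|g3,B|g4)100)60;")
        assert detect_duplications(gt, S, bp=70) == []
        assert len(detect_duplications(gt, S, bp=60)) == 1

    def test_low_child_support_rejected(self):
        sp = parse_newick("(A,B);", leaf_delimiter=None)
        S = SpeciesIndex(sp)
        gt = parse_newick("((A|g1,B|g2)50,(A|g3,B|g4)100)100;")
        assert detect_duplications(gt, S, sub_bp=70) == []

    def test_missing_supports_pass(self):
        sp = parse_newick("(A,B);", leaf_delimiter=None)
        S = SpeciesIndex(sp)
        gt = parse_newick("((A|g1,B|g2),(A|g3,B|g4));")
        assert len(detect_duplications(gt, S)) == 1

    def test_monotone_in_thresholds(self, four_taxon_species):
        """Raising bp or min_shared_species never adds events."""

        S = SpeciesIndex(four_taxon_species)
        rng = np.random.default_rng(3)
        taxa = ["A", "B", "C", "D"]
        for _ in range(50):
            gt = random_gene_topology(rng, taxa, 8)
            rooted = root_gene_tree(gt, S)
            prev = None
            for bp in (0, 50, 70, 90, 101):
                n = len(detect_duplications(rooted, S, bp=bp))
                if prev is not None:
                    assert n <= prev
                prev = n
            prev = None
            for shared in (1, 2, 3, 4):
                n = len(detect_duplications(rooted, S, min_shared_species=shared))
                if prev is not None:
                    assert n <= prev
                prev = n

    def test_summarize_counts(self):
        from riceshift.reconcile import GDEvent

        events = [
            GDEvent("f", "X", None, (frozenset("ab"), frozenset("ab")), (None, None))
            for _ in range(3)
        ] + [
            GDEvent("f", "Y", None, (frozenset("ab"), frozenset("ab")), (None, None))
            for _ in range(2)
        ]
        assert summarize_gd(events) == {"X": 3, "Y": 2}
        assert summarize_gd([]) == {}


class TestPlantedRecovery:
    def test_no_duplications_planted_none_found(self, rice_species, rice_index):
        families, truth = simulate_gene_trees(rice_species, 20, [], seed=5)
        for _, tree in families:
            rooted = root_gene_tree(tree, rice_index)
            assert detect_duplications(rooted, rice_index, bp=0) == []

    def test_planted_events_recovered_exactly(self, rice_species, rice_index):
        families, truth = simulate_gene_trees(
            rice_species, 30, [("sativa", 1, "ABAB")], loss_prob=0.0, seed=5
        )
        for fam_id, tree in families:
            rooted = root_gene_tree(tree, rice_index)
            events = detect_duplications(rooted, rice_index, family_id=fam_id)
            assert len(events) == 1
            assert events[0].species_node == "sativa"

    def test_losses_replayed_truth_matches_detection(self, rice_species, rice_index):
        families, truth = simulate_gene_trees(
            rice_species, 200, [("sativa", 1, "ABAB")], loss_prob=0.2, seed=7
        )
        by_family = {e["family_id"]: e for e in truth["events"]}
        for fam_id, tree in families:
            rooted = root_gene_tree(tree, rice_index)
            events = detect_duplications(rooted, rice_index, family_id=fam_id)
            expected = by_family[fam_id]
            assert len(events) == (1 if expected["survived"] else 0)
            if expected["survived"]:
                assert events[0].species_node == expected["realized_species_node"]
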