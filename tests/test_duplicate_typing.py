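"""Linkage, reconciliation, Dollo losses and family category calls."""

import numpy as np
import pandas as pd
import pytest

from ohnotype.duplicate_typing import (
    classify_family,
    classify_linkage,
    dollo_loss_branches,
    infer_losses,
    reconcile,
    summarize_repertoire,
)
from ohnotype.genome_model import (
    GeneRecord,
    SpeciesGenome,
    read_gene_tree,
    read_species_tree,
)
from oracles import (
    brute_lca,
    brute_min_dollo_losses,
    brute_reconcile,
    random_gene_tree_newick,
)


def genome(species, rows):
    genes = [
        GeneRecord(gid, species, chrom, start, start + 90, strand, family_id=fam)
        for gid, chrom, start, strand, fam in rows
    ]
    chroms = {}
    for g in genes:
        chroms[g.chromosome_id] = max(chroms.get(g.chromosome_id, 0), g.end)
    return SpeciesGenome(species, chroms, genes)


class TestLinkage:
    def setup_method(self):
        self.genome = genome(
            "Sp",
            [
                ("a", "c1", 0, "+", "F"),
                ("b", "c1", 50_000, "+", "F"),
                ("far", "c1", 40_000_000, "+", "F"),
                ("other", "c2", 0, "+", "F"),
            ],
        )

    def test_adjacent_pair_is_clustered(self):
        call = classify_linkage("a", "b", self.genome)
        assert call.relation == "clustered"
        assert call.intervening_gene_count == 0
        assert call.distance_bp == 50_000 - 90

    def test_distant_same_chromosome_pair_is_linked_only(self):
        call = classify_linkage("a", "far", self.genome)
        assert call.relation == "linked"
        assert call.distance_bp > 1_000_000

    def test_different_chromosomes_dispersed(self):
        call = classify_linkage("a", "other", self.genome)
        assert call.relation == "dispersed"
        assert call.distance_bp is None

    def test_same_gene_twice_is_an_error(self):
        with pytest.raises(ValueError, match="itself"):
            classify_linkage("a", "a", self.genome)


SMALL_STREE = "(((A,B)WGD,C),D);"


class TestReconcile:
    def test_duplicated_pair_maps_above_shared_ancestor(self):
        stree = read_species_tree(data=SMALL_STREE)
        gt = read_gene_tree(data="(('A|g1','B|g1'),('A|g2','B|g2'));")
        recon = reconcile(gt, stree)
        root = gt.tree.seed_node
        assert recon[root].event == "duplication"
        assert stree.leafset[recon[root].species_node] == frozenset({"A", "B"})
        assert recon[root].wgd_compatible
        for child in root.child_nodes():
            assert recon[child].event == "speciation"

    def test_congruent_topology_is_all_speciations(self):
        stree = read_species_tree(data=SMALL_STREE)
        gt = read_gene_tree(data="((('A|g1','B|g1'),'C|g1'),'D|g1');")
        recon = reconcile(gt, stree)
        for node in gt.tree.preorder_node_iter():
            if not node.is_leaf():
                assert recon[node].event == "speciation"

    def test_species_missing_from_tree_is_an_error(self):
        stree = read_species_tree(data=SMALL_STREE)
        gt = read_gene_tree(data="(('A|g1','Z|g1'),'C|g2');")
        with pytest.raises(ValueError, match="not in the species tree"):
            reconcile(gt, stree)

    def test_matches_brute_force_oracle_on_random_trees(self, species_tree):
        rng = np.random.default_rng(99)
        species = species_tree.species
        for _ in range(200):
            n = int(rng.integers(2, 9))
            gt = read_gene_tree(
                data=random_gene_tree_newick(rng, species, n)
            )
            recon = reconcile(gt, species_tree)
            oracle = brute_reconcile(gt, species_tree)
            for node in gt.tree.preorder_node_iter():
                if node.is_leaf():
                    continue
                assert recon[node].event == oracle[node][0]
                assert recon[node].species_node is oracle[node][1]


class TestDollo:
    def test_full_presence_means_no_losses(self, species_tree):
        losses = dollo_loss_branches(
            set(species_tree.wgd_species), species_tree, species_tree.wgd_node
        )
        assert losses == []

    def test_scorpion_only_presence_is_one_spider_stem_loss(self, species_tree):
        losses = dollo_loss_branches({"Cscu"}, species_tree, species_tree.wgd_node)
        assert losses == ["spiders"]

    def test_matches_exhaustive_minimum_on_six_leaf_tree(self):
        stree = read_species_tree(data="(((A,B),(C,D))WGD,(E,F));")
        wgd_leaves = ["A", "B", "C", "D"]
        import itertools

        for r in range(1, len(wgd_leaves) + 1):
            for combo in itertools.combinations(wgd_leaves, r):
                present = set(combo)
                ours = dollo_loss_branches(
                    present, stree, stree.wgd_node
                )
                expected = brute_min_dollo_losses(
                    stree, stree.wgd_node, present
                )
                assert len(ours) == expected, present

    def test_infer_losses_refines_sol_and_eol(self, species_tree):
        wgd = sorted(species_tree.wgd_species)
        presence = pd.DataFrame(
            0, index=["famX:A", "famY:B", "famZ:A"], columns=species_tree.species
        )
        presence.loc["famX:A", "Cscu"] = 1  # lost in all spiders
        for sp in ["Cscu", "Dsil"]:
            presence.loc["famY:B", sp] = 1  # lost in entelegynes
        for sp in wgd:
            presence.loc["famZ:A", sp] = 1  # fully retained
        out = infer_losses(presence, species_tree)
        assert out.loc["famX:A", "refined_category"] == "SOL"
        assert out.loc["famX:A", "loss_branches"] == "spiders"
        assert out.loc["famY:B", "refined_category"] == "EOL"
        assert out.loc["famY:B", "loss_branches"] == "entelegynes"
        assert out.loc["famZ:A", "refined_category"] == ""
        assert out.loc["famZ:A", "n_losses"] == 0


def _two_copy_genomes(stree_species, dispersed: bool):
    genomes = {}
    for sp in ("A", "B"):
        rows = [("F.0", "c1", 0, "+", "F")]
        rows.append(
            ("F.1", "c2" if dispersed else "c1", 10_000, "+", "F")
        )
        genomes[sp] = genome(sp, rows)
    genomes["C"] = genome("C", [("F.0", "c1", 0, "+", "F")])
    return genomes


class TestClassifyFamily:
    def test_dispersed_wgd_duplication_is_ohnologue(self):
        stree = read_species_tree(data="((A,B)WGD,C);")
        genomes = _two_copy_genomes(stree.species, dispersed=True)
        gt = read_gene_tree(
            data="((('A|F.0','B|F.0'),('A|F.1','B|F.1')),'C|F.0');"
        )
        call = classify_family("F", genomes, gt, stree)
        assert call.category == "O"
        assert call.evidence["majority_relation"] == "dispersed"
        assert not call.evidence["conflict"]

    def test_pre_wgd_clustered_duplication_is_ancient_tandem(self):
        stree = read_species_tree(data="((A,B)WGD,C);")
        genomes = {
            sp: genome(
                sp,
                [("F.0", "c1", 0, "+", "F"), ("F.1", "c1", 10_000, "+", "F")],
            )
            for sp in ("A", "B", "C")
        }
        gt = read_gene_tree(
            data="((('A|F.0','B|F.0'),'C|F.0'),(('A|F.1','B|F.1'),'C|F.1'));"
        )
        call = classify_family("F", genomes, gt, stree)
        assert call.category == "AT"
        assert call.evidence["majority_relation"] == "clustered"
        assert not call.evidence["conflict"]

    def test_post_wgd_clustered_duplication_is_recent_tandem(self):
        stree = read_species_tree(data="((A,B)WGD,C);")
        genomes = {
            "A": genome(
                "A", [("F.0", "c1", 0, "+", "F"), ("F.1", "c1", 10_000, "+", "F")]
            ),
            "B": genome("B", [("F.0", "c1", 0, "+", "F")]),
            "C": genome("C", [("F.0", "c1", 0, "+", "F")]),
        }
        gt = read_gene_tree(
            data="((('A|F.0','A|F.1'),'B|F.0'),'C|F.0');"
        )
        call = classify_family("F", genomes, gt, stree)
        assert call.category == "RT"
        assert call.duplication_branch == "A"

    def test_single_copy_everywhere_is_sc(self):
        stree = read_species_tree(data="((A,B)WGD,C);")
        genomes = {
            sp: genome(sp, [("F.0", "c1", 0, "+", "F")]) for sp in "ABC"
        }
        gt = read_gene_tree(data="(('A|F.0','B|F.0'),'C|F.0');")
        call = classify_family("F", genomes, gt, stree)
        assert call.category == "SC"

    def test_conflicting_linkage_flags_but_keeps_reconciliation(self):
        # WGD-compatible duplication whose copies are clustered in both
        # species: reconciliation wins (O) with a conflict flag
        stree = read_species_tree(data="((A,B)WGD,C);")
        genomes = _two_copy_genomes(stree.species, dispersed=False)
        gt = read_gene_tree(
            data="((('A|F.0','B|F.0'),('A|F.1','B|F.1')),'C|F.0');"
        )
        call = classify_family("F", genomes, gt, stree)
        assert call.category == "O"
        assert call.evidence["conflict"]

    def test_deterministic_across_repeated_runs(self):
        stree = read_species_tree(data="((A,B)WGD,C);")
        genomes = _two_copy_genomes(stree.species, dispersed=True)
        gt = read_gene_tree(
            data="((('A|F.0','B|F.0'),('A|F.1','B|F.1')),'C|F.0');"
        )
        c1 = classify_family("F", genomes, gt, stree)
        c2 = classify_family("F", genomes, gt, stree)
        assert (c1.category, c1.duplication_branch, c1.evidence) == (
            c2.category,
            c2.duplication_branch,
            c2.evidence,
        )


class TestRecoveryOnSimulation:
    def test_category_recovery_with_default_configuration(
        self, default_sim, default_inference
    ):
        from ohnotype.reporting_cli import recovery_report

        genomes, calls = default_inference
        rep = recovery_report(default_sim, calls)
        assert rep["category_accuracy"] >= 0.95
        assert rep["o_rt_confusion"] <= 0.02

    def test_loss_placement_recovery(self, default_sim, default_inference):
        from ohnotype.reporting_cli import recovery_report

        _, calls = default_inference
        rep = recovery_report(default_sim, calls)
        assert rep["n_sol_eol"] > 0
        assert rep["loss_placement_accuracy"] >= 0.9


class TestSummaries:
    def test_summary_counts_are_consistent(
        self, default_sim, default_inference
    ):
        genomes, calls = default_inference
        table, stats = summarize_repertoire(
            genomes, calls, default_sim.species_tree
        )
        assert len(table) == 14
        for _, row in table.iterrows():
            assert row["families_present"] >= row["families_single_copy"]
            assert row["families_present"] >= row["families_AT"]
            assert row["total_genes"] >= row["families_present"]
        wgd_rows = table[table["wgd"]]
        assert wgd_rows["families_retained_ohnologues"].notna().all()
        assert stats["wgd_outgroup_ratio"] is not None
        assert stats["wgd_outgroup_ratio"] > 1.0

    def test_empty_genomes_give_na_ratio(self, species_tree):
        genomes = {sp: SpeciesGenome(sp) for sp in species_tree.species}
        table, stats = summarize_repertoire(genomes, {}, species_tree)
        assert (table["total_genes"] == 0).all()
        assert stats["wgd_outgroup_ratio"] is None
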