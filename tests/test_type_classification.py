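import pytest

from polyorigin import origin_assignment as oa
from polyorigin import type_classification as tc
from polyorigin.errors import AssignmentError, MappingError
from polyorigin.origin_assignment import UNRESOLVED, OriginTagging
from polyorigin.simulate import simulate_gene_family_trees
from polyorigin.treeio import GeneFamilyTree


def tagging(tree_id, tags):
    return OriginTagging(tree_id=tree_id, tags=tags)


class TestClassifyTree:
    def test_signature_invariant_to_leaf_order(self, smap):
        a = tagging("T1", {"Nben_1": ("Alatae",), "Nben_2": ("Noctiflorae",)})
        b = tagging("T2", {"Nben_2": ("Noctiflorae",), "Nben_1": ("Alatae",)})
        assert tc.classify_tree(a, smap) == tc.classify_tree(b, smap)

    def test_signature_names_both_origins(self, smap):
        tg = tagging("T1", {"Nben_1": ("Alatae",), "Nben_2": ("Noctiflorae",)})
        assert tc.classify_tree(tg, smap) == "Nben:{Alatae},{Noctiflorae}"

    def test_unresolved_distinct_from_resolved(self, smap):
        resolved = tagging("T1", {"Nben_1": ("Alatae",), "Nben_2": ("Noctiflorae",)})
        unresolved = tagging("T2", {"Nben_1": ("Alatae",), "Nben_2": UNRESOLVED})
        assert tc.classify_tree(resolved, smap) != tc.classify_tree(unresolved, smap)

    def test_multi_origin_tag_inside_braces(self, smap):
        tg = tagging("T1", {"Nben_1": ("Alatae", "Sylvestres"), "Ntab_1": ("Sylvestres",)})
        assert (
            tc.classify_tree(tg, smap)
            == "Nben:{Alatae,Sylvestres}|Ntab:{Sylvestres}"
        )


class TestControlFilter:
    def test_expected_parents_kept(self, smap):
        tg = tagging("T1", {"Ntab_1": ("Sylvestres",), "Ntab_2": ("Tomentosae",)})
        result = tc.apply_control_filter([tg], smap)
        assert result.kept == ["T1"] and not result.discarded

    def test_foreign_singleton_discarded(self, smap):
        tg = tagging("T1", {"Ntab_1": ("Petunioides",), "Ntab_2": ("Tomentosae",)})
        result = tc.apply_control_filter([tg], smap)
        assert result.discarded == {"T1": "unexpected_parent"}

    def test_missing_expected_parent_discarded(self, smap):
        tg = tagging("T1", {"Ntab_1": ("Sylvestres",)})
        result = tc.apply_control_filter([tg], smap)
        assert result.discarded == {"T1": "missing_expected_parent"}

    def test_multi_origin_covering_parent_kept_but_flagged(self, smap):
        tg = tagging(
            "T1",
            {"Ntab_1": ("Sylvestres",), "Ntab_2": ("Alatae", "Tomentosae")},
        )
        result = tc.apply_control_filter([tg], smap)
        assert result.kept == ["T1"] and result.flagged == ["T1"]

    def test_unresolved_control_discarded(self, smap):
        tg = tagging("T1", {"Ntab_1": UNRESOLVED, "Ntab_2": ("Tomentosae",)})
        result = tc.apply_control_filter([tg], smap)
        assert result.discarded == {"T1": "control_unresolved"}

    def test_no_control_configured_keeps_all(self, truth):
        from dataclasses import replace

        smap_nc = replace(truth, control_polyploid=None).section_map()
        tgs = [tagging("T1", {"Nben_1": ("Alatae",)})]
        result = tc.apply_control_filter(tgs, smap_nc)
        assert result.kept == ["T1"]


class TestGroupByType:
    def test_sizes_5_3_2_with_min_trees_3(self):
        sigs = {}
        for i in range(5):
            sigs[f"A{i}"] = "sigA"
        for i in range(3):
            sigs[f"B{i}"] = "sigB"
        for i in range(2):
            sigs[f"C{i}"] = "sigC"
        groups = tc.group_by_type(sigs, min_trees=3)
        assert [(g.type_id, len(g), g.retained) for g in groups] == [
            ("Type001", 5, True),
            ("Type002", 3, True),
            ("Type003", 2, False),
        ]

    def test_all_identical_single_group(self):
        groups = tc.group_by_type({f"T{i}": "sig" for i in range(4)})
        assert len(groups) == 1 and groups[0].type_id == "Type001"

    def test_min_trees_1_no_exclusions(self):
        groups = tc.group_by_type({"T1": "a", "T2": "b"}, min_trees=1)
        assert all(g.retained for g in groups)

    def test_retained_plus_excluded_counts_conserve_trees(self):
        sigs = {f"T{i}": f"sig{i % 4}" for i in range(10)}
        groups = tc.group_by_type(sigs, min_trees=3)
        assert sum(len(g) for g in groups) == 10


class TestTaxonMap:
    def test_origin_suffix_abbreviates_section(self, smap):
        tgs = [
            tagging("T1", {"Nafr_1": ("Sylvestres",), "Nafr_2": ("Noctiflorae",)})
        ]
        group = tc.TypeGroup("Type001", "sig", ["T1"], True)
        mapping = tc.build_taxon_map(group, tgs, smap)
        assert mapping["Nafr_S"] == ["Nafr_1"]
        assert mapping["Nafr_N"] == ["Nafr_2"]

    def test_diploids_map_to_identity(self, truth, smap):
        ts = simulate_gene_family_trees(truth, 3, seed=31)
        rooted = [oa.root_on_outgroup(g, smap) for g in ts.trees]
        tgs = [oa.assign_leaf_origins(g, smap) for g in rooted]
        group = tc.TypeGroup("Type001", "sig", [g.id for g in rooted], True)
        mapping = tc.complete_taxon_map(group, tgs, rooted, smap)
        assert mapping["Nala"] == ["Nala"]
        assert mapping["Slyc"] == ["Slyc"]

    def test_empty_group_raises(self, smap):
        group = tc.TypeGroup("Type001", "sig", [], True)
        with pytest.raises(AssignmentError):
            tc.build_taxon_map(group, [], smap)

    def test_astral_map_format(self, tmp_path):
        tc.write_astral_map({"Nafr_S": ["Nafr_1", "Nafr_3"]}, tmp_path / "map.txt")
        assert (tmp_path / "map.txt").read_text() == "Nafr_S: Nafr_1,Nafr_3\n"


def identity_map(*names):
    return {n: [n] for n in names}


class TestConsensusTree:
    def test_identical_trees_consensus_is_the_tree(self):
        trees = [
            GeneFamilyTree.from_newick("((A,B),(C,D));", f"T{i}") for i in range(3)
        ]
        cons = tc.consensus_tree(trees, identity_map("A", "B", "C", "D"))
        newick = tc.consensus_newick(cons)
        assert "1" in newick  # all clade frequencies 1
        clades = {
            frozenset(l.taxon.label for l in nd.leaf_iter())
            for nd in cons.preorder_internal_node_iter()
        }
        assert frozenset("AB") in clades and frozenset("CD") in clades

    def test_two_to_one_majority(self):
        trees = [
            GeneFamilyTree.from_newick("((A,B),C);", "T1"),
            GeneFamilyTree.from_newick("((A,B),C);", "T2"),
            GeneFamilyTree.from_newick("((A,C),B);", "T3"),
        ]
        cons = tc.consensus_tree(trees, identity_map("A", "B", "C"))
        ab_nodes = [
            nd
            for nd in cons.preorder_internal_node_iter()
            if {l.taxon.label for l in nd.leaf_iter()} == {"A", "B"}
        ]
        assert len(ab_nodes) == 1
        assert float(ab_nodes[0].label) == pytest.approx(2 / 3, abs=1e-3)

    def test_synthetic_group_consensus_places_donor_as_sister(self, truth, smap):
        ts = simulate_gene_family_trees(truth, 40, seed=33, nest_prob=0.0)
        rooted = [oa.root_on_outgroup(g, smap) for g in ts.trees]
        tgs = [oa.assign_leaf_origins(g, smap) for g in rooted]
        sigs = {tg.tree_id: tc.classify_tree(tg, smap) for tg in tgs}
        groups = tc.group_by_type(sigs, min_trees=3)
        group = groups[0]
        members = [g for g in rooted if g.id in set(group.members)]
        tmap = tc.complete_taxon_map(group, tgs, rooted, smap)
        cons = tc.consensus_tree(members, tmap)
        # the reference polyploid's Alatae-derived homeolog clusters with Alatae
        clades = [
            {l.taxon.label for l in nd.leaf_iter()}
            for nd in cons.preorder_internal_node_iter()
        ]
        assert any(
            "Nben_A" in clade and {"Nala", "Nlan"} <= clade and "Nben_N" not in clade
            for clade in clades
        )

    def test_unmapped_leaf_raises(self):
        trees = [GeneFamilyTree.from_newick("((A,B),C);", "T1")]
        with pytest.raises(MappingError):
            tc.consensus_tree(trees, identity_map("A", "B"))

    def test_clade_frequencies_bounded(self, truth, smap):
        ts = simulate_gene_family_trees(truth, 12, seed=34)
        rooted = [oa.root_on_outgroup(g, smap) for g in ts.trees]
        tgs = [oa.assign_leaf_origins(g, smap) for g in rooted]
        group = tc.TypeGroup("Type001", "sig", [g.id for g in rooted], True)
        tmap = tc.complete_taxon_map(group, tgs, rooted, smap)
        cons = tc.consensus_tree(rooted, tmap)
        for nd in cons.preorder_internal_node_iter():
            if nd.label:
                assert 0.0 <= float(nd.label) <= 1.0
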