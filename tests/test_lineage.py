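"""Crossing, secondary mutagenesis, genealogy queries and MTA propagation."""

import oracles
import pytest

import seedledger as sl
from seedledger import lineage, registry
from seedledger.models import FeatureCategory, FeatureSpec, MtaInfo


class TestCross:
    def test_child_unions_parental_features_by_reference(self, family):
        db, x = family["db"], family["x"]
        labels = sorted(f["label"] for f in lineage.feature_table(db, x))
        assert labels == ["Pro35S:GUS from L1", "pht1;1-1 from L2"]
        assert all(f["inherited"] for f in lineage.feature_table(db, x))

    def test_mixed_ecotypes_combine_in_label(self, family):
        assert family["x"].ecotype_label == "Col-0 × Ler"

    def test_interspecies_cross_is_refused(self, adb):
        ara = registry.create_line(adb, "A", "person-KESTREL",
                                   "Arabidopsis thaliana")
        rice = registry.create_line(adb, "R", "person-KESTREL",
                                    "Oryza sativa")
        with pytest.raises(sl.SpeciesMismatchError):
            lineage.cross(adb, ara, rice, "bad")

    def test_self_cross_is_refused(self, adb):
        line = registry.create_line(adb, "A", "person-KESTREL",
                                    "Arabidopsis thaliana")
        with pytest.raises(sl.ValidationError):
            lineage.cross(adb, line, line, "selfed")

    def test_cross_batches_must_belong_to_their_parents(self, family):
        db, l1, l2 = family["db"], family["l1"], family["l2"]
        foreign = registry.add_seed_batch(db, l2, "s-of-l2")
        with pytest.raises(sl.ConsistencyError):
            lineage.cross(db, l1, l2, "bad", female_batch=foreign)

    def test_batches_used_are_recorded_on_the_edges(self, adb):
        l1 = registry.create_line(adb, "A", "person-KESTREL",
                                  "Arabidopsis thaliana")
        l2 = registry.create_line(adb, "B", "person-KESTREL",
                                  "Arabidopsis thaliana")
        fb = registry.add_seed_batch(adb, l1, "fem-seed")
        child = lineage.cross(adb, l1, l2, "C", female_batch=fb)
        g = lineage.ancestry_tree(adb, child)
        assert g.edges[l1.line_id, child.line_id]["batch_id"] == fb.system_id
        assert g.edges[l2.line_id, child.line_id]["batch_id"] is None

    def test_pollen_mutagenesis_extra_feature_is_owned_by_child(self, adb):
        l1 = registry.create_line(adb, "A", "person-KESTREL",
                                  "Arabidopsis thaliana")
        l2 = registry.create_line(adb, "B", "person-KESTREL",
                                  "Arabidopsis thaliana")
        child = lineage.cross(adb, l1, l2, "C", extra_feature=FeatureSpec(
            designation="pollen-ems-1", category=FeatureCategory.ENDOGENOUS))
        feats = lineage.effective_features(adb, child)
        assert len(feats) == 1
        assert feats[0].origin_line_id == child.line_id

    def test_parent_edit_is_visible_from_child_but_not_editable_there(
            self, family):
        db, l1, x, f1 = family["db"], family["l1"], family["x"], family["f1"]
        registry.edit_feature(db, l1, f1, gene="AT5G43350")
        from_child = [f for f in lineage.effective_features(db, x)
                      if f.feature_id == f1.feature_id]
        assert from_child[0].gene == "AT5G43350"
        with pytest.raises(sl.ImmutableFeatureError):
            registry.edit_feature(db, x, f1, gene="AT0G00000")


class TestMutag:
    def test_child_inherits_everything_and_owns_the_new_feature(self, family):
        db, m = family["db"], family["m"]
        table = lineage.feature_table(db, m)
        assert sorted(t["label"] for t in table) == [
            "Pro35S:GUS from L1", "pht1;1-1 from L2", "pht1;4-2"]
        owned = [t for t in table if not t["inherited"]]
        assert [t["designation"] for t in owned] == ["pht1;4-2"]

    def test_inherits_species_and_ecotype(self, adb):
        parent = registry.create_line(adb, "P", "person-KESTREL",
                                      "Arabidopsis thaliana", ecotype="Ws-2")
        child = lineage.mutagenize(adb, parent, FeatureSpec(
            designation="m", category=FeatureCategory.ENDOGENOUS), "C")
        assert (child.species, child.ecotype_label) == \
            ("Arabidopsis thaliana", "Ws-2")

    def test_chained_mutagenesis_accumulates_origin_labels(self, adb):
        """Two successive mutageneses: the grandchild carries 3 features,
        each labelled with the line where it was created."""
        l0 = registry.create_line(adb, "G0", "person-KESTREL",
                                  "Arabidopsis thaliana")
        registry.add_feature(adb, l0, FeatureSpec(
            designation="f0", category=FeatureCategory.ENDOGENOUS))
        l1 = lineage.mutagenize(adb, l0, FeatureSpec(
            designation="f1", category=FeatureCategory.ENDOGENOUS), "G1")
        l2 = lineage.mutagenize(adb, l1, FeatureSpec(
            designation="f2", category=FeatureCategory.ENDOGENOUS), "G2")
        labels = sorted(t["label"] for t in lineage.feature_table(adb, l2))
        assert labels == ["f0 from G0", "f1 from G1", "f2"]

    def test_missing_designation_is_rejected(self, adb):
        parent = registry.create_line(adb, "P", "person-KESTREL",
                                      "Arabidopsis thaliana")
        with pytest.raises(sl.ValidationError):
            lineage.mutagenize(adb, parent, FeatureSpec(
                designation="", category=FeatureCategory.ENDOGENOUS), "C")


class TestGenealogy:
    def test_de_novo_line_is_a_single_node(self, adb):
        line = registry.create_line(adb, "L", "person-KESTREL",
                                    "Arabidopsis thaliana")
        g = lineage.ancestry_tree(adb, line)
        assert (g.number_of_nodes(), g.number_of_edges()) == (1, 0)

    def test_cross_child_has_three_nodes_two_edges(self, family):
        g = lineage.ancestry_tree(family["db"], family["x"])
        assert (g.number_of_nodes(), g.number_of_edges()) == (3, 2)

    def test_cross_then_mutag_has_four_nodes_three_edges(self, family):
        g = lineage.ancestry_tree(family["db"], family["m"])
        assert (g.number_of_nodes(), g.number_of_edges()) == (4, 3)

    def test_tree_equals_transitive_parent_closure(self, pedigree):
        db = pedigree
        for lid in oracles.all_line_ids(db):
            g = lineage.ancestry_tree(db, lid)
            assert set(g.nodes) == oracles.ancestor_closure(db, lid)

    def test_descendant_count_on_a_chain(self, adb):
        a = registry.create_line(adb, "A", "person-KESTREL",
                                 "Arabidopsis thaliana")
        b = lineage.mutagenize(adb, a, FeatureSpec(
            designation="m1", category=FeatureCategory.ENDOGENOUS), "B")
        lineage.mutagenize(adb, b, FeatureSpec(
            designation="m2", category=FeatureCategory.ENDOGENOUS), "C")
        assert lineage.descendant_count(adb, a) == 2
        assert lineage.descendant_count(adb, b) == 1

    def test_leaf_has_zero_descendants(self, family):
        assert lineage.descendant_count(family["db"], family["m"]) == 0

    def test_descendant_count_equals_reverse_reachability(self, pedigree):
        db = pedigree
        for lid in oracles.all_line_ids(db):
            assert lineage.descendant_count(db, lid) == \
                len(oracles.descendant_ids(db, lid))


class TestInheritanceSoundness:
    def test_effective_sets_equal_recursive_union(self, pedigree):
        db = pedigree
        for lid in oracles.all_line_ids(db):
            got = {f.feature_id for f in lineage.effective_features(db, lid)}
            assert got == oracles.effective_feature_ids(db, lid)

    def test_origin_labels_survive_renames(self, family):
        db, l1, x = family["db"], family["l1"], family["x"]
        registry.rename_line(db, l1, "L1-renamed")
        labels = [t["label"] for t in lineage.feature_table(db, x)]
        assert "Pro35S:GUS from L1-renamed" in labels

    def test_gmo_flag_iff_a_green_box_is_present(self, pedigree):
        db = pedigree
        for lid in oracles.all_line_ids(db):
            greens = any(t["color"] == "GREEN"
                         for t in lineage.feature_table(db, lid))
            assert lineage.is_transgenic(db, lid) == greens


class TestMta:
    def test_unprotected_founder_is_unencumbered(self, adb):
        line = registry.create_line(adb, "L", "person-KESTREL",
                                    "Arabidopsis thaliana")
        assert lineage.mta_affected_set(adb, line) == set()

    def test_child_of_protected_parent_is_constrained(self, adb):
        parent = registry.create_line(
            adb, "P", "person-KESTREL", "Arabidopsis thaliana",
            mta=MtaInfo(True, "recipient: institute X"))
        child = lineage.mutagenize(adb, parent, FeatureSpec(
            designation="m", category=FeatureCategory.ENDOGENOUS), "C")
        assert lineage.mta_affected_set(adb, child) == {parent.line_id}

    def test_deep_pedigree_recovers_all_protected_founders(self, pedigree):
        db = pedigree
        for lid in oracles.all_line_ids(db):
            assert lineage.mta_affected_set(db, lid) == \
                oracles.protected_ancestors(db, lid)


class TestExport:
    def test_single_node_dot(self, adb):
        line = registry.create_line(adb, "Solo", "person-KESTREL",
                                    "Arabidopsis thaliana")
        dot = lineage.to_dot(adb, line)
        assert dot.count("->") == 0
        assert '[label="Solo"]' in dot

    def test_mta_parent_is_red(self, adb):
        p = registry.create_line(adb, "Prot", "person-KESTREL",
                                 "Arabidopsis thaliana",
                                 mta=MtaInfo(True, "x"))
        q = registry.create_line(adb, "Free", "person-KESTREL",
                                 "Arabidopsis thaliana")
        child = lineage.cross(adb, p, q, "C")
        dot = lineage.to_dot(adb, child)
        assert f'n{p.line_id} [label="Prot", fillcolor=red];' in dot
        assert f'n{q.line_id} [label="Free"];' in dot

    def test_dot_output_is_wellformed_and_stable(self, pedigree):
        db = pedigree
        last = oracles.all_line_ids(db)[-1]
        dot = lineage.to_dot(db, last)
        # minimal DOT grammar: header, balanced braces, terminated statements
        assert dot.startswith("digraph ") and dot.rstrip().endswith("}")
        body = dot[dot.index("{") + 1:dot.rindex("}")]
        assert all(line.rstrip().endswith(";")
                   for line in body.strip().splitlines())
        assert dot == lineage.to_dot(db, last)  # bit-stable

    def test_png_export_yields_png_bytes(self, family):
        payload = lineage.export_tree(family["db"], family["m"], "PNG")
        assert payload[:8] == b"\x89PNG\r\n\x1a\n"
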