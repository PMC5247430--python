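"""Line, feature, plant and seed-batch record contracts."""

import random

import pytest

import seedledger as sl
from seedledger import registry
from seedledger.models import (FeatureCategory, FeatureSpec, GenotypeState,
                               InsertionSite)


class TestLines:
    def test_wildtype_line_has_no_features(self, adb):
        line = registry.create_line(adb, "WT-Col0", "person-KESTREL",
                                    "Arabidopsis thaliana", ecotype="Col-0")
        assert sl.lineage.effective_features(adb, line) == []
        assert not sl.lineage.is_transgenic(adb, line)

    def test_missing_mandatory_fields_are_named(self, adb):
        with pytest.raises(sl.ValidationError) as exc:
            registry.create_line(adb, "only-name")
        assert set(exc.value.missing) == {"person", "species"}

    def test_unknown_species_is_a_vocabulary_error(self, adb):
        with pytest.raises(sl.NotFoundError):
            registry.create_line(adb, "L", "person-KESTREL",
                                 "Solanum tuberosum")

    def test_fields_persist_across_reopen(self, tmp_path):
        path = tmp_path / "lab.db"
        db = sl.SeedDatabase(path, login="admin")
        sl.fixtures.seed_vocabularies(db)
        line = registry.create_line(db, "WT", "person-KESTREL",
                                    "Arabidopsis thaliana", ecotype="Col-0",
                                    origin="NASC")
        db.close()
        db = sl.SeedDatabase(path, login="admin")
        again = registry.get_line(db, line.line_id)
        assert (again.name, again.person, again.species, again.ecotype_label,
                again.origin) == ("WT", "person-KESTREL",
                                  "Arabidopsis thaliana", "Col-0", "NASC")
        db.close()

    def test_ecotype_must_belong_to_species(self, adb):
        with pytest.raises(sl.NotFoundError):
            registry.create_line(adb, "L", "person-KESTREL", "Oryza sativa",
                                 ecotype="Col-0")


class TestFeatures:
    def test_transgenesis_is_green_endogenous_is_blue(self, adb):
        line = registry.create_line(adb, "L", "person-KESTREL",
                                    "Arabidopsis thaliana")
        green = registry.add_feature(adb, line, FeatureSpec(
            designation="Pro35S:GUS", category=FeatureCategory.TRANSGENESIS))
        blue = registry.add_feature(adb, line, FeatureSpec(
            designation="pht1;1-1", category=FeatureCategory.ENDOGENOUS,
            mutation_method="EMS"))
        assert green.color == "GREEN" and blue.color == "BLUE"

    def test_crispr_event_is_one_green_plus_one_blue_box(self, adb):
        """Cas9 T-DNA (transgene) + edited target locus (endogenous)."""
        line = registry.create_line(adb, "crispr-line", "person-KESTREL",
                                    "Arabidopsis thaliana")
        registry.add_feature(adb, line, FeatureSpec(
            designation="pUbi:Cas9", category=FeatureCategory.TRANSGENESIS,
            mutation_method="T-DNA"))
        registry.add_feature(adb, line, FeatureSpec(
            designation="pht1;4-cr1", category=FeatureCategory.ENDOGENOUS,
            mutation_method="CRISPR"))
        colors = sorted(f["color"] for f in sl.lineage.feature_table(adb, line))
        assert colors == ["BLUE", "GREEN"]
        assert sl.lineage.is_transgenic(adb, line)

    def test_designation_is_mandatory(self, adb):
        line = registry.create_line(adb, "L", "person-KESTREL",
                                    "Arabidopsis thaliana")
        with pytest.raises(sl.ValidationError):
            registry.add_feature(adb, line, FeatureSpec(
                designation="  ", category=FeatureCategory.ENDOGENOUS))

    def test_strain_and_resistance_are_transgenesis_only(self, adb):
        line = registry.create_line(adb, "L", "person-KESTREL",
                                    "Arabidopsis thaliana")
        with pytest.raises(sl.CategoryError):
            registry.add_feature(adb, line, FeatureSpec(
                designation="m1", category=FeatureCategory.ENDOGENOUS,
                agro_strain="GV3101"))

    def test_shared_designation_is_allowed_with_warning(self, adb):
        line = registry.create_line(adb, "L", "person-KESTREL",
                                    "Arabidopsis thaliana")
        spec = FeatureSpec(designation="dup",
                           category=FeatureCategory.ENDOGENOUS)
        registry.add_feature(adb, line, spec)
        with pytest.warns(UserWarning, match="dup"):
            registry.add_feature(adb, line, spec)


class TestSeedBatchIds:
    def test_monotonic_allocation(self, adb):
        line = registry.create_line(adb, "L", "person-KESTREL",
                                    "Arabidopsis thaliana")
        ids = [registry.add_seed_batch(adb, line, f"s{i}").system_id
               for i in range(3)]
        assert ids == [1, 2, 3]

    def test_deleted_id_is_never_reallocated(self, adb):
        line = registry.create_line(adb, "L", "person-KESTREL",
                                    "Arabidopsis thaliana")
        for i in range(3):
            registry.add_seed_batch(adb, line, f"s{i}")
        registry.delete_seed_batch(adb, 2)
        registry.delete_seed_batch(adb, 3)
        assert registry.add_seed_batch(adb, line, "s-next").system_id == 4

    def test_same_personal_identifier_distinct_system_ids(self, adb):
        line = registry.create_line(adb, "L", "person-KESTREL",
                                    "Arabidopsis thaliana")
        a = registry.add_seed_batch(adb, line, "harvest-1")
        b = registry.add_seed_batch(adb, line, "harvest-1")
        assert a.personal_identifier == b.personal_identifier
        assert a.system_id != b.system_id

    def test_random_trace_never_reuses_ids(self, adb):
        """Randomized create/delete/copy trace against a counter model."""
        line = registry.create_line(adb, "L", "person-KESTREL",
                                    "Arabidopsis thaliana")
        rng = random.Random(1)
        issued: list[int] = []
        live: list[int] = []
        next_expected = 1
        for _ in range(300):
            op = rng.random()
            if op < 0.5 or not live:
                b = registry.add_seed_batch(adb, line, "s")
                new_id = b.system_id
            elif op < 0.75:
                new_id = registry.copy_seed_batch(adb,
                                                  rng.choice(live)).system_id
            else:
                victim = rng.choice(live)
                registry.delete_seed_batch(adb, victim)
                live.remove(victim)
                continue
            assert new_id == next_expected  # strictly increasing, no reuse
            assert new_id not in issued
            issued.append(new_id)
            live.append(new_id)
            next_expected += 1


class TestCopy:
    def test_batch_copy_gets_fresh_id_and_same_fields(self, adb):
        line = registry.create_line(adb, "L", "person-KESTREL",
                                    "Arabidopsis thaliana")
        src = registry.add_seed_batch(adb, line, "s1", generation_label="T2",
                                      storage_place="box-9",
                                      harvest_date="2024-05-01")
        dup = registry.copy_seed_batch(adb, src)
        assert dup.system_id == src.system_id + 1
        assert (dup.personal_identifier, dup.generation_label,
                dup.storage_place, dup.harvest_date) == \
               (src.personal_identifier, src.generation_label,
                src.storage_place, src.harvest_date)

    def test_plant_copy_is_independent(self, adb):
        line = registry.create_line(adb, "L", "person-KESTREL",
                                    "Arabidopsis thaliana")
        feat = registry.add_feature(adb, line, FeatureSpec(
            designation="t", category=FeatureCategory.TRANSGENESIS))
        src = registry.add_plant(adb, line, "p1", genotypes={
            feat.feature_id: GenotypeState.HETEROZYGOUS})
        dup = registry.copy_plant(adb, src)
        registry.set_genotype(adb, dup, feat, GenotypeState.HOMOZYGOUS)
        assert registry.get_plant(adb, src.plant_id).genotypes[
            feat.feature_id] is GenotypeState.HETEROZYGOUS

    def test_copy_across_lines_is_refused(self, adb):
        l1 = registry.create_line(adb, "L1", "person-KESTREL",
                                  "Arabidopsis thaliana")
        l2 = registry.create_line(adb, "L2", "person-KESTREL",
                                  "Arabidopsis thaliana")
        batch = registry.add_seed_batch(adb, l1, "s")
        plant = registry.add_plant(adb, l1, "p")
        with pytest.raises(sl.ConsistencyError):
            registry.copy_seed_batch(adb, batch, target_line=l2)
        with pytest.raises(sl.ConsistencyError):
            registry.copy_plant(adb, plant, target_line=l2)


class TestInsertionSites:
    def test_independent_transformants_in_one_datasheet(self, adb):
        line = registry.create_line(adb, "L", "person-KESTREL",
                                    "Arabidopsis thaliana")
        feat = registry.add_feature(adb, line, FeatureSpec(
            designation="t", category=FeatureCategory.TRANSGENESIS))
        p1 = registry.add_plant(adb, line, "T1-1", generation_label="T1")
        p2 = registry.add_plant(adb, line, "T1-2", generation_label="T1")
        registry.set_insertion_sites(adb, p1, feat,
                                     [InsertionSite("Chr1:1234")])
        registry.set_insertion_sites(adb, p2, feat,
                                     [InsertionSite("Chr4:9876")])
        s1 = registry.get_plant(adb, p1.plant_id).insertion_sites
        s2 = registry.get_plant(adb, p2.plant_id).insertion_sites
        assert s1[feat.feature_id][0].location == "Chr1:1234"
        assert s2[feat.feature_id][0].location == "Chr4:9876"

    def test_endogenous_features_have_no_insertion_sites(self, adb):
        line = registry.create_line(adb, "L", "person-KESTREL",
                                    "Arabidopsis thaliana")
        feat = registry.add_feature(adb, line, FeatureSpec(
            designation="m", category=FeatureCategory.ENDOGENOUS))
        plant = registry.add_plant(adb, line, "p")
        with pytest.raises(sl.CategoryError):
            registry.set_insertion_sites(adb, plant, feat,
                                         [InsertionSite("Chr1:1")])

    def test_empty_list_clears_sites(self, adb):
        line = registry.create_line(adb, "L", "person-KESTREL",
                                    "Arabidopsis thaliana")
        feat = registry.add_feature(adb, line, FeatureSpec(
            designation="t", category=FeatureCategory.TRANSGENESIS))
        plant = registry.add_plant(adb, line, "p")
        registry.set_insertion_sites(adb, plant, feat,
                                     [InsertionSite("Chr1:1")])
        registry.set_insertion_sites(adb, plant, feat, [])
        assert registry.get_plant(adb, plant.plant_id).insertion_sites == {}


class TestConsistencyAndLocking:
    def test_genotype_keys_restricted_to_line_features(self, adb):
        l1 = registry.create_line(adb, "L1", "person-KESTREL",
                                  "Arabidopsis thaliana")
        l2 = registry.create_line(adb, "L2", "person-KESTREL",
                                  "Arabidopsis thaliana")
        foreign = registry.add_feature(adb, l2, FeatureSpec(
            designation="f", category=FeatureCategory.ENDOGENOUS))
        with pytest.raises(sl.ConsistencyError):
            registry.add_plant(adb, l1, "p", genotypes={
                foreign.feature_id: GenotypeState.WT})

    def test_empty_identifier_is_rejected(self, adb):
        line = registry.create_line(adb, "L", "person-KESTREL",
                                    "Arabidopsis thaliana")
        for op in (registry.add_plant, registry.add_seed_batch):
            with pytest.raises(sl.ValidationError) as exc:
                op(adb, line, "   ")
            assert exc.value.missing == ("personal_identifier",)

    def test_locked_record_rejects_edits_until_unlocked(self, adb):
        line = registry.create_line(adb, "L", "person-KESTREL",
                                    "Arabidopsis thaliana")
        registry.set_locked(adb, line, True)
        locked = registry.get_line(adb, line.line_id)
        with pytest.raises(sl.LockedError):
            registry.edit_line(adb, locked, origin="donated")
        registry.set_locked(adb, locked, False)
        unlocked = registry.get_line(adb, line.line_id)
        assert registry.edit_line(adb, unlocked, origin="donated").origin \
            == "donated"

    def test_unlock_does_not_unlock_inherited_fields(self, family):
        db, x, f1 = family["db"], family["x"], family["f1"]
        registry.set_locked(db, x, False)
        child = registry.get_line(db, x.line_id)
        with pytest.raises(sl.ImmutableFeatureError):
            registry.edit_feature(db, child, f1, gene="AT1G01010")

    def test_line_with_batches_or_descendants_cannot_be_deleted(self, family):
        db = family["db"]
        with pytest.raises(sl.ConsistencyError):
            registry.delete_line(db, family["l1"])  # has a descendant
        leaf = family["m"]
        registry.add_seed_batch(db, leaf, "s1")
        with pytest.raises(sl.ConsistencyError):
            registry.delete_line(db, leaf)


def test_table_csv_lists_one_row_per_record(adb):
    line = registry.create_line(adb, "L", "person-KESTREL",
                                "Arabidopsis thaliana")
    registry.add_plant(adb, line, "p1", generation_label="T1")
    registry.add_seed_batch(adb, line, "s1", storage_place="box-1")
    plants_csv = registry.table_csv(adb, line, "plants")
    batches_csv = registry.table_csv(adb, line, "batches")
    assert plants_csv.count("\n") == 2 and "p1" in plants_csv
    assert batches_csv.count("\n") == 2 and "box-1" in batches_csv
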