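"""Set up a laboratory registry: vocabularies, a wild-type line, a
transgenic line, plants and seed batches.

Run:  python examples/build_registry.py
"""

import seedledger as sl
from seedledger import lineage, registry, vocab

db = sl.SeedDatabase(":memory:", login="admin")

# the administrator registers the scroll-down options first
vocab.add_entry(db, sl.VocabCategory.PERSON, "alice")
vocab.add_entry(db, sl.VocabCategory.SPECIES, "Arabidopsis thaliana")
vocab.add_entry(db, sl.VocabCategory.ECOTYPE, "Col-0",
                linked_species="Arabidopsis thaliana")
vocab.add_entry(db, sl.VocabCategory.STRAIN, "GV3101")
vocab.add_entry(db, sl.VocabCategory.RESISTANCE, "Kanamycin")

# a wild-type line needs only name, person and species
wt = registry.create_line(db, "WT-Col0", "alice", "Arabidopsis thaliana",
                          ecotype="Col-0")
print(f"{wt.name}: {len(lineage.effective_features(db, wt))} features"
      f" -> wild type, GMO = {lineage.is_transgenic(db, wt)}")

# a reporter line carries one transgene (green box -> classified GMO)
reporter = registry.create_line(db, "GUS-reporter", "alice",
                                "Arabidopsis thaliana", ecotype="Col-0")
registry.add_feature(db, reporter, sl.FeatureSpec(
    designation="Pro35S:GUS", category=sl.FeatureCategory.TRANSGENESIS,
    mutation_method="T-DNA", selectable_resistance="Kanamycin",
    agro_strain="GV3101"))
print(f"{reporter.name}: GMO = {lineage.is_transgenic(db, reporter)}")

# independent T1 transformants live in one datasheet, each with its own
# insertion site
feat = lineage.effective_features(db, reporter)[0]
for i, loc in enumerate(["Chr1:443210", "Chr4:98765"], start=1):
    plant = registry.add_plant(db, reporter, f"T1-{i}", generation_label="T1")
    registry.set_insertion_sites(db, plant, feat, [sl.InsertionSite(loc)])
    print(f"  plant T1-{i}: insertion at {loc}")

# seed batches receive unique system ids that are never reused
b1 = registry.add_seed_batch(db, reporter, "harvest-1", generation_label="T2")
b2 = registry.add_seed_batch(db, reporter, "harvest-1", generation_label="T2")
print(f"two batches named 'harvest-1' -> system ids {b1.system_id},"
      f" {b2.system_id} (always distinct)")
registry.delete_seed_batch(db, b2)
b3 = registry.add_seed_batch(db, reporter, "harvest-2")
print(f"after deleting id {b2.system_id}, the next batch gets id"
      f" {b3.system_id}: retired ids are never reallocated")
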