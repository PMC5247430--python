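"""Cross and mutagenize lines, inspect the genealogy, and trace which
Material Transfer Agreements constrain a descendant.

Run:  python examples/pedigree_and_mta.py
"""

import seedledger as sl
from seedledger import lineage, registry, vocab

db = sl.SeedDatabase(":memory:", login="admin")
for p in ("alice",):
    vocab.add_entry(db, sl.VocabCategory.PERSON, p)
vocab.add_entry(db, sl.VocabCategory.SPECIES, "Arabidopsis thaliana")
for e in ("Col-0", "Ler"):
    vocab.add_entry(db, sl.VocabCategory.ECOTYPE, e,
                    linked_species="Arabidopsis thaliana")

# founder 1 came from another lab under an MTA; founder 2 is unencumbered
donor = registry.create_line(db, "ProPHT1:GFP", "alice",
                             "Arabidopsis thaliana", ecotype="Col-0",
                             mta=sl.MtaInfo(True, "recipient: institute X"))
registry.add_feature(db, donor, sl.FeatureSpec(
    designation="ProPHT1:GFP", category=sl.FeatureCategory.TRANSGENESIS))
mutant = registry.create_line(db, "pht1;1-1", "alice",
                              "Arabidopsis thaliana", ecotype="Ler")
registry.add_feature(db, mutant, sl.FeatureSpec(
    designation="pht1;1-1", category=sl.FeatureCategory.ENDOGENOUS))

# cross, then apply a secondary mutagenesis to the F-generation line
f1 = lineage.cross(db, donor, mutant, "GFPxpht1")
final = lineage.mutagenize(db, f1, sl.FeatureSpec(
    designation="pht1;4-cr3", category=sl.FeatureCategory.ENDOGENOUS), "triple")

print("feature table of 'triple' (green = transgene, blue = endogenous):")
for row in lineage.feature_table(db, final):
    print(f"  [{row['color']:5}] {row['label']}")

print(f"\ndescendants of {donor.name}: {lineage.descendant_count(db, donor)}")
print(f"mixed-ecotype label of the cross: {f1.ecotype_label!r}")

affected = lineage.mta_affected_set(db, final)
names = [registry.get_line(db, i).name for i in sorted(affected)]
print(f"MTAs constraining 'triple': {names}")
print("  -> the agreement follows the material through every cross and"
      " mutagenesis")

print("\ngenealogy (Graphviz DOT, MTA lines filled red):")
print(lineage.to_dot(db, final))
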