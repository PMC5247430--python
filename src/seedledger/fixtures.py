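"""Synthetic-pedigree generator.

Builds a fully populated registry — vocabularies, founder lines, random
cross/mutagenesis events, MTA flags, plants, seed batches, attachments —
deterministically from a seed.  It emulates the bookkeeping state of a
plant-genetics laboratory: 2 model species with a handful of ecotypes,
founders carrying 0–2 genetic features of both categories, and a pedigree
grown by repeatedly crossing same-species lines or applying secondary
mutagenesis.  Sensitive values (person names, notebook references, storage
places, MTA details) use distinctive tokens so redaction can be verified by
brute-force string scans.
"""

from __future__ import annotations

import random

from . import lineage, registry, vocab
from .db import SeedDatabase
from .errors import ValidationError
from .models import (FeatureCategory, FeatureSpec, GenotypeState, InsertionSite,
                     Attachment, MtaInfo, Role, Segregation, VocabCategory)

SPECIES = {
    "Arabidopsis thaliana": ["Col-0", "Ler", "Ws-2"],
    "Oryza sativa": ["Nipponbare", "Kitaake"],
}
PERSONS = ["person-KESTREL", "person-IBIS", "person-TANAGER"]
STRAINS = ["GV3101", "C58C1"]
RESISTANCES = ["Kanamycin", "Hygromycin", "BASTA"]
METHOD_REFS = ["Clough & Bent 1998", "lab protocol 12"]
GENERATIONS = ["T1", "T2", "F1", "F2", "F3", "unknown", "Tx"]

_TRANS_METHODS = ["T-DNA", "Transposon"]
_ENDO_METHODS = ["EMS", "CRISPR", "Gamma irradiation", "Natural variant"]


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def seed_vocabularies(db: SeedDatabase) -> None:
    """Register the standard persons/species/ecotypes/strains/resistances."""
    for p in PERSONS:
        vocab.add_entry(db, VocabCategory.PERSON, p)
    for sp, ecos in SPECIES.items():
        vocab.add_entry(db, VocabCategory.SPECIES, sp)
        for e in ecos:
            vocab.add_entry(db, VocabCategory.ECOTYPE, e, linked_species=sp)
    for s in STRAINS:
        vocab.add_entry(db, VocabCategory.STRAIN, s)
    for r in RESISTANCES:
        vocab.add_entry(db, VocabCategory.RESISTANCE, r)
    for m in METHOD_REFS:
        vocab.add_entry(db, VocabCategory.METHOD_REFERENCE, m)


def _random_feature(rng: random.Random, tag: str) -> FeatureSpec:
    if rng.random() < 0.5:
        return FeatureSpec(
            designation=f"Pro35S:GUS-{tag}",
            category=FeatureCategory.TRANSGENESIS,
            gene=f"AT{rng.randint(1, 5)}G{rng.randint(10000, 79999)}",
            mutation_method=rng.choice(_TRANS_METHODS),
            sequence=_random_seq(rng, 40),
            selectable_resistance=rng.choice(RESISTANCES),
            agro_strain=rng.choice(STRAINS))
    return FeatureSpec(
        designation=f"pht{rng.randint(1, 4)};{rng.randint(1, 4)}-{tag}",
        category=FeatureCategory.ENDOGENOUS,
        gene=f"AT{rng.randint(1, 5)}G{rng.randint(10000, 79999)}",
        mutation_method=rng.choice(_ENDO_METHODS),
        sequence=_random_seq(rng, 30))


def _populate_samples(db: SeedDatabase, rng: random.Random, line,
                      max_samples: int) -> None:
    feats = lineage.effective_features(db, line)
    plants = []
    for i in range(rng.randint(0, max_samples)):
        genos = {f.feature_id: rng.choice(list(GenotypeState))
                 for f in feats if rng.random() < 0.7}
        plant = registry.add_plant(
            db, line, f"{line.name}-p{i + 1}",
            generation_label=rng.choice(GENERATIONS), genotypes=genos,
            phenotype_note=rng.choice(["", "dwarf", "pale leaves",
                                       "GUS staining in roots"]),
            notebook_ref=f"NB-{rng.randint(100, 999)}-p{rng.randint(1, 80)}",
            person=rng.choice(PERSONS))
        for f in feats:
            if f.category is FeatureCategory.TRANSGENESIS and rng.random() < 0.4:
                registry.set_insertion_sites(db, plant, f, [
                    InsertionSite(
                        location=f"Chr{rng.randint(1, 5)}:"
                                 f"{rng.randint(1000, 999999)}",
                        flanking_sequence=_random_seq(rng, 20))
                    for _ in range(rng.randint(1, 2))])
        plants.append(registry.get_plant(db, plant.plant_id))
    for i in range(rng.randint(0, max_samples)):
        seg = {f.feature_id: Segregation(
                   observed_counts=f"{rng.randint(10, 60)}:"
                                   f"{rng.randint(5, 30)}",
                   note=rng.choice(["", "3:1", "close to 15:1"]))
               for f in feats if rng.random() < 0.5}
        mother = rng.choice(plants) if plants and rng.random() < 0.5 else None
        batch = registry.add_seed_batch(
            db, line, f"{line.name}-s{i + 1}",
            generation_label=rng.choice(GENERATIONS), mother_plant=mother,
            segregation=seg,
            harvest_date=f"20{rng.randint(15, 24)}-0{rng.randint(1, 9)}-15",
            storage_place=f"freezer-{rng.choice('XYZ')}-box{rng.randint(1, 30)}",
            germination_result=rng.choice(["", "92% after 7 d", "poor"]),
            phenotype_note=rng.choice(["", "late flowering"]),
            notebook_ref=f"NB-{rng.randint(100, 999)}-s{rng.randint(1, 80)}",
            person=rng.choice(PERSONS))
        if rng.random() < 0.3:
            registry.add_attachment(db, batch, Attachment(
                filename=f"gel-{batch.system_id}.txt",
                media_type="text/plain", slot="genotyping",
                content=_random_seq(rng, 60).encode()))


def generate_fixture(n_founders: int = 5, n_events: int = 20,
                     p_cross: float = 0.5, p_mta: float = 0.2,
                     seed: int = 0, path: str = ":memory:",
                     max_samples: int = 2) -> SeedDatabase:
    """Create a deterministic synthetic laboratory database.

    ``n_founders`` de-novo lines (each with 0–2 random genetic features of
    both categories, MTA-protected with probability ``p_mta``) are followed
    by ``n_events`` pedigree events: a cross between two same-species lines
    with probability ``p_cross``, else a secondary mutagenesis of a random
    line.  Plants and seed batches with random generation labels, genotypes
    and segregation notes are attached throughout.  The same seed always
    yields byte-identical database content.
    """
    if n_founders < 1:
        raise ValidationError("n_founders must be >= 1")
    if n_events < 0:
        raise ValidationError("n_events must be >= 0")
    for name, p in (("p_cross", p_cross), ("p_mta", p_mta)):
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"{name} must be within [0, 1]")
    rng = random.Random(seed)
    db = SeedDatabase(path, login="admin")
    seed_vocabularies(db)
    db.create_user("writer", Role.WRITER)

    lines = []
    for i in range(n_founders):
        sp = rng.choice(sorted(SPECIES))
        line = registry.create_line(
            db, f"L{i + 1:03d}", rng.choice(PERSONS), sp,
            ecotype=rng.choice(SPECIES[sp]),
            origin=rng.choice(["lab stock", "NASC", "donated"]),
            mta=(MtaInfo(True, f"MTA-details-{rng.randint(1000, 9999)}"
                               f" recipient institute {rng.choice('ABC')}")
                 if rng.random() < p_mta else MtaInfo()))
        for k in range(rng.randint(0, 2)):
            registry.add_feature(db, line, _random_feature(rng, f"f{i + 1}{k}"))
        _populate_samples(db, rng, line, max_samples)
        lines.append(line)

    for j in range(n_events):
        do_cross = rng.random() < p_cross
        child = None
        if do_cross:
            by_species: dict[str, list] = {}
            for l in lines:
                by_species.setdefault(l.species, []).append(l)
            pools = [v for v in by_species.values() if len(v) >= 2]
            if pools:
                pool = rng.choice(sorted(pools, key=lambda v: v[0].species))
                female, male = rng.sample(pool, 2)
                batches = registry.list_seed_batches(db, female)
                fb = rng.choice(batches) if batches and rng.random() < 0.5 \
                    else None
                child = lineage.cross(db, female, male, f"X{j + 1:03d}",
                                      female_batch=fb)
        if child is None:
            parent = rng.choice(lines)
            child = lineage.mutagenize(
                db, parent, _random_feature(rng, f"m{j + 1}"),
                f"M{j + 1:03d}")
        _populate_samples(db, rng, child, max_samples)
        lines.append(child)
    return db


def sensitive_strings(db: SeedDatabase) -> set[str]:
    """Every redaction-class value present in the database.

    Person names, notebook references, storage places and MTA details — the
    values an interchange export must never contain.
    """
    out: set[str] = set()
    for e in vocab.list_entries(db, VocabCategory.PERSON,
                                include_inactive=True):
        out.add(e.value)
    for row in db.execute("SELECT mta_details FROM lines"):
        out.add(row["mta_details"])
    for row in db.execute("SELECT notebook_ref FROM plants"):
        out.add(row["notebook_ref"])
    for row in db.execute(
            "SELECT notebook_ref, storage_place FROM seed_batches"):
        out.add(row["notebook_ref"])
        out.add(row["storage_place"])
    out.discard("")
    return out
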