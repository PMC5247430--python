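"""Plant-line record store: the five-part datasheet as a data model.

A *plant line* groups all selfed/backcrossed material sharing one genetic
context (species, ecotype, set of genetic features).  Its datasheet holds
general information, the genetic-feature table, the genealogy tree, and the
plant and seed-batch tables.  Mandatory fields are deliberately minimal —
``{name, person, species}`` for a line, ``{designation}`` for a feature,
``{personal_identifier}`` for plants and batches — so records can be
completed later without guesswork.

Seed batches receive a system-wide unique ID that is strictly increasing and
never reused, even after deletion; two batches may share a personal
identifier yet remain unambiguous through this ID.
"""

from __future__ import annotations

import csv
import io
from typing import Iterable, Mapping

from . import vocab
from .db import SeedDatabase
from .errors import (CategoryError, ConsistencyError, ImmutableFeatureError,
                     LockedError, NotFoundError, ValidationError)
from .models import (Attachment, CreationMode, FeatureCategory, FeatureSpec,
                     GenotypeState, GeneticFeature, InsertionSite, MtaInfo,
                     ParentLink, ParentRole, Plant, PlantLine, Role, SeedBatch,
                     Segregation, VocabCategory)

MANDATORY_LINE_FIELDS = ("name", "person", "species")
MANDATORY_FEATURE_FIELDS = ("designation",)
MANDATORY_SAMPLE_FIELDS = ("personal_identifier",)


# ---------------------------------------------------------------------------
# hydration helpers

def _vocab_value(db: SeedDatabase, entry_id: int | None) -> str | None:
    if entry_id is None:
        return None
    row = db.execute("SELECT value FROM vocab WHERE id = ?", (entry_id,)).fetchone()
    return row["value"] if row else None


def _line_from_row(db: SeedDatabase, row) -> PlantLine:
    parents = tuple(
        ParentLink(parent_id=r["parent_id"], role=ParentRole(r["role"]),
                   batch_id=r["batch_id"])
        for r in db.execute(
            "SELECT parent_id, role, batch_id FROM line_parents"
            " WHERE child_id = ? ORDER BY role", (row["id"],)))
    return PlantLine(
        line_id=row["id"], name=row["name"],
        person=_vocab_value(db, row["person_id"]),
        species=_vocab_value(db, row["species_id"]),
        ecotype_label=row["ecotype_label"], origin=row["origin"],
        creation_mode=CreationMode(row["creation_mode"]),
        mta=MtaInfo(bool(row["mta_protected"]), row["mta_details"]),
        parents=parents, locked=bool(row["locked"]))


def get_line(db: SeedDatabase, line_id: int) -> PlantLine:
    row = db.execute("SELECT * FROM lines WHERE id = ?", (line_id,)).fetchone()
    if row is None:
        raise NotFoundError(f"no plant line with id {line_id}")
    return _line_from_row(db, row)


def get_line_by_name(db: SeedDatabase, name: str) -> PlantLine:
    rows = db.execute("SELECT * FROM lines WHERE name = ? COLLATE NOCASE",
                      (name,)).fetchall()
    if not rows:
        raise NotFoundError(f"no plant line named {name!r}")
    if len(rows) > 1:
        ids = ", ".join(str(r["id"]) for r in rows)
        raise ValidationError(
            f"line name {name!r} is ambiguous (ids {ids}); address by id")
    return _line_from_row(db, rows[0])


def list_lines(db: SeedDatabase) -> list[PlantLine]:
    return [_line_from_row(db, r)
            for r in db.execute("SELECT * FROM lines ORDER BY name, id")]


def _feature_from_row(db: SeedDatabase, row) -> GeneticFeature:
    return GeneticFeature(
        feature_id=row["id"], origin_line_id=row["origin_line"],
        designation=row["designation"],
        category=FeatureCategory(row["category"]), gene=row["gene"],
        mutation_method=_vocab_value(db, row["mutation_method"]),
        method_reference=_vocab_value(db, row["method_reference"]),
        sequence=row["sequence"],
        selectable_resistance=_vocab_value(db, row["resistance"]),
        agro_strain=_vocab_value(db, row["agro_strain"]),
        genotyping_protocol=row["genotyping_protocol"],
        provenance=row["provenance"])


def get_feature(db: SeedDatabase, feature_id: int) -> GeneticFeature:
    row = db.execute("SELECT * FROM features WHERE id = ?",
                     (feature_id,)).fetchone()
    if row is None:
        raise NotFoundError(f"no genetic feature with id {feature_id}")
    return _feature_from_row(db, row)


def owned_features(db: SeedDatabase, line: PlantLine | int) -> list[GeneticFeature]:
    """Features created on this line itself (excludes inherited ones)."""
    line_id = line if isinstance(line, int) else line.line_id
    return [_feature_from_row(db, r) for r in db.execute(
        "SELECT * FROM features WHERE origin_line = ? ORDER BY id", (line_id,))]


def _plant_from_row(db: SeedDatabase, row) -> Plant:
    genos = {r["feature_id"]: GenotypeState(r["state"]) for r in db.execute(
        "SELECT feature_id, state FROM plant_genotypes WHERE plant_id = ?",
        (row["id"],))}
    sites: dict[int, tuple[InsertionSite, ...]] = {}
    for r in db.execute(
            "SELECT feature_id, location, flanking_sequence FROM insertion_sites"
            " WHERE plant_id = ? ORDER BY feature_id, position", (row["id"],)):
        sites.setdefault(r["feature_id"], ())
        sites[r["feature_id"]] += (InsertionSite(r["location"],
                                                 r["flanking_sequence"]),)
    return Plant(
        plant_id=row["id"], line_id=row["line_id"],
        personal_identifier=row["personal_identifier"],
        generation_label=row["generation_label"], genotypes=genos,
        insertion_sites=sites, phenotype_note=row["phenotype_note"],
        notebook_ref=row["notebook_ref"],
        person=_vocab_value(db, row["person_id"]), locked=bool(row["locked"]))


def get_plant(db: SeedDatabase, plant_id: int) -> Plant:
    row = db.execute("SELECT * FROM plants WHERE id = ?", (plant_id,)).fetchone()
    if row is None:
        raise NotFoundError(f"no plant with id {plant_id}")
    return _plant_from_row(db, row)


def list_plants(db: SeedDatabase, line: PlantLine | int) -> list[Plant]:
    line_id = line if isinstance(line, int) else line.line_id
    return [_plant_from_row(db, r) for r in db.execute(
        "SELECT * FROM plants WHERE line_id = ? ORDER BY id", (line_id,))]


def _batch_from_row(db: SeedDatabase, row) -> SeedBatch:
    seg = {r["feature_id"]: Segregation(r["observed_counts"], r["note"])
           for r in db.execute(
               "SELECT feature_id, observed_counts, note FROM segregation"
               " WHERE batch_id = ?", (row["system_id"],))}
    return SeedBatch(
        system_id=row["system_id"], line_id=row["line_id"],
        personal_identifier=row["personal_identifier"],
        generation_label=row["generation_label"],
        mother_plant_id=row["mother_plant"], segregation=seg,
        harvest_date=row["harvest_date"], storage_place=row["storage_place"],
        germination_result=row["germination_result"],
        phenotype_note=row["phenotype_note"], notebook_ref=row["notebook_ref"],
        person=_vocab_value(db, row["person_id"]), locked=bool(row["locked"]))


def get_seed_batch(db: SeedDatabase, system_id: int) -> SeedBatch:
    row = db.execute("SELECT * FROM seed_batches WHERE system_id = ?",
                     (system_id,)).fetchone()
    if row is None:
        raise NotFoundError(f"no seed batch with system id {system_id}")
    return _batch_from_row(db, row)


def list_seed_batches(db: SeedDatabase, line: PlantLine | int) -> list[SeedBatch]:
    line_id = line if isinstance(line, int) else line.line_id
    return [_batch_from_row(db, r) for r in db.execute(
        "SELECT * FROM seed_batches WHERE line_id = ? ORDER BY system_id",
        (line_id,))]


# ---------------------------------------------------------------------------
# line creation and editing

def create_line(db: SeedDatabase, name: str | None = None,
                person: str | None = None, species: str | None = None, *,
                ecotype: str | None = None, origin: str = "",
                mta: MtaInfo | None = None,
                creation_mode: CreationMode = CreationMode.NEW) -> PlantLine:
    """Record a plant line de novo.

    Only name, responsible person and species are required; a line with no
    genetic features is wild type.  ``ecotype`` must name a registered
    ecotype of the species when given.
    """
    db.require(Role.WRITER)
    missing = [f for f, v in
               zip(MANDATORY_LINE_FIELDS, (name, person, species))
               if not v or not str(v).strip()]
    if missing:
        raise ValidationError(
            "missing mandatory field(s): " + ", ".join(missing),
            missing=tuple(missing))
    person_id = vocab.resolve_id(db, VocabCategory.PERSON, person)
    species_id = vocab.resolve_id(db, VocabCategory.SPECIES, species)
    ecotype_id = None
    ecotype_label = ""
    if ecotype is not None:
        ecotype_id = vocab.get_entry(db, VocabCategory.ECOTYPE, ecotype,
                                     species=species).entry_id
        ecotype_label = ecotype
    mta = mta or MtaInfo()
    if mta.details and not mta.protected:
        raise ValidationError("MTA details require the protected flag")
    cur = db.execute(
        "INSERT INTO lines (name, person_id, species_id, ecotype_id,"
        " ecotype_label, origin, creation_mode, mta_protected, mta_details)"
        " VALUES (?,?,?,?,?,?,?,?,?)",
        (name, person_id, species_id, ecotype_id, ecotype_label, origin,
         creation_mode.value, int(mta.protected), mta.details))
    db.commit()
    db.audit("create_line", name=name, mode=creation_mode.value)
    return get_line(db, cur.lastrowid)


def _check_unlocked(record: PlantLine | Plant | SeedBatch) -> None:
    if record.locked:
        raise LockedError("record is locked; unlock it before editing")


_INHERITING_MODES = (CreationMode.CROSS, CreationMode.MUTAG)


def edit_line(db: SeedDatabase, line: PlantLine, *, name: str | None = None,
              person: str | None = None, ecotype: str | None = None,
              origin: str | None = None, mta: MtaInfo | None = None) -> PlantLine:
    """Edit the general-information fields of a line.

    Species is never editable; ecotype is inherited (hence immutable) on
    CROSS/MUTAG lines regardless of the lock state.
    """
    db.require(Role.WRITER)
    _check_unlocked(line)
    sets: list[str] = []
    params: list = []
    if name is not None:
        if not name.strip():
            raise ValidationError("missing mandatory field(s): name",
                                  missing=("name",))
        sets.append("name = ?"); params.append(name)
    if person is not None:
        sets.append("person_id = ?")
        params.append(vocab.resolve_id(db, VocabCategory.PERSON, person))
    if ecotype is not None:
        if line.creation_mode in _INHERITING_MODES:
            raise ImmutableFeatureError(
                "ecotype is inherited from the parental line(s) and cannot be"
                " edited on the descendant")
        eid = vocab.get_entry(db, VocabCategory.ECOTYPE, ecotype,
                              species=line.species).entry_id
        sets += ["ecotype_id = ?", "ecotype_label = ?"]
        params += [eid, ecotype]
    if origin is not None:
        sets.append("origin = ?"); params.append(origin)
    if mta is not None:
        if mta.details and not mta.protected:
            raise ValidationError("MTA details require the protected flag")
        sets += ["mta_protected = ?", "mta_details = ?"]
        params += [int(mta.protected), mta.details]
    if sets:
        db.execute(f"UPDATE lines SET {', '.join(sets)} WHERE id = ?",
                   (*params, line.line_id))
        db.commit()
        db.audit("edit_line", line=line.line_id)
    return get_line(db, line.line_id)


def rename_line(db: SeedDatabase, line: PlantLine, new_name: str) -> PlantLine:
    return edit_line(db, line, name=new_name)


def delete_line(db: SeedDatabase, line: PlantLine) -> None:
    """Delete a line; refused while descendants or seed batches exist."""
    db.require(Role.WRITER)
    kids = db.execute("SELECT COUNT(*) AS n FROM line_parents WHERE parent_id = ?",
                      (line.line_id,)).fetchone()["n"]
    if kids:
        raise ConsistencyError(
            f"line {line.name!r} has {kids} descendant link(s); deletion would"
            " break the pedigree")
    batches = db.execute("SELECT COUNT(*) AS n FROM seed_batches WHERE line_id = ?",
                         (line.line_id,)).fetchone()["n"]
    if batches:
        raise ConsistencyError(
            f"line {line.name!r} still has {batches} seed batch(es)")
    for p in list_plants(db, line):
        db.execute("DELETE FROM plants WHERE id = ?", (p.plant_id,))
    db.execute("DELETE FROM attachments WHERE owner_kind='line' AND owner_id=?",
               (line.line_id,))
    db.execute("DELETE FROM features WHERE origin_line = ?", (line.line_id,))
    db.execute("DELETE FROM line_parents WHERE child_id = ?", (line.line_id,))
    db.execute("DELETE FROM lines WHERE id = ?", (line.line_id,))
    db.commit()
    db.audit("delete_line", line=line.line_id)


# ---------------------------------------------------------------------------
# genetic features

def _resolve_method(db: SeedDatabase, method: str | None,
                    category: FeatureCategory) -> int | None:
    if method is None:
        return None
    entry = vocab.get_entry(db, VocabCategory.MUTATION_METHOD, method)
    if entry.feature_category is not category:
        raise CategoryError(
            f"mutation method {method!r} is registered for "
            f"{entry.feature_category.value} features, not {category.value}")
    return entry.entry_id


def add_feature(db: SeedDatabase, line: PlantLine, spec: FeatureSpec, *,
                provenance: str = "") -> GeneticFeature:
    """Add an owned genetic feature (a transgenesis or an endogenous edit).

    Only the designation is mandatory.  The mutation method, when given, must
    be registered for the feature's category; selectable resistance and
    Agrobacterium strain apply to TRANSGENESIS features only.
    """
    db.require(Role.WRITER)
    _check_unlocked(line)
    if not spec.designation or not spec.designation.strip():
        raise ValidationError("missing mandatory field(s): designation",
                              missing=("designation",))
    if spec.category is not FeatureCategory.TRANSGENESIS and (
            spec.selectable_resistance or spec.agro_strain):
        raise CategoryError(
            "selectable resistance and Agrobacterium strain apply to"
            " TRANSGENESIS features only")
    dup = db.execute(
        "SELECT 1 FROM features WHERE origin_line = ? AND designation = ?",
        (line.line_id, spec.designation)).fetchone()
    if dup:
        # allowed, but worth flagging: two features of one line sharing a name
        import warnings
        warnings.warn(
            f"line {line.name!r} already has a feature designated"
            f" {spec.designation!r}", stacklevel=2)
    method_id = _resolve_method(db, spec.mutation_method, spec.category)
    ref_id = (vocab.resolve_id(db, VocabCategory.METHOD_REFERENCE,
                               spec.method_reference)
              if spec.method_reference else None)
    res_id = (vocab.resolve_id(db, VocabCategory.RESISTANCE,
                               spec.selectable_resistance)
              if spec.selectable_resistance else None)
    strain_id = (vocab.resolve_id(db, VocabCategory.STRAIN, spec.agro_strain)
                 if spec.agro_strain else None)
    cur = db.execute(
        "INSERT INTO features (origin_line, designation, category, gene,"
        " mutation_method, method_reference, sequence, resistance, agro_strain,"
        " genotyping_protocol, provenance) VALUES (?,?,?,?,?,?,?,?,?,?,?)",
        (line.line_id, spec.designation, spec.category.value, spec.gene,
         method_id, ref_id, spec.sequence, res_id, strain_id,
         spec.genotyping_protocol, provenance))
    db.commit()
    db.audit("add_feature", line=line.line_id, designation=spec.designation)
    return get_feature(db, cur.lastrowid)


def edit_feature(db: SeedDatabase, line: PlantLine, feature: GeneticFeature,
                 **changes) -> GeneticFeature:
    """Edit a feature *via its origin line*.

    Inherited features are read-only through descendants: any modification
    must be entered on the parental line, and all descendants observe it
    because features are stored once and referenced.
    """
    db.require(Role.WRITER)
    if feature.origin_line_id != line.line_id:
        origin = get_line(db, feature.origin_line_id)
        raise ImmutableFeatureError(
            f"feature {feature.designation!r} is inherited from"
            f" {origin.name!r}; edit it there")
    _check_unlocked(line)
    allowed = {"designation", "gene", "sequence", "genotyping_protocol",
               "mutation_method", "method_reference", "selectable_resistance",
               "agro_strain"}
    bad = set(changes) - allowed
    if bad:
        raise ValidationError(f"unknown feature field(s): {', '.join(sorted(bad))}")
    sets: list[str] = []
    params: list = []
    if "designation" in changes:
        if not changes["designation"] or not changes["designation"].strip():
            raise ValidationError("missing mandatory field(s): designation",
                                  missing=("designation",))
        sets.append("designation = ?"); params.append(changes["designation"])
    for key, col in (("gene", "gene"), ("sequence", "sequence"),
                     ("genotyping_protocol", "genotyping_protocol")):
        if key in changes:
            sets.append(f"{col} = ?"); params.append(changes[key])
    if "mutation_method" in changes:
        sets.append("mutation_method = ?")
        params.append(_resolve_method(db, changes["mutation_method"],
                                      feature.category))
    if "method_reference" in changes:
        sets.append("method_reference = ?")
        params.append(vocab.resolve_id(db, VocabCategory.METHOD_REFERENCE,
                                       changes["method_reference"])
                      if changes["method_reference"] else None)
    if "selectable_resistance" in changes or "agro_strain" in changes:
        if feature.category is not FeatureCategory.TRANSGENESIS:
            raise CategoryError(
                "selectable resistance and Agrobacterium strain apply to"
                " TRANSGENESIS features only")
        if "selectable_resistance" in changes:
            sets.append("resistance = ?")
            params.append(vocab.resolve_id(db, VocabCategory.RESISTANCE,
                                           changes["selectable_resistance"])
                          if changes["selectable_resistance"] else None)
        if "agro_strain" in changes:
            sets.append("agro_strain = ?")
            params.append(vocab.resolve_id(db, VocabCategory.STRAIN,
                                           changes["agro_strain"])
                          if changes["agro_strain"] else None)
    if sets:
        db.execute(f"UPDATE features SET {', '.join(sets)} WHERE id = ?",
                   (*params, feature.feature_id))
        db.commit()
        db.audit("edit_feature", feature=feature.feature_id)
    return get_feature(db, feature.feature_id)


# ---------------------------------------------------------------------------
# plants and seed batches

def _effective_ids(db: SeedDatabase, line_id: int) -> set[int]:
    from . import lineage  # deferred: lineage builds on this module
    return {f.feature_id for f in lineage.effective_features(db, line_id)}


def _validate_keys(db: SeedDatabase, line_id: int,
                   keys: Iterable[int], what: str) -> None:
    eff = _effective_ids(db, line_id)
    foreign = [k for k in keys if k not in eff]
    if foreign:
        raise ConsistencyError(
            f"{what} keyed by feature(s) {foreign} not in the line's feature set")


def add_plant(db: SeedDatabase, line: PlantLine, personal_identifier: str, *,
              generation_label: str = "",
              genotypes: Mapping[int, GenotypeState] | None = None,
              phenotype_note: str = "", notebook_ref: str = "",
              person: str | None = None) -> Plant:
    """Record an individual plant under a line (identifier is mandatory)."""
    db.require(Role.WRITER)
    if not personal_identifier or not personal_identifier.strip():
        raise ValidationError(
            "missing mandatory field(s): personal_identifier",
            missing=("personal_identifier",))
    genotypes = dict(genotypes or {})
    _validate_keys(db, line.line_id, genotypes, "genotype")
    person_id = (vocab.resolve_id(db, VocabCategory.PERSON, person)
                 if person else None)
    cur = db.execute(
        "INSERT INTO plants (line_id, personal_identifier, generation_label,"
        " phenotype_note, notebook_ref, person_id) VALUES (?,?,?,?,?,?)",
        (line.line_id, personal_identifier, generation_label, phenotype_note,
         notebook_ref, person_id))
    plant_id = cur.lastrowid
    for fid, state in genotypes.items():
        db.execute("INSERT INTO plant_genotypes (plant_id, feature_id, state)"
                   " VALUES (?,?,?)", (plant_id, fid, state.value))
    db.commit()
    db.audit("add_plant", line=line.line_id, identifier=personal_identifier)
    return get_plant(db, plant_id)


def add_seed_batch(db: SeedDatabase, line: PlantLine,
                   personal_identifier: str, *, generation_label: str = "",
                   mother_plant: Plant | int | None = None,
                   segregation: Mapping[int, Segregation] | None = None,
                   harvest_date: str = "", storage_place: str = "",
                   germination_result: str = "", phenotype_note: str = "",
                   notebook_ref: str = "",
                   person: str | None = None) -> SeedBatch:
    """Record a seed batch; a fresh, never-reused system ID is allocated."""
    db.require(Role.WRITER)
    if not personal_identifier or not personal_identifier.strip():
        raise ValidationError(
            "missing mandatory field(s): personal_identifier",
            missing=("personal_identifier",))
    segregation = dict(segregation or {})
    _validate_keys(db, line.line_id, segregation, "segregation")
    mother_id = None
    if mother_plant is not None:
        mother = (mother_plant if isinstance(mother_plant, Plant)
                  else get_plant(db, mother_plant))
        mother_id = mother.plant_id
    person_id = (vocab.resolve_id(db, VocabCategory.PERSON, person)
                 if person else None)
    cur = db.execute(
        "INSERT INTO seed_batches (line_id, personal_identifier,"
        " generation_label, mother_plant, harvest_date, storage_place,"
        " germination_result, phenotype_note, notebook_ref, person_id)"
        " VALUES (?,?,?,?,?,?,?,?,?,?)",
        (line.line_id, personal_identifier, generation_label, mother_id,
         harvest_date, storage_place, germination_result, phenotype_note,
         notebook_ref, person_id))
    batch_id = cur.lastrowid
    for fid, seg in segregation.items():
        db.execute(
            "INSERT INTO segregation (batch_id, feature_id, observed_counts,"
            " note) VALUES (?,?,?,?)",
            (batch_id, fid, seg.observed_counts, seg.note))
    db.commit()
    db.audit("add_seed_batch", line=line.line_id, system_id=batch_id)
    return get_seed_batch(db, batch_id)


def delete_seed_batch(db: SeedDatabase, batch: SeedBatch | int) -> None:
    """Delete a batch; its system ID is retired forever."""
    db.require(Role.WRITER)
    system_id = batch if isinstance(batch, int) else batch.system_id
    if not db.execute("SELECT 1 FROM seed_batches WHERE system_id = ?",
                      (system_id,)).fetchone():
        raise NotFoundError(f"no seed batch with system id {system_id}")
    db.execute("DELETE FROM attachments WHERE owner_kind='batch' AND owner_id=?",
               (system_id,))
    db.execute("DELETE FROM seed_batches WHERE system_id = ?", (system_id,))
    db.commit()
    db.audit("delete_seed_batch", system_id=system_id)


def delete_plant(db: SeedDatabase, plant: Plant | int) -> None:
    db.require(Role.WRITER)
    plant_id = plant if isinstance(plant, int) else plant.plant_id
    if not db.execute("SELECT 1 FROM plants WHERE id = ?",
                      (plant_id,)).fetchone():
        raise NotFoundError(f"no plant with id {plant_id}")
    ref = db.execute("SELECT COUNT(*) AS n FROM seed_batches WHERE mother_plant = ?",
                     (plant_id,)).fetchone()["n"]
    if ref:
        raise ConsistencyError(
            f"plant {plant_id} is the mother of {ref} seed batch(es)")
    db.execute("DELETE FROM attachments WHERE owner_kind='plant' AND owner_id=?",
               (plant_id,))
    db.execute("DELETE FROM plants WHERE id = ?", (plant_id,))
    db.commit()
    db.audit("delete_plant", plant=plant_id)


def copy_plant(db: SeedDatabase, plant: Plant | int,
               target_line: PlantLine | None = None) -> Plant:
    """Duplicate a plant's user fields as an independent record (same line)."""
    db.require(Role.WRITER)
    src = plant if isinstance(plant, Plant) else get_plant(db, plant)
    if target_line is not None and target_line.line_id != src.line_id:
        raise ConsistencyError("a copied plant stays in its own line")
    line = get_line(db, src.line_id)
    new = add_plant(db, line, src.personal_identifier,
                    generation_label=src.generation_label,
                    genotypes=src.genotypes,
                    phenotype_note=src.phenotype_note,
                    notebook_ref=src.notebook_ref, person=src.person)
    for fid, sites in src.insertion_sites.items():
        set_insertion_sites(db, new, get_feature(db, fid), list(sites))
    _copy_attachments(db, "plant", src.plant_id, new.plant_id)
    return get_plant(db, new.plant_id)


def copy_seed_batch(db: SeedDatabase, batch: SeedBatch | int,
                    target_line: PlantLine | None = None) -> SeedBatch:
    """Duplicate a batch's user fields; a fresh system ID is allocated."""
    db.require(Role.WRITER)
    src = batch if isinstance(batch, SeedBatch) else get_seed_batch(db, batch)
    if target_line is not None and target_line.line_id != src.line_id:
        raise ConsistencyError("a copied seed batch stays in its own line")
    line = get_line(db, src.line_id)
    new = add_seed_batch(db, line, src.personal_identifier,
                         generation_label=src.generation_label,
                         mother_plant=src.mother_plant_id,
                         segregation=src.segregation,
                         harvest_date=src.harvest_date,
                         storage_place=src.storage_place,
                         germination_result=src.germination_result,
                         phenotype_note=src.phenotype_note,
                         notebook_ref=src.notebook_ref, person=src.person)
    _copy_attachments(db, "batch", src.system_id, new.system_id)
    return get_seed_batch(db, new.system_id)


def set_genotype(db: SeedDatabase, plant: Plant, feature: GeneticFeature,
                 state: GenotypeState) -> None:
    db.require(Role.WRITER)
    _check_unlocked(plant)
    _validate_keys(db, plant.line_id, [feature.feature_id], "genotype")
    db.execute(
        "INSERT INTO plant_genotypes (plant_id, feature_id, state)"
        " VALUES (?,?,?) ON CONFLICT(plant_id, feature_id)"
        " DO UPDATE SET state = excluded.state",
        (plant.plant_id, feature.feature_id, state.value))
    db.commit()


def set_segregation(db: SeedDatabase, batch: SeedBatch,
                    feature: GeneticFeature, seg: Segregation) -> None:
    db.require(Role.WRITER)
    _check_unlocked(batch)
    _validate_keys(db, batch.line_id, [feature.feature_id], "segregation")
    db.execute(
        "INSERT INTO segregation (batch_id, feature_id, observed_counts, note)"
        " VALUES (?,?,?,?) ON CONFLICT(batch_id, feature_id) DO UPDATE SET"
        " observed_counts = excluded.observed_counts, note = excluded.note",
        (batch.system_id, feature.feature_id, seg.observed_counts, seg.note))
    db.commit()


def set_insertion_sites(db: SeedDatabase, plant: Plant,
                        feature: GeneticFeature,
                        sites: list[InsertionSite]) -> None:
    """Store per-plant genomic insertion sites of a transgene.

    Distinct plants of one line may carry different sites, so independent
    transformants can live in a single datasheet.  An empty list clears the
    stored sites.  Only TRANSGENESIS features carry insertion sites.
    """
    db.require(Role.WRITER)
    _check_unlocked(plant)
    if feature.category is not FeatureCategory.TRANSGENESIS:
        raise CategoryError(
            "insertion sites can only be recorded for plants resulting from"
            " transgenesis (TRANSGENESIS features)")
    _validate_keys(db, plant.line_id, [feature.feature_id], "insertion site")
    db.execute("DELETE FROM insertion_sites WHERE plant_id = ? AND feature_id = ?",
               (plant.plant_id, feature.feature_id))
    for pos, site in enumerate(sites):
        db.execute(
            "INSERT INTO insertion_sites (plant_id, feature_id, position,"
            " location, flanking_sequence) VALUES (?,?,?,?,?)",
            (plant.plant_id, feature.feature_id, pos, site.location,
             site.flanking_sequence))
    db.commit()
    db.audit("set_insertion_sites", plant=plant.plant_id,
             feature=feature.feature_id, n=len(sites))


def edit_plant(db: SeedDatabase, plant: Plant, **changes) -> Plant:
    db.require(Role.WRITER)
    _check_unlocked(plant)
    allowed = {"personal_identifier": "personal_identifier",
               "generation_label": "generation_label",
               "phenotype_note": "phenotype_note",
               "notebook_ref": "notebook_ref"}
    return _edit_sample(db, "plants", "id", plant.plant_id, allowed, changes,
                        get_plant)


def edit_seed_batch(db: SeedDatabase, batch: SeedBatch, **changes) -> SeedBatch:
    db.require(Role.WRITER)
    _check_unlocked(batch)
    allowed = {"personal_identifier": "personal_identifier",
               "generation_label": "generation_label",
               "harvest_date": "harvest_date",
               "storage_place": "storage_place",
               "germination_result": "germination_result",
               "phenotype_note": "phenotype_note",
               "notebook_ref": "notebook_ref"}
    return _edit_sample(db, "seed_batches", "system_id", batch.system_id,
                        allowed, changes, get_seed_batch)


def _edit_sample(db, table, pk, key, allowed, changes, getter):
    bad = set(changes) - set(allowed)
    if bad:
        raise ValidationError(f"unknown field(s): {', '.join(sorted(bad))}")
    if "personal_identifier" in changes and not str(
            changes["personal_identifier"]).strip():
        raise ValidationError(
            "missing mandatory field(s): personal_identifier",
            missing=("personal_identifier",))
    sets = [f"{allowed[k]} = ?" for k in changes]
    if sets:
        db.execute(f"UPDATE {table} SET {', '.join(sets)} WHERE {pk} = ?",
                   (*changes.values(), key))
        db.commit()
    return getter(db, key)


# ---------------------------------------------------------------------------
# locking and attachments

def set_locked(db: SeedDatabase, record: PlantLine | Plant | SeedBatch,
               locked: bool) -> None:
    """Lock (freeze) or unlock a line, plant or seed batch.

    Unlocking never re-enables editing of inherited fields — those stay
    immutable through descendants regardless of lock state.
    """
    db.require(Role.WRITER)
    table, pk, key = _locate(record)
    db.execute(f"UPDATE {table} SET locked = ? WHERE {pk} = ?",
               (int(locked), key))
    db.commit()
    db.audit("set_locked", table=table, id=key, locked=locked)


def _locate(record) -> tuple[str, str, int]:
    if isinstance(record, PlantLine):
        return "lines", "id", record.line_id
    if isinstance(record, Plant):
        return "plants", "id", record.plant_id
    if isinstance(record, SeedBatch):
        return "seed_batches", "system_id", record.system_id
    raise ValidationError(f"cannot lock a {type(record).__name__}")


_OWNER_KIND = {PlantLine: "line", GeneticFeature: "feature", Plant: "plant",
               SeedBatch: "batch"}


def add_attachment(db: SeedDatabase, record, attachment: Attachment) -> None:
    db.require(Role.WRITER)
    kind = _OWNER_KIND.get(type(record))
    if kind is None:
        raise ValidationError(f"cannot attach files to a {type(record).__name__}")
    owner_id = {"line": "line_id", "feature": "feature_id", "plant": "plant_id",
                "batch": "system_id"}[kind]
    db.execute(
        "INSERT INTO attachments (owner_kind, owner_id, slot, filename,"
        " media_type, content) VALUES (?,?,?,?,?,?)",
        (kind, getattr(record, owner_id), attachment.slot,
         attachment.filename, attachment.media_type, attachment.content))
    db.commit()


def list_attachments(db: SeedDatabase, record) -> list[Attachment]:
    kind = _OWNER_KIND.get(type(record))
    owner_id = {"line": "line_id", "feature": "feature_id", "plant": "plant_id",
                "batch": "system_id"}[kind]
    return [Attachment(r["filename"], r["media_type"], r["content"], r["slot"])
            for r in db.execute(
                "SELECT * FROM attachments WHERE owner_kind = ? AND owner_id = ?"
                " ORDER BY id", (kind, getattr(record, owner_id)))]


def _copy_attachments(db: SeedDatabase, kind: str, src_id: int,
                      dst_id: int) -> None:
    for r in db.execute(
            "SELECT slot, filename, media_type, content FROM attachments"
            " WHERE owner_kind = ? AND owner_id = ? ORDER BY id",
            (kind, src_id)).fetchall():
        db.execute(
            "INSERT INTO attachments (owner_kind, owner_id, slot, filename,"
            " media_type, content) VALUES (?,?,?,?,?,?)",
            (kind, dst_id, r["slot"], r["filename"], r["media_type"],
             r["content"]))
    db.commit()


# ---------------------------------------------------------------------------
# tabular export

def table_csv(db: SeedDatabase, line: PlantLine, kind: str) -> str:
    """CSV export of a line's plant or seed-batch table (one row/record)."""
    buf = io.StringIO()
    if kind == "plants":
        w = csv.writer(buf)
        w.writerow(["plant_id", "personal_identifier", "generation",
                    "genotypes", "phenotype", "notebook", "person"])
        for p in list_plants(db, line):
            genos = "; ".join(
                f"{get_feature(db, fid).designation}={st.value}"
                for fid, st in sorted(p.genotypes.items()))
            w.writerow([p.plant_id, p.personal_identifier, p.generation_label,
                        genos, p.phenotype_note, p.notebook_ref, p.person or ""])
    elif kind == "batches":
        w = csv.writer(buf)
        w.writerow(["system_id", "personal_identifier", "generation",
                    "mother_plant", "harvest_date", "storage_place",
                    "germination", "phenotype", "notebook", "person"])
        for b in list_seed_batches(db, line):
            w.writerow([b.system_id, b.personal_identifier, b.generation_label,
                        b.mother_plant_id or "", b.harvest_date,
                        b.storage_place, b.germination_result,
                        b.phenotype_note, b.notebook_ref, b.person or ""])
    else:
        raise ValidationError("kind must be 'plants' or 'batches'")
    return buf.getvalue()
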