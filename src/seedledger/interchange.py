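"""JSON interchange: redacting export and link-severing import.

One exported document is a self-contained exchange unit for one plant line
(optionally with seed batches, their mother plants, and all attached files,
base64-embedded) that can be sent to a collaborating laboratory and imported
into their database.

Redaction: exported documents never carry personal names, notebook
references, storage places or MTA details — those fields simply do not
exist in the payload models.  The MTA *protected* flag is preserved, with
the details field left empty, so the receiving laboratory knows the
material is encumbered without learning the agreement's content.

Import severs all parental links: every feature becomes owned by the
imported line, with its ``from <line>`` provenance preserved as text, and
the genealogy survives only as the embedded tree image, stored as a
"file from source" attachment.
"""

from __future__ import annotations

import base64
import binascii
from dataclasses import dataclass
from typing import Literal

import pydantic

from . import lineage, registry, vocab
from .db import SeedDatabase
from .errors import (ConsistencyError, FormatError, NotFoundError,
                     ValidationError, VocabularyError)
from .models import (Attachment, CreationMode, FeatureCategory, FeatureSpec,
                     GenotypeState, InsertionSite, MtaInfo, PlantLine, Role,
                     SeedBatch, Segregation, VocabCategory)

FORMAT_VERSION = "1"

#: the sensitive field classes that exports must never contain
REDACTED_FIELDS = ("person", "notebook_ref", "storage_place", "mta_details")


class _Base(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")


class AttachmentPayload(_Base):
    filename: str
    media_type: str = "application/octet-stream"
    slot: str = ""
    content_b64: str

    @pydantic.field_validator("content_b64")
    @classmethod
    def _decodable(cls, v: str) -> str:
        try:
            base64.b64decode(v, validate=True)
        except (binascii.Error, ValueError) as exc:
            raise ValueError(f"invalid base64 content: {exc}") from exc
        return v

    def to_attachment(self) -> Attachment:
        return Attachment(self.filename, self.media_type,
                          base64.b64decode(self.content_b64), self.slot)

    @classmethod
    def from_attachment(cls, att: Attachment) -> "AttachmentPayload":
        return cls(filename=att.filename, media_type=att.media_type,
                   slot=att.slot,
                   content_b64=base64.b64encode(att.content).decode())


class FeaturePayload(_Base):
    designation: str
    category: Literal["TRANSGENESIS", "ENDOGENOUS"]
    gene: str = ""
    mutation_method: str | None = None
    method_reference: str | None = None
    sequence: str = ""
    selectable_resistance: str | None = None
    agro_strain: str | None = None
    genotyping_protocol: str = ""
    #: origin-line name retained as provenance text ("from <line>")
    provenance: str = ""
    attachments: list[AttachmentPayload] = []


class GenotypeEntry(_Base):
    feature: int  # index into the document's features list
    state: Literal["WT", "HETEROZYGOUS", "HOMOZYGOUS", "UNKNOWN"]


class SiteEntry(_Base):
    feature: int
    location: str = ""
    flanking_sequence: str = ""


class SegregationEntry(_Base):
    feature: int
    observed_counts: str = ""
    note: str = ""


class PlantPayload(_Base):
    personal_identifier: str
    generation_label: str = ""
    genotypes: list[GenotypeEntry] = []
    insertion_sites: list[SiteEntry] = []
    phenotype_note: str = ""
    attachments: list[AttachmentPayload] = []


class BatchPayload(_Base):
    #: the exporting database's system id — provenance only, never reused
    source_system_id: int
    personal_identifier: str
    generation_label: str = ""
    mother_plant: int | None = None  # index into mother_plants
    segregation: list[SegregationEntry] = []
    harvest_date: str = ""
    germination_result: str = ""
    phenotype_note: str = ""
    attachments: list[AttachmentPayload] = []


class LinePayload(_Base):
    name: str
    species: str
    ecotype: str = ""
    origin: str = ""
    mta_protected: bool = False
    #: always empty on export (confidentiality); present so the round trip
    #: shape matches the datasheet
    mta_details: str = ""
    files_from_source: list[AttachmentPayload] = []


class InterchangeDocument(_Base):
    format_version: Literal["1"]
    line: LinePayload
    features: list[FeaturePayload] = []
    seed_batches: list[BatchPayload] = []
    mother_plants: list[PlantPayload] = []
    tree_image: AttachmentPayload | None = None

    def to_json(self, indent: int = 2) -> str:
        return self.model_dump_json(indent=indent)


def json_schema() -> dict:
    """The published JSON schema of the interchange format."""
    return InterchangeDocument.model_json_schema()


def load_document(source: str | bytes | dict) -> InterchangeDocument:
    """Parse + validate a document; schema violations carry a JSON pointer."""
    try:
        if isinstance(source, dict):
            return InterchangeDocument.model_validate(source)
        return InterchangeDocument.model_validate_json(source)
    except pydantic.ValidationError as exc:
        first = exc.errors()[0]
        loc = "/" + "/".join(str(p) for p in first["loc"])
        raise FormatError(
            f"invalid interchange document at {loc}: {first['msg']}",
            location=loc) from exc


# ---------------------------------------------------------------------------
# export

def export_line(db: SeedDatabase, line: PlantLine,
                include_batches: list[SeedBatch | int] | None = None, *,
                include_tree: bool = True) -> InterchangeDocument:
    """Export one line (± seed batches) as a redacted interchange document.

    Inherited features are flattened to copies carrying ``from <origin>``
    provenance text.  Any plant referenced as the mother of an exported
    batch is exported too.  The genealogy is embedded as a rendered image.
    """
    feats = lineage.effective_features(db, line)
    index_of = {f.feature_id: i for i, f in enumerate(feats)}
    feat_payloads = []
    for f in feats:
        provenance = f.provenance
        if f.origin_line_id != line.line_id:
            origin = registry.get_line(db, f.origin_line_id)
            provenance = f"from {origin.name}"
        feat_payloads.append(FeaturePayload(
            designation=f.designation, category=f.category.value, gene=f.gene,
            mutation_method=f.mutation_method,
            method_reference=f.method_reference, sequence=f.sequence,
            selectable_resistance=f.selectable_resistance,
            agro_strain=f.agro_strain,
            genotyping_protocol=f.genotyping_protocol, provenance=provenance,
            attachments=[AttachmentPayload.from_attachment(a)
                         for a in registry.list_attachments(db, f)]))

    batches: list[SeedBatch] = []
    for b in include_batches or []:
        batch = b if isinstance(b, SeedBatch) else registry.get_seed_batch(db, b)
        if batch.line_id != line.line_id:
            raise ConsistencyError(
                f"seed batch {batch.system_id} does not belong to line"
                f" {line.name!r}")
        batches.append(batch)

    mother_ids = sorted({b.mother_plant_id for b in batches
                         if b.mother_plant_id is not None})
    mother_index = {pid: i for i, pid in enumerate(mother_ids)}
    mothers = []
    for pid in mother_ids:
        p = registry.get_plant(db, pid)
        mothers.append(PlantPayload(
            personal_identifier=p.personal_identifier,
            generation_label=p.generation_label,
            genotypes=[GenotypeEntry(feature=index_of[fid], state=st.value)
                       for fid, st in sorted(p.genotypes.items())
                       if fid in index_of],
            insertion_sites=[
                SiteEntry(feature=index_of[fid], location=s.location,
                          flanking_sequence=s.flanking_sequence)
                for fid, sites in sorted(p.insertion_sites.items())
                if fid in index_of for s in sites],
            phenotype_note=p.phenotype_note,
            attachments=[AttachmentPayload.from_attachment(a)
                         for a in registry.list_attachments(db, p)]))

    batch_payloads = [BatchPayload(
        source_system_id=b.system_id,
        personal_identifier=b.personal_identifier,
        generation_label=b.generation_label,
        mother_plant=(mother_index[b.mother_plant_id]
                      if b.mother_plant_id is not None else None),
        segregation=[SegregationEntry(feature=index_of[fid],
                                      observed_counts=s.observed_counts,
                                      note=s.note)
                     for fid, s in sorted(b.segregation.items())
                     if fid in index_of],
        harvest_date=b.harvest_date,
        germination_result=b.germination_result,
        phenotype_note=b.phenotype_note,
        attachments=[AttachmentPayload.from_attachment(a)
                     for a in registry.list_attachments(db, b)])
        for b in batches]

    tree_image = None
    if include_tree:
        tree_image = AttachmentPayload(
            filename=f"{line.name}-genealogy.png", media_type="image/png",
            slot="files_from_source",
            content_b64=base64.b64encode(
                lineage.render_png(db, line)).decode())

    doc = InterchangeDocument(
        format_version=FORMAT_VERSION,
        line=LinePayload(
            name=line.name, species=line.species,
            ecotype=line.ecotype_label, origin=line.origin,
            mta_protected=line.mta.protected, mta_details="",
            files_from_source=[AttachmentPayload.from_attachment(a)
                               for a in registry.list_attachments(db, line)]),
        features=feat_payloads, seed_batches=batch_payloads,
        mother_plants=mothers, tree_image=tree_image)
    db.audit("export_line", line=line.line_id, batches=len(batch_payloads))
    return doc


def export_lines_batch(db: SeedDatabase,
                       lines: list[PlantLine], *,
                       include_tree: bool = True) -> list[InterchangeDocument]:
    """Batch export (e.g. of a search result): one document per line.

    No seed batches can accompany the lines in this mode.
    """
    if not lines:
        raise ValidationError("batch export requires at least one line")
    return [export_line(db, line, None, include_tree=include_tree)
            for line in lines]


# ---------------------------------------------------------------------------
# import

@dataclass
class ImportResult:
    line: PlantLine
    warnings: list[str]


_MAPPABLE = {
    "species": VocabCategory.SPECIES,
    "mutation_method": VocabCategory.MUTATION_METHOD,
    "method_reference": VocabCategory.METHOD_REFERENCE,
    "resistance": VocabCategory.RESISTANCE,
    "strain": VocabCategory.STRAIN,
}


def _resolve_vocab(db: SeedDatabase, kind: str, value: str | None,
                   mappings: dict[str, str],
                   unknown: dict[str, list[str]]) -> str | None:
    if value is None:
        return None
    value = mappings.get(f"{kind}:{value}", value)
    try:
        vocab.get_entry(db, _MAPPABLE[kind], value)
        return value
    except NotFoundError:
        unknown.setdefault(kind, [])
        if value not in unknown[kind]:
            unknown[kind].append(value)
        return value


def import_line(db: SeedDatabase, document: InterchangeDocument | str | bytes | dict,
                new_name: str, person: str, *,
                mappings: dict[str, str] | None = None) -> ImportResult:
    """Create a line from an interchange document under a new name.

    Parental links are severed: the line has creation mode IMPORT and no
    parents, every feature becomes owned (provenance preserved as text), and
    the embedded tree image is stored as a "file from source" attachment.

    ``person`` names the registered PERSON taking responsibility for the
    record (exports carry no personal names).  An ecotype absent from the
    vocabulary is mapped to the species' "(Other)" sentinel with a warning;
    unknown species, mutation methods, method references, strains or
    resistances abort the import with an actionable report unless
    ``mappings`` (``{"<kind>:<unknown value>": "<existing value>"}``)
    substitutes known values.
    """
    db.require(Role.WRITER)
    if not new_name or not new_name.strip():
        raise ValidationError("missing mandatory field(s): new_name",
                              missing=("new_name",))
    doc = (document if isinstance(document, InterchangeDocument)
           else load_document(document))
    mappings = dict(mappings or {})
    warnings: list[str] = []
    unknown: dict[str, list[str]] = {}

    species = _resolve_vocab(db, "species", doc.line.species, mappings, unknown)
    for f in doc.features:
        _resolve_vocab(db, "mutation_method", f.mutation_method, mappings,
                       unknown)
        _resolve_vocab(db, "method_reference", f.method_reference, mappings,
                       unknown)
        _resolve_vocab(db, "resistance", f.selectable_resistance, mappings,
                       unknown)
        _resolve_vocab(db, "strain", f.agro_strain, mappings, unknown)
    if unknown:
        report = "; ".join(f"{k}: {', '.join(v)}"
                           for k, v in sorted(unknown.items()))
        raise VocabularyError(
            "the administrator must create the corresponding vocabulary"
            f" choices before import — unknown {report}", unknown=unknown)

    ecotype = None
    ecotype_warn = None
    if doc.line.ecotype:
        try:
            ecotype = vocab.get_entry(db, VocabCategory.ECOTYPE,
                                      doc.line.ecotype,
                                      species=species).value
        except NotFoundError:
            ecotype = vocab.other_ecotype(db, species).value
            ecotype_warn = (f"ecotype {doc.line.ecotype!r} is not in the"
                            f" vocabulary; recorded as {ecotype!r}")
            warnings.append(ecotype_warn)

    line = registry.create_line(
        db, new_name, person, species, ecotype=ecotype,
        origin=doc.line.origin,
        mta=MtaInfo(doc.line.mta_protected, ""),
        creation_mode=CreationMode.IMPORT)

    def mapped(kind: str, value: str | None) -> str | None:
        if value is None:
            return None
        return mappings.get(f"{kind}:{value}", value)

    new_features = []
    for f in doc.features:
        feat = registry.add_feature(db, line, FeatureSpec(
            designation=f.designation,
            category=FeatureCategory(f.category), gene=f.gene,
            mutation_method=mapped("mutation_method", f.mutation_method),
            method_reference=mapped("method_reference", f.method_reference),
            sequence=f.sequence,
            selectable_resistance=mapped("resistance",
                                         f.selectable_resistance),
            agro_strain=mapped("strain", f.agro_strain),
            genotyping_protocol=f.genotyping_protocol),
            provenance=f.provenance)
        for att in f.attachments:
            registry.add_attachment(db, feat, att.to_attachment())
        new_features.append(feat)

    for att in doc.line.files_from_source:
        registry.add_attachment(db, line, att.to_attachment())
    if doc.tree_image is not None:
        registry.add_attachment(db, line, doc.tree_image.to_attachment())

    mother_plants = []
    for p in doc.mother_plants:
        plant = registry.add_plant(
            db, line, p.personal_identifier,
            generation_label=p.generation_label,
            genotypes={new_features[g.feature].feature_id:
                       GenotypeState(g.state) for g in p.genotypes},
            phenotype_note=p.phenotype_note, person=person)
        sites: dict[int, list[InsertionSite]] = {}
        for s in p.insertion_sites:
            sites.setdefault(s.feature, []).append(
                InsertionSite(s.location, s.flanking_sequence))
        for fidx, slist in sites.items():
            registry.set_insertion_sites(db, plant, new_features[fidx], slist)
        for att in p.attachments:
            registry.add_attachment(db, plant, att.to_attachment())
        mother_plants.append(registry.get_plant(db, plant.plant_id))

    for b in doc.seed_batches:
        batch = registry.add_seed_batch(
            db, line, b.personal_identifier,
            generation_label=b.generation_label,
            mother_plant=(mother_plants[b.mother_plant]
                          if b.mother_plant is not None else None),
            segregation={new_features[s.feature].feature_id:
                         Segregation(s.observed_counts, s.note)
                         for s in b.segregation},
            harvest_date=b.harvest_date,
            germination_result=b.germination_result,
            phenotype_note=b.phenotype_note, person=person)
        for att in b.attachments:
            registry.add_attachment(db, batch, att.to_attachment())

    db.audit("import_line", line=line.line_id, name=new_name,
             warnings=warnings)
    return ImportResult(line=registry.get_line(db, line.line_id),
                        warnings=warnings)
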