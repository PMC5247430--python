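"""Enumerations and record dataclasses for the registry.

These are plain value objects hydrated from database rows; all mutation goes
through the operation functions in :mod:`seedledger.vocab`,
:mod:`seedledger.registry` and :mod:`seedledger.lineage`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Role(enum.Enum):
    """Account permission levels, ordered READER < WRITER < ADMINISTRATOR."""

    READER = "READER"
    WRITER = "WRITER"
    ADMINISTRATOR = "ADMINISTRATOR"

    @property
    def rank(self) -> int:
        return _ROLE_RANK[self]

    def allows(self, required: "Role") -> bool:
        return self.rank >= required.rank


_ROLE_RANK = {Role.READER: 0, Role.WRITER: 1, Role.ADMINISTRATOR: 2}


class VocabCategory(enum.Enum):
    """The seven customizable scroll-down menus of the admin interface."""

    PERSON = "PERSON"
    SPECIES = "SPECIES"
    ECOTYPE = "ECOTYPE"
    MUTATION_METHOD = "MUTATION_METHOD"
    METHOD_REFERENCE = "METHOD_REFERENCE"
    STRAIN = "STRAIN"
    RESISTANCE = "RESISTANCE"


class FeatureCategory(enum.Enum):
    """A genetic feature is either a transgene insertion or an endogenous edit.

    TRANSGENESIS (T-DNA/transposon; rendered green) marks the line as
    transgenic (GMO); ENDOGENOUS (point mutations, deletions, natural
    variants; rendered blue) does not.
    """

    TRANSGENESIS = "TRANSGENESIS"
    ENDOGENOUS = "ENDOGENOUS"


#: display colour class per feature category (green = transgenic/GMO)
FEATURE_COLOR = {FeatureCategory.TRANSGENESIS: "GREEN", FeatureCategory.ENDOGENOUS: "BLUE"}


class CreationMode(enum.Enum):
    """The four ways a plant line can enter the registry."""

    NEW = "NEW"
    CROSS = "CROSS"
    MUTAG = "MUTAG"
    IMPORT = "IMPORT"


class ParentRole(enum.Enum):
    FEMALE = "FEMALE"
    MALE = "MALE"
    MOTHER = "MOTHER"


class GenotypeState(enum.Enum):
    WT = "WT"
    HETEROZYGOUS = "HETEROZYGOUS"
    HOMOZYGOUS = "HOMOZYGOUS"
    UNKNOWN = "UNKNOWN"


#: the five parts of a plant-line datasheet
DATASHEET_SECTIONS = (
    "general_information",
    "genetic_features",
    "genealogy_tree",
    "plants",
    "seed_batches",
)

#: ecotype sentinel auto-seeded for every species; reserved, never deletable
OTHER_ECOTYPE = "(Other)"


@dataclass(frozen=True)
class UserAccount:
    login: str
    role: Role


@dataclass(frozen=True)
class VocabEntry:
    entry_id: int
    category: VocabCategory
    value: str
    active: bool = True
    linked_species: str | None = None
    feature_category: FeatureCategory | None = None
    reserved: bool = False


@dataclass(frozen=True)
class MtaInfo:
    protected: bool = False
    details: str = ""


@dataclass(frozen=True)
class Attachment:
    filename: str
    media_type: str
    content: bytes
    slot: str = ""


@dataclass(frozen=True)
class ParentLink:
    parent_id: int
    role: ParentRole
    batch_id: int | None = None


@dataclass(frozen=True)
class PlantLine:
    line_id: int
    name: str
    person: str
    species: str
    ecotype_label: str
    origin: str
    creation_mode: CreationMode
    mta: MtaInfo
    parents: tuple[ParentLink, ...] = ()
    locked: bool = False


@dataclass(frozen=True)
class InsertionSite:
    location: str = ""
    flanking_sequence: str = ""


@dataclass(frozen=True)
class GeneticFeature:
    feature_id: int
    origin_line_id: int
    designation: str
    category: FeatureCategory
    gene: str = ""
    mutation_method: str | None = None
    method_reference: str | None = None
    sequence: str = ""
    selectable_resistance: str | None = None
    agro_strain: str | None = None
    genotyping_protocol: str = ""
    provenance: str = ""

    @property
    def color(self) -> str:
        return FEATURE_COLOR[self.category]


@dataclass(frozen=True)
class Plant:
    plant_id: int
    line_id: int
    personal_identifier: str
    generation_label: str = ""
    genotypes: dict[int, GenotypeState] = field(default_factory=dict)
    insertion_sites: dict[int, tuple[InsertionSite, ...]] = field(default_factory=dict)
    phenotype_note: str = ""
    notebook_ref: str = ""
    person: str | None = None
    locked: bool = False


@dataclass(frozen=True)
class Segregation:
    observed_counts: str = ""
    note: str = ""


@dataclass(frozen=True)
class SeedBatch:
    system_id: int
    line_id: int
    personal_identifier: str
    generation_label: str = ""
    mother_plant_id: int | None = None
    segregation: dict[int, Segregation] = field(default_factory=dict)
    harvest_date: str = ""
    storage_place: str = ""
    germination_result: str = ""
    phenotype_note: str = ""
    notebook_ref: str = ""
    person: str | None = None
    locked: bool = False


@dataclass(frozen=True)
class FeatureSpec:
    """Description of a genetic feature to be created (wizard input)."""

    designation: str
    category: FeatureCategory
    gene: str = ""
    mutation_method: str | None = None
    method_reference: str | None = None
    sequence: str = ""
    selectable_resistance: str | None = None
    agro_strain: str | None = None
    genotyping_protocol: str = ""
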