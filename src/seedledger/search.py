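"""Search engine: generic keyword plus per-section criteria.

Patterns follow the SQL-LIKE-style wildcard grammar of the search form:
``%`` replaces any run of characters (including none), ``_`` stands for a
single unknown character, and prefixing either with ``$`` matches the
literal symbol instead.  Without any wildcard a pattern matches the whole
value exactly.  Matching is case-insensitive throughout.

The generic field is matched against all plant-line names, gene names and
feature designations; section criteria address one field of one of the four
datasheet sub-parts (general information, genetic features, plants, seed
batches) and combine as AND at the line level.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable

from . import lineage, registry
from .db import SeedDatabase
from .errors import FieldError, PatternError, ValidationError
from .models import PlantLine

Matcher = Callable[[str], bool]

ESCAPE = "$"


def compile_pattern(pattern: str) -> Matcher:
    """Compile a wildcard pattern into a case-insensitive whole-value matcher.

    ``%`` → any run of characters; ``_`` → exactly one character; ``$`` makes
    the following character literal (so ``50$%`` finds the value ``50%``).
    A trailing bare ``$`` is an error.
    """
    if not pattern:
        raise PatternError("pattern must be non-empty")
    out: list[str] = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == ESCAPE:
            if i + 1 >= len(pattern):
                raise PatternError(
                    f"pattern {pattern!r} ends with a bare {ESCAPE!r}")
            out.append(re.escape(pattern[i + 1]))
            i += 2
            continue
        if c == "%":
            out.append(".*")
        elif c == "_":
            out.append(".")
        else:
            out.append(re.escape(c))
        i += 1
    rx = re.compile("".join(out), re.IGNORECASE | re.DOTALL)
    return lambda value: rx.fullmatch(value) is not None


#: valid criterion fields per datasheet section
SECTION_FIELDS: dict[str, tuple[str, ...]] = {
    "general": ("name", "species", "ecotype", "origin", "person"),
    "features": ("designation", "gene", "category", "mutation_method",
                 "sequence"),
    "plants": ("personal_identifier", "generation", "phenotype", "person"),
    "batches": ("personal_identifier", "id", "generation", "phenotype",
                "storage_place", "person"),
}


@dataclass
class Query:
    """One search request.

    ``criteria`` maps ``"section.field"`` (see :data:`SECTION_FIELDS`) to a
    wildcard pattern.  ``show_all`` lists every line; otherwise at least one
    criterion must be present.
    """

    generic: str | None = None
    criteria: dict[str, str] = field(default_factory=dict)
    show_all: bool = False


def _candidate_values(db: SeedDatabase, line: PlantLine, section: str,
                      fld: str) -> list[str]:
    if section == "general":
        return {
            "name": [line.name],
            "species": [line.species],
            "ecotype": [line.ecotype_label],
            "origin": [line.origin],
            "person": [line.person],
        }[fld]
    if section == "features":
        feats = lineage.effective_features(db, line)
        return {
            "designation": [f.designation for f in feats],
            "gene": [f.gene for f in feats],
            "category": [f.category.value for f in feats],
            "mutation_method": [f.mutation_method or "" for f in feats],
            "sequence": [f.sequence for f in feats],
        }[fld]
    if section == "plants":
        plants = registry.list_plants(db, line)
        return {
            "personal_identifier": [p.personal_identifier for p in plants],
            "generation": [p.generation_label for p in plants],
            "phenotype": [p.phenotype_note for p in plants],
            "person": [p.person or "" for p in plants],
        }[fld]
    batches = registry.list_seed_batches(db, line)
    return {
        "personal_identifier": [b.personal_identifier for b in batches],
        "id": [str(b.system_id) for b in batches],
        "generation": [b.generation_label for b in batches],
        "phenotype": [b.phenotype_note for b in batches],
        "storage_place": [b.storage_place for b in batches],
        "person": [b.person or "" for b in batches],
    }[fld]


def _parse_criterion(key: str) -> tuple[str, str]:
    valid = ", ".join(f"{s}.{f}" for s, fs in SECTION_FIELDS.items()
                      for f in fs)
    if "." not in key:
        raise FieldError(
            f"criterion {key!r} must be section.field; valid names: {valid}")
    section, fld = key.split(".", 1)
    if section not in SECTION_FIELDS or fld not in SECTION_FIELDS[section]:
        raise FieldError(
            f"unknown search field {key!r}; valid names: {valid}")
    return section, fld


def generic_targets(db: SeedDatabase, line: PlantLine) -> list[str]:
    """The values the generic keyword field is matched against."""
    feats = lineage.effective_features(db, line)
    return [line.name] + [f.gene for f in feats] + [f.designation for f in feats]


def search(db: SeedDatabase, query: Query) -> list[PlantLine]:
    """Return the lines matching the query, ordered by line name.

    A line matches when the generic pattern (if any) matches at least one of
    its name / gene names / feature designations, AND every section
    criterion matches the addressed field on the line or on at least one of
    its plants or seed batches.
    """
    if not query.show_all and query.generic is None and not query.criteria:
        raise ValidationError(
            "provide a generic keyword or criteria, or request all lines")
    generic_m = compile_pattern(query.generic) if query.generic else None
    compiled = [(_parse_criterion(k), compile_pattern(v))
                for k, v in query.criteria.items()]
    out = []
    for line in registry.list_lines(db):
        if generic_m and not any(generic_m(v)
                                 for v in generic_targets(db, line)):
            continue
        ok = True
        for (section, fld), m in compiled:
            if not any(m(v) for v in _candidate_values(db, line, section, fld)):
                ok = False
                break
        if ok:
            out.append(line)
    return sorted(out, key=lambda l: (l.name.lower(), l.line_id))
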