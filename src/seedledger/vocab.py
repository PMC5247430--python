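"""Controlled-vocabulary administration.

Seven vocabulary categories (persons, species, ecotypes, mutation methods,
method references, strains, resistances) parameterize every scroll-down menu
of the registry; together with account management they form the eight
administrative tabs.  Entries are referenced by stable internal IDs, so
renaming an entry updates every record that uses it.  Values are unique per
category, compared case-insensitively.

Deletion is allowed only for unused entries; :func:`usage_count` reports how
many lines, genetic features, plants and seed batches reference an entry.
Persons are never deleted when referenced — they are *deactivated*, which
hides them from menus for new entries while old records keep displaying the
name.
"""

from __future__ import annotations

from .db import SeedDatabase
from .errors import (CategoryError, ConflictError, DependencyError, InUseError,
                     NotFoundError, ValidationError)
from .models import (OTHER_ECOTYPE, FeatureCategory, Role, VocabCategory,
                     VocabEntry)

#: number of administrative tabs = the vocabulary categories + user accounts
def admin_tab_names() -> tuple[str, ...]:
    return ("users",) + tuple(c.value.lower() for c in VocabCategory)


def _row_to_entry(db: SeedDatabase, row) -> VocabEntry:
    linked = None
    if row["linked_species"] is not None:
        r = db.execute("SELECT value FROM vocab WHERE id = ?",
                       (row["linked_species"],)).fetchone()
        linked = r["value"] if r else None
    return VocabEntry(
        entry_id=row["id"],
        category=VocabCategory(row["category"]),
        value=row["value"],
        active=bool(row["active"]),
        linked_species=linked,
        feature_category=(FeatureCategory(row["feature_category"])
                          if row["feature_category"] else None),
        reserved=bool(row["reserved"]),
    )


def get_entry(db: SeedDatabase, category: VocabCategory, value: str,
              species: str | None = None) -> VocabEntry:
    """Look up an entry by (category, value); case-insensitive.

    For ECOTYPE, ``species`` restricts the lookup to ecotypes of that species
    (ecotype values are unique database-wide, but the restriction catches
    cross-species mistakes early).
    """
    row = db.execute("SELECT * FROM vocab WHERE category = ? AND value = ?",
                     (category.value, value)).fetchone()
    if row is None:
        raise NotFoundError(f"no {category.value} entry {value!r}")
    entry = _row_to_entry(db, row)
    if species is not None and entry.linked_species is not None \
            and entry.linked_species.lower() != species.lower():
        raise NotFoundError(
            f"ecotype {value!r} belongs to species {entry.linked_species!r},"
            f" not {species!r}")
    return entry


def resolve_id(db: SeedDatabase, category: VocabCategory, value: str) -> int:
    return get_entry(db, category, value).entry_id


def add_entry(db: SeedDatabase, category: VocabCategory, value: str, *,
              linked_species: str | None = None,
              feature_category: FeatureCategory | None = None,
              reserved: bool = False) -> VocabEntry:
    """Add a scroll-down option (ADMINISTRATOR only).

    ECOTYPE entries require an existing species (the species must be recorded
    first); MUTATION_METHOD entries require a feature category so that the
    method can only be attached to features of that category.  Adding a
    SPECIES auto-seeds its reserved "(Other)" ecotype sentinel.
    """
    db.require(Role.ADMINISTRATOR)
    if not value or not value.strip():
        raise ValidationError("vocabulary value must be non-empty")
    species_id = None
    if category is VocabCategory.ECOTYPE:
        if not linked_species:
            raise DependencyError("an ecotype requires its species")
        try:
            species_id = resolve_id(db, VocabCategory.SPECIES, linked_species)
        except NotFoundError:
            raise DependencyError(
                f"species {linked_species!r} must be recorded before "
                "registering ecotypes") from None
    if category is VocabCategory.MUTATION_METHOD and feature_category is None:
        raise DependencyError(
            "a mutation method must declare its genetic-feature category")
    if db.execute("SELECT 1 FROM vocab WHERE category = ? AND value = ?",
                  (category.value, value)).fetchone():
        raise ConflictError(f"{category.value} entry {value!r} already exists")
    cur = db.execute(
        "INSERT INTO vocab (category, value, linked_species, feature_category,"
        " reserved) VALUES (?,?,?,?,?)",
        (category.value, value, species_id,
         feature_category.value if feature_category else None, int(reserved)))
    entry_id = cur.lastrowid
    if category is VocabCategory.SPECIES:
        # every species gets the "(Other)" sentinel, used as import fallback
        db.execute(
            "INSERT INTO vocab (category, value, linked_species, reserved)"
            " VALUES (?,?,?,1)",
            (VocabCategory.ECOTYPE.value, f"{OTHER_ECOTYPE} [{value}]", entry_id))
    db.commit()
    db.audit("add_vocab_entry", category=category.value, value=value)
    return _row_to_entry(db, db.execute(
        "SELECT * FROM vocab WHERE id = ?", (entry_id,)).fetchone())


def other_ecotype(db: SeedDatabase, species: str) -> VocabEntry:
    """The reserved "(Other)" ecotype sentinel of a species."""
    return get_entry(db, VocabCategory.ECOTYPE,
                     f"{OTHER_ECOTYPE} [{species}]")


def list_entries(db: SeedDatabase, category: VocabCategory, *,
                 include_inactive: bool = False,
                 species: str | None = None) -> list[VocabEntry]:
    """Menu listing: the active entries of a category, sorted by value."""
    rows = db.execute(
        "SELECT * FROM vocab WHERE category = ? ORDER BY value",
        (category.value,)).fetchall()
    entries = [_row_to_entry(db, r) for r in rows]
    if not include_inactive:
        entries = [e for e in entries if e.active]
    if species is not None:
        entries = [e for e in entries
                   if e.linked_species is None
                   or e.linked_species.lower() == species.lower()]
    return entries


# every (table, column) that can hold a vocab reference, used for usage
# counting and for the in-use deletion guard
_REFERENCING = (
    ("lines", "person_id"), ("lines", "species_id"), ("lines", "ecotype_id"),
    ("features", "mutation_method"), ("features", "method_reference"),
    ("features", "resistance"), ("features", "agro_strain"),
    ("plants", "person_id"),
    ("seed_batches", "person_id"),
)


def usage_count(db: SeedDatabase, entry: VocabEntry | int) -> int:
    """Number of lines, features, plants and seed batches referencing entry."""
    entry_id = entry if isinstance(entry, int) else entry.entry_id
    if not db.execute("SELECT 1 FROM vocab WHERE id = ?", (entry_id,)).fetchone():
        raise NotFoundError(f"no vocabulary entry with id {entry_id}")
    total = 0
    for table, col in _REFERENCING:
        row = db.execute(f"SELECT COUNT(*) AS n FROM {table} WHERE {col} = ?",
                         (entry_id,)).fetchone()
        total += row["n"]
    return total


def delete_entry(db: SeedDatabase, entry: VocabEntry) -> None:
    """Remove an unused, non-reserved menu option (ADMINISTRATOR only)."""
    db.require(Role.ADMINISTRATOR)
    if entry.reserved:
        raise ValidationError(
            f"{entry.value!r} is a reserved default entry and cannot be deleted")
    n = usage_count(db, entry)
    if n > 0:
        raise InUseError(
            f"{entry.category.value} entry {entry.value!r} is referenced by "
            f"{n} record(s)", count=n)
    if entry.category is VocabCategory.SPECIES:
        dependants = db.execute(
            "SELECT value, reserved FROM vocab WHERE linked_species = ?",
            (entry.entry_id,)).fetchall()
        real = [r["value"] for r in dependants if not r["reserved"]]
        if real:
            raise InUseError(
                f"species {entry.value!r} still has ecotypes: {', '.join(real)}",
                count=len(real))
        db.execute("DELETE FROM vocab WHERE linked_species = ?",
                   (entry.entry_id,))
    db.execute("DELETE FROM vocab WHERE id = ?", (entry.entry_id,))
    db.commit()
    db.audit("delete_vocab_entry", category=entry.category.value,
             value=entry.value)


def rename_entry(db: SeedDatabase, entry: VocabEntry, new_value: str) -> VocabEntry:
    """Rename an option; records reference the ID, so they follow along."""
    db.require(Role.ADMINISTRATOR)
    if not new_value or not new_value.strip():
        raise ValidationError("vocabulary value must be non-empty")
    clash = db.execute(
        "SELECT id FROM vocab WHERE category = ? AND value = ? AND id != ?",
        (entry.category.value, new_value, entry.entry_id)).fetchone()
    if clash:
        raise ConflictError(
            f"{entry.category.value} entry {new_value!r} already exists")
    db.execute("UPDATE vocab SET value = ? WHERE id = ?",
               (new_value, entry.entry_id))
    db.commit()
    db.audit("rename_vocab_entry", category=entry.category.value,
             old=entry.value, new=new_value)
    return get_entry(db, entry.category, new_value)


def set_person_active(db: SeedDatabase, entry: VocabEntry, active: bool) -> None:
    """Hide (or re-show) a person in menus for new entries.

    Existing records keep displaying the name; only menu listings change.
    """
    db.require(Role.ADMINISTRATOR)
    if entry.category is not VocabCategory.PERSON:
        raise CategoryError(
            f"activation toggling applies to PERSON entries, not "
            f"{entry.category.value}")
    db.execute("UPDATE vocab SET active = ? WHERE id = ?",
               (int(active), entry.entry_id))
    db.commit()
    db.audit("set_person_active", value=entry.value, active=active)
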