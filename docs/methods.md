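# Methods

## Data model

The registry is a single-file embedded SQLite database per laboratory.  The
schema is relational (lines, features, plants, seed batches, vocabulary,
attachments, parent edges); a client/server backend would be a drop-in
replacement since all access goes through one `SeedDatabase` connection
object, but a desk-scale laboratory does not need one.

A plant-line datasheet has five parts — general information, the genetic
feature table, the genealogy tree, the plant table and the seed-batch table
(`DATASHEET_SECTIONS`).  Mandatory fields are minimal by design, so records
can be completed later rather than guessed at entry time: `{name, person,
species}` for a line, `{designation}` for a feature,
`{personal_identifier}` for plants and seed batches.  Everything else
(generation labels, genotypes, phenotype notes, harvest dates, attachments)
is optional.

Generation labels are uninterpreted free text ("T1", "F3", "unknown",
"Tx").  Laboratories differ in how strictly they track generations; the
registry imposes no workflow and validates only non-emptiness where a label
is part of a mandatory field set (it is not).

## Feature inheritance

A genetic feature is created exactly once, on its origin line, and is
*referenced* — never copied — by descendants:

```
effective(L) = owned(L) ∪ ⋃_{p ∈ parents(L)} effective(p)
```

Consequences the implementation enforces:

* Editing an inherited feature through a descendant raises
  `ImmutableFeatureError`; the edit must happen on the origin line, and all
  descendants observe it instantly (there is only one row).
* The `from <origin>` display label is resolved at read time from the
  origin line's current name, so labels follow renames.
* The GMO classification (`is_transgenic`) is a pure function of the
  effective set: any TRANSGENESIS feature ⇒ transgenic.  A CRISPR event is
  modelled as two features — the Cas9 T-DNA (TRANSGENESIS) and the edited
  locus (ENDOGENOUS) — so the transgene is tracked independently of the
  edit and can later segregate away in a recorded cross.

Two features of one line may share a designation; this is allowed (an
origin line can host several alleles with a common working name) but emits
a `UserWarning`, since it usually indicates a typo.

## Pedigree operations

`cross` requires two distinct, same-species parents (inter-species crosses
are refused; self-crosses are refused because selfed progeny are by
definition new plants/batches of the *same* line).  The child's ecotype
label is `"<female> × <male>"` when the parental ecotypes differ, else the
shared label; edges record which parental seed batches were used.  The
single optional extra feature covers pollen mutagenesis (crossing combined
with mutagenesis); it is owned by the child.

`mutagenize` creates a child inheriting species, ecotype and all features
from one mother line, owning exactly the new feature.

Acyclicity holds by construction (parents must already exist, import severs
links); a cheap cycle assertion still runs after every creation as
corruption detection.  MTA encumbrance is computed transitively —
`ancestors(L) ∩ protected` — because a transfer agreement legally binds all
progeny of the transferred material, not just the original packet of seeds.

Genealogies export as Graphviz DOT written by the package itself (nodes in
creation order, `rankdir=BT` so founders sit at the bottom, MTA nodes
filled red, edge labels carrying role and batch).  The DOT writer is
deliberately tiny and bit-stable so exports diff cleanly.  PNG rendering
uses the `dot` binary when present and otherwise a layered
networkx/matplotlib drawing; when neither works, `RendererUnavailableError`
points the user at DOT output.

## Identifiers

Seed-batch system IDs use SQLite `AUTOINCREMENT`, which guarantees strict
monotonic allocation with no reuse across the database lifetime — deleting
the highest batch does not free its ID.  Personal identifiers are free text
and may collide; the system ID is the disambiguator and is what the search
field `batches.id` matches.

## Vocabularies and roles

Seven controlled vocabularies (persons, species, ecotypes, mutation
methods, method references, strains, resistances) plus account management
form the eight administrative tabs.  Entries are referenced by internal ID,
so renames propagate; values are unique per category, compared
case-insensitively (ASCII case folding via SQLite `NOCASE`; lab
vocabularies are effectively ASCII, and accented duplicates would be caught
by eye).  Ecotypes require a pre-existing species; mutation methods declare
the feature category they may be attached to.  Each new species auto-seeds
a reserved `"(Other) [species]"` ecotype used as the import fallback; a
fresh database also seeds six common mutation methods (T-DNA, Transposon →
TRANSGENESIS; CRISPR, EMS, Gamma irradiation, Natural variant →
ENDOGENOUS).  CRISPR is registered as an endogenous-category method because
the method annotates the *edited locus* feature; the delivery construct is
a separate T-DNA feature.

`usage_count` counts referencing lines, genetic features, plants and seed
batches; deletion is refused while the count is positive or the entry is a
reserved default.  Deleting a species additionally requires that no
non-reserved ecotype still points at it (the reserved sentinel is cascaded)
— otherwise ecotype rows would dangle.  Persons are soft-deactivated
instead of deleted: hidden from menus for new records, still displayed on
old ones.

Roles form a lattice READER < WRITER < ADMINISTRATOR: readers only read,
writers edit records, administrators additionally edit vocabularies and
accounts.  Authentication (salted SHA-256) is a thin gate for a single-lab
trust model, not a security boundary.  Every write operation is appended to
a JSONL audit log next to the database file with timestamp and login.

## Search

Patterns compile to anchored regular expressions: `%` → `.*`, `_` → `.`,
`$c` → literal `c` (a trailing bare `$` is an error), everything else
escaped; matching is case-insensitive and whole-value.  Substring search is
deliberately *not* the default — users widen matches by adding `%`.
Wildcards may appear anywhere in the pattern, not only at the edges.

The generic field matches line names, gene names and feature designations
of the line's effective feature set (inherited features are part of the
datasheet, so they are findable).  Section criteria (`general.*`,
`features.*`, `plants.*`, `batches.*`) combine as AND **at the line
level**: each criterion must hold on the line or on at least one of its
plants/batches, but different criteria need not co-occur on the same plant.
The alternative (per-sample co-occurrence) would be stricter; line-level
AND matches how results resolve — to a line's datasheet, not to a row.

## Interchange format

The `.json` schema (format_version "1") is defined by pydantic models with
`extra="forbid"`; `interchange.json_schema()` publishes the JSON-Schema
document.  Attachments are base64-embedded so one file is a complete
exchange unit.  Redacted field classes — person names, notebook references,
storage places, MTA details — are absent from the payload models by
construction, which makes redaction structural rather than a filtering
step.  The MTA protected flag is retained with empty details.

On import: links are severed (creation mode IMPORT, no parents), features
become owned with their provenance text, the embedded genealogy image is
stored as a "file from source" attachment, and the importer names a
registered person responsible for the new record (exports carry none).
Unknown ecotypes degrade to the species' `"(Other)"` sentinel with a
warning; unknown species, methods, strains or resistances abort with an
actionable report listing what the administrator must create, unless an
explicit mapping substitutes existing values.  Species is held to a
stricter standard than ecotype because cross validation depends on it.

## Synthetic-data generator

`fixtures.generate_fixture(n_founders, n_events, p_cross, p_mta, seed)`
emulates a working laboratory: 2 model species (Arabidopsis, rice) with
registered ecotypes, founders carrying 0–2 random features of both
categories, MTA protection on founders with probability `p_mta`, and a
pedigree grown by `n_events` events — a same-species cross with probability
`p_cross`, else a secondary mutagenesis.  Plants and seed batches (0–2 per
line by default) get random generation labels, genotypes, segregation
counts, insertion sites and occasional attachments.  Sensitive values use
distinctive tokens (`person-KESTREL`, `NB-401-p12`, `freezer-X-box3`,
`MTA-details-…`) so redaction tests can grep serialized exports without
false positives.  The generator is deterministic per seed (verified by
full-content snapshots).

What it does not emulate: real naming conventions, unbalanced pedigree
shapes from long-running programmes, multi-database provenance, or file
attachments beyond small text payloads.  Passing property suites therefore
demonstrate the bookkeeping invariants (inheritance, ID discipline,
redaction, search semantics), not robustness to messy real-world entry.

## Verification sizes

The acceptance checks run at the sizes the property suites were designed
for: a 200-line pedigree for inheritance soundness, 100 random pedigrees
(~12 lines each) for descendant/MTA traversal oracles, a 1,000-operation
trace for ID discipline, and 100 random wildcard patterns (including
`$`-escapes) for the search oracle.  All complete in seconds.

## Known limitations

* No Mendelian prediction: segregation is recorded, never simulated.
* No plasmid module, label printing or prefilled-MTA generation.
* Single-database sessions; merging two laboratories' databases is out of
  scope beyond per-line export/import.
* Case-insensitive uniqueness is ASCII-only.
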