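# seedledger

A seed-stock and plant-line registry for plant-genetics laboratories.

Basic plant research accumulates mutant and transgenic lines faster than
spreadsheets can track them: a single working line may combine a T-DNA
reporter, a CRISPR-edited locus and an EMS allele, each inherited from a
different ancestor through crosses and secondary mutagenesis.  On top of the
genetics sit two administrative obligations — knowing which lines are
transgenic (GMO) and knowing which material is encumbered by a Material
Transfer Agreement (MTA), including *all* progeny of the originally
transferred seeds.  `seedledger` is a small embedded database plus a library
and CLI that keeps those books.

## The model

* **Plant line** — a named genetic context: species, ecotype, and a set of
  *genetic features*.  All selfed/backcrossed plants and seed batches live
  under one line; crossing or re-mutagenizing creates a *new* line.
* **Genetic feature** — one heritable modification, of exactly two kinds:
  `TRANSGENESIS` (T-DNA/transposon insertion; rendered green) or
  `ENDOGENOUS` (point mutation, deletion, natural variant; rendered blue).
  A feature is stored once, on the line where it was created, and inherited
  **by reference**: for any line,

  ```
  effective(L) = owned(L) ∪ ⋃ effective(parent(L))
  ```

  Inherited features are read-only through descendants and carry a
  `from <origin line>` label that follows renames.  A line is transgenic
  (GMO) iff `effective(L)` contains a TRANSGENESIS feature.
* **Pedigree** — a DAG built by two wizards: `cross` (two same-species
  parents, ecotype labels combined, optional extra feature for pollen
  mutagenesis) and `mutagenize` (one mother line, one new owned feature).
  MTA constraints propagate transitively: the protected ancestors of a line
  are `ancestors(L) ∩ {protected}`, and they encumber every descendant.
* **Seed batches** carry system-wide IDs that are strictly increasing and
  *never* reused, even after deletion — safe for freezer-tube labels.
* **Search** uses SQL-LIKE-style wildcards: `%` (any run), `_` (one
  character), `$%`/`$_` (literals); patterns without wildcards match whole
  values, case-insensitively.
* **Interchange** — one JSON document per line (± seed batches, mother
  plants, attachments, genealogy image), with person names, notebook
  references, storage places and MTA details redacted; the MTA *protected*
  flag survives.  Import severs parental links and flattens inherited
  features to owned copies with provenance text.

## Worked example

`python examples/pedigree_and_mta.py` builds a reporter line obtained under
an MTA, crosses it into an endogenous mutant, and applies a secondary
CRISPR mutagenesis:

```
feature table of 'triple' (green = transgene, blue = endogenous):
  [GREEN] ProPHT1:GFP from ProPHT1:GFP
  [BLUE ] pht1;1-1 from pht1;1-1
  [BLUE ] pht1;4-cr3

descendants of ProPHT1:GFP: 2
mixed-ecotype label of the cross: 'Col-0 × Ler'
MTAs constraining 'triple': ['ProPHT1:GFP']
```

The final line shows three features: two inherited (labelled with their
origin lines; the green one makes the line a GMO) and one owned.  The MTA
check recovers the protected founder two generations up — the legal
constraint travelled with the material.  The script then prints the
genealogy as Graphviz DOT with the protected line filled red.

The other examples cover registry building and ID discipline
(`build_registry.py`), wildcard search (`search_patterns.py`) and the
redacting export/import round trip (`exchange_roundtrip.py`).

A thin CLI mirrors the library 1-to-1:

```sh
seedledger init --database lab.db
seedledger vocab add --category species --value "Arabidopsis thaliana"
seedledger line add WT-Col0 --person alice --species "Arabidopsis thaliana"
seedledger cross F1 --female WT-Col0 --male mutant-1
seedledger tree F1 --format dot
seedledger search --generic "pht%"
seedledger export --line F1 -o f1.json
```

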