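"""Export a line to the JSON interchange format and import it back.

The export redacts person names, notebook references, storage places and
MTA details; the MTA *protected* flag survives.  Import severs parental
links and flattens inherited features to owned copies with provenance text.

Run:  python examples/exchange_roundtrip.py
"""

from seedledger import fixtures, interchange, lineage, registry

db = fixtures.generate_fixture(n_founders=5, n_events=10, p_cross=0.6,
                               p_mta=0.5, seed=5)
# pick the best-furnished MTA-protected line for the demonstration
line = max((l for l in registry.list_lines(db) if l.mta.protected),
           key=lambda l: (len(lineage.effective_features(db, l)),
                          len(registry.list_seed_batches(db, l))))
batches = registry.list_seed_batches(db, line)

doc = interchange.export_line(db, line, batches, include_tree=False)
payload = doc.to_json()
print(f"exported {line.name!r} with {len(doc.seed_batches)} seed batch(es)"
      f" and {len(doc.features)} feature(s); {len(payload)} bytes of JSON")
print(f"MTA in the document: protected={doc.line.mta_protected},"
      f" details={doc.line.mta_details!r} (details always redacted)")

secrets = fixtures.sensitive_strings(db)
leaks = [s for s in secrets if s in payload]
print(f"sensitive values in the database: {len(secrets)};"
      f" present in the export: {len(leaks)}")

result = interchange.import_line(db, payload, "received-line",
                                 "person-KESTREL")
imp = result.line
print(f"\nimported as {imp.name!r}: creation mode {imp.creation_mode.value},"
      f" {len(imp.parents)} parents (links severed)")
for f in lineage.effective_features(db, imp):
    prov = f" ({f.provenance})" if f.provenance else ""
    print(f"  owned feature: {f.designation}{prov}")
for w in result.warnings:
    print(f"  warning: {w}")
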