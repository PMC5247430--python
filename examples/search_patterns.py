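"""Wildcard search over a synthetic registry.

`%` replaces any run of characters, `_` exactly one, and `$` escapes a
literal `%` or `_`.  Without wildcards a pattern matches the whole value.

Run:  python examples/search_patterns.py
"""

from seedledger import fixtures, registry, search
from seedledger.search import Query

db = fixtures.generate_fixture(n_founders=6, n_events=12, p_cross=0.5,
                               p_mta=0.2, seed=3)
print(f"registry holds {len(registry.list_lines(db))} lines\n")

for query, why in [
    (Query(show_all=True), "every line, name-sorted"),
    (Query(generic="pht%"), "designations starting with 'pht'"),
    (Query(generic="L00_"), "founder names: 'L00' plus one character"),
    (Query(criteria={"general.species": "Oryza%"}), "rice lines only"),
    (Query(criteria={"batches.id": "3"}), "the line owning seed batch #3"),
]:
    hits = search.search(db, query)
    label = query.generic or query.criteria or "show_all"
    print(f"{label!r:40} -> {len(hits):2d} line(s): "
          f"{[l.name for l in hits][:6]}")
    print(f"    ({why})")
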