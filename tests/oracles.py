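"""Brute-force reference implementations used as independent oracles.

These deliberately avoid the library's own traversal/matching code: they
read raw rows and recurse naively, so agreement with the package is a real
cross-check rather than a tautology.
"""

from __future__ import annotations


def wildcard_match(pattern: str, value: str) -> bool:
    """Recursive wildcard matcher: % = any run, _ = one char, $ escapes."""
    p = pattern.lower()
    v = value.lower()

    def rec(i: int, j: int) -> bool:
        if i == len(p):
            return j == len(v)
        c = p[i]
        if c == "$":
            # compile_pattern rejects trailing '$'; mirror literal semantics
            return (j < len(v) and i + 1 < len(p) and v[j] == p[i + 1]
                    and rec(i + 2, j + 1))
        if c == "%":
            return any(rec(i + 1, k) for k in range(j, len(v) + 1))
        if c == "_":
            return j < len(v) and rec(i + 1, j + 1)
        return j < len(v) and v[j] == c and rec(i + 1, j + 1)

    return rec(0, 0)


def parent_ids(db, line_id: int) -> list[int]:
    return [r["parent_id"] for r in db.execute(
        "SELECT parent_id FROM line_parents WHERE child_id = ?", (line_id,))]


def all_line_ids(db) -> list[int]:
    return [r["id"] for r in db.execute("SELECT id FROM lines ORDER BY id")]


def effective_feature_ids(db, line_id: int) -> set[int]:
    """Recursive union: owned(line) ∪ ⋃ effective(parent)."""
    owned = {r["id"] for r in db.execute(
        "SELECT id FROM features WHERE origin_line = ?", (line_id,))}
    for pid in parent_ids(db, line_id):
        owned |= effective_feature_ids(db, pid)
    return owned


def ancestor_closure(db, line_id: int) -> set[int]:
    out = {line_id}
    for pid in parent_ids(db, line_id):
        out |= ancestor_closure(db, pid)
    return out


def descendant_ids(db, line_id: int) -> set[int]:
    """Reverse reachability: every line whose ancestor closure contains us."""
    return {other for other in all_line_ids(db)
            if other != line_id and line_id in ancestor_closure(db, other)}


def protected_ancestors(db, line_id: int) -> set[int]:
    return {a for a in ancestor_closure(db, line_id)
            if db.execute("SELECT mta_protected FROM lines WHERE id = ?",
                          (a,)).fetchone()["mta_protected"]}


def usage_count_bruteforce(db, entry_id: int) -> int:
    """Scan every record row for references to a vocabulary entry."""
    n = 0
    for r in db.execute("SELECT person_id, species_id, ecotype_id FROM lines"):
        n += sum(1 for v in r if v == entry_id)
    for r in db.execute("SELECT mutation_method, method_reference,"
                        " resistance, agro_strain FROM features"):
        n += sum(1 for v in r if v == entry_id)
    for r in db.execute("SELECT person_id FROM plants"):
        n += sum(1 for v in r if v == entry_id)
    for r in db.execute("SELECT person_id FROM seed_batches"):
        n += sum(1 for v in r if v == entry_id)
    return n
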