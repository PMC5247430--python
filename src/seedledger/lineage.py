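"""Pedigree operations: crossing, secondary mutagenesis, genealogy.

Genetic features are stored once, on the line where they were created, and
inherited *by reference*: a child of a cross or mutagenesis sees the union
of its parents' effective feature sets plus the features it owns.  Editing
an inherited feature is only possible via its origin line, and every
descendant observes the change instantly.  A line is transgenic (GMO) iff
its effective feature set contains at least one TRANSGENESIS feature.

MTA constraints are transitive over descent: a Material Transfer Agreement
protecting an ancestor legally encumbers all its progeny, through every
series of seed amplifications and crosses.  :func:`mta_affected_set`
returns the protected ancestors (including the line itself) whose
agreements constrain a line.
"""

from __future__ import annotations

import shutil
import subprocess

import networkx as nx

from . import registry
from .db import SeedDatabase
from .errors import (ConsistencyError, NotFoundError, RendererUnavailableError,
                     SpeciesMismatchError, ValidationError)
from .models import (CreationMode, FeatureCategory, FeatureSpec,
                     GeneticFeature, ParentRole, PlantLine, Role, SeedBatch)


# ---------------------------------------------------------------------------
# feature inheritance

def effective_features(db: SeedDatabase, line: PlantLine | int) -> list[GeneticFeature]:
    """Owned features plus all features inherited from ancestors.

    Equals ``owned(line) ∪ ⋃ effective(parent)``; duplicates (the same
    feature reaching a line through both parents) appear once.  Ordered by
    feature id, i.e. creation order.
    """
    line_id = line if isinstance(line, int) else line.line_id
    seen: dict[int, GeneticFeature] = {}
    stack = [line_id]
    visited: set[int] = set()
    while stack:
        current = stack.pop()
        if current in visited:
            continue
        visited.add(current)
        for f in registry.owned_features(db, current):
            seen.setdefault(f.feature_id, f)
        stack.extend(r["parent_id"] for r in db.execute(
            "SELECT parent_id FROM line_parents WHERE child_id = ?", (current,)))
    return [seen[k] for k in sorted(seen)]


def feature_label(db: SeedDatabase, feature: GeneticFeature,
                  line: PlantLine | int) -> str:
    """Display label: designation, plus ``from <origin>`` when inherited.

    The origin name is resolved at call time, so labels follow renames of
    the origin line (reference semantics).
    """
    line_id = line if isinstance(line, int) else line.line_id
    if feature.origin_line_id == line_id:
        return feature.designation
    origin = registry.get_line(db, feature.origin_line_id)
    return f"{feature.designation} from {origin.name}"


def is_transgenic(db: SeedDatabase, line: PlantLine | int) -> bool:
    """GMO flag: does any effective feature carry a transgene?"""
    return any(f.category is FeatureCategory.TRANSGENESIS
               for f in effective_features(db, line))


def feature_table(db: SeedDatabase, line: PlantLine | int) -> list[dict]:
    """The datasheet's feature table: label + colour class per feature."""
    line_id = line if isinstance(line, int) else line.line_id
    return [{"designation": f.designation,
             "label": feature_label(db, f, line_id),
             "category": f.category.value,
             "color": f.color,
             "inherited": f.origin_line_id != line_id}
            for f in effective_features(db, line_id)]


# ---------------------------------------------------------------------------
# wizards

def _check_batch(db: SeedDatabase, batch: SeedBatch | int | None,
                 parent: PlantLine, role: str) -> int | None:
    if batch is None:
        return None
    b = (batch if isinstance(batch, SeedBatch)
         else registry.get_seed_batch(db, batch))
    if b.line_id != parent.line_id:
        raise ConsistencyError(
            f"seed batch {b.system_id} does not belong to the {role} parent"
            f" {parent.name!r}")
    return b.system_id


def cross(db: SeedDatabase, female: PlantLine, male: PlantLine, name: str, *,
          female_batch: SeedBatch | int | None = None,
          male_batch: SeedBatch | int | None = None,
          extra_feature: FeatureSpec | None = None) -> PlantLine:
    """Cross two recorded lines; only intra-species crosses are permitted.

    The child inherits the union of both parents' effective features by
    reference; its ecotype label combines the parental ecotypes when they
    differ.  ``extra_feature`` covers pollen mutagenesis, where a crossing
    is combined with an additional mutagenesis — that one feature is owned
    by the child.  The seed batches used for the crossing can be recorded
    on the parent edges.
    """
    db.require(Role.WRITER)
    if female.line_id == male.line_id:
        raise ValidationError(
            "self-crosses are not recorded as new lines; selfed progeny are"
            " new plants/seed batches of the same line")
    if female.species.lower() != male.species.lower():
        raise SpeciesMismatchError(
            f"only intra-species crosses are permitted"
            f" ({female.species} × {male.species})")
    fb = _check_batch(db, female_batch, female, "female")
    mb = _check_batch(db, male_batch, male, "male")
    if female.ecotype_label and male.ecotype_label \
            and female.ecotype_label.lower() != male.ecotype_label.lower():
        ecotype_label = f"{female.ecotype_label} × {male.ecotype_label}"
    else:
        ecotype_label = female.ecotype_label or male.ecotype_label
    child = registry.create_line(db, name, female.person, female.species,
                                 creation_mode=CreationMode.CROSS)
    db.execute("UPDATE lines SET ecotype_label = ? WHERE id = ?",
               (ecotype_label, child.line_id))
    db.execute("INSERT INTO line_parents (child_id, parent_id, role, batch_id)"
               " VALUES (?,?,?,?)",
               (child.line_id, female.line_id, ParentRole.FEMALE.value, fb))
    db.execute("INSERT INTO line_parents (child_id, parent_id, role, batch_id)"
               " VALUES (?,?,?,?)",
               (child.line_id, male.line_id, ParentRole.MALE.value, mb))
    db.commit()
    child = registry.get_line(db, child.line_id)
    if extra_feature is not None:
        registry.add_feature(db, child, extra_feature)
    _assert_acyclic(db, child.line_id)
    db.audit("cross", female=female.line_id, male=male.line_id,
             child=child.line_id)
    return registry.get_line(db, child.line_id)


def mutagenize(db: SeedDatabase, parent: PlantLine,
               new_feature: FeatureSpec, name: str, *,
               mother_batch: SeedBatch | int | None = None) -> PlantLine:
    """Secondary mutagenesis: a new line inheriting everything from its mother.

    Species, ecotype and all parental genetic features are imported by
    reference; the child owns exactly the new feature.
    """
    db.require(Role.WRITER)
    if not new_feature.designation or not new_feature.designation.strip():
        raise ValidationError("missing mandatory field(s): designation",
                              missing=("designation",))
    mb = _check_batch(db, mother_batch, parent, "mother")
    child = registry.create_line(db, name, parent.person, parent.species,
                                 creation_mode=CreationMode.MUTAG)
    db.execute("UPDATE lines SET ecotype_label = ?, ecotype_id ="
               " (SELECT ecotype_id FROM lines WHERE id = ?) WHERE id = ?",
               (parent.ecotype_label, parent.line_id, child.line_id))
    db.execute("INSERT INTO line_parents (child_id, parent_id, role, batch_id)"
               " VALUES (?,?,?,?)",
               (child.line_id, parent.line_id, ParentRole.MOTHER.value, mb))
    db.commit()
    child = registry.get_line(db, child.line_id)
    registry.add_feature(db, child, new_feature)
    _assert_acyclic(db, child.line_id)
    db.audit("mutag", parent=parent.line_id, child=child.line_id)
    return registry.get_line(db, child.line_id)


def _assert_acyclic(db: SeedDatabase, start: int) -> None:
    # parents must pre-exist, so cycles are impossible by construction;
    # assert anyway after each creation, as cheap corruption detection
    seen: set[int] = set()
    stack = [(start, frozenset())]
    while stack:
        node, path = stack.pop()
        if node in path:
            raise ConsistencyError(f"pedigree cycle detected at line {node}")
        for r in db.execute("SELECT parent_id FROM line_parents"
                            " WHERE child_id = ?", (node,)):
            stack.append((r["parent_id"], path | {node}))
        seen.add(node)


# ---------------------------------------------------------------------------
# genealogy queries

def ancestry_tree(db: SeedDatabase, line: PlantLine | int) -> nx.DiGraph:
    """The genealogy DAG of a line: itself plus all transitive parents.

    Nodes are line ids with ``name``, ``mta`` (red-flag) and ``features``
    (the companion colour-coded feature table) attributes; edges run
    parent → child and carry the parental ``role`` and the seed batches
    used for the generation, when recorded.
    """
    line_id = line if isinstance(line, int) else line.line_id
    registry.get_line(db, line_id)  # raises NotFoundError for unknown lines
    g = nx.DiGraph()
    stack = [line_id]
    done: set[int] = set()
    while stack:
        node = stack.pop()
        if node in done:
            continue
        done.add(node)
        rec = registry.get_line(db, node)
        g.add_node(node, name=rec.name, mta=rec.mta.protected,
                   features=feature_table(db, node))
        for link in rec.parents:
            g.add_edge(link.parent_id, node, role=link.role.value,
                       batch_id=link.batch_id)
            stack.append(link.parent_id)
    return g


def children_of(db: SeedDatabase, line_id: int) -> list[int]:
    return [r["child_id"] for r in db.execute(
        "SELECT DISTINCT child_id FROM line_parents WHERE parent_id = ?"
        " ORDER BY child_id", (line_id,))]


def descendant_count(db: SeedDatabase, line: PlantLine | int) -> int:
    """Distinct lines transitively derived from this line (excluding it)."""
    line_id = line if isinstance(line, int) else line.line_id
    registry.get_line(db, line_id)
    seen: set[int] = set()
    stack = [line_id]
    while stack:
        for child in children_of(db, stack.pop()):
            if child not in seen:
                seen.add(child)
                stack.append(child)
    seen.discard(line_id)
    return len(seen)


def mta_affected_set(db: SeedDatabase, line: PlantLine | int) -> set[int]:
    """MTA-protected ancestors (including self) constraining this line.

    An empty set means the material is unencumbered.
    """
    line_id = line if isinstance(line, int) else line.line_id
    registry.get_line(db, line_id)
    out: set[int] = set()
    seen: set[int] = set()
    stack = [line_id]
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        rec = registry.get_line(db, node)
        if rec.mta.protected:
            out.add(node)
        stack.extend(link.parent_id for link in rec.parents)
    return out


# ---------------------------------------------------------------------------
# rendering

def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def to_dot(db: SeedDatabase, line: PlantLine | int) -> str:
    """Graphviz DOT encoding of the ancestry DAG.

    Bit-stable for a given database state: nodes are emitted in creation
    order (line id).  Parents sit at the bottom (``rankdir=BT`` with edges
    parent → child).  MTA-protected lines are filled red; edge labels show
    the parental role and the seed batch used, when recorded.
    """
    g = ancestry_tree(db, line)
    lines_out = ["digraph genealogy {", "  rankdir=BT;",
                 '  node [shape=box, style=filled, fillcolor=white];']
    for node in sorted(g.nodes):
        attrs = g.nodes[node]
        style = ', fillcolor=red' if attrs["mta"] else ''
        lines_out.append(
            f'  n{node} [label="{_dot_escape(attrs["name"])}"{style}];')
    for u, v in sorted(g.edges):
        e = g.edges[u, v]
        label = e["role"].lower()
        if e.get("batch_id"):
            label += f" (batch {e['batch_id']})"
        lines_out.append(f'  n{u} -> n{v} [label="{_dot_escape(label)}"];')
    lines_out.append("}")
    return "\n".join(lines_out) + "\n"


def render_png(db: SeedDatabase, line: PlantLine | int) -> bytes:
    """Render the genealogy as PNG.

    Uses the Graphviz ``dot`` binary when present; otherwise falls back to a
    layered matplotlib drawing.  Raises :class:`RendererUnavailableError`
    (suggesting DOT output) if neither renderer works.
    """
    dot = to_dot(db, line)
    exe = shutil.which("dot")
    if exe:
        try:
            proc = subprocess.run([exe, "-Tpng"], input=dot.encode(),
                                  capture_output=True, check=True)
            return proc.stdout
        except (OSError, subprocess.CalledProcessError):
            pass
    try:
        return _matplotlib_png(db, line)
    except Exception as exc:  # pragma: no cover - depends on environment
        raise RendererUnavailableError(
            "no PNG renderer available; export the tree as DOT instead"
        ) from exc


def _matplotlib_png(db: SeedDatabase, line: PlantLine | int) -> bytes:
    import io

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = ancestry_tree(db, line)
    # layer = pedigree depth; founders at the bottom of the figure
    depth: dict[int, int] = {}
    for node in nx.topological_sort(g):
        preds = list(g.predecessors(node))
        depth[node] = max((depth[p] + 1 for p in preds), default=0)
    by_level: dict[int, list[int]] = {}
    for node, lvl in depth.items():
        by_level.setdefault(lvl, []).append(node)
    pos = {n: (i, lvl) for lvl, nodes in by_level.items()
           for i, n in enumerate(sorted(nodes))}
    colors = ["red" if g.nodes[n]["mta"] else "lightgray" for n in g.nodes]
    labels = {n: g.nodes[n]["name"] for n in g.nodes}
    fig, ax = plt.subplots(figsize=(max(4, len(g) * 1.2), max(3, len(by_level))))
    nx.draw_networkx(g, pos=pos, ax=ax, node_color=colors, labels=labels,
                     node_shape="s", node_size=1800, font_size=8,
                     edge_color="gray")
    ax.set_axis_off()
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=100, bbox_inches="tight")
    plt.close(fig)
    return buf.getvalue()


def export_tree(db: SeedDatabase, line: PlantLine | int, fmt: str = "DOT") -> bytes:
    """Export the genealogy as a file payload (``DOT`` text or ``PNG``)."""
    fmt = fmt.upper()
    if fmt == "DOT":
        return to_dot(db, line).encode()
    if fmt == "PNG":
        return render_png(db, line)
    raise ValidationError("format must be DOT or PNG")
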