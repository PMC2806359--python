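"""Tree and table I/O.

Readers accept Newick and Nexus (TREES block with TRANSLATE), including
BEAST-style ``[&key=value]`` comment annotations; parsing is delegated to
dendropy and the result converted to the package's annotated
:class:`~treefuse.model.Tree`.  Internal node labels become a column named
``"label"``; each distinct comment key becomes its own column.  A column is
numeric iff every non-missing value parses as a decimal/scientific literal,
otherwise text — matching spreadsheet-import semantics.

Support values are never rescaled on import (no percent/proportion
conversion); use an expression (:mod:`treefuse.datacols`) for that.

Annotation tables are tab-separated UTF-8 with a required header row, ``.``
as decimal separator, and no quoting dialect (tabs are forbidden in values).

The JSON project format is the package's lossless native serialization:
topology, lengths, all columns (including hidden ones) and declarations,
plus an opaque render-style section.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import dendropy

from .model import (
    HIDDEN,
    NUMERIC,
    TERMINAL_NAME_COLUMN,
    TEXT,
    VISIBLE,
    AnnotationColumn,
    ColumnError,
    Node,
    Tree,
    TreeError,
)

__all__ = [
    "ParseError",
    "ProjectFormatError",
    "SupportSpec",
    "TranslationTable",
    "ImportReport",
    "read_newick",
    "write_newick",
    "read_nexus",
    "write_nexus",
    "import_table",
    "export_table",
    "export_table_text",
    "apply_translation",
    "search_replace",
    "read_translation_table",
    "save_project",
    "load_project",
    "ProjectDocument",
]

PROJECT_FORMAT = "treefuse-project"
PROJECT_VERSION = 1

LABEL_COLUMN = "label"

_NUM_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


class ParseError(ValueError):
    """Malformed Newick/Nexus input."""


class ProjectFormatError(ValueError):
    """Project file missing, truncated, or of an unsupported version."""


@dataclass(frozen=True)
class SupportSpec:
    """Where a source tree's support values live.

    ``source`` is one of ``"internal-node-label"``, ``"comment-key"`` or
    ``"column"``; ``key`` names the comment key or column and is required
    exactly when the source is not the internal node label.
    """

    source: str = "internal-node-label"
    key: Optional[str] = None

    def __post_init__(self):
        if self.source not in ("internal-node-label", "comment-key", "column"):
            raise ValueError(f"unknown support source {self.source!r}")
        if (self.key is None) != (self.source == "internal-node-label"):
            raise ValueError(
                "key is required iff source is not 'internal-node-label'")

    @property
    def column_id(self) -> str:
        return LABEL_COLUMN if self.key is None else self.key


@dataclass
class TranslationTable:
    """Mapping old terminal name -> new name; new names must be unique."""

    rows: dict

    def __post_init__(self):
        new = list(self.rows.values())
        if len(set(new)) != len(new):
            dupes = sorted({n for n in new if new.count(n) > 1})
            raise ValueError(f"translation maps several names onto {dupes}")

    def inverted(self) -> "TranslationTable":
        return TranslationTable({v: k for k, v in self.rows.items()})


@dataclass
class ImportReport:
    """Outcome of a table import: how many rows landed, which did not."""

    matched: int
    unmatched_keys: list = field(default_factory=list)
    columns_added: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Newick / Nexus reading (dendropy-backed)
# ---------------------------------------------------------------------------

def _is_number(s: str) -> bool:
    return bool(_NUM_RE.match(s.strip()))


def _comment_values(dnode) -> dict:
    vals = {}
    for container in (dnode.annotations, dnode.edge.annotations):
        for a in container:
            v = a.value
            if isinstance(v, (list, tuple)):
                v = "{" + ",".join(str(x) for x in v) + "}"
            vals[a.name] = str(v)
    return vals


def _convert_dendropy(dtree: dendropy.Tree, name: str = "") -> Tree:
    labels: list[str] = []
    keys: dict[str, list] = {}
    entries = []  # (dnode, our Node) in creation order

    def build(dnode) -> Node:
        children = [build(c) for c in dnode.child_nodes()]
        if children:
            node = Node("", children=children)
            raw_label = dnode.label
            if raw_label is None and dnode.taxon is not None:
                raw_label = dnode.taxon.label
        else:
            if dnode.taxon is None or not dnode.taxon.label:
                raise ParseError("terminal node without a name")
            node = Node(dnode.taxon.label)
            raw_label = None
        node.branch.length = dnode.edge.length
        comments = _comment_values(dnode)
        entries.append((node, raw_label, comments))
        if raw_label is not None:
            labels.append(raw_label)
        for k, v in comments.items():
            keys.setdefault(k, []).append(v)
        return node

    root = build(dtree.seed_node)
    tree = Tree(root, name=name)
    if dtree.is_rooted is True:
        tree.rooting = "rooted"
    elif dtree.is_rooted is False and dtree.is_rootedness_undefined is False:
        tree.rooting = "unrooted"

    label_numeric = bool(labels) and all(_is_number(x) for x in labels)
    if labels:
        tree.declare_column(LABEL_COLUMN, VISIBLE,
                            NUMERIC if label_numeric else TEXT)
    key_numeric = {k: all(_is_number(v) for v in vs) for k, vs in keys.items()}
    for k in keys:
        tree.declare_column(k, VISIBLE, NUMERIC if key_numeric[k] else TEXT)

    for node, raw_label, comments in entries:
        if raw_label is not None:
            tree.set_annotation(node, LABEL_COLUMN,
                                float(raw_label) if label_numeric else raw_label)
        for k, v in comments.items():
            tree.set_annotation(node, k, float(v) if key_numeric[k] else v)
    return tree


def _wrap_parse_error(exc: Exception) -> ParseError:
    msg = str(exc)
    line = getattr(exc, "line_num", None)
    col = getattr(exc, "col_num", None)
    loc = ""
    if line is not None:
        loc = f" (line {line}" + (f", column {col})" if col is not None else ")")
    return ParseError(f"parse error{loc}: {msg}")


def read_newick(text: str) -> Tree:
    """Parse one Newick tree (quoted labels, lengths, ``[&k=v]`` comments)."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            extract_comment_metadata=True,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError flavors
        raise _wrap_parse_error(exc) from exc
    return _convert_dendropy(dtree)


def read_nexus(text: str) -> list:
    """Parse a Nexus TREES block; returns ``[(name, Tree), ...]`` in file order.

    TRANSLATE numbers are replaced by taxon names; ``[&R]``/``[&U]`` rooting
    comments are recorded on ``Tree.rooting``; other blocks are ignored.
    """
    try:
        dtrees = dendropy.TreeList.get(
            data=text, schema="nexus",
            extract_comment_metadata=True,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise _wrap_parse_error(exc) from exc
    translated = _translate_names(text)
    out = []
    for dt in dtrees:
        name = dt.label or ""
        tree = _convert_dendropy(dt, name=name)
        if translated is not None:
            stray = sorted(n for n in tree.terminal_names()
                           if n.isdigit() and n not in translated)
            if stray:
                raise ParseError(
                    f"tree {name or len(out) + 1!r} references numbers "
                    f"absent from the TRANSLATE table: {stray}")
        out.append((name, tree))
    return out


_TRANSLATE_RE = re.compile(r"\bTRANSLATE\b(.*?);", re.IGNORECASE | re.DOTALL)


def _translate_names(text: str):
    """Names defined by a TRANSLATE table, or None when there is no table."""
    m = _TRANSLATE_RE.search(text)
    if not m:
        return None
    names = set()
    for entry in m.group(1).split(","):
        parts = entry.split()
        if len(parts) >= 2:
            names.add(parts[1].strip("'\""))
    return names


# ---------------------------------------------------------------------------
# Newick writing
# ---------------------------------------------------------------------------

_QUOTE_NEEDED = re.compile(r"[\s()\[\]{}:;,='\"]")


def _quote(name: str) -> str:
    if name and not _QUOTE_NEEDED.search(name):
        return name
    return "'" + name.replace("'", "''") + "'"


def format_number(v: float) -> str:
    """Shortest exact decimal form; integers print without a decimal point."""
    if isinstance(v, float) and v.is_integer() and abs(v) < 1e16:
        return str(int(v))
    return repr(float(v))


def _fmt_value(v) -> str:
    return format_number(v) if isinstance(v, float) else str(v)


def write_newick(tree: Tree, label_column: Optional[str] = None,
                 comment_columns: Sequence[str] = ()) -> str:
    """Serialize to Newick.

    ``label_column`` is emitted as internal node labels; ``comment_columns``
    as ``[&k=v]`` comments placed after the label, before the colon.
    """
    if label_column is not None:
        tree.column(label_column)
    for c in comment_columns:
        tree.column(c)

    def emit(node: Node) -> str:
        parts = []
        if node.children:
            parts.append("(" + ",".join(emit(c) for c in node.children) + ")")
            if label_column is not None:
                lab = node.branch.annotations.get(label_column)
                if lab is not None:
                    s = _fmt_value(lab)
                    parts.append(_quote(s) if _QUOTE_NEEDED.search(s) else s)
        else:
            parts.append(_quote(node.name))
        comment_items = [
            (k, node.branch.annotations[k]) for k in comment_columns
            if k in node.branch.annotations
        ]
        if comment_items:
            parts.append("[&" + ",".join(
                f"{k}={_fmt_value(v)}" for k, v in comment_items) + "]")
        if node.branch.length is not None:
            parts.append(":" + format_number(node.branch.length))
        return "".join(parts)

    return emit(tree.root) + ";"


def write_nexus(named_trees: Sequence, label_column: Optional[str] = None,
                comment_columns: Sequence[str] = ()) -> str:
    """Serialize ``[(name, Tree), ...]`` as a Nexus TREES block."""
    lines = ["#NEXUS", "BEGIN TREES;"]
    for i, (name, tree) in enumerate(named_trees):
        rooting = ""
        if tree.rooting == "rooted":
            rooting = "[&R] "
        elif tree.rooting == "unrooted":
            rooting = "[&U] "
        tname = name or f"tree_{i + 1}"
        nwk = write_newick(tree, label_column=label_column,
                           comment_columns=comment_columns)
        lines.append(f"    TREE {_quote(tname)} = {rooting}{nwk}")
    lines.append("END;")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

def _parse_tsv(text: str) -> list:
    rows = [line.split("\t") for line in text.splitlines() if line.strip()]
    if not rows:
        raise ValueError("empty table")
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise ValueError(f"table row {i + 1} has {len(r)} fields, "
                             f"expected {width}")
    return rows


def import_table(tree: Tree, table: Union[str, Sequence[Sequence[str]]],
                 target_kind: str = HIDDEN,
                 match_column: Optional[str] = None) -> ImportReport:
    """Attach table values to the branches above matched terminals.

    The first table column holds keys; the header row names the new columns.
    Keys match terminal names, or values of ``match_column`` (e.g. a hidden
    lab-ID column) when given.  Unmatched tree terminals keep missing values;
    unmatched table rows are reported; zero matches is an error.
    """
    rows = _parse_tsv(table) if isinstance(table, str) else [list(r) for r in table]
    header, body = rows[0], rows[1:]
    if len(header) < 2:
        raise ValueError("table needs a key column plus at least one value column")
    keys = [r[0] for r in body]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate keys in table: {dupes}")

    if match_column is None:
        target = {t.name: t for t in tree.terminals()}
    else:
        tree.column(match_column)
        target = {}
        for t in tree.terminals():
            v = t.branch.annotations.get(match_column)
            if v is not None:
                target[str(v)] = t

    matched = [(k, target[k]) for k in keys if k in target]
    unmatched = [k for k in keys if k not in target]
    if not matched:
        raise ValueError("no table key matches any terminal "
                         "(wrong key column or match column?)")

    col_ids = header[1:]
    numeric = {}
    for j, cid in enumerate(col_ids, start=1):
        vals = [r[j] for r in body if r[j] != ""]
        numeric[cid] = bool(vals) and all(_is_number(v) for v in vals)
        tree.declare_column(cid, target_kind, NUMERIC if numeric[cid] else TEXT)

    by_key = {r[0]: r for r in body}
    for k, term in matched:
        row = by_key[k]
        for j, cid in enumerate(col_ids, start=1):
            raw = row[j]
            if raw == "":
                continue
            tree.set_annotation(term, cid,
                                float(raw) if numeric[cid] else raw)
    return ImportReport(matched=len(matched), unmatched_keys=unmatched,
                        columns_added=list(col_ids))


def _ordered_nodes(tree: Tree) -> list:
    terms = [nd for nd in tree.nodes() if nd.is_terminal]
    internals = [nd for nd in tree.nodes() if not nd.is_terminal]
    return terms + internals


def export_table(tree: Tree, columns: Sequence[str]) -> list:
    """Rows (header first): one per node, terminals first then internals in
    preorder; missing values render as empty cells.  Internal nodes are keyed
    ``node_<k>`` by preorder index (such rows cannot be re-imported)."""
    for c in columns:
        tree.column(c)
    rows = [["node"] + list(columns)]
    internal_idx = {}
    for i, nd in enumerate(tree.nodes()):
        if not nd.is_terminal:
            internal_idx[id(nd)] = i
    for nd in _ordered_nodes(tree):
        key = nd.name if nd.is_terminal else f"node_{internal_idx[id(nd)]}"
        row = [key]
        for c in columns:
            v = nd.branch.annotations.get(c)
            row.append("" if v is None else _fmt_value(v))
        rows.append(row)
    return rows


def export_table_text(tree: Tree, columns: Sequence[str]) -> str:
    return "\n".join("\t".join(r) for r in export_table(tree, columns)) + "\n"


# ---------------------------------------------------------------------------
# Name translation and search/replace
# ---------------------------------------------------------------------------

def read_translation_table(text: str) -> TranslationTable:
    """Two-column TSV, no header: old name, new name."""
    rows = {}
    for i, line in enumerate(text.splitlines()):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"translation table line {i + 1}: "
                             "expected exactly two tab-separated fields")
        if parts[0] in rows:
            raise ValueError(f"duplicate old name {parts[0]!r}")
        rows[parts[0]] = parts[1]
    return TranslationTable(rows)


def apply_translation(tree: Tree, table: TranslationTable,
                      keep_old_in: Optional[str] = None,
                      strict: bool = True) -> int:
    """Rename terminals per the table; returns the number renamed.

    With ``keep_old_in``, the old names (lab IDs) are stored in that hidden
    text column so later imports can still address terminals by them.  The
    tree is untouched if the translation would create a duplicate name.
    """
    names = {t.name for t in tree.terminals()}
    missing = sorted(set(table.rows) - names)
    if missing and strict:
        raise TreeError(f"translation keys absent from tree: {missing}")
    applicable = {k: v for k, v in table.rows.items() if k in names}
    result = {(applicable.get(n, n)) for n in names}
    if len(result) != len(names):
        raise TreeError("translation would create duplicate terminal names")
    if keep_old_in is not None and keep_old_in not in tree.columns:
        tree.declare_column(keep_old_in, HIDDEN, TEXT)
    count = 0
    for t in tree.terminals():
        if t.name in applicable:
            if keep_old_in is not None:
                tree.set_annotation(t, keep_old_in, t.name)
            t.name = applicable[t.name]
            count += 1
    tree.invalidate()
    return count


def search_replace(tree: Tree, columns: Sequence[str], pattern: str,
                   replacement: str, regex: bool = False) -> int:
    """Replace across text columns (and terminal names via the reserved id
    ``"terminal_name"``); returns the total occurrence count replaced."""
    if regex:
        try:
            rx = re.compile(pattern)
        except re.error as exc:
            raise ValueError(f"invalid regex: {exc}") from exc

    def sub(s: str):
        if regex:
            return rx.subn(replacement, s)
        n = s.count(pattern)
        return (s.replace(pattern, replacement), n) if n else (s, 0)

    total = 0
    plan = []  # (setter, new value)
    for cid in columns:
        if cid == TERMINAL_NAME_COLUMN:
            new_names = {}
            for t in tree.terminals():
                new, n = sub(t.name)
                total += n
                new_names[id(t)] = new
            if len(set(new_names.values())) != len(new_names):
                raise TreeError("replacement would create duplicate terminal names")
            for t in tree.terminals():
                plan.append((t, None, new_names[id(t)]))
            continue
        col = tree.column(cid)
        if col.value_type != TEXT:
            raise ColumnError(f"column {cid!r} is numeric; "
                              "search/replace applies to text columns only")
        for nd in tree.nodes():
            v = nd.branch.annotations.get(cid)
            if v is None:
                continue
            new, n = sub(v)
            if n:
                total += n
                plan.append((nd, cid, new))
    for nd, cid, new in plan:
        if cid is None:
            nd.name = new
        else:
            nd.branch.annotations[cid] = new
    tree.invalidate()
    return total


# ---------------------------------------------------------------------------
# JSON project format
# ---------------------------------------------------------------------------

@dataclass
class ProjectDocument:
    trees: list  # list of Tree
    render: Optional[dict] = None


def _node_to_json(node: Node) -> dict:
    d: dict = {}
    if node.name:
        d["name"] = node.name
    if node.branch.length is not None:
        d["length"] = node.branch.length
    if node.branch.annotations:
        d["annotations"] = dict(node.branch.annotations)
    if node.children:
        d["children"] = [_node_to_json(c) for c in node.children]
    return d


def _node_from_json(d: dict) -> Node:
    node = Node(d.get("name", ""),
                children=[_node_from_json(c) for c in d.get("children", [])])
    node.branch.length = d.get("length")
    node.branch.annotations = dict(d.get("annotations", {}))
    return node


def _tree_to_json(tree: Tree) -> dict:
    return {
        "name": tree.name,
        "rooting": tree.rooting,
        "columns": [
            {"id": c.id, "kind": c.kind, "value_type": c.value_type}
            for c in tree.columns.values()
        ],
        "root": _node_to_json(tree.root),
    }


def _tree_from_json(d: dict) -> Tree:
    cols = {c["id"]: AnnotationColumn(c["id"], c["kind"], c["value_type"])
            for c in d.get("columns", [])}
    tree = Tree(_node_from_json(d["root"]), cols,
                name=d.get("name", ""), rooting=d.get("rooting"))
    # re-coerce so numeric annotations survive int/float JSON ambiguity
    for nd in tree.nodes():
        for cid, v in list(nd.branch.annotations.items()):
            nd.branch.annotations[cid] = tree.coerce(cid, v)
    return tree


def save_project(trees: Union[Tree, Sequence[Tree]], file,
                 render: Optional[dict] = None) -> None:
    """Write the lossless JSON project document to a path or file object."""
    if isinstance(trees, Tree):
        trees = [trees]
    doc = {
        "format": PROJECT_FORMAT,
        "version": PROJECT_VERSION,
        "trees": [_tree_to_json(t) for t in trees],
    }
    if render is not None:
        doc["render"] = render
    if isinstance(file, (str, bytes)) or hasattr(file, "__fspath__"):
        with open(file, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    else:
        json.dump(doc, file, indent=1)
        file.write("\n")


def load_project(file) -> ProjectDocument:
    """Read a project document; errors on truncation or version mismatch."""
    if isinstance(file, str) and file.lstrip().startswith("{"):
        raw = file  # JSON content, not a path
    elif isinstance(file, (str, bytes)) or hasattr(file, "__fspath__"):
        with open(file, "r", encoding="utf-8") as fh:
            raw = fh.read()
    elif isinstance(file, io.IOBase) or hasattr(file, "read"):
        raw = file.read()
    else:
        raw = file
    try:
        doc = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise ProjectFormatError(f"not a valid project file: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != PROJECT_FORMAT:
        raise ProjectFormatError("not a treefuse project document")
    if doc.get("version") != PROJECT_VERSION:
        raise ProjectFormatError(
            f"unsupported project version: found {doc.get('version')!r}, "
            f"expected {PROJECT_VERSION}")
    trees = [_tree_from_json(d) for d in doc.get("trees", [])]
    return ProjectDocument(trees=trees, render=doc.get("render"))
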