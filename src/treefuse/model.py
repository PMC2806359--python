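"""Rooted, ordered phylogenetic tree with per-branch annotation columns.

Every non-root node owns the branch above it; the root carries a synthetic
branch so that root-level annotations are representable.  Node- and
branch-attached data are unified into one annotation map per branch, keyed
by declared column IDs.  A missing annotation is a first-class state,
distinct from numeric 0 and from empty text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "TreeError",
    "ColumnError",
    "AnnotationColumn",
    "Branch",
    "Node",
    "Tree",
    "VISIBLE",
    "HIDDEN",
    "NUMERIC",
    "TEXT",
    "TERMINAL_NAME_COLUMN",
]

VISIBLE = "visible"
HIDDEN = "hidden"
NUMERIC = "numeric"
TEXT = "text"

#: Reserved pseudo-column id addressing terminal names in search/replace.
TERMINAL_NAME_COLUMN = "terminal_name"

_ID_RE = re.compile(r"^\S+$")


class TreeError(ValueError):
    """Raised for ill-formed trees or invalid tree operations."""


class ColumnError(TreeError):
    """Raised for undeclared/duplicate columns or type mismatches."""


@dataclass
class AnnotationColumn:
    """Declaration of a per-branch data column.

    Parameters
    ----------
    id : str
        Case-sensitive identifier; nonempty, no whitespace.
    kind : str
        ``"visible"`` columns are rendered as branch labels; ``"hidden"``
        columns hold working data (lab IDs, intermediate calculations).
    value_type : str
        ``"numeric"`` (float) or ``"text"`` (str).
    """

    id: str
    kind: str = VISIBLE
    value_type: str = NUMERIC

    def __post_init__(self) -> None:
        if not _ID_RE.match(self.id):
            raise ColumnError(
                f"invalid column id {self.id!r}: must be nonempty without whitespace"
            )
        if self.kind not in (VISIBLE, HIDDEN):
            raise ColumnError(f"invalid column kind {self.kind!r}")
        if self.value_type not in (NUMERIC, TEXT):
            raise ColumnError(f"invalid column value type {self.value_type!r}")


class Branch:
    """The branch above a node: optional nonnegative length plus annotations.

    Lengths are uninterpreted (substitutions/site or time).  ``None`` means
    missing, both for the length and for any annotation lookup.
    """

    __slots__ = ("length", "annotations")

    def __init__(self, length: Optional[float] = None,
                 annotations: Optional[dict] = None):
        if length is not None and length < 0:
            raise TreeError(f"negative branch length {length}")
        self.length = length
        self.annotations: dict = dict(annotations) if annotations else {}

    def copy(self) -> "Branch":
        return Branch(self.length, dict(self.annotations))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Branch(length={self.length}, annotations={self.annotations})"


class Node:
    """A tree node.  ``name`` is nonempty iff the node is terminal."""

    __slots__ = ("name", "children", "branch", "parent")

    def __init__(self, name: str = "", children: Optional[list] = None,
                 branch: Optional[Branch] = None):
        self.name = name
        self.children: list[Node] = []
        self.branch = branch if branch is not None else Branch()
        self.parent: Optional[Node] = None
        for c in children or ():
            self.add_child(c)

    @property
    def is_terminal(self) -> bool:
        return not self.children

    def add_child(self, child: "Node", index: Optional[int] = None) -> None:
        child.parent = self
        if index is None:
            self.children.append(child)
        else:
            self.children.insert(index, child)

    def remove_child(self, child: "Node") -> int:
        idx = self.children.index(child)
        del self.children[idx]
        child.parent = None
        return idx

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def terminals(self) -> Iterator["Node"]:
        for nd in self.preorder():
            if nd.is_terminal:
                yield nd

    def copy(self) -> "Node":
        """Deep copy of the subtree rooted here (annotations included)."""
        clone = Node(self.name, branch=self.branch.copy())
        for c in self.children:
            clone.add_child(c.copy())
        return clone

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, {len(self.children)} children)"


@dataclass
class Tree:
    """Rooted, ordered tree plus its annotation-column declarations.

    Invariants enforced at construction and after every edit:

    * exactly one root; every non-root node has exactly one parent;
    * terminal names are unique;
    * annotation values conform to their declared column type.

    Child order is significant for rendering and ladderize but never affects
    leafset computations.
    """

    root: Node
    columns: dict = field(default_factory=dict)  # id -> AnnotationColumn
    name: str = ""
    rooting: Optional[str] = None  # "rooted"/"unrooted" flag from Nexus, if any

    def __post_init__(self) -> None:
        self._leafsets: dict[int, frozenset] = {}
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        seen: set[str] = set()
        for nd in self.root.preorder():
            if nd.is_terminal:
                if not nd.name:
                    raise TreeError("terminal node with empty name")
                if nd.name in seen:
                    raise TreeError(f"duplicate terminal name {nd.name!r}")
                seen.add(nd.name)
            for c in nd.children:
                if c.parent is not nd:
                    raise TreeError("broken parent link")

    def nodes(self) -> Iterator[Node]:
        return self.root.preorder()

    def terminals(self) -> list[Node]:
        return list(self.root.terminals())

    def terminal_names(self) -> frozenset:
        return self.leafset(self.root)

    @property
    def terminal_index(self) -> dict:
        return {t.name: t for t in self.root.terminals()}

    def find_terminal(self, name: str) -> Node:
        for t in self.root.terminals():
            if t.name == name:
                return t
        raise TreeError(f"no terminal named {name!r}")

    def invalidate(self) -> None:
        """Drop leafset caches; must follow any topology edit."""
        self._leafsets.clear()

    def leafset(self, node: Node) -> frozenset:
        """Set of terminal names in the subtree rooted at ``node`` (cached)."""
        cached = self._leafsets.get(id(node))
        if cached is not None:
            return cached
        if node.is_terminal:
            ls = frozenset((node.name,))
        else:
            ls = frozenset().union(*(self.leafset(c) for c in node.children))
        self._leafsets[id(node)] = ls
        return ls

    def leafset_multiset(self, include_root: bool = False) -> list:
        """Sorted list of leafsets of all non-root (optionally +root) nodes."""
        out = [self.leafset(nd) for nd in self.nodes()
               if include_root or nd is not self.root]
        return sorted(out, key=lambda s: (len(s), sorted(s)))

    # -- columns -----------------------------------------------------------

    def declare_column(self, column_id: str, kind: str = VISIBLE,
                       value_type: str = NUMERIC) -> AnnotationColumn:
        if column_id == TERMINAL_NAME_COLUMN:
            raise ColumnError(
                f"column id {column_id!r} is reserved for terminal names")
        if column_id in self.columns:
            raise ColumnError(f"column {column_id!r} already declared")
        col = AnnotationColumn(column_id, kind, value_type)
        self.columns[column_id] = col
        return col

    def column(self, column_id: str) -> AnnotationColumn:
        try:
            return self.columns[column_id]
        except KeyError:
            raise ColumnError(f"column {column_id!r} is not declared") from None

    def coerce(self, column_id: str, value):
        """Validate/convert a value against a column's declared type."""
        col = self.column(column_id)
        if value is None:
            return None
        if col.value_type == NUMERIC:
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ColumnError(
                    f"column {column_id!r} is numeric; got {value!r}")
            return float(value)
        if not isinstance(value, str):
            raise ColumnError(f"column {column_id!r} is text; got {value!r}")
        return value

    def set_annotation(self, node_or_branch, column_id: str, value) -> None:
        branch = (node_or_branch.branch if isinstance(node_or_branch, Node)
                  else node_or_branch)
        coerced = self.coerce(column_id, value)
        if coerced is None:
            branch.annotations.pop(column_id, None)
        else:
            branch.annotations[column_id] = coerced

    def get_annotation(self, node_or_branch, column_id: str):
        branch = (node_or_branch.branch if isinstance(node_or_branch, Node)
                  else node_or_branch)
        self.column(column_id)  # undeclared -> error
        return branch.annotations.get(column_id)

    # -- misc --------------------------------------------------------------

    def total_length(self) -> float:
        return sum(nd.branch.length or 0.0 for nd in self.nodes())

    def copy(self) -> "Tree":
        return Tree(self.root.copy(),
                    {k: AnnotationColumn(v.id, v.kind, v.value_type)
                     for k, v in self.columns.items()},
                    name=self.name, rooting=self.rooting)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"Tree({len(self.terminals())} terminals, "
                f"{len(self.columns)} columns)")


def leafset(tree: Tree, node: Node) -> frozenset:
    """Module-level alias for :meth:`Tree.leafset`."""
    return tree.leafset(node)
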