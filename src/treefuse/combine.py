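"""Transfer support values from source trees onto a reference topology.

Each branch of a rooted tree defines a clade — the set of terminals below
it.  For every non-trivial internal branch of the reference tree and every
source tree, the branch is classified as:

* **congruent** — the source contains a branch with the identical leafset;
  the source's support value is transferred as-is;
* **conflicting** — the source contains at least one branch whose leafset
  overlaps the reference clade without nesting either way; the *maximum*
  support among those contradictory branches is transferred;
* **unresolved** — neither of the above (the source is compatible with the
  reference branch but less resolved, e.g. a polytomy).

The conflict search proceeds in three steps: (1) find the source branch
whose subtree has the smallest number of terminals yet contains every leaf
of the reference clade (the MRCA subtree); (2) inside that subtree collect
every branch whose leafset contains at least one terminal of the reference
clade and at least one terminal outside it; (3) take the highest support
value carried by any such branch.  Restricting the scan to the covering
subtree loses nothing: any branch outside it is either an ancestor (a
superset of the reference clade) or disjoint from it.

Semantics are rooted throughout: leafsets are taken relative to the shared
root, and differently rooted inputs must be reconciled with an explicit
reroot first.  Conflict values are written to a separate ``<id>_conflict``
column so that data stay numeric; bracket/color styling is a renderer
concern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .model import NUMERIC, VISIBLE, Node, Tree, TreeError
from .treeio import SupportSpec

__all__ = [
    "CONGRUENT",
    "CONFLICTING",
    "UNRESOLVED",
    "CombineRecord",
    "SourceIndex",
    "TerminalReport",
    "check_compatible_terminals",
    "find_congruent",
    "minimal_covering_branch",
    "conflicting_branches",
    "max_conflict",
    "combine",
    "records_to_rows",
]

logger = logging.getLogger(__name__)

CONGRUENT = "congruent"
CONFLICTING = "conflicting"
UNRESOLVED = "unresolved"


@dataclass
class CombineRecord:
    """One reference branch x one source: classification and value.

    ``witness`` is the conflicting source clade that achieved the maximum
    support (``None`` unless conflicting with a value)."""

    ref_leafset: frozenset
    source_id: str
    classification: str
    value: Optional[float] = None
    witness: Optional[frozenset] = None


@dataclass
class TerminalReport:
    """Terminal-name comparison between reference and a source."""

    only_ref: list
    only_source: list

    @property
    def ok(self) -> bool:
        return not self.only_ref and not self.only_source


class SourceIndex:
    """Leafset -> (node, support value) lookup over a source tree."""

    def __init__(self, tree: Tree, support: SupportSpec):
        self.tree = tree
        self.support = support
        col = support.column_id
        if col in tree.columns and tree.columns[col].value_type != NUMERIC:
            raise TreeError(
                f"support column {col!r} of source tree is not numeric")
        self.by_leafset: dict = {}
        for nd in tree.nodes():
            if nd is tree.root:
                continue
            value = nd.branch.annotations.get(col) if col in tree.columns else None
            self.by_leafset[tree.leafset(nd)] = (nd, value)


def check_compatible_terminals(ref: Tree, source: Tree) -> TerminalReport:
    """Compare terminal-name sets; combining requires them to be equal."""
    r, s = ref.terminal_names(), source.terminal_names()
    return TerminalReport(only_ref=sorted(r - s), only_source=sorted(s - r))


def find_congruent(ref_leafset: frozenset, index: SourceIndex):
    """The unique source branch with the identical leafset, or ``None``."""
    return index.by_leafset.get(ref_leafset)


def minimal_covering_branch(ref_leafset: frozenset, source: Tree) -> Node:
    """Source node whose leafset is the smallest superset of ``ref_leafset``.

    In a rooted tree this is the most recent common ancestor of the set,
    hence unique."""
    if not ref_leafset:
        raise TreeError("empty reference leafset")
    if not ref_leafset <= source.terminal_names():
        raise TreeError("reference leafset is not a subset of source terminals")
    node = source.root
    while True:
        carrier = [c for c in node.children
                   if ref_leafset & source.leafset(c)]
        if len(carrier) == 1 and ref_leafset <= source.leafset(carrier[0]):
            node = carrier[0]
        else:
            return node


def conflicting_branches(ref_leafset: frozenset, source: Tree) -> list:
    """All source branches contradicting the reference clade, in preorder.

    A branch with leafset L contradicts reference clade R iff L and R
    overlap without nesting: L∩R ≠ ∅, L⊄R and R⊄L.  Only branches strictly
    inside the minimal covering subtree can qualify (ancestors are supersets
    of R; disjoint branches do not intersect R), so the scan is confined
    there.  Returns ``[(node, leafset), ...]``."""
    cover = minimal_covering_branch(ref_leafset, source)
    out = []
    for nd in cover.preorder():
        if nd is cover:
            continue
        ls = source.leafset(nd)
        if (ls & ref_leafset) and not (ls <= ref_leafset) \
                and not (ref_leafset <= ls):
            out.append((nd, ls))
    return out


def max_conflict(ref_leafset: frozenset, source: Tree,
                 support: SupportSpec):
    """Highest support among contradicting branches.

    Returns ``(value, witness_leafset)``; when no contradicting branch
    carries a support value, ``(None, None)``; when there is no conflict at
    all, ``None``.  Ties keep the first witness in source preorder."""
    conflicts = conflicting_branches(ref_leafset, source)
    if not conflicts:
        return None
    col = support.column_id
    has_col = col in source.columns
    best_value, best_witness = None, None
    for nd, ls in conflicts:
        v = nd.branch.annotations.get(col) if has_col else None
        if v is not None and (best_value is None or v > best_value):
            best_value, best_witness = v, ls
    return (best_value, best_witness)


def _smallest_root_child_leafset(tree: Tree) -> frozenset:
    return min((tree.leafset(c) for c in tree.root.children),
               key=lambda s: (len(s), sorted(s)))


def combine(ref: Tree, sources: Sequence, prune_to_common: bool = False):
    """Map congruent and maximum-conflicting support onto the reference tree.

    ``sources`` is a sequence of ``(id, tree, SupportSpec)``.  For each
    source, congruent values land in a numeric column named after the source
    id and conflict maxima in ``<id>_conflict``; terminal branches and the
    root are never assigned output.  Returns ``(tree, records)`` where
    ``tree`` is a new annotated copy of the reference (pruned to the common
    terminal set when ``prune_to_common`` and sets differ).

    Raises on a terminal-set mismatch unless ``prune_to_common`` is given.
    """
    from .editops import prune_terminals  # local import avoids a cycle

    ref = ref.copy()
    records: list[CombineRecord] = []

    prepared = []
    for source_id, stree, spec in sources:
        report = check_compatible_terminals(ref, stree)
        if not report.ok:
            if not prune_to_common:
                raise TreeError(
                    f"source {source_id!r} has different terminals: "
                    f"only in reference {report.only_ref}, "
                    f"only in source {report.only_source}")
            common = ref.terminal_names() & stree.terminal_names()
            if len(common) < 2:
                raise TreeError(
                    f"source {source_id!r}: common terminal set has "
                    f"{len(common)} names; nothing to combine")
            if report.only_ref:
                ref = prune_terminals(ref, set(report.only_ref))
            stree = prune_terminals(stree, stree.terminal_names() - common)
        prepared.append((source_id, stree, spec))

    all_terms = ref.terminal_names()
    internal = [nd for nd in ref.nodes()
                if nd is not ref.root and not nd.is_terminal
                and 1 < len(ref.leafset(nd)) < len(all_terms)]

    for source_id, stree, spec in prepared:
        if (_smallest_root_child_leafset(ref)
                != _smallest_root_child_leafset(stree)):
            logger.warning(
                "source %r: root's smallest child clade differs from the "
                "reference's; check that both trees are rooted consistently",
                source_id)
        index = SourceIndex(stree, spec)
        col = source_id
        col_conf = f"{source_id}_conflict"
        for cid in (col, col_conf):
            if cid not in ref.columns:
                ref.declare_column(cid, VISIBLE, NUMERIC)
        for nd in internal:
            ls = ref.leafset(nd)
            hit = find_congruent(ls, index)
            if hit is not None:
                _, value = hit
                if value is not None:
                    ref.set_annotation(nd, col, value)
                records.append(CombineRecord(ls, source_id, CONGRUENT, value))
                continue
            mc = max_conflict(ls, stree, spec)
            if mc is None:
                records.append(CombineRecord(ls, source_id, UNRESOLVED))
                continue
            value, witness = mc
            if value is not None:
                ref.set_annotation(nd, col_conf, value)
            records.append(
                CombineRecord(ls, source_id, CONFLICTING, value, witness))
    return ref, records


def records_to_rows(records: Sequence[CombineRecord]) -> list:
    """TSV-ready report rows, one per record (header included)."""
    rows = [["ref_branch", "source", "classification", "value", "witness"]]
    for r in records:
        rows.append([
            ",".join(sorted(r.ref_leafset)),
            r.source_id,
            r.classification,
            "" if r.value is None else repr(r.value)
            if not float(r.value).is_integer() else str(int(r.value)),
            "" if r.witness is None else ",".join(sorted(r.witness)),
        ])
    return rows
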