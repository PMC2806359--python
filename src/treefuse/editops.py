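"""Topology editing: reroot, ladderize, collapse, prune, subtree copy/paste.

All operations are functional — they return a new tree and leave their
input untouched — so a pipeline step can never corrupt the file it read.
Branches may be identified either by a :class:`~treefuse.model.Node`
belonging to the input tree or by the branch's leafset.

Conventions with no single field standard, fixed here: rerooting splits the
chosen edge's length 50/50 and gives *both* new root edges a copy of the
original edge's annotations (a support value describes the unrooted
bipartition, which both represent); collapsing a branch discards its
annotations (merging them into the parent has no defined semantics); nodes
suppressed while pruning have their two incident lengths summed and their
annotations discarded, with a logged count.
"""

from __future__ import annotations

import logging
from typing import Optional, Set, Union

from .model import Branch, ColumnError, Node, Tree, TreeError

__all__ = [
    "reroot",
    "ladderize",
    "collapse_branch",
    "prune_terminals",
    "copy_subtree",
    "paste_subtree",
]

logger = logging.getLogger(__name__)

BranchRef = Union[Node, frozenset, Set[str]]


def _resolve(tree: Tree, ref: BranchRef) -> Node:
    if isinstance(ref, Node):
        ref = tree.leafset(ref)
    ls = frozenset(ref)
    for nd in tree.nodes():
        if tree.leafset(nd) == ls:
            return nd
    raise TreeError(f"no branch with leafset {sorted(ls)}")


def _merge_branches(up: Branch, down: Branch) -> Branch:
    """Collapse two edges of a suppressed degree-2 node into one."""
    if up.length is None and down.length is None:
        length = None
    else:
        length = (up.length or 0.0) + (down.length or 0.0)
    ann = dict(up.annotations)
    ann.update(down.annotations)
    return Branch(length, ann)


def reroot(tree: Tree, outgroup: Union[frozenset, Set[str]]) -> Tree:
    """Place the root on the branch subtending ``outgroup``.

    ``outgroup`` must be the leafset of exactly one existing branch, or the
    complement of one (the root then goes on that same edge, outgroup side
    up).  The split edge's length is divided equally between the two new
    root children and its annotations are copied to both.  If the old root
    is left with a single child it is suppressed.
    """
    outgroup = frozenset(outgroup)
    all_terms = tree.terminal_names()
    if not outgroup or not outgroup < all_terms:
        raise TreeError("outgroup must be a proper nonempty subset of terminals")
    work = tree.copy()
    target: Optional[Node] = None
    outgroup_on_child_side = True
    for nd in work.nodes():
        if nd is work.root:
            continue
        ls = work.leafset(nd)
        if ls == outgroup:
            target = nd
            break
        if ls == all_terms - outgroup:
            target = nd
            outgroup_on_child_side = False
            break
    if target is None:
        near = minimal_cover_hint(work, outgroup)
        raise TreeError(
            f"no branch has leafset {sorted(outgroup)} (or its complement); "
            f"smallest covering clade is {sorted(near)}")

    parent = target.parent
    if parent is work.root and len(work.root.children) == 2:
        # root already sits on this edge
        return work

    # path from the split edge's parent up to the old root
    path = []
    nd = parent
    while nd is not None:
        path.append(nd)
        nd = nd.parent
    orig_branch = {id(p): p.branch for p in path}

    parent.remove_child(target)
    for i in range(len(path) - 1):
        path[i + 1].remove_child(path[i])

    split = target.branch
    half = None if split.length is None else split.length / 2.0
    target.branch = Branch(half, dict(split.annotations))
    path[0].branch = Branch(half, dict(split.annotations))

    new_root = Node("", branch=Branch())
    if outgroup_on_child_side:
        new_root.add_child(target)
        new_root.add_child(path[0])
    else:
        new_root.add_child(path[0])
        new_root.add_child(target)

    for i in range(len(path) - 1):
        path[i].add_child(path[i + 1])
        path[i + 1].branch = orig_branch[id(path[i])]

    old_root = path[-1]
    if len(old_root.children) == 1 and len(path) >= 2:
        carrier = path[-2]
        (only,) = old_root.children
        idx = carrier.remove_child(old_root)
        only.branch = _merge_branches(old_root.branch, only.branch)
        carrier.add_child(only, idx)

    return Tree(new_root, dict(work.columns), name=work.name,
                rooting=work.rooting)


def minimal_cover_hint(tree: Tree, names: frozenset) -> frozenset:
    """Leafset of the smallest clade containing ``names`` (error reporting)."""
    node = tree.root
    while True:
        carrier = [c for c in node.children if names & tree.leafset(c)]
        if len(carrier) == 1 and names <= tree.leafset(carrier[0]):
            node = carrier[0]
        else:
            return tree.leafset(node)


def ladderize(tree: Tree, direction: str = "up") -> Tree:
    """Sort every node's children by subtree terminal count; stable on ties.

    ``"up"`` sorts ascending (small clades first), ``"down"`` descending.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    work = tree.copy()
    reverse = direction == "down"
    for nd in work.nodes():
        if nd.children:
            nd.children.sort(key=lambda c: len(work.leafset(c)),
                             reverse=reverse)
    work.invalidate()
    return work


def collapse_branch(tree: Tree, branch: BranchRef) -> Tree:
    """Remove an internal non-root branch, splicing its children into its
    parent at its position (creating or extending a polytomy).  The branch's
    annotations are discarded with a logged warning."""
    work = tree.copy()
    node = _resolve(work, branch if not isinstance(branch, Node)
                    else tree.leafset(branch))
    if node is work.root:
        raise TreeError("cannot collapse the root branch")
    if node.is_terminal:
        raise TreeError(f"cannot collapse terminal branch {node.name!r}")
    if node.branch.annotations:
        logger.warning("collapsing branch %s discards %d annotation value(s)",
                       sorted(work.leafset(node)), len(node.branch.annotations))
    parent = node.parent
    idx = parent.remove_child(node)
    for i, c in enumerate(list(node.children)):
        node.remove_child(c)
        parent.add_child(c, idx + i)
    work.invalidate()
    return work


def prune_terminals(tree: Tree, names: Union[frozenset, Set[str]]) -> Tree:
    """Remove the named terminals; resulting degree-2 nodes are suppressed
    with their two incident branch lengths summed."""
    names = frozenset(names)
    if not names:
        return tree.copy()
    terms = tree.terminal_names()
    unknown = names - terms
    if unknown:
        raise TreeError(f"cannot prune unknown terminals {sorted(unknown)}")
    if len(terms - names) < 2:
        raise TreeError("pruning would leave fewer than 2 terminals")
    work = tree.copy()
    suppressed = 0

    def prune(node: Node) -> Optional[Node]:
        nonlocal suppressed
        if node.is_terminal:
            return None if node.name in names else node
        kept = []
        for c in node.children:
            r = prune(c)
            if r is not None:
                kept.append(r)
        if not kept:
            return None
        if len(kept) == 1:
            if node.branch.annotations:
                suppressed += 1
            (only,) = kept
            only.branch = _merge_branches(node.branch, only.branch)
            return only
        node.children = []
        for c in kept:
            node.add_child(c)
        return node

    new_root = prune(work.root)
    assert new_root is not None
    new_root.parent = None
    if suppressed:
        logger.info("pruning discarded annotations of %d suppressed node(s)",
                    suppressed)
    return Tree(new_root, dict(work.columns), name=work.name,
                rooting=work.rooting)


def copy_subtree(source: Tree, branch: BranchRef) -> Tree:
    """Deep-copy a clade (with all annotations) into a standalone tree; the
    source's column declarations come along."""
    node = _resolve(source, branch if not isinstance(branch, Node)
                    else source.leafset(branch))
    clone = node.copy()
    clone.branch = Branch(None, dict(node.branch.annotations))
    return Tree(clone, {k: v for k, v in source.columns.items()},
                name=source.name)


def paste_subtree(target: Tree, at_node: BranchRef, subtree: Tree,
                  length: Optional[float] = None) -> Tree:
    """Insert a copy of ``subtree`` as a new child of ``at_node``.

    The subtree's column declarations are merged into the target; a type
    clash on a shared column id is an error, as is any duplicate terminal
    name."""
    dup = target.terminal_names() & subtree.terminal_names()
    if dup:
        raise TreeError(f"paste would duplicate terminal names {sorted(dup)}")
    for cid, col in subtree.columns.items():
        if cid in target.columns:
            mine = target.columns[cid]
            if mine.value_type != col.value_type:
                raise ColumnError(
                    f"column {cid!r} is {mine.value_type} in target but "
                    f"{col.value_type} in pasted subtree")
    work = target.copy()
    at = _resolve(work, at_node if not isinstance(at_node, Node)
                  else target.leafset(at_node))
    graft = subtree.root.copy()
    graft.branch.length = length
    at.add_child(graft)
    for cid, col in subtree.columns.items():
        if cid not in work.columns:
            work.declare_column(cid, col.kind, col.value_type)
    work.invalidate()
    work.validate()
    return work
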