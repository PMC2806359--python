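"""Reproducible synthetic trees for tests, demos and fixtures.

Random rooted topologies are grown by sequential random attachment: start
from a two-terminal cherry, then repeatedly pick a random existing branch
and bisect it with a new internal node carrying the next terminal (with an
optional probability of instead attaching the terminal directly to a random
internal node, which creates polytomies).  Branch lengths are uniform on
[0.01, 1); support values are integers uniform on [0, 100], mimicking
bootstrap percentages.

Controlled incongruence comes from nearest-neighbor-interchange (NNI)
moves: each move picks a random internal edge and swaps one child of its
lower node with one sibling.  ``k`` moves on a copy of a reference tree
yield a source tree whose expected disagreement with the reference grows
with ``k``; ``k = 0`` reproduces the reference topology exactly.
"""

from __future__ import annotations

import random
from typing import Optional, Sequence

from .model import Branch, Node, Tree, VISIBLE, NUMERIC

__all__ = [
    "random_tree",
    "add_random_supports",
    "random_nni",
    "make_fixture_set",
]


def random_tree(n_taxa: int, rng: random.Random,
                names: Optional[Sequence[str]] = None,
                polytomy_prob: float = 0.0,
                with_lengths: bool = True) -> Tree:
    """Random rooted tree on ``n_taxa`` terminals (binary unless
    ``polytomy_prob`` > 0)."""
    if n_taxa < 2:
        raise ValueError("need at least 2 terminals")
    if names is None:
        names = [f"t{i}" for i in range(1, n_taxa + 1)]
    elif len(names) != n_taxa:
        raise ValueError("len(names) != n_taxa")

    def blen() -> Optional[float]:
        return round(rng.uniform(0.01, 1.0), 6) if with_lengths else None

    root = Node("", children=[Node(names[0], branch=Branch(blen())),
                              Node(names[1], branch=Branch(blen()))])
    nodes = list(root.children)  # non-root nodes, i.e. candidate edges
    internals = [root]
    for name in names[2:]:
        leaf = Node(name, branch=Branch(blen()))
        if internals and rng.random() < polytomy_prob:
            rng.choice(internals).add_child(leaf)
        else:
            edge_child = rng.choice(nodes)
            parent = edge_child.parent
            idx = parent.remove_child(edge_child)
            mid = Node("", branch=Branch(blen()))
            parent.add_child(mid, idx)
            mid.add_child(edge_child)
            mid.add_child(leaf)
            nodes.append(mid)
            internals.append(mid)
        nodes.append(leaf)
    return Tree(root)


def add_random_supports(tree: Tree, column: str, rng: random.Random,
                        low: int = 0, high: int = 100) -> Tree:
    """Attach integer supports ~ uniform[low, high] to every non-trivial
    internal branch (root and terminals excluded), in a numeric column."""
    if column not in tree.columns:
        tree.declare_column(column, VISIBLE, NUMERIC)
    n = len(tree.terminal_names())
    for nd in tree.nodes():
        if nd is tree.root or nd.is_terminal:
            continue
        if 1 < len(tree.leafset(nd)) < n:
            tree.set_annotation(nd, column, float(rng.randint(low, high)))
    return tree


def random_nni(tree: Tree, rng: random.Random, moves: int = 1) -> Tree:
    """Apply ``moves`` random NNI rearrangements to a copy of the tree.

    An eligible edge joins two internal nodes; the move exchanges a random
    child of the lower node with a random sibling across the edge.
    """
    work = tree.copy()
    for _ in range(moves):
        edges = [nd for nd in work.nodes()
                 if nd is not work.root and not nd.is_terminal
                 and nd.parent is not None and len(nd.parent.children) >= 2]
        if not edges:
            break
        lower = rng.choice(edges)
        parent = lower.parent
        siblings = [c for c in parent.children if c is not lower]
        sib = rng.choice(siblings)
        child = rng.choice(lower.children)
        si = parent.children.index(sib)
        ci = lower.children.index(child)
        parent.remove_child(sib)
        lower.remove_child(child)
        parent.add_child(child, si)
        lower.add_child(sib, ci)
        work.invalidate()
    return work


def make_fixture_set(n_taxa: int, n_trees: int, seed: int,
                     nni_moves: int = 2, polytomy_prob: float = 0.0):
    """Reference tree plus ``n_trees`` NNI-perturbed sources with supports.

    Returns ``(reference, [source, ...])``; all trees carry supports in the
    ``"label"`` column so they serialize as plain Newick internal labels.
    Fully reproducible from ``seed``.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 terminals for meaningful fixtures")
    rng = random.Random(seed)
    ref = random_tree(n_taxa, rng, polytomy_prob=polytomy_prob)
    add_random_supports(ref, "label", rng)
    sources = []
    for _ in range(n_trees):
        src = random_nni(ref, rng, moves=nni_moves)
        for nd in src.nodes():  # fresh supports for the perturbed analysis
            nd.branch.annotations.pop("label", None)
        add_random_supports(src, "label", rng)
        sources.append(src)
    return ref, sources
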