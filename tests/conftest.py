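import random

import pytest

from treefuse import Tree, add_random_supports, random_nni, random_tree


@pytest.fixture
def quartet() -> Tree:
    from treefuse import read_newick
    return read_newick("((A,B),(C,D));")


def brute_force_conflicts(ref_leafset, source: Tree):
    """Independent oracle: every source branch whose leafset overlaps the
    reference clade without nesting either way."""
    out = []
    for nd in source.nodes():
        if nd is source.root:
            continue
        ls = source.leafset(nd)
        if (ls & ref_leafset) and not (ls <= ref_leafset) \
                and not (ref_leafset <= ls):
            out.append(ls)
    return out


def unrooted_edge_lengths(tree: Tree) -> dict:
    """Bipartition -> total length, normalized to the side excluding a fixed
    reference terminal; the two root-incident half-edges merge into one."""
    all_t = tree.terminal_names()
    fix = min(all_t)
    acc: dict = {}
    for nd in tree.nodes():
        if nd is tree.root:
            continue
        ls = tree.leafset(nd)
        key = ls if fix not in ls else all_t - ls
        if not key:
            continue
        acc[key] = acc.get(key, 0.0) + (nd.branch.length or 0.0)
    return acc


def trees_equal(a: Tree, b: Tree, tol: float = 1e-9,
                check_annotations: bool = True) -> bool:
    """Rooted equality: same leafset multiset, same lengths (relative tol),
    same annotations per branch."""
    amap = {a.leafset(nd): nd for nd in a.nodes()}
    bmap = {b.leafset(nd): nd for nd in b.nodes()}
    if set(amap) != set(bmap):
        return False
    for ls, na in amap.items():
        nb = bmap[ls]
        la, lb = na.branch.length, nb.branch.length
        if (la is None) != (lb is None):
            return False
        if la is not None and abs(la - lb) > tol * max(1.0, abs(la)):
            return False
        if check_annotations and na.branch.annotations != nb.branch.annotations:
            return False
    return True


def random_pair(rng: random.Random, n_min=5, n_max=12):
    """A (reference, source) pair on shared terminals with source supports;
    mixes binary/multifurcating topologies and independent/perturbed sources."""
    n = rng.randint(n_min, n_max)
    p = rng.choice([0.0, 0.0, 0.3])
    ref = random_tree(n, rng, polytomy_prob=p)
    if rng.random() < 0.5:
        source = random_tree(n, rng, polytomy_prob=p)
    else:
        source = random_nni(ref, rng, moves=rng.randint(1, 4))
    add_random_supports(source, "label", rng)
    return ref, source
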