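import random

import pytest

from treefuse import (
    CONFLICTING,
    CONGRUENT,
    SourceIndex,
    SupportSpec,
    TreeError,
    UNRESOLVED,
    add_random_supports,
    check_compatible_terminals,
    combine,
    conflicting_branches,
    find_congruent,
    max_conflict,
    minimal_covering_branch,
    random_tree,
    read_newick,
)
from treefuse.editops import collapse_branch

from conftest import brute_force_conflicts, random_pair

LABEL = SupportSpec("internal-node-label")


class TestTerminalCheck:
    def test_same_sets_different_order_ok(self):
        a = read_newick("((A,B),(C,D));")
        b = read_newick("((D,C),(B,A));")
        assert check_compatible_terminals(a, b).ok

    def test_mismatch_reported_per_side(self):
        a = read_newick("((A,B),C);")
        b = read_newick("((A,B),D);")
        rep = check_compatible_terminals(a, b)
        assert (rep.only_ref, rep.only_source) == (["C"], ["D"])


class TestFindCongruent:
    def test_child_order_irrelevant(self):
        src = read_newick("((B,A)99,(C,D));")
        idx = SourceIndex(src, LABEL)
        node, value = find_congruent(frozenset("AB"), idx)
        assert value == 99.0

    def test_absent_leafset_gives_none(self):
        src = read_newick("((A,C),(B,D));")
        idx = SourceIndex(src, LABEL)
        assert find_congruent(frozenset("AB"), idx) is None

    def test_self_congruence_on_every_branch(self):
        rng = random.Random(7)
        t = random_tree(9, rng)
        add_random_supports(t, "label", rng)
        idx = SourceIndex(t, LABEL)
        for nd in t.nodes():
            if nd is t.root:
                continue
            hit = find_congruent(t.leafset(nd), idx)
            assert hit is not None
            assert hit[1] == nd.branch.annotations.get("label")


class TestMinimalCoveringBranch:
    def test_split_pair_covered_by_root(self):
        src = read_newick("((A,C),(B,D));")
        # brute-force: smallest leafset containing {A,B} among all nodes
        best = min((src.leafset(nd) for nd in src.nodes()
                    if src.leafset(nd) >= frozenset("AB")), key=len)
        node = minimal_covering_branch(frozenset("AB"), src)
        assert src.leafset(node) == best == frozenset("ABCD")

    def test_exact_match_is_its_own_cover(self):
        src = read_newick("((A,B),(C,D));")
        node = minimal_covering_branch(frozenset("AB"), src)
        assert src.leafset(node) == frozenset("AB")

    def test_singleton_cover_is_the_terminal(self):
        src = read_newick("((A,B),(C,D));")
        node = minimal_covering_branch(frozenset("A"), src)
        assert node.is_terminal and node.name == "A"


class TestConflictingBranches:
    def test_four_taxon_conflict_set(self):
        src = read_newick("((A,C),(B,D));")
        got = {ls for _, ls in conflicting_branches(frozenset("AB"), src)}
        assert got == set(brute_force_conflicts(frozenset("AB"), src)) \
            == {frozenset("AC"), frozenset("BD")}

    def test_congruent_case_has_empty_conflict_set(self):
        src = read_newick("((A,B),(C,D));")
        assert conflicting_branches(frozenset("AB"), src) == []

    def test_six_taxon_case_matches_oracle(self):
        src = read_newick("((A,(B,E)),((C,D),F));")
        ref = frozenset("ABC")
        got = {ls for _, ls in conflicting_branches(ref, src)}
        assert got == set(brute_force_conflicts(ref, src))

    @pytest.mark.parametrize("seed", range(60))
    def test_cover_restriction_loses_nothing(self, seed):
        """Scanning only the minimal covering subtree equals the full scan."""
        rng = random.Random(3000 + seed)
        ref, source = random_pair(rng)
        for nd in ref.nodes():
            ls = ref.leafset(nd)
            if nd is ref.root or len(ls) < 2 \
                    or len(ls) >= len(ref.terminal_names()):
                continue
            got = sorted((sorted(s) for _, s in
                          conflicting_branches(ls, source)))
            want = sorted(sorted(s) for s in
                          brute_force_conflicts(ls, source))
            assert got == want


class TestMaxConflict:
    def test_maximum_and_witness(self):
        src = read_newick("((A,C)70,(B,D)85);")
        value, witness = max_conflict(frozenset("AB"), src, LABEL)
        assert (value, witness) == (85.0, frozenset("BD"))

    def test_missing_supports_are_ignored(self):
        src = read_newick("((A,C)70,(B,D));")
        value, witness = max_conflict(frozenset("AB"), src, LABEL)
        assert (value, witness) == (70.0, frozenset("AC"))

    def test_all_missing_gives_no_value(self):
        src = read_newick("((A,C),(B,D));")
        assert max_conflict(frozenset("AB"), src, LABEL) == (None, None)

    def test_raising_a_conflict_support_never_lowers_the_max(self):
        rng = random.Random(11)
        for _ in range(30):
            ref, source = random_pair(rng)
            for nd in ref.nodes():
                ls = ref.leafset(nd)
                if nd is ref.root or len(ls) < 2 \
                        or len(ls) >= len(ref.terminal_names()):
                    continue
                conf = conflicting_branches(ls, source)
                if not conf:
                    continue
                before, _ = max_conflict(ls, source, LABEL)
                bumped, _ = rng.choice(conf)
                old = bumped.branch.annotations.get("label")
                bumped.branch.annotations["label"] = (old or 0.0) + 50.0
                after, _ = max_conflict(ls, source, LABEL)
                bumped.branch.annotations["label"] = old
                if old is None:
                    bumped.branch.annotations.pop("label")
                assert before is None or after >= before


class TestCombine:
    def test_worked_two_source_example(self):
        ref = read_newick("((A,B),(C,D));")
        s1 = read_newick("((A,B)90,(C,D)90);")
        s2 = read_newick("((A,C)70,(B,D)85);")
        out, records = combine(ref, [("s1", s1, LABEL), ("s2", s2, LABEL)])
        by_ls = {out.leafset(nd): nd for nd in out.nodes()}
        for ls in (frozenset("AB"), frozenset("CD")):
            ann = by_ls[ls].branch.annotations
            assert ann["s1"] == 90.0
            assert ann["s2_conflict"] == 85.0
            assert "s2" not in ann
        rec = {(r.source_id, tuple(sorted(r.ref_leafset))): r for r in records}
        assert rec[("s2", ("A", "B"))].witness == frozenset("BD")

    @pytest.mark.parametrize("seed", range(15))
    def test_self_map_identity(self, seed):
        """Combining a tree with itself reproduces its own supports."""
        rng = random.Random(4000 + seed)
        t = random_tree(rng.randint(5, 12), rng,
                        polytomy_prob=rng.choice([0.0, 0.3]))
        add_random_supports(t, "label", rng)
        out, records = combine(t, [("x", t, LABEL)])
        n = len(t.terminal_names())
        nontrivial = [nd for nd in t.nodes() if nd is not t.root
                      and 1 < len(t.leafset(nd)) < n]
        assert len(records) == len(nontrivial)
        assert all(r.classification == CONGRUENT for r in records)
        by_ls = {t.leafset(nd): nd for nd in t.nodes()}
        for r in records:
            assert r.value == by_ls[r.ref_leafset].branch.annotations["label"]

    def test_source_polytomy_is_unresolved(self):
        ref = read_newick("((A,B),(C,D));")
        src = read_newick("((A,B,C)77,D);")
        out, records = combine(ref, [("s", src, LABEL)])
        rec = {tuple(sorted(r.ref_leafset)): r for r in records}
        assert rec[("A", "B")].classification == UNRESOLVED
        assert rec[("A", "B")].value is None and rec[("A", "B")].witness is None
        by_ls = {out.leafset(nd): nd for nd in out.nodes()}
        ann = by_ls[frozenset("AB")].branch.annotations
        assert "s" not in ann and "s_conflict" not in ann

    def test_trichotomy_matches_oracle(self):
        """Classification is congruent iff the leafset exists in the source,
        conflicting iff the oracle set is nonempty, else unresolved."""
        rng = random.Random(5)
        for _ in range(50):
            ref, source = random_pair(rng)
            src_sets = {source.leafset(nd) for nd in source.nodes()}
            _, records = combine(ref, [("s", source, LABEL)])
            for r in records:
                oracle = brute_force_conflicts(r.ref_leafset, source)
                if r.ref_leafset in src_sets:
                    assert r.classification == CONGRUENT
                    assert not oracle  # congruence excludes conflict
                elif oracle:
                    assert r.classification == CONFLICTING
                else:
                    assert r.classification == UNRESOLVED

    def test_collapsing_source_never_creates_congruence(self):
        """Resolution monotonicity: collapsing source branches can only move
        classifications away from congruent, never toward it."""
        rank = {CONGRUENT: 0, CONFLICTING: 1, UNRESOLVED: 2}
        rng = random.Random(17)
        done = 0
        while done < 25:
            ref, source = random_pair(rng)
            collapsible = [source.leafset(nd) for nd in source.nodes()
                           if nd is not source.root and not nd.is_terminal]
            if not collapsible:
                continue
            coarser = collapse_branch(source, rng.choice(collapsible))
            _, before = combine(ref, [("s", source, LABEL)])
            _, after = combine(ref, [("s", coarser, LABEL)])
            bmap = {tuple(sorted(r.ref_leafset)): r.classification
                    for r in before}
            amap = {tuple(sorted(r.ref_leafset)): r.classification
                    for r in after}
            for key, cls_after in amap.items():
                cls_before = bmap[key]
                if cls_before == CONGRUENT:
                    assert cls_after in (CONGRUENT, UNRESOLVED)
                elif cls_before == CONFLICTING:
                    assert cls_after in (CONFLICTING, UNRESOLVED)
                assert rank[cls_after] >= 0  # trichotomy: always classified
            done += 1

    def test_terminal_and_root_branches_never_assigned(self):
        ref = read_newick("((A,B),(C,D));")
        src = read_newick("((A,C)70,(B,D)85);")
        out, _ = combine(ref, [("s", src, LABEL)])
        for nd in out.nodes():
            if nd.is_terminal or nd is out.root:
                assert "s" not in nd.branch.annotations
                assert "s_conflict" not in nd.branch.annotations

    def test_terminal_mismatch_names_the_source(self):
        ref = read_newick("((A,B),C);")
        src = read_newick("((A,B),D);")
        with pytest.raises(TreeError, match="bad_source"):
            combine(ref, [("bad_source", src, LABEL)])

    def test_prune_to_common_restricts_both_trees(self):
        ref = read_newick("(((A,B),(C,D)),E);")
        src = read_newick("((A,B)88,(C,(D,F))60);")
        out, records = combine(ref, [("s", src, LABEL)],
                               prune_to_common=True)
        assert out.terminal_names() == {"A", "B", "C", "D"}
        by_ls = {out.leafset(nd): nd for nd in out.nodes()}
        assert by_ls[frozenset("AB")].branch.annotations["s"] == 88.0

    def test_prune_to_common_with_disjoint_sets_is_error(self):
        ref = read_newick("((A,B),C);")
        src = read_newick("((X,Y),Z);")
        with pytest.raises(TreeError):
            combine(ref, [("s", src, LABEL)], prune_to_common=True)


class TestFixtureCongruence:
    def test_unperturbed_sources_fully_congruent(self):
        from treefuse import make_fixture_set
        ref, sources = make_fixture_set(10, 3, seed=42, nni_moves=0)
        for src in sources:
            _, records = combine(ref, [("s", src, LABEL)])
            by_ls = {src.leafset(nd): nd for nd in src.nodes()}
            for r in records:
                assert r.classification == CONGRUENT
                assert r.value == \
                    by_ls[r.ref_leafset].branch.annotations["label"]

    def test_perturbed_sources_show_incongruence(self):
        from treefuse import make_fixture_set
        ref, sources = make_fixture_set(12, 5, seed=42, nni_moves=8)
        non_congruent = 0
        for src in sources:
            _, records = combine(ref, [("s", src, LABEL)])
            non_congruent += sum(r.classification != CONGRUENT
                                 for r in records)
        assert non_congruent > 0
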