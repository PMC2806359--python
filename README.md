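# treefuse

Combine statistical support values from multiple phylogenetic analyses onto
one reference topology, manage per-branch annotation data, edit trees, and
render annotation-driven SVG figures — as a scriptable library and CLI.

## The problem

Modern phylogenetic studies routinely analyse the same dataset (or several
partitions of it) under several inference methods — parsimony and likelihood
bootstraps, Bayesian posterior probabilities, jackknife proportions. The
resulting trees usually agree on most of the topology but differ in how
strongly they support each clade, and occasionally contradict each other.
Preparing a publication figure then means mapping every method's support onto
the branches of one chosen topology, and — for branches a method rejects —
finding the *strongest contradictory* signal in that method's tree. Done by
eye this is laborious and error-prone; `treefuse` automates it.

## The algorithm

In a rooted tree, every branch defines a clade: the set of terminals (the
*leafset*) below it. For a reference tree *T* and a source tree *S* on the
same terminals, each non-trivial internal branch of *T* with clade *R* is
classified against *S*:

* **congruent** — some branch of *S* has exactly the leafset *R*; its support
  transfers as-is into a column named after the source;
* **conflicting** — otherwise, if *S* contains branches whose leafsets *L*
  overlap *R* without nesting (*L* ∩ *R* ≠ ∅, *L* ⊄ *R*, *R* ⊄ *L*). The
  search (1) finds the branch of *S* whose subtree is the smallest containing
  all of *R* (the MRCA subtree), (2) collects every branch inside it that
  contains at least one terminal of *R* and at least one outside *R*, and
  (3) transfers the **maximum** support over that set into a separate
  `<id>_conflict` column, recording the witnessing clade;
* **unresolved** — neither holds (the source is compatible but less resolved,
  e.g. a polytomy): both columns stay missing.

Restricting step 2 to the MRCA subtree is exact: any branch outside it is an
ancestor of *R* (a superset) or disjoint from *R*, so it can never conflict.
The test suite verifies this against a whole-tree brute-force oracle on
thousands of random tree pairs.

Around this core the package provides Newick/Nexus I/O (including
BEAST-style `[&key=value]` comment annotations), tab-separated annotation
table import/export, taxon-name translation tables with hidden lab-ID
retention, an expression engine over annotation columns (with
missing-value propagation), topology edits (reroot, ladderize, collapse,
prune, subtree copy/paste), and a deterministic SVG renderer in which any
numeric column can drive branch widths, branch colors or label text heights
through linear format mappings.

## Worked example

```python
from treefuse import read_newick, combine, SupportSpec, write_newick
from treefuse.combine import records_to_rows

ref   = read_newick("((A,B),(C,D));")
mp    = read_newick("((A,B)90,(C,D)95);")   # bootstrap tree
bayes = read_newick("((A,C)70,(B,D)85);")   # conflicting posterior tree

out, records = combine(ref, [("bs", mp, SupportSpec()),
                             ("pp", bayes, SupportSpec())])
print(write_newick(out, None, ["bs", "bs_conflict", "pp", "pp_conflict"]))
for row in records_to_rows(records):
    print("\t".join(row))
```

prints

```
((A,B)[&bs=90,pp_conflict=85],(C,D)[&bs=95,pp_conflict=85]);
ref_branch	source	classification	value	witness
A,B	bs	congruent	90
C,D	bs	congruent	95
A,B	pp	conflicting	85	B,D
C,D	pp	conflicting	85	B,D
```

The bootstrap tree matches the reference, so its values (90, 95) transfer as
congruent support. The Bayesian tree groups (A,C) and (B,D) instead; both of
its clades contradict each reference clade, and the stronger one (85, the
clade {B,D}) is reported as the maximum conflicting support — the kind of
value a figure shows in brackets next to the congruent supports. (A warning
on stderr notes that the two trees disagree near the root — a hint to check
rooting consistency before combining real data.)

The same run from the shell:

```sh
treefuse combine ref.nwk mp.nwk bayes.nwk --id bs --id pp \
         -o combined.nwk --report report.tsv
treefuse render combined.nwk --config style.json -o figure.svg
```

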