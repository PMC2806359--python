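# Methods

## Data model

A document is a rooted, ordered tree. Every non-root node owns the branch
above it; the root carries a synthetic branch so root-level annotations are
representable. Node- and branch-attached data are deliberately unified into
one annotation map per branch: the combining algorithm and the renderer
treat them identically, and keeping one map avoids an ambiguity the rooted
document model would otherwise have to resolve for every operation.

Annotation columns are declared per tree with an id (case-sensitive,
nonempty, no whitespace), a kind (`visible` columns are rendered as branch
labels, `hidden` columns hold working data such as lab IDs) and a value type
(`numeric` = float, `text` = str). **Missing is a first-class state**,
distinct from `0` and from the empty string, and it propagates through every
computation rather than being zero-filled; a column is numeric iff every
non-missing value parses as a decimal/scientific literal, which matches how
a spreadsheet import behaves without per-cell type flags.

Terminal names are unique by construction — the combining algorithm is
undefined under duplicate terminals, so duplicates are a hard error rather
than a warning. Child order is significant for rendering and ladderizing but
never enters leafset computations. Leafsets are cached per node and
invalidated by any topology edit.

## Support combining

Semantics are rooted throughout: a branch's clade is its leafset relative to
the shared root, and inputs rooted differently must be reconciled with an
explicit `reroot` first. A silent unrooted reinterpretation could mask
rooting errors in real data, so instead `combine` emits a cheap heuristic
warning when the reference and a source disagree on the leafset of the
root's smallest child clade.

For each non-trivial internal reference branch (1 < |clade| < #terminals;
terminal branches and the root are never assigned output, since terminal
clades exist in every tree and the root clade spans all terminals):

1. *Congruence*: a hash index from leafset to (branch, support) gives O(1)
   lookup of an identical clade in the source.
2. *Conflict*: the minimal covering branch — the source clade of smallest
   cardinality containing the reference clade, i.e. the MRCA subtree — is
   located by descending from the root. Every branch strictly inside it
   whose leafset both intersects and escapes the reference clade is a
   conflict. Restricting the scan to the covering subtree is provably
   exhaustive (branches outside it are ancestors, hence supersets, or
   disjoint), and the test suite re-verifies this against a whole-tree
   brute-force oracle on 1000 random pairs.
3. *Maximum*: the highest support among conflicting branches that carry one;
   on ties the witness is the first conflicting branch in source preorder
   (the value is unaffected). If no conflicting branch carries support, the
   branch is still classified conflicting, with a missing value.

Congruent values land in a numeric column named after the source id,
conflict maxima in `<id>_conflict`. Keeping conflict values in a separate
numeric column (rather than formatting them into a shared text column)
keeps the data machine-readable; brackets/colors are applied by the
renderer. Support values are never rescaled on import — mixing bootstrap
percentages and posteriors is a user decision, made explicit with an
expression such as `col("pp")*100`.

With the `prune_to_common` option both trees are restricted to their shared
terminals before combining; branches of nodes suppressed by pruning are
merged by summing lengths, and their annotations are discarded with a
logged count — transferring a support value across a suppressed path has no
defined meaning.

## Expression engine

A small infix grammar over per-branch values: `+ - * / ^` (with `^`
right-associative and binding tighter than unary minus, as in most
calculators), comparisons, `min max abs round sqrt log log10 exp if
isMissing`, constants `pi` and `e`, and `col("id")` references. Evaluation
is pure and per-branch — expressions cannot reach a neighbour's values, so
evaluation order over the tree can never matter. Any missing operand makes
the result missing except inside `isMissing` and the untaken arm of `if`;
division by zero and out-of-domain `log`/`sqrt` yield missing rather than
aborting a whole-tree calculation. `round` is half-away-from-zero (so
`round(2.5) = 3`, `round(-2.5) = -3`), matching the everyday convention
rather than banker's rounding. Text columns are not numeric operands; only
`isMissing` accepts them. The parser is a hand-written tokenizer plus
recursive-descent/Pratt parser so that errors carry exact character
positions and the formatted canonical form reparses to an identical tree.

## Edit operations

All edits are functional (input untouched, new tree returned).

* **reroot** places the root on the branch whose leafset is the outgroup
  (or its complement), splitting that edge's length 50/50 — the simplest
  defensible convention absent a field standard — and copying the edge's
  annotations to *both* new root branches, because a support value
  describes the unrooted bipartition, which both represent. An old root
  left with a single child is suppressed (lengths summed, annotation maps
  merged with the lower branch winning on clashes). Per-unrooted-edge
  lengths — root-incident halves summed — are preserved exactly, which is
  the equality rerooting can promise; per-rooted-edge lengths near the root
  necessarily redistribute.
* **ladderize** stably sorts children by subtree terminal count, both
  directions; stability keeps tied siblings in input order so the
  operation is idempotent.
* **collapse** splices a branch's children into its parent in place,
  discarding the branch's annotations with a logged warning (no merge
  semantics exist).
* **prune** removes terminals and suppresses the resulting degree-2 nodes,
  summing the two incident lengths; pruning one terminal therefore reduces
  total tree length by exactly that terminal's branch length.
* **copy/paste subtree** deep-copies clades with all annotations and merges
  column declarations, refusing type clashes and duplicate names before
  touching the target.

## Rendering

SVG 1.1, assembled from deterministic string templates so repeated renders
are byte-identical. Distances are millimeters, or DTP points converted at
exactly 25.4/72 mm/pt; document width/height are emitted in true mm with a
matching viewBox, so figures print at designed size. View modes: cladogram
(uniform unit depth per branch), phylogram (cumulative branch length),
chronogram (cumulative length with tips right-aligned and the scale bar
running right-to-left in time units). Each branch is one rectilinear path;
the root gets a short stem so a 3-taxon cladogram contains exactly 5 branch
paths. Format mappings are linear with clamping; a degenerate domain maps
everything to `out_min`; colors interpolate per RGB channel with half-up
rounding. Labels are placed above/below branch midpoints in per-branch
bands of one text height each — a documented simplification of fully
collision-free placement, sufficient to keep labels off branches. Conflict
columns are conventionally given a `("(", ")")` wrapper in their
`LabelSpec`.

Defaults (mm): line width 0.3, text height 3, tip spacing 5, cladogram
depth step 10, length scale 30 per substitution/site, root stem 2,
margin 5. These are ordinary print-figure dimensions; all are style fields.

## Synthetic data

`treefuse.simulate` grows random rooted topologies by sequential random
edge attachment (each new terminal bisects a uniformly chosen branch; an
optional polytomy probability attaches it to an internal node instead).
Branch lengths are uniform on [0.01, 1); supports are integers uniform on
[0, 100], mimicking bootstrap percentages. Controlled incongruence comes
from nearest-neighbor-interchange moves: `k` moves per derived tree, with
`k = 0` reproducing the reference exactly — so fixture sets span the range
from full congruence to heavy conflict, reproducibly from a single seed.

What this emulates — and what it does not: generated trees have uniform
random supports uncorrelated with branch length or depth, equal terminal
sets, and no rogue taxa; real analyses produce correlated supports,
missing taxa and rooting disagreements. Passing tests on these fixtures
demonstrates algorithmic correctness (the classification and maximum are
exact for any input, verified against brute force), not robustness to
upstream data pathologies, which the terminal-set check, the rooting
heuristic and strict name handling are designed to surface instead.

Problem sizes used by the test suite and the acceptance script — 1000
random pairs of 5–12-terminal trees for the oracle comparison, 100 trees
for self-combination, 200 for round trips, 100 for edit invariants — keep
the exhaustive brute-force oracle cheap while covering all topology shapes
the algorithm distinguishes (binary, multifurcating, nested/disjoint/
overlapping clades).

## Known limitations

* Rooted semantics only; users must reroot consistently before combining
  (the package warns but does not auto-reroot).
* Terminal branches never receive combine output; sources that only
  annotate cherries contribute nothing to them.
* The Nexus writer emits a TREES block without a TRANSLATE table.
* The renderer's label banding does not resolve collisions between labels
  of horizontally adjacent short branches.
* The expression engine is scalar per-branch; no aggregations across the
  tree and no user-defined functions.
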