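# Methods

This note records the model, conventions, numerical choices and known
limitations of phylokit, in the order a reader meets them: tree model,
search, metrics, manipulation, rerooting, file formats, layout, the
chi-square CDF, and the randomized-tree generator that drives the tests.

## Tree model and conventions

A phylogeny is a `Tree` (rootedness flag, identifier, name) wrapping a root
`Clade`; each clade holds an ordered list of child clades, nested
recursively, with no parent pointers and no auxiliary graph structure. The
topology is therefore a tree by construction — each clade has one implicit
parent — and any arity is legal (polytomies are first-class). All shared
methods live on a mixin inherited by both `Tree` and `Clade`, so a subtree
supports the same operations as a whole tree.

Conventions that matter and are easy to get wrong:

- **Absent vs zero branch length.** `branch_length=None` means *absent* and
  is distinct from 0; it is treated as 0 only inside depth/distance sums.
  Negative branch lengths (which occur in neighbor-joining output) are
  accepted with a `NegativeBranchLengthWarning`, never rejected.
- **Depths include the root's own branch.** `depths()` charges the root its
  own branch length (absent → 0), so a rooted tree serialized with a root
  branch keeps consistent depths. In unit mode every edge counts 1 and the
  root has depth 0.
- **Containment includes self**: `is_parent_of(root, root)` is true.
  `is_preterminal` of a terminal is false (it has no descendants at all).
- **Paths**: `get_path` excludes the start and includes the target;
  `trace(a, b)` excludes `a`, passes through the MRCA and includes `b`;
  `trace(a, a)` is empty.
- **Cascading display attributes**: color and width apply to a clade and
  all descendants unless overridden. The cascade is kept *virtual* — it is
  resolved at render time, never materialized onto descendant clades, so
  converting to a format without color loses nothing structural.

Search queries are, deliberately, exact: a string query means name
*equality*, so metacharacters in taxon names are harmless. Pattern matching
is opt-in through the separate `Regex` query type. Queries may also be
attribute mappings (all must match), predicates, or element classes, and
matching is side-effect free. `find_clades`/`find_elements` are generators:
consuming k items performs no work beyond what produces them, and
`find_any` stops traversal at the first hit.

## Manipulation semantics

- `ladderize` sorts children at every node by descendant-terminal count
  with a stable sort, ascending by default; `reverse=True` lists larger
  clades first (the conventional "staircase" display).
- `prune` removes a terminal. A non-root internal left with a single child
  is collapsed by merging branch lengths (`child += parent`), conserving
  remaining path lengths; a *root* left with a single child is replaced by
  that child, so pruning one of two leaves yields a single-node tree.
- `collapse` splices an internal clade out, adding its branch length to
  each child's, so all pairwise terminal distances are preserved (total
  branch length grows by `(arity − 1) · branch`). `collapse_all` processes
  matching internals bottom-up (reverse level order) and never touches the
  root; with no query it produces a star tree whose terminal branches equal
  the original root-to-tip depths.
- `split` appends n children named `<parent name> + "0", "1", ...`; an
  unnamed parent yields bare indices.

## Rerooting

`root_with_outgroup` places the new root at the junction of the outgroup's
branch and its former parent: the parent node *becomes* the root, the
outgroup keeps its branch length, and every edge on the path back to the
old root is reversed (keeping each edge's length — the lengths are
snapshotted first, since each reversal overwrites a value a shallower one
still needs). An old root left with one child is collapsed by summing
branch lengths. An optional `bisect=True` instead splits the outgroup's
branch in half around a fresh root node; the default is off because the
junction placement is the more common convention. The terminal name set and
all pairwise terminal distances are invariant; the old root's own
(root-edge) branch length, if any, has no representation after rerooting
and is dropped.

`root_at_midpoint` finds the maximal tip-to-tip path by exhaustive pairwise
distances (O(n²) pairs; adequate for the tree sizes this library targets),
breaking ties by lexicographic terminal-name order so the result is
deterministic, then walks the path to the edge containing the half-distance
point and reroots there. A midpoint landing exactly on an existing node
produces a zero-length branch to that node rather than reusing the node.
A tree with no branch lengths cannot be midpoint-rooted; the error suggests
unit-branch-length preprocessing. Total branch length is conserved exactly
(up to float rounding, observed < 1e-13).

## File formats

All formats go through one registry; names are explicit and
case-insensitive, and file extensions are never used for detection. `write`
never mutates its input; writing to a path truncates. One tokenizer serves
two grammars (Newick and the labels inside NEXUS).

**Newick.** One or more semicolon-terminated statements per file. The
dialect is fixed up front (no data-dependent switching): by default an
unquoted numeric *internal* label is a confidence (bootstrap convention)
while terminal labels are always names; quoted labels use single quotes
with doubled-quote escape; bracketed comments are skipped with one-plus
levels of nesting; underscores are preserved verbatim (round-trip fidelity
beats the old underscore-means-space convention, which is available as a
dialect flag). The serializer quotes minimally — only names containing
structural characters or whitespace, plus the one subtle case of a numeric
internal *name*, which must be quoted or it would re-parse as a confidence
— and prints each branch length as the shortest decimal that round-trips
(integral values print as integers). Any truncation of a valid statement is
a reported error, never a silent partial tree. Newick carries no
rootedness, so parsed trees default to unrooted.

**NEXUS.** Only the TREES block is interpreted; all other blocks are
skipped, since this toolkit is scoped to trees. TRANSLATE tokens are
substituted into terminal labels only; a leading `[&R]`/`[&U]` comment sets
the rooted flag, and the statement's name is kept on `Tree.name`. The
writer emits a single TREES block with explicit rootedness comments and no
translate table (valid per the standard and trivially round-trippable).
Keywords are case-insensitive; comments support one level of nesting
(tools disagree beyond that).

**phyloXML.** Each `<phylogeny>` requires an explicit `rooted` attribute
(a missing one is an error naming the phylogeny). Parsing streams via
`iterparse`, detaching each phylogeny element once converted, so peak
memory is bounded by the largest single phylogeny regardless of document
length. The implemented annotation types are Taxonomy (with its closed rank
vocabulary enforced at construction), MolecularSequence (alphabet
mismatches warn rather than fail), ProteinDomain — whose coordinates are
**1-based inclusive**, per the format's convention, not 0-based half-open —
DomainArchitecture, Confidence, Events, Property, Uri, Id and Accession.
Anything else (dates, distributions, foreign-namespace elements) is
preserved verbatim in `extras` and re-emitted, so third-party documents
survive a convert cycle modulo namespace normalization; repeated elements
keep document order. `branch_length` is written as an attribute and
accepted as attribute or child element. Promotion of a plain tree
(`as_phyloxml`) is lossless: a bare confidence becomes
`Confidence(value, type="unknown")`.

Conversion between formats keeps the common core — topology, names, branch
lengths, one confidence per clade — and silently narrows away annotations
the target cannot express (a count is available via logging).

## Layout and text rendering

`compute_layout` assigns x = branch-length depth (falling back to unit
lengths, with a warning, when the tree has none) and y = row index:
terminals get the integers 0..n−1 in preorder, internals the mean of their
children. `draw_ascii` scales depths into the requested column width
(auto-widening with a warning when names would not fit) and guarantees the
structural properties — one name-bearing line per terminal, in row order,
with horizontal extent proportional to depth; the specific glyphs are an
internal detail. `layout_segments` exposes the same geometry as plain
coordinate pairs for any external plotting backend, so no graphics library
is a dependency.

## Chi-square CDF

`cdf_chi2(x, df)` is the regularized lower incomplete gamma
P(df/2, x/2), implemented from first principles because the dependency-free
re-implementation is the point of the module: a power series for
x < df + 1, a modified-Lentz continued fraction otherwise, and a Lanczos
(g = 7, 9-term) log-gamma. Iterations stop at relative 1e-16 (cap 500).
Observed accuracy: ≤ 1e-15 against the df = 2 closed form 1 − e^(−x/2),
and ≤ 1e-8 against an independent numerical oracle over x ∈ [0, 50],
df ∈ 1..10; the two internal branches agree to 1e-9 in a band around their
crossover. The domain is x ≥ 0 and integer df ≥ 1 (validated; accurate to
at least df = 200). `lrt` clamps a negative statistic at 0 with a warning —
a lower alternative likelihood indicates an optimizer artifact, and the
boundary-corrected mixture distributions some model comparisons need are
out of scope.

## Randomized trees and what the tests show

`Tree.randomized` starts from a single root and repeatedly splits a
uniformly chosen terminal until the taxon count is reached, then assigns
the names in random order — a Yule-like growth process giving strictly
bifurcating trees with 2n − 1 clades and, by default, all branch lengths
equal to 1.0 (the root, having no parent edge, carries none). The RNG is
injectable and seedable, so every randomized battery in the suite is
reproducible.

The test batteries use these trees at the following sizes, chosen to probe
the combinatorics thoroughly while keeping the default run in seconds:
200 trees of 2–64 taxa (with deterministic post-edits introducing
polytomies, absent names and absent lengths) for the three-format
round-trip; 100 8-leaf trees, with uniform branch lengths on (0.05, 2),
for the distance/MRCA/monophyly oracles over all pairs and subsets of size
≤ 5; and 100 trees of 4–16 taxa for the rerooting invariants. What passing
shows: the algebraic and serialization properties hold on a broad sample
of tree shapes. What it does not show: behavior on real data's quirks —
duplicate taxon labels, zero-length and negative branches everywhere,
million-leaf files — beyond the specific cases unit tests cover, nor
performance at supertree scale, where the O(n²) midpoint pair search would
be the first thing to replace.

## Other known limitations

- No format sniffing, and no NeXML.
- No NHX: Newick comments are skipped, not interpreted.
- No unrooted/radial layout and no graph-library export.
- Rerooting on a `Clade` alone is not supported (it may need to replace the
  root); use the enclosing `Tree`.
- `find_elements` on plain (non-phyloXML) trees yields the clades
  themselves — there are no sub-elements to yield.
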