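# phylokit

A unified Python toolkit for phylogenetic trees: one object model, one I/O
API, three standard file formats.

Phylogenetic data arrives in incompatible containers — plain Newick strings
from inference programs, NEXUS files with TREES blocks and TRANSLATE tables,
and richly annotated phyloXML documents. Pipelines that mix these formats
end up with ad-hoc glue code for each one. phylokit addresses this for
people building such pipelines: every parser returns the same `Tree` object,
every `Tree` supports the same inspection and manipulation methods
regardless of where it came from, and any two formats convert with a single
call.

## What it provides

- **Tree model** — a `Tree` wraps a root `Clade`; each clade holds a branch
  length, name, confidence, display color/width and an ordered list of child
  clades, nested recursively. Trees need not be bifurcating. `Tree` and
  `Clade` share one method set (a common mixin), so the distinction between
  a tree and its root clade can usually be ignored.
- **Inspection & manipulation** — lazy traversal and search
  (`find_clades`, `find_elements`, `find_any` with name/attribute/predicate/
  regex queries), paths and ancestry (`get_path`, `trace`,
  `common_ancestor`), metrics (`depths`, `distance(a,b) = d(a) + d(b) −
  2·d(MRCA)`, `total_branch_length`), predicates (`is_bifurcating`,
  `is_monophyletic`, ...), and in-place surgery (`ladderize`, `prune`,
  `collapse`, `collapse_all`, `split`, `root_with_outgroup`,
  `root_at_midpoint`). A seeded random bifurcating tree generator
  (`Tree.randomized`) supports simulation and testing.
- **I/O** — `read`, `parse` (lazy, one tree at a time), `write`, `convert`
  and `format_tree` over a pluggable case-insensitive format registry with
  `newick`, `nexus` and `phyloxml` built in. The complete phyloXML element
  set used for clade annotation (taxonomies, molecular sequences, protein
  domains, confidences, events, properties, URIs) is modeled as Python
  classes; unrecognized elements are preserved verbatim across a convert
  cycle.
- **Visualization** — `draw_ascii` renders a rooted phylogram as text;
  `compute_layout`/`layout_segments` expose the coordinates and line
  segments for any external plotting layer.
- **Likelihood-ratio tests** — `cdf_chi2(x, df)`, a dependency-free
  chi-square CDF (regularized incomplete gamma `P(df/2, x/2)`), and
  `lrt(lnL0, lnL1, df)` returning the statistic `2·ΔlnL` and its p-value.
- **CLI** — `phylokit convert|stats|reroot|draw`, pipe-safe (`-` reads
  stdin / writes stdout), including rerooting a tree at every internal and
  external node in one command.

## Worked example

```python
import io
import phylokit as pk

tree = pk.read(io.StringIO("((A:1,B:2)X:3,(C:4,D:5)Y:6)R:0;"), "newick")
print(tree.count_terminals(), tree.total_branch_length(), tree.distance("A", "D"))

tree.root_at_midpoint()
print(pk.format_tree(tree, "newick").strip())
pk.draw_ascii(tree, column_width=46)
```

prints

```
4 21.0 15.0
((C:4,D:5)Y:3,(A:1,B:2)X:6);
                |_____________________ C
|________________
|               |__________________________ D
_
|                               |_____ A
|________________________________
                                |__________ B
```

The tree has 4 terminals, total branch length 21 and a path of length 15
between tips A and D. The two most distant tips (B and D, 16 apart) become
equidistant after midpoint rooting: the root lands on the branch above
clade Y, splitting its length 6 into 3 + 3, so both deepest tips sit at
depth 8.

A likelihood-ratio test between nested models with log-likelihoods
−1002.1 (null) and −1000.0 (alternative), one extra parameter:

```python
result = pk.lrt(-1002.1, -1000.0, 1)
print(result.statistic, round(result.p_value, 6))   # 4.2 0.040424
```

The statistic 2·(−1000.0 − (−1002.1)) = 4.2 exceeds the 5% chi-square
critical value for df = 1 (3.84), so the null is rejected at that level.

From the shell:

```sh
$ phylokit stats t1.nwk newick          # terminals, total length, bifurcating
4 21 true
$ phylokit reroot t1.nwk newick --all-nodes | wc -l   # one tree per node
7
```

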