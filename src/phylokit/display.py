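"""Text rendering and 2-D layout of rooted phylograms.

A phylogram draws branch lengths to scale: the x coordinate of a clade is
its cumulative branch-length depth, and terminal rows are evenly spaced
integers with internal rows at the mean of their children.  The same layout
drives both the ASCII-art renderer and the plotting adapter
(:func:`layout_segments`), which emits plain coordinates and line segments
so any external graphics layer can draw the tree without this module
depending on one.
"""

from __future__ import annotations

import sys
import warnings

from .treemodel import _postorder


class LayoutWarning(UserWarning):
    pass


def compute_layout(tree, unit_branch_lengths=False):
    """Map each clade to ``(x, y)`` drawing coordinates.

    x is the clade's branch-length depth (monotone non-decreasing from root
    to tip along every path); terminal y values are the distinct integers
    0..n-1 in preorder, and each internal y is the mean of its children's.
    A tree without branch lengths falls back to unit branch lengths, with a
    warning.
    """
    depths = tree.depths(unit_branch_lengths=unit_branch_lengths)
    if not unit_branch_lengths and max(depths.values()) <= 0 and len(depths) > 1:
        warnings.warn(
            "tree has no branch lengths; using unit branch lengths for layout",
            LayoutWarning,
            stacklevel=2,
        )
        depths = tree.depths(unit_branch_lengths=True)
    ys = {}
    for i, leaf in enumerate(tree.get_terminals()):
        ys[leaf] = float(i)
    for clade in _postorder(tree.root):
        if clade.clades:
            ys[clade] = sum(ys[c] for c in clade.clades) / len(clade.clades)
    return {clade: (depths[clade], ys[clade]) for clade in depths}


def layout_segments(tree, unit_branch_lengths=False):
    """Plotting adapter: the layout plus horizontal/vertical line segments.

    Returns ``(layout, segments)`` where each segment is a pair of (x, y)
    endpoints: one horizontal segment per branch and one vertical connector
    per internal clade.  Suitable for feeding directly to a 2-D graphics
    library.
    """
    layout = compute_layout(tree, unit_branch_lengths)
    segments = []

    def walk(clade, parent_x):
        x, y = layout[clade]
        segments.append(((parent_x, y), (x, y)))
        if clade.clades:
            child_ys = [layout[c][1] for c in clade.clades]
            segments.append(((x, min(child_ys)), (x, max(child_ys))))
            for child in clade.clades:
                walk(child, x)

    root_x = layout[tree.root][0]
    walk(tree.root, 0.0 if root_x > 0 else root_x)
    return layout, segments


def draw_ascii(tree, file=None, column_width=80):
    """Draw an ASCII-art phylogram of the given tree.

    Exactly one output line carries each terminal's name, ordered top to
    bottom by row; the horizontal extent of each tip is proportional to its
    depth, scaled into ``column_width`` columns.  A column width too narrow
    for the names triggers a warning and is widened automatically.  The
    output always ends with a newline.
    """
    if file is None:
        file = sys.stdout
    layout = compute_layout(tree)
    terminals = tree.get_terminals()
    longest = max((len(leaf.name or "") for leaf in terminals), default=0)
    minimum = 2 * longest + 4
    if column_width < minimum:
        warnings.warn(
            f"column_width {column_width} too narrow for names; widening to {minimum}",
            LayoutWarning,
            stacklevel=2,
        )
        column_width = minimum
    drawing_width = max(column_width - longest - 2, 4)
    max_depth = max(x for x, _ in layout.values())
    scale = (drawing_width - 1) / max_depth if max_depth > 0 else 0.0

    def col(clade):
        return int(round(layout[clade][0] * scale))

    def row(clade):
        return int(round(2 * layout[clade][1]))

    n_rows = max(row(leaf) for leaf in terminals) + 1 if terminals else 1
    grid = [[" "] * (drawing_width + 2) for _ in range(n_rows)]

    def hline(r, c0, c1):
        for c in range(max(c0, 0), c1 + 1):
            grid[r][c] = "_"

    def vline(c, r0, r1):
        for r in range(r0, r1 + 1):
            if grid[r][c] == " ":
                grid[r][c] = "|"

    # horizontal branch of the root itself (may be zero-length)
    hline(row(tree.root), 0, col(tree.root))
    stack = [tree.root]
    while stack:
        clade = stack.pop()
        if clade.clades:
            child_rows = [row(c) for c in clade.clades]
            vline(col(clade), min(child_rows), max(child_rows))
            for child in clade.clades:
                hline(row(child), col(clade) + 1, col(child))
                stack.append(child)
    lines = ["".join(cells).rstrip() for cells in grid]
    for leaf in terminals:
        r = row(leaf)
        pad = col(leaf) + 1 - len(lines[r])
        lines[r] = lines[r] + " " * max(pad, 0) + " " + (leaf.name or "")
    file.write("\n".join(lines) + "\n")


def tree_repr(tree, max_depth=None):
    """Indented text showing the nested object hierarchy of a tree.

    Each line names an element type and its set attributes; absent
    attributes are not printed.  ``max_depth`` truncates deeper levels with
    an ellipsis marker.
    """
    from .treemodel import Tree

    lines = []
    if isinstance(tree, Tree):
        lines.append(repr(tree))
        root = tree.root
    else:
        root = tree
    indent = "    "

    def walk(clade, depth):
        lines.append(indent * (depth + 1) + repr(clade))
        if clade.clades:
            if max_depth is not None and depth + 1 > max_depth:
                lines.append(indent * (depth + 2) + "...")
            else:
                for child in clade.clades:
                    walk(child, depth + 1)

    walk(root, 0)
    return "\n".join(lines)
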