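"""Format-independent phylogenetic tree objects and manipulation methods.

The object model is deliberately plain: a :class:`Tree` wraps a root
:class:`Clade`, and each clade holds an ordered list of child clades, nested
recursively.  There is no auxiliary graph structure and no parent pointers;
every clade has (implicitly) a single parent, so the topology is a tree, never
a network.  Trees are not required to be bifurcating — any arity is legal.

All inspection and manipulation methods live on :class:`TreeMixin`, shared by
``Tree`` and ``Clade``, so in practice the distinction between the whole tree
and its root clade can usually be ignored.
"""

from __future__ import annotations

import copy
import random
import re
import warnings
from collections import deque


class TreeError(ValueError):
    """A structural operation on a tree could not be carried out."""


class NotInTreeError(TreeError):
    """A concrete clade passed as a target is not part of this tree."""


class NegativeBranchLengthWarning(UserWarning):
    """Negative branch lengths occur in e.g. neighbor-joining output.

    They are accepted, with this warning, rather than rejected.
    """


_SENTINEL = object()


# ---------------------------------------------------------------------------
# Branch color

class BranchColor:
    """RGB color of a branch, with 0-255 integer channels.

    Color (like branch width) applies to a clade and all of its descendants
    unless a descendant overrides it — the "cascading" convention used by
    phyloXML-aware viewers.
    """

    #: A small palette of standard HTML color names.
    color_names = {
        "black": (0, 0, 0), "white": (255, 255, 255),
        "red": (255, 0, 0), "green": (0, 128, 0), "blue": (0, 0, 255),
        "lime": (0, 255, 0), "yellow": (255, 255, 0), "fuchsia": (255, 0, 255),
        "magenta": (255, 0, 255), "aqua": (0, 255, 255), "cyan": (0, 255, 255),
        "gray": (128, 128, 128), "grey": (128, 128, 128),
        "silver": (192, 192, 192), "maroon": (128, 0, 0),
        "olive": (128, 128, 0), "navy": (0, 0, 128), "purple": (128, 0, 128),
        "teal": (0, 128, 128), "orange": (255, 165, 0),
        "salmon": (250, 128, 114), "pink": (255, 192, 203),
        "brown": (165, 42, 42), "gold": (255, 215, 0),
    }

    def __init__(self, red, green, blue):
        for channel, value in (("red", red), ("green", green), ("blue", blue)):
            if not isinstance(value, int) or not 0 <= value <= 255:
                raise ValueError(
                    f"{channel} channel must be an integer in [0, 255], got {value!r}"
                )
        self.red = red
        self.green = green
        self.blue = blue

    @classmethod
    def from_name(cls, name):
        try:
            return cls(*cls.color_names[name.lower()])
        except KeyError:
            raise ValueError(f"unknown color name {name!r}") from None

    @classmethod
    def from_hex(cls, hexstr):
        if not re.fullmatch(r"#[0-9a-fA-F]{6}", hexstr):
            raise ValueError(f"invalid hex color {hexstr!r}")
        return cls(*(int(hexstr[i:i + 2], 16) for i in (1, 3, 5)))

    def to_hex(self):
        return f"#{self.red:02x}{self.green:02x}{self.blue:02x}"

    def to_rgb(self):
        return (self.red, self.green, self.blue)

    def __eq__(self, other):
        if not isinstance(other, BranchColor):
            return NotImplemented
        return self.to_rgb() == other.to_rgb()

    def __hash__(self):
        return hash(self.to_rgb())

    def __repr__(self):
        return f"BranchColor({self.red}, {self.green}, {self.blue})"


def _as_color(value):
    if value is None or isinstance(value, BranchColor):
        return value
    if isinstance(value, str):
        if value.startswith("#"):
            return BranchColor.from_hex(value)
        return BranchColor.from_name(value)
    if isinstance(value, (tuple, list)) and len(value) == 3:
        return BranchColor(*value)
    raise ValueError(f"cannot interpret {value!r} as a branch color")


# ---------------------------------------------------------------------------
# Queries

class Regex:
    """Query matching an element attribute against a regular expression.

    The default string query uses exact name equality (metacharacters in
    taxon names are then harmless); use this wrapper for pattern matching.
    The pattern is applied with :func:`re.search`.
    """

    def __init__(self, pattern, attr="name"):
        self.pattern = re.compile(pattern)
        self.attr = attr

    def __call__(self, element):
        value = getattr(element, self.attr, None)
        return value is not None and bool(self.pattern.search(str(value)))

    def __repr__(self):
        return f"Regex({self.pattern.pattern!r}, attr={self.attr!r})"


def _attribute_predicate(key, want):
    def check(element):
        got = getattr(element, key, _SENTINEL)
        if got is _SENTINEL:
            return False
        if isinstance(want, Regex):
            return want(element)
        if callable(want) and not isinstance(want, type):
            return bool(want(got))
        return got == want
    return check


def compile_query(query=None, attrs=None):
    """Turn a query (name, attribute mapping, predicate, or class) into a
    deterministic, side-effect-free predicate over tree elements."""
    attrs = dict(attrs or {})
    predicates = []
    if query is not None:
        if isinstance(query, str):
            q = query
            predicates.append(lambda e: getattr(e, "name", None) == q)
        elif isinstance(query, type):
            cls = query
            predicates.append(lambda e: isinstance(e, cls))
        elif isinstance(query, dict):
            attrs = {**query, **attrs}
        elif callable(query):
            predicates.append(query)
        else:
            raise TypeError(
                f"query must be a name, mapping, predicate or class, not {type(query).__name__}"
            )
    for key, want in attrs.items():
        predicates.append(_attribute_predicate(key, want))
    if not predicates:
        return lambda element: True
    if len(predicates) == 1:
        return predicates[0]
    return lambda element: all(p(element) for p in predicates)


# ---------------------------------------------------------------------------
# Traversal

def _preorder(root):
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(node.clades))


def _postorder(root):
    # iterative two-phase: (node, expanded?)
    stack = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            yield node
        else:
            stack.append((node, True))
            stack.extend((c, False) for c in reversed(node.clades))


def _levelorder(root):
    queue = deque([root])
    while queue:
        node = queue.popleft()
        yield node
        queue.extend(node.clades)


_ORDERS = {
    "preorder": _preorder,
    "postorder": _postorder,
    "level": _levelorder,
    "level-order": _levelorder,
}


def _get_traversal(order):
    try:
        return _ORDERS[order]
    except KeyError:
        valid = ", ".join(sorted(set(_ORDERS) - {"level-order"}))
        raise ValueError(f"unknown traversal order {order!r}; valid orders: {valid}") from None


# ---------------------------------------------------------------------------
# Shared tree methods

class TreeMixin:
    """Inspection and manipulation methods shared by Tree and Clade."""

    # -- search -----------------------------------------------------------

    def find_clades(self, query=None, terminal=None, order="preorder", **attrs):
        """Yield each clade containing an element matching the query.

        Traversal is lazy (a generator): consuming ``k`` items does no work
        beyond what is needed to produce them.  ``terminal`` restricts the
        result to leaves (True) or internal clades (False).
        """
        traverse = _get_traversal(order)
        match = compile_query(query, attrs)

        def generate():
            for clade in traverse(self.root):
                if terminal is not None and clade.is_terminal() != terminal:
                    continue
                if any(match(el) for el in clade._iter_elements()):
                    yield clade

        return generate()

    def find_elements(self, query=None, terminal=None, order="preorder", **attrs):
        """Yield every matching element (clades and their annotations).

        On plain trees the elements of a clade are the clade itself, so the
        result coincides with :meth:`find_clades`; richly annotated clades
        also expose their sub-elements (taxonomies, sequences, ...).
        """
        traverse = _get_traversal(order)
        match = compile_query(query, attrs)

        def generate():
            for clade in traverse(self.root):
                if terminal is not None and clade.is_terminal() != terminal:
                    continue
                for element in clade._iter_elements():
                    if match(element):
                        yield element

        return generate()

    def find_any(self, query=None, terminal=None, order="preorder", **attrs):
        """First element matching the query, or None; traversal stops at the
        first hit, so no further work is performed."""
        return next(self.find_elements(query, terminal, order, **attrs), None)

    # -- target resolution -------------------------------------------------

    def _resolve(self, target, **attrs):
        """Return the clade designated by ``target`` (a clade or a query)."""
        if isinstance(target, Tree):
            target = target.root
        if isinstance(target, Clade):
            return target
        clade = next(self.find_clades(target, **attrs), None)
        if clade is None:
            raise TreeError(f"no clade matching query {target!r}")
        return clade

    # -- paths and ancestry ------------------------------------------------

    def get_path(self, target=None, **attrs):
        """Clades directly between this root and the target, excluding the
        start, including the target as last element (empty if the target is
        the root itself)."""
        root = self.root
        if isinstance(target, Tree):
            target = target.root
        if isinstance(target, Clade):
            goal = target
            match = lambda c: c is goal  # identity, never attribute equality
            missing = NotInTreeError("target clade is not in this tree")
        else:
            match = compile_query(target, attrs)
            missing = TreeError(f"no clade matching query {target!r}")
        stack = [(root, [])]
        while stack:
            node, path = stack.pop()
            if match(node):
                return path
            for child in reversed(node.clades):
                stack.append((child, path + [child]))
        raise missing

    def trace(self, start, finish):
        """Clades on the path from ``start`` to ``finish``, excluding the
        start, passing through their common ancestor, including the end."""
        a = self._resolve(start)
        b = self._resolve(finish)
        if a is b:
            return []
        mrca = self.common_ancestor(a, b)
        from_start = mrca.get_path(a)[-2::-1]
        to_finish = mrca.get_path(b)
        return from_start + [mrca] + to_finish

    def common_ancestor(self, targets, *more_targets):
        """Most recent common ancestor of all the given targets.

        A single target is its own MRCA.
        """
        if isinstance(targets, (list, tuple, set, frozenset)) or (
            not isinstance(targets, (Clade, Tree, str, dict))
            and hasattr(targets, "__iter__")
        ):
            all_targets = list(targets) + list(more_targets)
        else:
            all_targets = [targets, *more_targets]
        if not all_targets:
            raise TreeError("common_ancestor requires at least one target")
        paths = [self.get_path(self._resolve(t)) for t in all_targets]
        mrca = self.root
        for level in zip(*paths):
            first = level[0]
            if all(other is first for other in level[1:]):
                mrca = first
            else:
                break
        return mrca

    # -- basic information -------------------------------------------------

    def get_terminals(self, order="preorder"):
        """All leaf clades, in traversal order (preorder by default)."""
        return list(self.find_clades(terminal=True, order=order))

    def get_nonterminals(self, order="preorder"):
        """All internal clades, in traversal order (preorder by default)."""
        return list(self.find_clades(terminal=False, order=order))

    def count_terminals(self):
        return sum(1 for _ in self.find_clades(terminal=True))

    def depths(self, unit_branch_lengths=False):
        """Map each clade to its depth: the sum of branch lengths from (and
        including) the root's own branch down to the clade's branch.

        Absent branch lengths count as 0.  With ``unit_branch_lengths`` every
        edge counts 1 and the root has depth 0.
        """
        if unit_branch_lengths:
            root_depth = 0
            edge = lambda c: 1
        else:
            root_depth = self.root.branch_length or 0
            edge = lambda c: c.branch_length or 0
        result = {}
        stack = [(self.root, root_depth)]
        while stack:
            node, depth = stack.pop()
            result[node] = depth
            stack.extend((child, depth + edge(child)) for child in node.clades)
        return result

    def distance(self, target1, target2):
        """Sum of branch lengths on the path between two targets."""
        a = self._resolve(target1)
        b = self._resolve(target2)
        depths = self.depths()
        mrca = self.common_ancestor(a, b)
        return depths[a] + depths[b] - 2 * depths[mrca]

    def total_branch_length(self):
        """Sum of all branch lengths in the tree (absent lengths count 0)."""
        return sum(clade.branch_length or 0 for clade in self.find_clades())

    # -- predicates --------------------------------------------------------

    def is_bifurcating(self):
        """True iff every internal clade has exactly two children."""
        return all(
            len(clade.clades) == 2 for clade in self.find_clades(terminal=False)
        )

    def is_monophyletic(self, terminals, *more_terminals):
        """If the given terminals comprise a complete subclade, return their
        MRCA; otherwise return False."""
        if isinstance(terminals, (list, tuple, set, frozenset)):
            targets = list(terminals) + list(more_terminals)
        else:
            targets = [terminals, *more_terminals]
        clades = {self._resolve(t) for t in targets}
        mrca = self.common_ancestor(clades)
        if set(mrca.get_terminals()) == clades:
            return mrca
        return False

    def is_parent_of(self, target=None, **attrs):
        """True if the target is contained in this tree (self included)."""
        if isinstance(target, Tree):
            target = target.root
        if isinstance(target, Clade):
            try:
                self.get_path(target)
                return True
            except NotInTreeError:
                return False
        return next(self.find_clades(target, **attrs), None) is not None

    def is_preterminal(self):
        """True if all direct descendants are terminal (False for a leaf)."""
        root = self.root
        if root.is_terminal():
            return False
        return all(child.is_terminal() for child in root.clades)

    def is_terminal(self):
        """True if this clade has no descendants."""
        return not self.root.clades

    # -- manipulation ------------------------------------------------------

    def ladderize(self, reverse=False):
        """Sort children at every clade, in place, by number of descendant
        terminals — ascending by default, descending with ``reverse``.  The
        sort is stable, so ties keep their original order."""
        counts = {}
        for clade in _postorder(self.root):
            if clade.is_terminal():
                counts[clade] = 1
            else:
                counts[clade] = sum(counts[c] for c in clade.clades)
        for clade in self.find_clades(terminal=False):
            clade.clades.sort(key=counts.__getitem__, reverse=reverse)

    def prune(self, target=None, **attrs):
        """Remove a terminal clade from the tree; return its former parent.

        A non-root internal clade left with a single child is collapsed, the
        child's branch length absorbing the parent's, so remaining path
        lengths are conserved.  A root left with a single child is replaced
        by that child.
        """
        target = self._resolve(target, **attrs)
        if not target.is_terminal():
            raise TreeError("cannot prune a non-terminal clade")
        path = self.get_path(target)
        if not path:
            raise TreeError("cannot prune the root clade")
        parent = path[-2] if len(path) >= 2 else self.root
        parent.clades.remove(target)
        if len(parent.clades) == 1:
            if parent is self.root:
                # move the root down onto the lone remaining child
                new_root = parent.clades[0]
                new_root.branch_length = None
                if isinstance(self, Tree):
                    self.root = new_root
                else:
                    raise TreeError(
                        "pruning left the root clade with one child; "
                        "prune from the enclosing Tree to allow root replacement"
                    )
            else:
                child = parent.clades[0]
                if parent.branch_length is not None:
                    child.branch_length = (child.branch_length or 0) + parent.branch_length
                grandparent = path[-3] if len(path) >= 3 else self.root
                grandparent.clades[grandparent.clades.index(parent)] = child
        return parent

    def collapse(self, target=None, **attrs):
        """Delete an internal clade, relinking its children to its parent.

        Each child's branch length grows by the collapsed clade's, so all
        pairwise terminal distances are preserved.
        """
        target = self._resolve(target, **attrs)
        if target.is_terminal():
            raise TreeError("cannot collapse a terminal clade")
        path = self.get_path(target)
        if not path:
            raise TreeError("cannot collapse the root clade")
        parent = path[-2] if len(path) >= 2 else self.root
        for child in target.clades:
            if target.branch_length is not None:
                child.branch_length = (child.branch_length or 0) + target.branch_length
        index = parent.clades.index(target)
        parent.clades[index:index + 1] = target.clades

    def collapse_all(self, target=None, **attrs):
        """Collapse every matching internal clade (all of them when no query
        is given), processed bottom-up; the root is never collapsed."""
        match = compile_query(target, attrs)
        # snapshot in reverse level order, excluding the root, so children
        # are collapsed before their parents
        candidates = list(self.find_clades(order="level"))[:0:-1]
        for clade in candidates:
            if clade.is_terminal():
                continue
            if match(clade):
                self.collapse(clade)

    def split(self, n=2, branch_length=1.0):
        """Give this clade ``n`` new children with the given branch length.

        Children are named after the parent with an appended index
        ("X0", "X1", ...); an unnamed parent uses the bare index.
        """
        root = self.root
        prefix = root.name or ""
        cls = type(root)
        for i in range(n):
            root.clades.append(
                cls(branch_length=branch_length, name=f"{prefix}{i}")
            )


# ---------------------------------------------------------------------------

class Clade(TreeMixin):
    """A node of a phylogenetic tree together with all its descendants.

    Attributes
    ----------
    branch_length : float or None
        Length of the branch leading to this clade (substitutions/site or
        arbitrary units).  ``None`` means *absent*, which is distinct from 0
        and treated as 0 only inside depth/distance sums.
    name : str or None
    confidence : float or None
        Support for this clade, e.g. a bootstrap percentage.
    color, width
        Display attributes; both apply to this clade and all descendants
        unless overridden (cascading).
    clades : list of Clade
        Ordered children; empty for a terminal.
    """

    def __init__(self, branch_length=None, name=None, clades=None,
                 confidence=None, color=None, width=None):
        self.branch_length = branch_length
        self.name = name
        self.clades = list(clades) if clades else []
        self.confidence = confidence
        self.color = color
        self.width = width
        if branch_length is not None and branch_length < 0:
            warnings.warn(
                f"negative branch length {branch_length} on clade {name!r}",
                NegativeBranchLengthWarning,
                stacklevel=2,
            )

    @property
    def root(self):
        return self

    @property
    def color(self):
        return self._color

    @color.setter
    def color(self, value):
        self._color = _as_color(value)

    def _iter_elements(self):
        yield self

    # container-like conveniences over the children
    def __iter__(self):
        return iter(self.clades)

    def __len__(self):
        return len(self.clades)

    def __getitem__(self, index):
        if isinstance(index, (int, slice)):
            return self.clades[index]
        # allow nested indexing with a tuple of child indices
        clade = self
        for i in index:
            clade = clade.clades[i]
        return clade

    def __bool__(self):
        return True

    def __repr__(self):
        parts = []
        if self.branch_length is not None:
            parts.append(f"branch_length={self.branch_length!r}")
        if self.name is not None:
            parts.append(f"name={self.name!r}")
        if self.confidence is not None:
            parts.append(f"confidence={self.confidence!r}")
        return f"{type(self).__name__}({', '.join(parts)})"

    def __str__(self):
        return self.name if self.name else repr(self)


class Tree(TreeMixin):
    """A complete phylogeny: a root :class:`Clade` plus global information
    (rootedness, an identifier and a name)."""

    def __init__(self, root=None, rooted=False, id=None, name=None):
        self.root = root if root is not None else Clade()
        self.rooted = rooted
        self.id = id
        self.name = name

    @property
    def clade(self):
        """The root clade (convenience alias)."""
        return self.root

    # -- construction ------------------------------------------------------

    @classmethod
    def from_clade(cls, clade, **kwargs):
        """New tree around a deep copy of ``clade``; mutating the result
        leaves the source untouched."""
        return cls(root=copy.deepcopy(clade), **kwargs)

    @classmethod
    def randomized(cls, taxa, branch_length=1.0, seed=None, rng=None):
        """Random strictly-bifurcating tree over the given taxa.

        Starts from a single root and repeatedly splits a uniformly chosen
        terminal until the taxon count is reached, then assigns the taxon
        names to the terminals in random order.  All branch lengths equal
        ``branch_length`` (the root, having no parent edge, has none).
        Deterministic for a fixed ``seed``; alternatively an existing
        ``random.Random`` may be injected via ``rng``.
        """
        if isinstance(taxa, int):
            names = [f"taxon{i}" for i in range(1, taxa + 1)]
        else:
            names = list(taxa)
        if not names:
            raise ValueError("at least one taxon is required")
        if rng is None:
            rng = random.Random(seed)
        root = Clade()
        terminals = [root]
        while len(terminals) < len(names):
            index = rng.randrange(len(terminals))
            node = terminals.pop(index)
            node.clades = [
                Clade(branch_length=branch_length),
                Clade(branch_length=branch_length),
            ]
            terminals.extend(node.clades)
        shuffled = names[:]
        rng.shuffle(shuffled)
        tree = cls(root=root)
        for clade, name in zip(tree.get_terminals(), shuffled):
            clade.name = name
        return tree

    # -- rerooting ---------------------------------------------------------

    def root_with_outgroup(self, outgroup, *more_targets, bisect=False):
        """Reroot the tree at the given outgroup clade, in place.

        The new root is placed at the junction of the outgroup's branch and
        its former parent: the parent becomes the root, the outgroup keeps
        its branch length, and edges on the path back to the old root are
        reversed.  An old root left with a single child is collapsed (branch
        lengths summed).  With ``bisect=True`` the outgroup's branch is
        instead split in half and a fresh root node placed at its middle.

        Terminal names and all pairwise terminal distances are invariant.
        """
        if more_targets:
            outgroup_clade = self.common_ancestor(outgroup, *more_targets)
        elif isinstance(outgroup, (list, tuple, set, frozenset)):
            outgroup_clade = self.common_ancestor(outgroup)
        else:
            outgroup_clade = self._resolve(outgroup)
        if outgroup_clade is self.root:
            self.rooted = True
            return
        if bisect:
            half = (outgroup_clade.branch_length or 0) / 2.0
            self._reroot_on_branch(outgroup_clade, half)
            return
        path = [self.root] + self.get_path(outgroup_clade)
        new_root = path[-2]
        if new_root is self.root:
            self.rooted = True
            return
        self._reverse_path(path[:-1])
        new_root.branch_length = None
        old_root = path[0]
        if len(old_root.clades) == 1:
            self._absorb_single_child(old_root, path[1])
        self.root = new_root
        self.rooted = True

    @staticmethod
    def _reverse_path(path):
        # path runs old-root -> ... -> new attachment point; flip each edge
        # so former parents hang beneath their former children, keeping the
        # connecting edge's length.  Original lengths are snapshotted first:
        # each reversal overwrites a length a shallower reversal still needs.
        lengths = [node.branch_length for node in path]
        for i in range(len(path) - 1, 0, -1):
            parent, child = path[i - 1], path[i]
            parent.clades.remove(child)
            child.clades.append(parent)
            parent.branch_length = lengths[i]

    @staticmethod
    def _absorb_single_child(node, holder):
        # replace `node` (which has exactly one child) inside `holder` by
        # its child, summing branch lengths so path lengths are conserved
        lone = node.clades[0]
        lone.branch_length = (lone.branch_length or 0) + (node.branch_length or 0)
        holder.clades[holder.clades.index(node)] = lone

    def _reroot_on_branch(self, clade, length_below_root):
        """Place a new root on the branch leading to ``clade``, so that the
        clade retains ``length_below_root`` of its branch."""
        path = [self.root] + self.get_path(clade)
        parent = path[-2]
        remainder = (clade.branch_length or 0) - length_below_root
        parent.clades.remove(clade)
        clade.branch_length = length_below_root
        self._reverse_path(path[:-1])
        parent.branch_length = remainder
        new_root = type(path[0])()
        new_root.clades = [clade, parent]
        if len(path) >= 3 and len(path[0].clades) == 1:
            self._absorb_single_child(path[0], path[1])
        if len(parent.clades) == 1:
            self._absorb_single_child(parent, new_root)
        self.root = new_root
        self.rooted = True

    def root_at_midpoint(self):
        """Reroot at the midpoint of the path between the two most distant
        terminals, in place.

        Ties between maximal pairs are broken by lexicographic terminal-name
        order.  A midpoint falling exactly on an existing node yields a
        zero-length branch to that node.  Total branch length is conserved.
        """
        terminals = self.get_terminals()
        if len(terminals) < 2:
            self.rooted = True
            return
        depths = self.depths()
        best = None  # (distance, name-key, pair)
        for i, p in enumerate(terminals):
            for q in terminals[i + 1:]:
                mrca = self.common_ancestor(p, q)
                d = depths[p] + depths[q] - 2 * depths[mrca]
                key = tuple(sorted((p.name or "", q.name or "")))
                if best is None or d > best[0] or (d == best[0] and key < best[1]):
                    best = (d, key, (p, q))
        max_distance, _, (p, q) = best
        if max_distance <= 0:
            raise TreeError(
                "tree has no branch lengths; assign unit branch lengths "
                "(e.g. via depths(unit_branch_lengths=True)) before midpoint rooting"
            )
        if (q.name or "") < (p.name or ""):
            p, q = q, p
        half = max_distance / 2.0
        path = [p] + self.trace(p, q)
        # cumulative distance from p at each node; the edge between two
        # consecutive path nodes is the branch of whichever one is the child
        cumulative = [0.0]
        for u, v in zip(path, path[1:]):
            if self._is_child(u, v):          # v is u's parent: edge is u's branch
                weight = u.branch_length or 0
            else:                             # v is u's child: edge is v's branch
                weight = v.branch_length or 0
            cumulative.append(cumulative[-1] + weight)
        for i in range(1, len(path)):
            if cumulative[i] >= half - 1e-12:
                u, v = path[i - 1], path[i]
                if self._is_child(v, u):      # downward edge: v is the child
                    child = v
                    below = cumulative[i] - half
                else:                         # upward edge: u is the child
                    child = u
                    below = half - cumulative[i - 1]
                below = min(max(below, 0.0), child.branch_length or 0)
                self._reroot_on_branch(child, below)
                return
        raise TreeError("midpoint not found on the maximal path")  # pragma: no cover

    @staticmethod
    def _is_child(a, b):
        """True if ``a`` is a direct child of ``b``."""
        return any(c is a for c in b.clades)

    # -- conversion conveniences (thin wrappers over the I/O layer) --------

    def format(self, fmt):
        """Serialize this tree as a string in the given file format."""
        from . import io_core
        return io_core.format_tree(self, fmt)

    def as_phyloxml(self):
        """Promote to the annotation-rich phyloXML tree class."""
        from . import phyloxml_io
        return phyloxml_io.as_phyloxml(self)

    def __repr__(self):
        parts = []
        if self.name is not None:
            parts.append(f"name={self.name!r}")
        if self.id is not None:
            parts.append(f"id={self.id!r}")
        parts.append(f"rooted={self.rooted!r}")
        return f"{type(self).__name__}({', '.join(parts)})"

    def __str__(self):
        from . import display
        return display.tree_repr(self)
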