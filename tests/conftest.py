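"""Shared fixtures and independent brute-force oracles."""

import io

import pytest

import phylokit as pk

T1_NEWICK = "((A:1,B:2)X:3,(C:4,D:5)Y:6)R:0;"
T2_NEWICK = "((A:1,B:1)X:1,C:1)R;"


def read_newick(text):
    return pk.read(io.StringIO(text), "newick")


@pytest.fixture
def t1():
    return read_newick(T1_NEWICK)


@pytest.fixture
def t2():
    return read_newick(T2_NEWICK)


# ---------------------------------------------------------------------------
# structural comparison

def clades_equal(a, b, tol=0.0):
    if a.name != b.name:
        return False
    if (a.branch_length is None) != (b.branch_length is None):
        return False
    if a.branch_length is not None:
        if tol == 0.0:
            if a.branch_length != b.branch_length:
                return False
        elif abs(a.branch_length - b.branch_length) > tol:
            return False
    if a.confidence != b.confidence:
        return False
    if len(a.clades) != len(b.clades):
        return False
    return all(clades_equal(x, y, tol) for x, y in zip(a.clades, b.clades))


def trees_equal(a, b, tol=0.0):
    return clades_equal(a.root, b.root, tol)


# ---------------------------------------------------------------------------
# brute-force oracles, independent of the TreeMixin implementations

def parent_map(tree):
    parents = {}
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for child in node.clades:
            parents[id(child)] = node
            stack.append(child)
    return parents


def path_to_root(tree, clade, parents):
    path = [clade]
    while id(path[-1]) in parents:
        path.append(parents[id(path[-1])])
    return path


def brute_mrca(tree, clades):
    """MRCA by intersecting root-ward paths — no tree methods involved."""
    parents = parent_map(tree)
    paths = [path_to_root(tree, c, parents) for c in clades]
    common = set(id(n) for n in paths[0])
    for p in paths[1:]:
        common &= set(id(n) for n in p)
    # deepest common node = first on any root-ward path
    for node in paths[0]:
        if id(node) in common:
            return node
    raise AssertionError("disconnected tree")


def brute_distance(tree, a, b):
    """Path-length sum between two clades via explicit root-ward paths."""
    parents = parent_map(tree)
    mrca = brute_mrca(tree, [a, b])
    total = 0.0
    for leaf in (a, b):
        node = leaf
        while node is not mrca:
            total += node.branch_length or 0
            node = parents[id(node)]
    return total


def subtree_leaves(clade):
    """Terminal clades of a subtree by plain recursion."""
    if not clade.clades:
        return [clade]
    out = []
    for child in clade.clades:
        out.extend(subtree_leaves(child))
    return out


def brute_is_monophyletic(tree, leaves):
    """True iff some clade's terminal set equals the given set exactly."""
    target = set(id(x) for x in leaves)
    stack = [tree.root]
    while stack:
        node = stack.pop()
        if set(id(x) for x in subtree_leaves(node)) == target:
            return node
        stack.extend(node.clades)
    return False


def random_weighted_tree(n, seed):
    """Seeded random bifurcating tree with varied branch lengths."""
    import random

    rng = random.Random(seed)
    tree = pk.Tree.randomized(n, rng=rng)
    for clade in tree.find_clades():
        if clade is not tree.root:
            clade.branch_length = round(rng.uniform(0.05, 2.0), 6)
    return tree
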