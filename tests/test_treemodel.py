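"""Unit tests for the tree object model and its manipulation methods."""

import io

import pytest

import phylokit as pk
from phylokit.treemodel import Clade, NotInTreeError, Tree, TreeError

from conftest import T1_NEWICK, read_newick, trees_equal


def names(clades):
    return [c.name for c in clades]


class TestSearch:
    def test_find_clades_by_name(self, t1):
        assert names(t1.find_clades(name="C")) == ["C"]

    def test_find_clades_terminal_filter_preorder(self, t1):
        assert names(t1.find_clades(terminal=True)) == ["A", "B", "C", "D"]
        assert names(t1.find_clades(terminal=False)) == ["R", "X", "Y"]

    def test_find_clades_no_match_on_single_node(self):
        tree = read_newick("A;")
        assert list(tree.find_clades(name="Z")) == []

    def test_find_clades_unknown_order_names_valid_set(self, t1):
        with pytest.raises(ValueError, match="preorder.*"):
            t1.find_clades(order="inorder")

    @pytest.mark.parametrize("order,expected", [
        ("preorder", ["R", "X", "A", "B", "Y", "C", "D"]),
        ("postorder", ["A", "B", "X", "C", "D", "Y", "R"]),
        ("level", ["R", "X", "Y", "A", "B", "C", "D"]),
    ])
    def test_traversal_orders(self, t1, order, expected):
        assert names(t1.find_clades(order=order)) == expected

    def test_find_clades_is_lazy(self, t1):
        seen = []

        def probe(clade):
            seen.append(clade)
            return True

        gen = t1.find_clades(probe)
        assert not seen  # nothing evaluated before consumption
        first = next(gen)
        assert first.name == "R"
        assert len(seen) == 1

    def test_find_elements_coincides_with_find_clades_on_plain_tree(self, t1):
        assert list(t1.find_elements(name="X")) == list(t1.find_clades(name="X"))

    def test_find_elements_empty_query_yields_every_element(self, t1):
        elements = list(t1.find_elements())
        assert len(elements) >= sum(1 for _ in t1.find_clades())

    def test_find_any(self, t1):
        assert t1.find_any(name="D").name == "D"
        assert t1.find_any(name="Z") is None
        assert t1.find_any().name == "R"  # preorder first element

    def test_find_any_stops_at_first_hit(self, t1):
        calls = []

        def probe(clade):
            calls.append(clade)
            return clade.name == "X"

        assert t1.find_any(probe).name == "X"
        assert names(calls) == ["R", "X"]

    def test_query_kinds(self, t1):
        # attribute mapping: every condition must match
        assert names(t1.find_clades({"name": "Y", "branch_length": 6.0})) == ["Y"]
        assert names(t1.find_clades({"name": "Y", "branch_length": 1.0})) == []
        # predicate
        assert names(t1.find_clades(lambda c: (c.branch_length or 0) > 4)) == ["Y", "D"]
        # class restriction
        assert len(list(t1.find_clades(Clade))) == 7
        # regex (explicit; plain strings are exact name equality)
        assert names(t1.find_clades(pk.Regex("^[AB]$"))) == ["A", "B"]
        assert names(t1.find_clades("A|B")) == []  # not a regex by default

    def test_callable_attribute_values(self, t1):
        hits = t1.find_clades(branch_length=lambda bl: bl is not None and bl >= 4)
        assert names(hits) == ["Y", "C", "D"]


class TestPathsAndAncestry:
    def test_get_path(self, t1):
        d = t1.find_any(name="D")
        assert names(t1.get_path(d)) == ["Y", "D"]
        assert t1.get_path(t1.root) == []
        x = t1.find_any(name="X")
        assert names(x.get_path("B")) == ["B"]

    def test_get_path_errors_distinguish_clade_from_query(self, t1):
        foreign = Clade(name="D")  # same name, different object
        with pytest.raises(NotInTreeError):
            t1.get_path(foreign)
        with pytest.raises(TreeError) as err:
            t1.get_path("nope")
        assert not isinstance(err.value, NotInTreeError)

    def test_trace(self, t1):
        assert names(t1.trace("A", "D")) == ["X", "R", "Y", "D"]
        assert names(t1.trace("A", "B")) == ["X", "B"]
        assert t1.trace("A", "A") == []

    def test_common_ancestor(self, t1):
        assert t1.common_ancestor("A", "B").name == "X"
        assert t1.common_ancestor({"A", "D"}).name == "R"
        assert t1.common_ancestor(["C"]).name == "C"  # singleton is its own MRCA

    def test_common_ancestor_unresolvable_target(self, t1):
        with pytest.raises(TreeError):
            t1.common_ancestor("A", "nope")


class TestBasicInformation:
    def test_get_terminals(self, t1):
        assert names(t1.get_terminals()) == ["A", "B", "C", "D"]
        assert names(read_newick("A;").get_terminals()) == ["A"]
        y = t1.find_any(name="Y")
        assert names(y.get_terminals()) == ["C", "D"]

    def test_get_nonterminals(self, t1):
        assert names(t1.get_nonterminals()) == ["R", "X", "Y"]
        assert read_newick("A;").get_nonterminals() == []

    def test_terminal_nonterminal_partition(self, t1):
        total = sum(1 for _ in t1.find_clades())
        assert len(t1.get_terminals()) + len(t1.get_nonterminals()) == total

    def test_count_terminals(self, t1):
        assert t1.count_terminals() == 4
        assert read_newick("A;").count_terminals() == 1
        assert t1.count_terminals() == len(t1.get_terminals())

    def test_depths_by_branch_length(self, t1):
        expected = {"R": 0, "X": 3, "A": 4, "B": 5, "Y": 6, "C": 10, "D": 11}
        assert {c.name: d for c, d in t1.depths().items()} == expected

    def test_depths_unit_mode(self, t1):
        expected = {"R": 0, "X": 1, "A": 2, "B": 2, "Y": 1, "C": 2, "D": 2}
        assert {c.name: d for c, d in t1.depths(unit_branch_lengths=True).items()} == expected

    def test_depths_single_node(self):
        tree = read_newick("A;")
        assert list(tree.depths().values()) == [0]

    def test_distance(self, t1):
        assert t1.distance("A", "D") == 15
        assert t1.distance("A", "B") == 3
        assert t1.distance("A", "A") == 0

    def test_total_branch_length(self, t1):
        assert t1.total_branch_length() == 21
        assert read_newick("(A,(B,C));").total_branch_length() == 0
        t1.ladderize(reverse=True)
        assert t1.total_branch_length() == 21  # invariant under reordering


class TestPredicates:
    def test_is_bifurcating(self, t1):
        assert t1.is_bifurcating()
        assert not read_newick("(A,B,C);").is_bifurcating()
        assert read_newick("A;").is_bifurcating()  # no internals at all

    def test_is_monophyletic(self, t1):
        cd = [t1.find_any(name=n) for n in "CD"]
        assert t1.is_monophyletic(cd).name == "Y"
        ac = [t1.find_any(name=n) for n in "AC"]
        assert t1.is_monophyletic(ac) is False
        every = t1.get_terminals()
        assert t1.is_monophyletic(every).name == "R"

    def test_is_parent_of(self, t1):
        assert t1.is_parent_of(t1.find_any(name="D"))
        x = t1.find_any(name="X")
        assert not x.is_parent_of(t1.find_any(name="C"))
        assert t1.is_parent_of(t1.root)  # containment includes self

    def test_is_preterminal(self, t1):
        assert t1.find_any(name="X").is_preterminal()
        assert not t1.is_preterminal()  # root of T1 has internal children
        assert not t1.find_any(name="A").is_preterminal()  # a leaf is not

    def test_is_terminal(self, t1):
        assert t1.find_any(name="A").is_terminal()
        assert not t1.find_any(name="X").is_terminal()
        assert read_newick("A;").is_terminal()


class TestManipulation:
    def test_ladderize_ascending_default(self, t2):
        t2.ladderize()
        assert names(t2.root.clades) == ["C", "X"]

    def test_ladderize_reverse(self, t2):
        t2.ladderize(reverse=True)
        assert names(t2.root.clades) == ["X", "C"]

    def test_ladderize_stable_on_ties(self, t1):
        before = pk.format_tree(t1, "newick")
        t1.ladderize()
        assert pk.format_tree(t1, "newick") == before

    def test_prune_collapses_single_child_internal(self, t1):
        parent = t1.prune("B")
        assert parent.name == "X"
        assert trees_equal(t1, read_newick("(A:4,(C:4,D:5)Y:6)R:0;"))
        assert t1.total_branch_length() == 19

    def test_prune_last_sibling_promotes_root(self):
        tree = read_newick("(A:1,B:1);")
        tree.prune("B")
        assert tree.root.name == "A"
        assert tree.root.is_terminal()

    def test_prune_rejects_internal(self, t1):
        with pytest.raises(TreeError):
            t1.prune("X")

    def test_prune_decrements_terminal_count(self, t1):
        before = t1.count_terminals()
        t1.prune("C")
        assert t1.count_terminals() == before - 1

    def test_collapse(self, t1):
        a, c = t1.find_any(name="A"), t1.find_any(name="C")
        before = t1.distance(a, c)
        t1.collapse("X")
        assert names(t1.root.clades) == ["A", "B", "Y"]
        assert [cl.branch_length for cl in t1.root.clades] == [4, 5, 6]
        assert t1.distance(a, c) == before == 14  # path conservation

    def test_collapse_root_is_an_error(self, t1):
        with pytest.raises(TreeError):
            t1.collapse(t1.root)

    def test_collapse_all_yields_star(self, t1):
        t1.collapse_all()
        assert trees_equal(t1, read_newick("(A:4,B:5,C:10,D:11)R:0;"))

    def test_collapse_all_with_query(self):
        tree = read_newick("((A:1,B:1)30:1,(C:1,D:1)90:1);")
        tree.collapse_all(lambda c: c.confidence is not None and c.confidence < 50)
        assert sum(1 for _ in tree.find_clades(terminal=False)) == 2  # one collapsed

    def test_collapse_all_on_star_is_noop(self):
        tree = read_newick("(A:1,B:2,C:3);")
        before = pk.format_tree(tree, "newick")
        tree.collapse_all()
        assert pk.format_tree(tree, "newick") == before

    def test_split(self, t1):
        d = t1.find_any(name="D")
        d.split()
        assert t1.count_terminals() == 5
        assert names(d.clades) == ["D0", "D1"]
        assert [c.branch_length for c in d.clades] == [1.0, 1.0]

    def test_split_n3(self, t1):
        t1.find_any(name="D").split(n=3)
        assert t1.count_terminals() == 6

    def test_split_unnamed_parent_uses_bare_index(self):
        tree = read_newick("(A,B);")
        tree.root.split(n=2, branch_length=0.5)
        # appended alongside existing children, named by bare index
        assert names(tree.root.clades)[-2:] == ["0", "1"]


class TestRerooting:
    def test_outgroup_rerooting_matches_hand_derivation(self, t1):
        t1.root_with_outgroup("C")
        assert names(t1.root.clades) == ["C", "D", "X"]
        assert [c.branch_length for c in t1.root.clades] == [4, 5, 9]
        assert names(t1.find_any(name="X").clades) == ["A", "B"]
        assert t1.rooted

    def test_outgroup_rerooting_preserves_distances(self, t1):
        t1.root_with_outgroup("C")
        assert t1.distance("A", "C") == 14

    def test_outgroup_rerooting_idempotent(self, t1):
        t1.root_with_outgroup("C")
        once = pk.format_tree(t1, "newick")
        t1.root_with_outgroup("C")
        assert pk.format_tree(t1, "newick") == once

    def test_outgroup_not_found(self, t1):
        with pytest.raises(TreeError):
            t1.root_with_outgroup("ZZZ")

    def test_outgroup_bisect_option(self, t1):
        t1.root_with_outgroup("C", bisect=True)
        c = t1.find_any(name="C")
        assert c.branch_length == 2  # half of 4 on each side
        assert c in t1.root.clades
        assert t1.distance("A", "C") == 14

    def test_midpoint_rooting_matches_hand_derivation(self, t1):
        t1.root_at_midpoint()
        assert names(t1.root.clades) == ["Y", "X"]
        assert [c.branch_length for c in t1.root.clades] == [3, 6]
        depths = {c.name: d for c, d in t1.depths().items()}
        assert depths["B"] == depths["D"] == 8
        assert t1.total_branch_length() == 21
        assert t1.rooted

    def test_midpoint_requires_branch_lengths(self):
        tree = read_newick("((A,B),(C,D));")
        with pytest.raises(TreeError, match="unit branch lengths"):
            tree.root_at_midpoint()


class TestConstruction:
    def test_from_clade_copies(self, t1):
        sub = Tree.from_clade(t1.find_any(name="X"))
        assert names(sub.get_terminals()) == ["A", "B"]
        sub.find_any(name="A").name = "renamed"
        assert t1.find_any(name="A") is not None  # source untouched

    def test_from_clade_of_root_reproduces_tree(self, t1):
        assert trees_equal(Tree.from_clade(t1.root), t1)

    def test_randomized_counts(self):
        tree = Tree.randomized(3, seed=7)
        assert tree.count_terminals() == 3
        assert sum(1 for _ in tree.find_clades()) == 5
        assert tree.is_bifurcating()

    def test_randomized_single_taxon(self):
        tree = Tree.randomized(["only"], seed=0)
        assert tree.root.is_terminal() and tree.root.name == "only"

    def test_randomized_uses_given_taxa_and_is_deterministic(self):
        taxa = ["w", "x", "y", "z"]
        a = Tree.randomized(taxa, seed=3)
        b = Tree.randomized(taxa, seed=3)
        assert sorted(names(a.get_terminals())) == sorted(taxa)
        assert pk.format_tree(a, "newick") == pk.format_tree(b, "newick")


class TestBranchColor:
    def test_channel_validation(self):
        with pytest.raises(ValueError):
            pk.BranchColor(256, 0, 0)
        with pytest.raises(ValueError):
            pk.BranchColor(-1, 0, 0)

    def test_equality_and_conversions(self):
        assert pk.BranchColor(255, 0, 255) == pk.BranchColor.from_name("fuchsia")
        assert pk.BranchColor.from_hex("#ff00ff").to_hex() == "#ff00ff"

    def test_clade_color_coercion(self):
        clade = Clade(name="A", color="blue")
        assert clade.color == pk.BranchColor(0, 0, 255)


def test_negative_branch_length_warns_but_is_accepted():
    with pytest.warns(pk.NegativeBranchLengthWarning):
        clade = Clade(branch_length=-0.5, name="nj")
    assert clade.branch_length == -0.5
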