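"""Topology representation, edit operations, enumeration and guide trees."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from spliceforest import (
    GeneTree,
    Topology,
    TreeShape,
    branch_swap,
    build_guide_tree,
    canonical_key,
    enumerate_topologies,
    is_valid,
    make_caterpillar,
    remove_edge,
)
from spliceforest.simulate import enumerate_all_topologies
from spliceforest.topology import shape_deaths, shape_span


def spanning(tree):
    return TreeShape(tree.root, tuple(tree.leaves))


class TestShapes:
    def test_span_is_union_of_root_leaf_paths(self, cat3):
        s = TreeShape("a2", ("g1", "g3"))
        assert shape_span(cat3, s) == {"a2", "a1", "g1", "g3"}

    def test_deaths_count_missing_children(self, cat3):
        # root -> g3 and root -> a1 -> g1: a1 misses its g2 child
        s = TreeShape("a2", ("g1", "g3"))
        assert shape_deaths(cat3, s) == 1
        assert shape_deaths(cat3, spanning(cat3)) == 0

    def test_leaf_outside_root_subtree_rejected(self, cat3):
        with pytest.raises(ValueError):
            shape_span(cat3, TreeShape("a1", ("g3",)))


class TestEditOperations:
    def test_remove_edge_adds_tree_and_death(self, cherry):
        topo = Topology(cherry, [spanning(cherry)])
        out = remove_edge(topo, 0, "D")
        assert out.n_tree == topo.n_tree + 1
        assert out.n_death == topo.n_death + 1
        assert {s.root for s in out.trees} == {"A", "D"}

    def test_remove_both_root_links_gives_three_trees_two_deaths(self, cherry):
        topo = Topology(cherry, [spanning(cherry)])
        one = remove_edge(topo, 0, "D")
        # the remnant A(-,E) would become childless: removal refused
        rem_idx = next(
            i for i, s in enumerate(one.trees) if s.root == "A"
        )
        with pytest.raises(ValueError):
            remove_edge(one, rem_idx, "E")

    def test_remove_missing_link_is_error(self, cherry):
        topo = Topology(cherry, [TreeShape("D", ("D",)), TreeShape("A", ("E",))])
        with pytest.raises(ValueError):
            remove_edge(topo, 0, "D")  # single-node tree has no link

    def test_swap_with_itself_is_identity(self, cherry):
        topo = Topology(cherry, [spanning(cherry)])
        assert canonical_key(branch_swap(topo, (0, "D"), (0, "D"))) == \
            canonical_key(topo)

    def test_swap_of_shape_symmetric_links_preserves_key(self, cherry):
        topo = Topology(cherry, [spanning(cherry), spanning(cherry)])
        out = branch_swap(topo, (0, "D"), (1, "D"))
        assert canonical_key(out) == canonical_key(topo)

    def test_swap_produces_new_shape(self, cherry):
        t1 = spanning(cherry)
        t2 = spanning(cherry)
        topo = Topology(cherry, [t1, t2])
        # swapping a D-subtree against an E-subtree is not allowed (different
        # genes); swapping D-subtrees between distinct-shape trees changes key
        topo2 = Topology(
            cherry, [spanning(cherry), TreeShape("A", ("D",)),
                     TreeShape("E", ("E",))]
        )
        out = branch_swap(topo2, (0, "D"), (1, "D"))
        assert canonical_key(out) == canonical_key(topo2)  # same shapes swap
        with pytest.raises(ValueError):
            branch_swap(topo2, (0, "D"), (0, "E"))

    def test_swap_closure_stays_within_level(self, cherry):
        level = [
            t for t in enumerate_topologies(cherry, {"D": 2, "E": 2})
        ]
        keys = {t.canonical_key for t in level}
        for topo in level:
            links = [
                (i, child)
                for i, s in enumerate(topo.trees)
                for child in topo.spans[i]
                if child != s.root and topo.gene_tree.parent(child) in topo.spans[i]
            ]
            for l1, l2 in itertools.combinations(links, 2):
                if l1[1] != l2[1]:
                    continue
                out = branch_swap(topo, l1, l2)
                if out.n_tree == topo.n_tree and is_valid(out):
                    assert out.canonical_key in keys


class TestValidity:
    def test_spanning_tree_is_valid(self, cherry):
        assert is_valid(Topology(cherry, [spanning(cherry)]))

    def test_uncovered_root_gene_is_invalid(self, cherry):
        topo = Topology(cherry, [TreeShape("D", ("D",)), TreeShape("E", ("E",))])
        assert not is_valid(topo)

    def test_newborn_leaf_without_spanned_edge_is_invalid(self, cherry):
        # the right gene hosts a slot but no link reaches it: the gene graph
        # is disconnected, mirroring the requirement that all genes be linked
        topo = Topology(cherry, [TreeShape("A", ("D",)), TreeShape("E", ("E",))])
        assert not is_valid(topo)


class TestCanonicalKey:
    def test_key_ignores_tree_order(self, cherry):
        a = Topology(cherry, [TreeShape("A", ("D",)), TreeShape("A", ("E",))])
        b = Topology(cherry, [TreeShape("A", ("E",)), TreeShape("A", ("D",))])
        assert canonical_key(a) == canonical_key(b)

    def test_extra_death_changes_key(self, cherry):
        a = Topology(cherry, [spanning(cherry)])
        b = Topology(cherry, [TreeShape("A", ("D", "E")), TreeShape("A", ("D",)),
                              TreeShape("E", ("E",))])
        assert canonical_key(a) != canonical_key(b)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.permutations(range(4)))
    def test_key_invariant_under_any_permutation(self, perm):
        tree = make_caterpillar(3)
        shapes = [
            TreeShape("a2", ("g1", "g2", "g3")),
            TreeShape("a2", ("g1", "g3")),
            TreeShape("a1", ("g2",)),
            TreeShape("g1", ("g1",)),
        ]
        base = Topology(tree, shapes)
        permuted = Topology(tree, [shapes[i] for i in perm])
        assert canonical_key(base) == canonical_key(permuted)


class TestEnumeration:
    @pytest.mark.parametrize(
        "leaf_counts",
        [{"D": 1, "E": 1}, {"D": 2, "E": 1}, {"D": 2, "E": 2}],
    )
    def test_stream_equals_independent_enumerator_on_cherry(
        self, cherry, leaf_counts
    ):
        stream = {t.canonical_key for t in enumerate_topologies(cherry, leaf_counts)}
        indep = {
            t.canonical_key
            for t in enumerate_all_topologies(cherry, leaf_counts)
        }
        assert stream == indep

    @pytest.mark.parametrize(
        "leaf_counts",
        [
            {"g1": 1, "g2": 1, "g3": 1},
            {"g1": 2, "g2": 1, "g3": 2},
            {"g1": 2, "g2": 2, "g3": 2},
        ],
    )
    def test_stream_equals_independent_enumerator_on_caterpillar(
        self, cat3, leaf_counts
    ):
        stream = {t.canonical_key for t in enumerate_topologies(cat3, leaf_counts)}
        indep = {
            t.canonical_key for t in enumerate_all_topologies(cat3, leaf_counts)
        }
        assert stream == indep

    def test_no_duplicate_keys_and_increasing_tree_count(self, cat3):
        seen = set()
        last_t = 0
        for topo in enumerate_topologies(cat3, {"g1": 2, "g2": 1, "g3": 1}):
            assert topo.canonical_key not in seen
            seen.add(topo.canonical_key)
            assert topo.n_tree >= last_t
            last_t = topo.n_tree

    def test_counts_recomputable_from_structure(self, cat3):
        for topo in enumerate_topologies(cat3, {"g1": 2, "g2": 2, "g3": 1}):
            assert topo.n_tree == len(topo.trees)
            assert topo.n_death == sum(
                shape_deaths(cat3, s) for s in topo.trees
            )
            assert topo.leaf_counts() == {"g1": 2, "g2": 2, "g3": 1}

    def test_stream_ends_at_total_transcript_count(self, cherry):
        topos = list(enumerate_topologies(cherry, {"D": 1, "E": 1}))
        assert max(t.n_tree for t in topos) <= 2

    def test_max_trees_bound_respected(self, cat3):
        topos = list(
            enumerate_topologies(cat3, {"g1": 2, "g2": 2, "g3": 2}, max_trees=3)
        )
        assert topos and all(t.n_tree <= 3 for t in topos)


class TestGuideTree:
    def test_fig_style_boxes_and_dot_counts(self):
        tree = GeneTree.from_newick("((D,E)B,(F,G)C)A;")
        topo = Topology(tree, [
            TreeShape("A", ("D", "E", "F", "G")),
            TreeShape("A", ("D", "F")),
            TreeShape("B", ("D",)),
            TreeShape("C", ("F",)),
            TreeShape("E", ("E",)),
            TreeShape("G", ("G",)),
        ])
        guide = build_guide_tree(topo)
        assert guide.boxes["B"] == {("D", "E"): 1, ("D",): 2}
        assert guide.boxes["C"] == {("F", "G"): 1, ("F",): 2}
        assert guide.slot_count("B") == 3

    def test_identical_shapes_share_one_box(self, cherry):
        topo = Topology(cherry, [spanning(cherry), spanning(cherry)])
        guide = build_guide_tree(topo)
        assert guide.boxes["A"] == {("D", "E"): 2}

    def test_leaf_gene_has_single_leaf_box(self, cherry):
        topo = Topology(cherry, [spanning(cherry), TreeShape("D", ("D",))])
        guide = build_guide_tree(topo)
        assert guide.boxes["D"] == {("D",): 2}
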