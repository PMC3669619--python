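"""Tree model, Newick/NEXUS I/O, MRCA and patristic distances."""

import itertools

import numpy as np
import pytest

from phylotastic import (mrca, parse_newick, parse_nexus_trees,
                         patristic_matrix, write_newick)
from phylotastic.errors import (LabelLookupError, NewickParseError,
                                TreeInvariantError)
from phylotastic.fixtures import GeneratorSpec, random_tree

from conftest import make_random_trees


class TestParseNewick:
    def test_three_tip_topology_only(self):
        tree = parse_newick("((Homo_sapiens,Pan_troglodytes),Mus_musculus);")
        assert sorted(tree.tip_labels()) == [
            "Homo_sapiens", "Mus_musculus", "Pan_troglodytes"]
        internals = [n for n in tree.preorder() if not n.is_tip]
        assert len(internals) == 2
        assert all(n.branch_length is None for n in tree.preorder())

    def test_lengths_parsed(self):
        tree = parse_newick("(A:1.0,B:2.0):0.0;")
        lengths = {n.label: n.branch_length for n in tree.tips()}
        assert lengths == {"A": 1.0, "B": 2.0}

    def test_underscores_significant_by_default(self):
        tree = parse_newick("(Homo_sapiens,B);")
        assert "Homo_sapiens" in tree.tip_labels()
        tree2 = parse_newick("(Homo_sapiens,B);", underscores_to_spaces=True)
        assert "Homo sapiens" in tree2.tip_labels()

    def test_quoted_labels_and_comments(self):
        tree = parse_newick("('Homo sapiens'[a comment],B);")
        assert "Homo sapiens" in tree.tip_labels()

    @pytest.mark.parametrize("bad,fragment", [
        ("((A,B),C;", "nbalanced"),
        ("((A,B),A);", "ultiple"),       # duplicate tip label
        ("(A:-1,B:1);", "negative"),
        ("", "empty"),
        ("(A,B)", "';'"),
    ])
    def test_errors_name_the_problem(self, bad, fragment):
        with pytest.raises(NewickParseError, match=fragment):
            parse_newick(bad)

    def test_polytomies_and_internal_labels_preserved(self):
        tree = parse_newick("((A,B,C)poly,D)root;")
        poly = [n for n in tree.preorder() if n.label == "poly"]
        assert len(poly) == 1 and len(poly[0].children) == 3
        assert tree.root.label == "root"


class TestWriteNewick:
    def test_classic_three_taxon_tree_exact_string(self):
        tree = parse_newick("((Homo_sapiens,Pan_troglodytes),Mus_musculus);")
        assert write_newick(tree) == \
            "((Homo_sapiens,Pan_troglodytes),Mus_musculus);"

    def test_single_tip(self):
        assert write_newick(parse_newick("A;")) == "A;"

    def test_labels_with_spaces_are_quoted(self):
        tree = parse_newick("('Homo sapiens',B);")
        assert write_newick(tree) == "('Homo sapiens',B);"

    def test_no_scientific_notation_for_small_lengths(self):
        tree = parse_newick("(A:0.00005,B:1);")
        out = write_newick(tree)
        assert "e" not in out and "0.00005" in out

    def test_write_parse_write_fixed_point(self):
        for tree in make_random_trees(30, seed=77):
            once = write_newick(tree)
            assert write_newick(parse_newick(once)) == once


class TestRoundTrip:
    def test_roundtrip_is_identity_on_random_trees(self):
        # labels, topology and lengths survive write→parse for 200 trees
        for tree in make_random_trees(200, seed=13):
            back = parse_newick(write_newick(tree))
            assert sorted(back.tip_labels()) == sorted(tree.tip_labels())
            assert back.isomorphic_to(tree, tol=1e-9)

    def test_roundtrip_without_lengths(self):
        for tree in make_random_trees(20, seed=29, with_lengths=False):
            back = parse_newick(write_newick(tree))
            assert back.isomorphic_to(tree)


class TestSerializationProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.floats(min_value=0, max_value=1e9, allow_nan=False,
                     allow_infinity=False))
    def test_length_formatting_roundtrips_exactly(self, x):
        from phylotastic.trees import format_length
        s = format_length(x)
        assert float(s) == x
        assert "e" not in s and "E" not in s

    _label_chars = st.sampled_from(
        list("abcXYZ019 _-.():;,'") + ["é"])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet=_label_chars, min_size=1, max_size=25))
    def test_arbitrary_labels_survive_write_parse(self, label):
        from hypothesis import assume
        assume(label.strip() == label and label.strip("'") == label)
        assume(any(c.isalnum() for c in label))
        from phylotastic.trees import Node, Tree
        root = Node()
        root.add_child(Node(label=label))
        root.add_child(Node(label="other"))
        tree = Tree(root)
        back = parse_newick(write_newick(tree))
        assert sorted(back.tip_labels()) == sorted([label, "other"])


class TestNexus:
    NEXUS = """#NEXUS
BEGIN TREES;
  TRANSLATE 1 Homo_sapiens, 2 Pan_troglodytes, 3 Mus_musculus;
  TREE one = ((1,2),3);
  TREE two = ((Ailuropoda_melanoleuca,Ursus_arctos),Canis_lupus);
END;
"""

    def test_translate_resolved(self):
        trees = parse_nexus_trees(self.NEXUS)
        assert write_newick(trees[0]) == \
            "((Homo_sapiens,Pan_troglodytes),Mus_musculus);"

    def test_two_statements_two_trees(self):
        assert len(parse_nexus_trees(self.NEXUS)) == 2

    def test_cross_format_agreement(self):
        for tree in make_random_trees(10, seed=31):
            nexus = ("#NEXUS\nBEGIN TREES;\n  TREE t = "
                     + write_newick(tree) + "\nEND;\n")
            [back] = parse_nexus_trees(nexus)
            assert back.isomorphic_to(tree)

    def test_missing_trees_block_errors(self):
        with pytest.raises(NewickParseError):
            parse_nexus_trees("#NEXUS\nBEGIN TAXA;\nEND;\n")


class TestMrca:
    def test_cherry_and_root(self):
        tree = parse_newick("((A,B),C);")
        assert sorted(t.label for t in
                      _subtree_tips(mrca(tree, {"A", "B"}))) == ["A", "B"]
        assert mrca(tree, {"A", "C"}) is tree.root

    def test_single_label_is_the_tip(self):
        tree = parse_newick("((A,B),C);")
        assert mrca(tree, {"A"}).label == "A"

    def test_unknown_label_lists_missing(self):
        tree = parse_newick("((A,B),C);")
        with pytest.raises(LabelLookupError, match="X"):
            mrca(tree, {"A", "X"})

    def test_agrees_with_root_path_intersection_oracle(self):
        rng = np.random.default_rng(3)
        for tree in make_random_trees(50, seed=41, max_tips=40):
            labels = tree.tip_labels()
            for _ in range(10):
                k = int(rng.integers(1, min(6, len(labels)) + 1))
                query = list(rng.choice(labels, size=k, replace=False))
                expected = _mrca_oracle(tree, query)
                assert mrca(tree, query) is expected


def _subtree_tips(node):
    stack = [node]
    while stack:
        n = stack.pop()
        if not n.children:
            yield n
        stack.extend(n.children)


def _mrca_oracle(tree, labels):
    """Deepest node on the intersection of all root paths (computed naively)."""
    paths = []
    for lb in labels:
        node = tree.find_tip(lb)
        path = list(tree.ancestors(node))[::-1]  # root ... tip
        paths.append(path)
    common = None
    for path in paths:
        ids = [id(n) for n in path]
        common = ids if common is None else [
            i for i in common if i in set(ids)]
    deepest_id = common[-1]
    return next(n for n in tree.preorder() if id(n) == deepest_id)


class TestPatristic:
    def test_forced_sums(self):
        tree = parse_newick("((A:2,B:2):3,C:5);")
        d = patristic_matrix(tree)
        assert d.loc["A", "B"] == 4
        assert d.loc["A", "C"] == 10 == d.loc["B", "C"]
        assert (np.diag(d.to_numpy()) == 0).all()

    def test_single_tip_zero_matrix(self):
        d = patristic_matrix(parse_newick("A:3;"))
        assert d.shape == (1, 1) and d.iloc[0, 0] == 0

    def test_missing_length_names_node(self):
        with pytest.raises(TreeInvariantError, match="B"):
            patristic_matrix(parse_newick("(A:1,B);"))

    def test_symmetry_and_four_point_condition(self):
        # additive distances satisfy the four-point condition on quartets
        for tree in make_random_trees(15, seed=53, max_tips=12, min_tips=4):
            d = patristic_matrix(tree)
            assert np.allclose(d, d.T)
            labels = list(d.index)
            for q in itertools.combinations(labels, 4):
                i, j, k, l = q
                sums = sorted([d.loc[i, j] + d.loc[k, l],
                               d.loc[i, k] + d.loc[j, l],
                               d.loc[i, l] + d.loc[j, k]])
                assert sums[2] - sums[1] < 1e-9

    def test_ultrametric_tips_equidistant_from_root(self):
        from phylotastic.fixtures import random_ultrametric_tree
        for seed in range(10):
            tree = random_ultrametric_tree(
                GeneratorSpec(n_tips=12, seed=seed, age_root=42.0))
            depth = tree.depths()
            tip_depths = [depth[t.id] for t in tree.tips()]
            assert np.allclose(tip_depths, 42.0, atol=1e-9)
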