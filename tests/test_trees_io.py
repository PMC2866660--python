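"""Tree/character parsing, writing and majority-rule consensus."""

import numpy as np
import pytest

from _oracles import brute_force_clade_frequencies
from conftest import random_binary_tree, tree_from_newick
from priormap.trees import (
    MISSING,
    CharacterColumn,
    CharacterFormatError,
    TreeFormatError,
    clade_frequencies,
    majority_rule_consensus,
    read_character_column,
    read_tree_sample,
    write_tree_sample,
)


def leafset(tree):
    return {l.taxon.label for l in tree.leaf_node_iter()}


def clades(tree):
    out = set()
    for node in tree.postorder_internal_node_iter():
        if node is not tree.seed_node:
            out.add(frozenset(l.taxon.label for l in node.leaf_iter()))
    return out


class TestReadTreeSample:
    def test_newick_parse_and_lengths(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("(A:1,(B:2,C:3):4);\n")
        (tree,) = read_tree_sample(path)
        assert leafset(tree) == {"A", "B", "C"}
        c = next(l for l in tree.leaf_node_iter() if l.taxon.label == "C")
        assert c.edge.length == 3

    def test_last_n_selects_final_trees_in_order(self, tmp_path):
        path = tmp_path / "t.nwk"
        lines = ["(A:%d,(B:2,C:3):4);" % i for i in range(1, 6)]
        path.write_text("\n".join(lines) + "\n")
        sample = read_tree_sample(path, last_n=2)
        lengths = [
            next(l for l in t.leaf_node_iter() if l.taxon.label == "A").edge.length
            for t in sample
        ]
        assert lengths == [4, 5]

    def test_last_n_too_large_errors(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("(A:1,B:2);\n")
        with pytest.raises(TreeFormatError, match="last 3"):
            read_tree_sample(path, last_n=3)

    def test_malformed_line_is_named(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("(A:1,B:2);\n(A:1,B:2;\n")
        with pytest.raises(TreeFormatError, match="line 2"):
            read_tree_sample(path)

    def test_missing_branch_length_errors(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("(A:1,(B:2,C:3));\n")
        with pytest.raises(TreeFormatError, match="branch length"):
            read_tree_sample(path)

    def test_nexus_translate_table(self, tmp_path):
        path = tmp_path / "t.nex"
        path.write_text(
            "#NEXUS\nbegin trees;\n translate 1 A, 2 B;\n"
            " tree t1 = (1:1,2:1);\nend;\n"
        )
        (tree,) = read_tree_sample(path)
        assert leafset(tree) == {"A", "B"}

    def test_write_read_round_trip_preserves_lengths(self, tmp_path):
        rng = np.random.default_rng(5)
        labels = ["t%d" % i for i in range(8)]
        trees = [random_binary_tree(rng, labels) for _ in range(4)]
        path = tmp_path / "rt.nwk"
        write_tree_sample(trees, path)
        back = read_tree_sample(path)
        for orig, rt in zip(trees, back):
            assert clades(orig) == clades(rt)
            orig_lengths = {
                frozenset(l.taxon.label for l in n.leaf_iter()): n.edge.length
                for n in orig.postorder_node_iter()
                if n is not orig.seed_node
            }
            rt_lengths = {
                frozenset(l.taxon.label for l in n.leaf_iter()): n.edge.length
                for n in rt.postorder_node_iter()
                if n is not rt.seed_node
            }
            for clade, length in orig_lengths.items():
                assert rt_lengths[clade] == pytest.approx(length, rel=1e-10)


class TestReadCharacterColumn:
    def test_csv(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("A,0\nB,1\nC,?\n")
        column = read_character_column(path)
        assert column.states == {"A": 0, "B": 1, "C": MISSING}

    def test_nexus_matches_csv(self, tmp_path):
        csv_path = tmp_path / "c.csv"
        csv_path.write_text("A,0\nB,1\nC,?\n")
        nex_path = tmp_path / "c.nex"
        nex_path.write_text(
            "#NEXUS\nbegin data;\ndimensions ntax=3 nchar=1;\n"
            'format datatype=standard symbols="01" missing=? gap=-;\n'
            "matrix\nA 0\nB 1\nC ?\n;\nend;\n"
        )
        assert read_character_column(nex_path).states == read_character_column(csv_path).states

    def test_gap_symbol_is_missing(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("A,-\nB,1\n")
        assert read_character_column(path).states["A"] is MISSING

    def test_bad_state_names_taxon(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("A,0\nB,2\n")
        with pytest.raises(CharacterFormatError, match="B"):
            read_character_column(path)

    def test_nexus_column_selection_by_label(self, tmp_path):
        path = tmp_path / "c.nex"
        path.write_text(
            "#NEXUS\nbegin data;\ndimensions ntax=2 nchar=2;\n"
            'format datatype=standard symbols="01" missing=?;\n'
            "charlabels slow fast;\nmatrix\nA 01\nB 10\n;\nend;\n"
        )
        assert read_character_column(path, "fast").states == {"A": 1, "B": 0}
        assert read_character_column(path, "2").states == {"A": 1, "B": 0}


class TestConsensus:
    def test_identical_trees_return_same_topology(self):
        trees = [tree_from_newick("((A:1,B:2):0.5,(C:1,D:1):0.5);") for _ in range(3)]
        cons = majority_rule_consensus(trees)
        assert clades(cons) == {frozenset("AB"), frozenset("CD")}

    def test_majority_clade_kept_minority_dropped(self):
        trees = [
            tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);"),
            tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);"),
            tree_from_newick("((A:1,C:1):1,(B:1,D:1):1);"),
        ]
        cons = majority_rule_consensus(trees)
        assert frozenset("AB") in clades(cons)
        assert frozenset("AC") not in clades(cons)

    def test_fifty_percent_tie_becomes_polytomy(self):
        trees = [
            tree_from_newick("((A:1,B:1):1,C:1,D:1);"),
            tree_from_newick("((A:1,C:1):1,B:1,D:1);"),
        ]
        cons = majority_rule_consensus(trees)
        assert clades(cons) == set()
        assert cons.seed_node.num_child_nodes() == 4

    def test_branch_lengths_are_means_over_supporting_trees(self):
        trees = [
            tree_from_newick("((A:1,B:2):1.0,(C:1,D:1):0.5);"),
            tree_from_newick("((A:3,B:4):2.0,(C:1,D:1):1.5);"),
        ]
        cons = majority_rule_consensus(trees)
        lengths = {
            frozenset(l.taxon.label for l in n.leaf_iter()): n.edge.length
            for n in cons.postorder_node_iter()
            if n is not cons.seed_node
        }
        assert lengths[frozenset("AB")] == pytest.approx(1.5)
        assert lengths[frozenset({"A"})] == pytest.approx(2.0)
        assert lengths[frozenset("CD")] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_clade_frequencies(self, seed):
        rng = np.random.default_rng(seed)
        labels = ["t%d" % i for i in range(7)]
        trees = [random_binary_tree(rng, labels) for _ in range(9)]
        freqs = clade_frequencies(trees)
        assert freqs == brute_force_clade_frequencies(trees)
        cons_clades = clades(majority_rule_consensus(trees))
        expected = {c for c, f in freqs.items() if f > 0.5 and len(c) < len(labels)}
        assert cons_clades == expected
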