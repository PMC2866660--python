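import dendropy
import numpy as np
import pytest

from priormap.synthetic import FixtureSpec, make_study_fixture
from priormap.trees import CharacterColumn


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


@pytest.fixture
def quartet_tree():
    return tree_from_newick("((A:0.5,B:0.8):0.4,(C:0.6,D:0.3):0.7);")


@pytest.fixture
def triplet_tree():
    return tree_from_newick("((A:0.5,B:0.8):0.4,C:0.9);")


@pytest.fixture
def quartet_column():
    return CharacterColumn({"A": 1, "B": 1, "C": 0, "D": 0})


@pytest.fixture(scope="session")
def small_study():
    """A reduced study fixture shared across tests: 16 taxa, 6 jittered trees,
    one slow single-origin and one fast homoplastic character."""
    spec = FixtureSpec(n_taxa=16, n_trees=6, seed=11)
    sample, slow, fast = make_study_fixture(spec)
    return spec, sample, slow, fast


def random_binary_tree(rng: np.random.Generator, labels):
    """Random topology with exponential branch lengths, built by joining."""
    nodes = []
    tns = dendropy.TaxonNamespace(sorted(labels))
    for label in labels:
        leaf = dendropy.Node()
        leaf.taxon = tns.get_taxon(label)
        leaf.edge.length = float(rng.exponential(0.5)) + 0.05
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        parent.edge.length = float(rng.exponential(0.5)) + 0.05
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = None
    return tree


def random_column(rng: np.random.Generator, tree, p_one=0.5):
    return CharacterColumn(
        {
            l.taxon.label: int(rng.random() < p_one)
            for l in tree.leaf_node_iter()
        }
    )
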