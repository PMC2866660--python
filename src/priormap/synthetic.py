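"""Synthetic tree samples and binary characters with the statistical
structure the mapping analysis assumes.

The study fixture emulates a Bayesian tree sample over ~66 taxa (a pure-birth
topology whose branch lengths are jittered across trees, standing in for
posterior branch-length spread) carrying two contrasting characters: a slow,
homoplasy-free one that arose once in a single clade (consistency index 1)
and a fast, homoplastic one (consistency index <= 0.2) with a few tips
scored as missing.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .mk2 import Mk2Params, transition_probabilities
from .parsimony import directional_counts, fitch_length
from .trees import MISSING, CharacterColumn, write_character_csv, write_tree_sample

RESIM_CAP = 1000


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the synthetic fixture.

    Branch lengths emulate a family-level molecular tree (mean root-to-tip
    depth ``tree_depth`` expected substitutions per site), so morphological
    transformation rates per unit branch length land on the 1 (slow,
    single-origin) to 10 (fast, homoplastic) scale that the rate-prior grid
    E(T) in {1, 5, 10, 15} is meant to bracket.
    """

    n_taxa: int = 66
    n_trees: int = 201
    tree_depth: float = 0.1
    branch_jitter_sd: float = 0.1
    slow_theta: float = 1.0
    fast_theta: float = 10.0
    bias: float = 0.5
    missing_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3 or self.n_trees < 1:
            raise ValueError("need n_taxa >= 3 and n_trees >= 1")
        if self.slow_theta <= 0 or self.fast_theta <= 0:
            raise ValueError("thetas must be positive")


def simulate_yule_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Pure-birth tree on n_taxa extant tips, rescaled to mean root-to-tip 1."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=random.Random(int(seed)),
    )
    width = len(str(n_taxa))
    tns = dendropy.TaxonNamespace()
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)):
        leaf.taxon = tns.new_taxon("t%0*d" % (width, i + 1))
    tree.taxon_namespace = tns
    depths = []
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    mean_depth = sum(depths) / len(depths)
    if mean_depth == 0.0:
        # degenerate 2-tip start: give the cherry unit-depth branches
        for leaf in tree.leaf_node_iter():
            leaf.edge.length = 1.0
        mean_depth = 1.0
    factor = 1.0 / mean_depth
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length *= factor
    tree.seed_node.edge.length = None
    return tree


def jitter_tree_sample(tree, n_trees, branch_jitter_sd, seed):
    """Copies of ``tree`` with every branch scaled by an independent lognormal
    factor of median 1 (log-sd ``branch_jitter_sd``); topology fixed."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 101])
    sample = []
    for _ in range(n_trees):
        clone = tree.clone(depth=1)
        for node in clone.preorder_node_iter():
            if node is clone.seed_node:
                continue
            node.edge.length *= float(np.exp(rng.normal(0.0, branch_jitter_sd)))
        sample.append(clone)
    return sample


def evolve_character(tree, params: Mk2Params, seed) -> CharacterColumn:
    """Forward simulation: root state from (1-bias, bias), child states from
    the branch transition probabilities; returns the tip states."""
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 202])
    states = {}
    root = tree.seed_node
    states[id(root)] = int(rng.random() < params.bias)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        P = transition_probabilities(params, node.edge.length)
        states[id(node)] = int(rng.random() < P[states[id(node.parent_node)], 1])
    return CharacterColumn(
        states={
            l.taxon.label: states[id(l)] for l in tree.leaf_node_iter()
        }
    )


def _resimulate(tree, params, seed, accept, cap=RESIM_CAP):
    for attempt in range(cap):
        column = evolve_character(tree, params, seed * cap + attempt)
        if accept(column):
            return column
    raise RuntimeError(
        "no acceptable character in %d attempts; try different thetas" % cap
    )


def base_tree(spec: FixtureSpec) -> dendropy.Tree:
    """The fixture's unjittered base tree, scaled to ``spec.tree_depth``."""
    tree = simulate_yule_tree(spec.n_taxa, spec.seed)
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length *= spec.tree_depth
    return tree


def make_study_fixture(spec: FixtureSpec):
    """(TreeSample, slow, fast): the study conditions in miniature.

    The slow character is resimulated until it shows a single origin of the
    derived state on the base tree (Fitch length 1, at least two derived
    taxa, ci = 1); the fast one until its Fitch length is >= 5 (ci <= 0.2),
    after which ~5% of its tips are masked as missing.
    """
    tree = base_tree(spec)

    def slow_ok(col):
        if sum(1 for s in col.states.values() if s == 1) < 2:
            return False
        return fitch_length(tree, col) == 1 and directional_counts(tree, col) == (1, 0)

    def fast_ok(col):
        return fitch_length(tree, col) >= 5

    slow = _resimulate(tree, Mk2Params(spec.slow_theta, spec.bias), spec.seed, slow_ok)
    slow.name = "slow"
    fast = _resimulate(
        tree, Mk2Params(spec.fast_theta, spec.bias), spec.seed + 7_000_000, fast_ok
    )
    fast.name = "fast"
    rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, 303])
    taxa = sorted(fast.states)
    n_missing = max(1, round(spec.missing_fraction * len(taxa)))
    for taxon in rng.choice(taxa, size=n_missing, replace=False):
        fast.states[str(taxon)] = MISSING
    sample = jitter_tree_sample(tree, spec.n_trees, spec.branch_jitter_sd, spec.seed)
    return sample, slow, fast


def write_fixture(spec: FixtureSpec, out_dir) -> dict:
    """Write trees (Newick + NEXUS), characters (NEXUS + CSV) and a manifest."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    sample, slow, fast = make_study_fixture(spec)
    paths = {
        "trees_newick": os.path.join(out_dir, "trees.nwk"),
        "trees_nexus": os.path.join(out_dir, "trees.nex"),
        "characters_nexus": os.path.join(out_dir, "characters.nex"),
        "slow_csv": os.path.join(out_dir, "slow.csv"),
        "fast_csv": os.path.join(out_dir, "fast.csv"),
        "manifest": os.path.join(out_dir, "manifest.tsv"),
    }
    write_tree_sample(sample, paths["trees_newick"])
    tree_list = dendropy.TreeList(sample, taxon_namespace=sample[0].taxon_namespace)
    tree_list.write(
        path=paths["trees_nexus"],
        schema="nexus",
        suppress_rooting=True,
        real_value_format_specifier=".12g",
    )
    _write_characters_nexus([slow, fast], paths["characters_nexus"])
    write_character_csv(slow, paths["slow_csv"])
    write_character_csv(fast, paths["fast_csv"])
    with open(paths["manifest"], "w") as fh:
        fh.write("key\tvalue\n")
        for key, value in vars(spec).items():
            fh.write("%s\t%s\n" % (key, value))
    return paths


def _write_characters_nexus(columns, path) -> None:
    taxa = sorted(columns[0].states)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(
            "  DIMENSIONS NTAX=%d NCHAR=%d;\n" % (len(taxa), len(columns))
        )
        fh.write('  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;\n')
        fh.write("  CHARLABELS %s;\n" % " ".join(c.name for c in columns))
        fh.write("  MATRIX\n")
        for taxon in taxa:
            symbols = "".join(
                "?" if c.states[taxon] is MISSING else str(c.states[taxon])
                for c in columns
            )
            fh.write("    %s  %s\n" % (taxon, symbols))
        fh.write("  ;\nEND;\n")
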