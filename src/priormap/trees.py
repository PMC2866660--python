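"""Reading, writing and summarising tree samples and binary character columns.

Trees are carried as :class:`dendropy.Tree` objects (rooted, with branch
lengths in expected substitutions per site); a tree sample is a list of such
trees over one shared leaf set.  Character columns map leaf labels to
``0``, ``1`` or :data:`MISSING`.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field

import dendropy

#: Sentinel for an unobserved / uncertain character state.
MISSING = None

_STATE_SYMBOLS = {"0": 0, "1": 1, "?": MISSING, "-": MISSING}


class TreeFormatError(ValueError):
    """Raised when a tree file cannot be parsed or violates the contract."""


class CharacterFormatError(ValueError):
    """Raised when a character matrix cannot be parsed or holds bad symbols."""


@dataclass
class CharacterColumn:
    """One binary character: leaf label -> state in {0, 1, MISSING}."""

    states: dict
    name: str = "character"

    def scored_taxa(self):
        """Labels with an observed (non-missing) state."""
        return {t for t, s in self.states.items() if s is not MISSING}

    def validate_against(self, tree: dendropy.Tree) -> None:
        """Require the column's taxa to equal the tree's leaf set exactly."""
        leaves = {l.taxon.label for l in tree.leaf_node_iter()}
        keys = set(self.states)
        if leaves != keys:
            diff = sorted(leaves.symmetric_difference(keys))
            raise ValueError(
                "character column and tree leaves disagree on taxa: %s" % diff
            )


def _check_tree(tree: dendropy.Tree, where: str) -> dendropy.Tree:
    """Validate the PhyloTree contract: unique leaf labels, lengths >= 0.

    Branch lengths must be present on every non-root edge (the root edge is
    ignored: mapping never simulates above the root).
    """
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise TreeFormatError("duplicate leaf labels in %s" % where)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise TreeFormatError(
                "missing branch length in %s (node above %s)"
                % (where, _clade_hint(node))
            )
        if node.edge.length < 0:
            raise TreeFormatError("negative branch length in %s" % where)
    tree.seed_node.edge.length = None
    return tree


def _clade_hint(node) -> str:
    leaf = next(node.leaf_iter())
    return leaf.taxon.label


def read_tree_sample(path, last_n="all"):
    """Read a tree sample from Newick (one tree per line) or a NEXUS trees block.

    Returns the final ``last_n`` trees in file order; leaf labels are resolved
    through the NEXUS translate table when one is present.
    """
    with open(path) as fh:
        text = fh.read()
    if text.lstrip().upper().startswith("#NEXUS"):
        try:
            trees = dendropy.TreeList.get(data=text, schema="nexus")
        except Exception as exc:  # dendropy raises several error types
            raise TreeFormatError("cannot parse NEXUS trees in %s: %s" % (path, exc))
        trees = list(trees)
    else:
        trees = []
        tns = dendropy.TaxonNamespace()
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            try:
                trees.append(
                    dendropy.Tree.get(
                        data=line, schema="newick", taxon_namespace=tns
                    )
                )
            except Exception as exc:
                raise TreeFormatError(
                    "cannot parse tree on line %d of %s: %s" % (lineno, path, exc)
                )
    if not trees:
        raise TreeFormatError("no trees found in %s" % path)
    if last_n != "all":
        if last_n > len(trees):
            raise TreeFormatError(
                "requested last %d trees but %s holds only %d"
                % (last_n, path, len(trees))
            )
        trees = trees[-last_n:]
    sample = [_check_tree(t, "%s (tree %d)" % (path, i + 1)) for i, t in enumerate(trees)]
    leafsets = {frozenset(l.taxon.label for l in t.leaf_node_iter()) for t in sample}
    if len(leafsets) != 1:
        raise TreeFormatError("trees in %s do not share one leaf set" % path)
    return sample


def write_tree_sample(trees, path) -> None:
    """Write a tree sample as Newick, one tree per line, 12 significant digits."""
    with open(path, "w") as fh:
        for t in trees:
            fh.write(
                t.as_string(
                    schema="newick",
                    suppress_rooting=True,
                    real_value_format_specifier=".12g",
                ).strip()
            )
            fh.write("\n")


def _read_charlabels(text: str):
    m = re.search(r"charlabels\s+(.*?);", text, re.IGNORECASE | re.DOTALL)
    if not m:
        return None
    return m.group(1).split()


def read_character_column(path, character_name=None) -> CharacterColumn:
    """Read one binary character column from NEXUS (characters/data block) or CSV.

    For multi-character NEXUS matrices ``character_name`` selects a column by
    CHARLABELS entry or 1-based index; for two-column CSV files it only names
    the returned column.  ``?`` and ``-`` both denote MISSING.
    """
    with open(path) as fh:
        text = fh.read()
    if text.lstrip().upper().startswith("#NEXUS"):
        return _column_from_nexus(text, character_name, path)
    return _column_from_csv(text, character_name, path)


def _column_from_nexus(text, character_name, path) -> CharacterColumn:
    try:
        matrix = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:
        raise CharacterFormatError("cannot parse NEXUS characters in %s: %s" % (path, exc))
    nchar = max(len(matrix[t]) for t in matrix)
    labels = _read_charlabels(text)
    index = 0
    name = character_name
    if character_name is not None:
        if labels and character_name in labels:
            index = labels.index(character_name)
        else:
            try:
                index = int(character_name) - 1
            except ValueError:
                raise CharacterFormatError(
                    "character %r not found in %s" % (character_name, path)
                )
            if labels and 0 <= index < len(labels):
                name = labels[index]
    elif labels:
        name = labels[0]
    if not 0 <= index < nchar:
        raise CharacterFormatError(
            "character index %d out of range for %s (nchar=%d)"
            % (index + 1, path, nchar)
        )
    states = {}
    for taxon in matrix:
        symbol = str(matrix[taxon][index])
        if symbol not in _STATE_SYMBOLS:
            raise CharacterFormatError(
                "taxon %s has state %r outside {0,1,?,-}" % (taxon.label, symbol)
            )
        states[taxon.label] = _STATE_SYMBOLS[symbol]
    return CharacterColumn(states=states, name=name or "character")


def _column_from_csv(text, character_name, path) -> CharacterColumn:
    rows = [r for r in csv.reader(io.StringIO(text)) if r and any(c.strip() for c in r)]
    if not rows:
        raise CharacterFormatError("empty character file %s" % path)
    # Optional header: first row whose second cell is not a state symbol.
    start = 0
    if len(rows[0]) >= 2 and rows[0][1].strip() not in _STATE_SYMBOLS:
        start = 1
    states = {}
    for row in rows[start:]:
        if len(row) < 2:
            raise CharacterFormatError("row %r in %s lacks a state column" % (row, path))
        taxon, symbol = row[0].strip(), row[1].strip()
        if symbol not in _STATE_SYMBOLS:
            raise CharacterFormatError(
                "taxon %s has state %r outside {0,1,?,-}" % (taxon, symbol)
            )
        states[taxon] = _STATE_SYMBOLS[symbol]
    if not any(s is not MISSING for s in states.values()):
        raise CharacterFormatError("no observed states in %s" % path)
    return CharacterColumn(states=states, name=character_name or "character")


def write_character_csv(column: CharacterColumn, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for taxon in sorted(column.states):
            state = column.states[taxon]
            writer.writerow([taxon, "?" if state is MISSING else state])


# ---------------------------------------------------------------------------
# Majority-rule consensus
# ---------------------------------------------------------------------------

def _clades(tree: dendropy.Tree):
    """Yield (frozenset of leaf labels, branch length) for every non-root node."""
    out = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._leafset = frozenset([node.taxon.label])
        else:
            node._leafset = frozenset().union(*(c._leafset for c in node.child_nodes()))
        if node is not tree.seed_node:
            out[node._leafset] = node.edge.length
    return out


def majority_rule_consensus(sample) -> dendropy.Tree:
    """Strict majority-rule consensus of a rooted tree sample.

    Keeps exactly the clades present in more than half the trees (ties at 50%
    are excluded) and sets each retained branch length to the mean length of
    that clade over the trees that contain it.
    """
    if not sample:
        raise ValueError("empty tree sample")
    n = len(sample)
    counts: dict = {}
    length_sums: dict = {}
    for tree in sample:
        for clade, length in _clades(tree).items():
            counts[clade] = counts.get(clade, 0) + 1
            length_sums[clade] = length_sums.get(clade, 0.0) + (length or 0.0)
    all_leaves = frozenset(l.taxon.label for l in sample[0].leaf_node_iter())
    kept = [c for c, k in counts.items() if len(c) == 1 or 2 * k > n]
    kept.sort(key=lambda c: (-len(c), sorted(c)))

    tns = dendropy.TaxonNamespace(sorted(all_leaves))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node._leafset = all_leaves
    for clade in kept:
        # walk down to the smallest node containing this clade
        node = tree.seed_node
        while True:
            child = next(
                (c for c in node.child_nodes() if clade <= c._leafset), None
            )
            if child is None:
                break
            node = child
        if node._leafset == clade:  # root equals full set for 1-tree edge case
            continue
        new = dendropy.Node()
        new._leafset = clade
        new.edge.length = length_sums[clade] / counts[clade]
        if len(clade) == 1:
            new.taxon = tns.get_taxon(next(iter(clade)))
        # re-home children now fully inside the new clade
        for c in [c for c in node.child_nodes() if c._leafset <= clade]:
            node.remove_child(c)
            new.add_child(c)
        node.add_child(new)
    tree.is_rooted = True
    return tree


def clade_frequencies(sample):
    """Relative frequency of every internal (non-trivial) clade in the sample."""
    n = len(sample)
    counts: dict = {}
    for tree in sample:
        for clade in _clades(tree):
            if len(clade) > 1:
                counts[clade] = counts.get(clade, 0) + 1
    return {c: k / n for c, k in counts.items()}
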