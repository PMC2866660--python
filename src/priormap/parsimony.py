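"""Maximum-parsimony reference numbers: Fitch length, one deterministic
most-parsimonious reconstruction split by direction, and the consistency
index.

The minimum change count is computed with a unit-cost dynamic program
(Sankoff recursion), which generalizes Fitch/Hartigan counting to
multifurcating trees; MISSING tips are free (cost zero in both states).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trees import MISSING

INF = float("inf")


@dataclass(frozen=True)
class ParsimonyResult:
    length: int
    n01: int
    n10: int
    ci: float


def _node_costs(tree, column):
    """Unit-cost DP: cost[node][s] = min changes in the subtree with node in s."""
    costs = {}
    scored = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state = column.states.get(node.taxon.label, MISSING)
            if state is MISSING:
                costs[id(node)] = np.zeros(2)
            else:
                scored += 1
                vec = np.full(2, INF)
                vec[state] = 0.0
                costs[id(node)] = vec
        else:
            total = np.zeros(2)
            for child in node.child_nodes():
                c = costs[id(child)]
                # transition cost: stay free, switch costs 1
                total += np.minimum(c, c[::-1] + 1.0)
            costs[id(node)] = total
    if scored == 0:
        raise ValueError("no scored taxa on the tree")
    return costs


def fitch_length(tree, column) -> int:
    """Minimum number of state changes over all ancestral assignments."""
    costs = _node_costs(tree, column)
    return int(min(costs[id(tree.seed_node)]))


def directional_counts(tree, column):
    """(n01, n10) from one deterministic minimum-length reconstruction.

    Root ties resolve to state 0; a child keeps its parent's state whenever
    that is optimal (ties included), otherwise it switches.  The counts
    always sum to the Fitch length.
    """
    costs = _node_costs(tree, column)
    root = tree.seed_node
    root_cost = costs[id(root)]
    assignment = {id(root): int(root_cost[1] < root_cost[0])}
    n01 = n10 = 0
    for node in tree.preorder_node_iter():
        parent_state = assignment[id(node)]
        for child in node.child_nodes():
            c = costs[id(child)]
            stay = c[parent_state]
            switch = c[1 - parent_state] + 1.0
            state = parent_state if stay <= switch else 1 - parent_state
            assignment[id(child)] = state
            if state != parent_state:
                if parent_state == 0:
                    n01 += 1
                else:
                    n10 += 1
    return n01, n10


def consistency_index(min_conceivable: int, observed_length: int) -> float:
    """ci = m / s with m the minimum conceivable changes (states - 1)."""
    if observed_length == 0:
        raise ValueError("consistency index undefined for invariant characters")
    if not 1 <= min_conceivable <= observed_length:
        raise ValueError("need observed_length >= min_conceivable >= 1")
    return min_conceivable / observed_length


def parsimony_result(tree, column) -> ParsimonyResult:
    length = fitch_length(tree, column)
    n01, n10 = directional_counts(tree, column)
    observed = {s for s in column.states.values() if s is not MISSING}
    m = max(len(observed) - 1, 1)
    return ParsimonyResult(
        length=length, n01=n01, n10=n10, ci=consistency_index(m, length)
    )


def count_minimum_reconstructions(tree, column, max_internal=16) -> int:
    """Number of distinct minimum-length ancestral assignments (small trees).

    Diagnostic for how arbitrary the directional split is: brute-force
    enumeration, so limited to ``max_internal`` internal nodes.
    """
    import itertools

    internals = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    if len(internals) > max_internal:
        raise ValueError("too many internal nodes for enumeration")
    best = fitch_length(tree, column)
    count = 0
    for assignment in itertools.product([0, 1], repeat=len(internals)):
        states = dict(zip((id(n) for n in internals), assignment))
        changes = 0
        for node in tree.postorder_node_iter():
            if node is tree.seed_node:
                continue
            state = (
                column.states.get(node.taxon.label, MISSING)
                if node.is_leaf()
                else states[id(node)]
            )
            if state is MISSING:
                continue
            if state != states[id(node.parent_node)]:
                changes += 1
        if changes == best:
            count += 1
    return count


def parsimony_to_tsv(rows, path) -> None:
    """rows: iterable of (character name, ParsimonyResult)."""
    with open(path, "w") as fh:
        fh.write("character\tlength\tn01\tn10\tci\n")
        for name, r in rows:
            fh.write("%s\t%d\t%d\t%d\t%.4g\n" % (name, r.length, r.n01, r.n10, r.ci))
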