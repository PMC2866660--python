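"""Independent oracles used by the test suite.

Everything here is deliberately written by a different route than the
package: brute-force enumeration, quadrature, and a uniformization-series
DP for change-count distributions.
"""

import itertools
import math

import numpy as np
from scipy.stats import poisson

from priormap.trees import MISSING


# ---------------------------------------------------------------------------
# Likelihood by exhaustive enumeration over internal-node states
# ---------------------------------------------------------------------------

def enumeration_loglik(tree, column, params, root_prior="stationary"):
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    pi = np.array([1.0 - params.bias, params.bias])
    if root_prior == "flat":
        pi = np.array([0.5, 0.5])

    def P(t):
        from priormap.mk2 import transition_probabilities

        return transition_probabilities(params, t)

    total = 0.0
    for assignment in itertools.product([0, 1], repeat=len(internals)):
        states = {id(n): s for n, s in zip(internals, assignment)}
        prob = pi[states[id(tree.seed_node)]]
        ok = True
        for node in nodes:
            if node is tree.seed_node:
                continue
            parent = states[id(node.parent_node)]
            if node.is_leaf():
                tip = column.states[node.taxon.label]
                if tip is MISSING:
                    continue
                prob *= P(node.edge.length)[parent, tip]
            else:
                prob *= P(node.edge.length)[parent, states[id(node)]]
            if prob == 0.0:
                ok = False
                break
        if ok:
            total += prob
    return math.log(total)


def enumeration_node_marginals(tree, column, params):
    """Exact joint distribution over internal-node assignments given tips."""
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    pi = np.array([1.0 - params.bias, params.bias])
    from priormap.mk2 import transition_probabilities as P

    weights = {}
    for assignment in itertools.product([0, 1], repeat=len(internals)):
        states = {id(n): s for n, s in zip(internals, assignment)}
        prob = pi[states[id(tree.seed_node)]]
        for node in nodes:
            if node is tree.seed_node:
                continue
            parent = states[id(node.parent_node)]
            if node.is_leaf():
                tip = column.states[node.taxon.label]
                if tip is MISSING:
                    continue
                prob *= P(params, node.edge.length)[parent, tip]
            else:
                prob *= P(params, node.edge.length)[parent, states[id(node)]]
        weights[assignment] = prob
    total = sum(weights.values())
    return internals, {a: w / total for a, w in weights.items()}


# ---------------------------------------------------------------------------
# Endpoint-conditioned change-count distribution via uniformization series
# ---------------------------------------------------------------------------

def change_count_distribution(start, end, length, params, n_max=60, tol=1e-12):
    """P(number of true changes = n | X_0=start, X_t=end) for the 2-state
    chain, via the dominating-Poisson series with a per-step DP that counts
    real (state-changing) jumps."""
    q01 = 2.0 * params.theta * params.bias
    q10 = 2.0 * params.theta * (1.0 - params.bias)
    mu = max(q01, q10) * 1.25  # any dominating rate works; keep self-loops
    R = np.array([[1.0 - q01 / mu, q01 / mu], [q10 / mu, 1.0 - q10 / mu]])
    # D[s, n]: P(after m steps, state s with n real jumps | start)
    D = np.zeros((2, n_max + 1))
    D[start, 0] = 1.0
    joint = np.zeros(n_max + 1)
    mu_t = mu * length
    m = 0
    accumulated = 0.0
    while True:
        w = poisson.pmf(m, mu_t)
        joint += w * D[end]
        accumulated += w
        if accumulated > 1.0 - tol and m > mu_t:
            break
        m += 1
        if m > 10000:
            break
        new = np.zeros_like(D)
        for s in (0, 1):
            new[s, :] += D[s] * R[s, s]
            new[1 - s, 1:] += D[s, :-1] * R[s, 1 - s]
        D = new
    return joint / joint.sum()


def directional_split(start, n):
    """(n01, n10) implied by start state and n alternating changes."""
    if start == 0:
        return (n + 1) // 2, n // 2
    return n // 2, (n + 1) // 2


# ---------------------------------------------------------------------------
# Parsimony by brute force
# ---------------------------------------------------------------------------

def brute_force_parsimony(tree, column):
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    best = math.inf
    for assignment in itertools.product([0, 1], repeat=len(internals)):
        states = {id(n): s for n, s in zip(internals, assignment)}
        for leaf in tree.leaf_node_iter():
            s = column.states.get(leaf.taxon.label, MISSING)
            states[id(leaf)] = s
        changes = 0
        for node in nodes:
            if node is tree.seed_node:
                continue
            child_state = states[id(node)]
            if child_state is MISSING:
                continue
            if child_state != states[id(node.parent_node)]:
                changes += 1
        best = min(best, changes)
    return best


# ---------------------------------------------------------------------------
# Consensus by brute-force clade counting
# ---------------------------------------------------------------------------

def brute_force_clade_frequencies(sample):
    counts = {}
    for tree in sample:
        for node in tree.postorder_internal_node_iter():
            clade = frozenset(l.taxon.label for l in node.leaf_iter())
            if node is tree.seed_node:
                continue
            counts[clade] = counts.get(clade, 0) + 1
    return {c: k / len(sample) for c, k in counts.items()}


def brute_force_hpd(totals, mass=0.95):
    totals = np.asarray(totals, dtype=int)
    n = totals.size
    lo, hi = totals.min(), totals.max()
    best = None
    for a in range(lo, hi + 1):
        for b in range(a, hi + 1):
            covered = np.count_nonzero((totals >= a) & (totals <= b))
            if covered >= math.ceil(mass * n):
                if best is None or (b - a) < (best[1] - best[0]):
                    best = (a, b)
    return best
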