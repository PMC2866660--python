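"""Two-state continuous-time Markov model with overall rate and directional bias.

The generator convention, isolated here so it can be swapped wholesale, is

    q01 = 2*theta*bias,   q10 = 2*theta*(1-bias)

which reduces to the symmetric two-state Mk model with rate theta at
bias = 0.5 and has stationary distribution (1-bias, bias).  Transition
probabilities have the closed form P(t) = Pi + exp(-2*theta*t) (I - Pi)
with Pi the rank-one stationary projector.  The root state prior is the
stationary distribution (a flat root is available via ``root_prior``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trees import MISSING


@dataclass(frozen=True)
class Mk2Params:
    theta: float
    bias: float

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if not 0 < self.bias < 1:
            raise ValueError("bias must lie in (0, 1)")


def rate_matrix(params: Mk2Params) -> np.ndarray:
    q01 = 2.0 * params.theta * params.bias
    q10 = 2.0 * params.theta * (1.0 - params.bias)
    return np.array([[-q01, q01], [q10, -q10]])


def stationary_distribution(params: Mk2Params) -> np.ndarray:
    return np.array([1.0 - params.bias, params.bias])


def transition_probabilities(params: Mk2Params, t) -> np.ndarray:
    """P(t) for scalar t >= 0; rows are the departure state."""
    if t < 0:
        raise ValueError("t must be non-negative")
    pi1 = params.bias
    decay = np.exp(-2.0 * params.theta * t)
    return np.array(
        [
            [1.0 - pi1 + decay * pi1, pi1 - decay * pi1],
            [1.0 - pi1 - decay * (1.0 - pi1), pi1 + decay * (1.0 - pi1)],
        ]
    )


def _transition_grid(theta, bias, t):
    """P(t) for arrays theta, bias of shape (C,); returns (C, 2, 2)."""
    pi1 = np.asarray(bias, dtype=float)
    decay = np.exp(-2.0 * np.asarray(theta, dtype=float) * t)
    P = np.empty((pi1.shape[0], 2, 2))
    P[:, 0, 0] = 1.0 - pi1 + decay * pi1
    P[:, 0, 1] = pi1 - decay * pi1
    P[:, 1, 0] = (1.0 - pi1) * (1.0 - decay)
    P[:, 1, 1] = pi1 + decay * (1.0 - pi1)
    return P


def postorder_nodes(tree):
    """Postorder node list, cached on the tree object.

    The cache is invalidated when the root changes (e.g. after rerooting or
    cloning); other in-place topology edits require dropping _pm_postorder.
    """
    cached = getattr(tree, "_pm_postorder", None)
    if cached is None or cached[-1] is not tree.seed_node:
        cached = list(tree.postorder_node_iter())
        tree._pm_postorder = cached
        for i, node in enumerate(cached):
            node._pm_index = i
    return cached


def _tip_partial(state) -> np.ndarray:
    if state is MISSING:
        return np.ones(2)
    vec = np.zeros(2)
    vec[state] = 1.0
    return vec


def grid_partials(tree, column, theta, bias):
    """Scaled conditional likelihoods for a grid of (theta, bias) pairs.

    theta and bias are flat arrays of equal length C (one entry per grid
    cell).  Returns ``(partials, log_lik)`` where partials maps each node (by
    id) to a (C, 2) array of per-cell conditional likelihoods rescaled per
    node (rescaling factors are absorbed into log_lik), and log_lik is the
    (C,) per-cell log-likelihood with the stationary root prior.
    """
    column.validate_against(tree)
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    bias = np.atleast_1d(np.asarray(bias, dtype=float))
    C = theta.shape[0]
    partials = {}
    log_scale = np.zeros(C)
    for node in postorder_nodes(tree):
        if node.is_leaf():
            part = np.broadcast_to(
                _tip_partial(column.states[node.taxon.label]), (C, 2)
            ).copy()
        else:
            part = np.ones((C, 2))
            for child in node.child_nodes():
                P = _transition_grid(theta, bias, child.edge.length)
                part *= np.einsum("cij,cj->ci", P, partials[id(child)])
            scale = part.max(axis=1)
            scale[scale == 0.0] = 1.0
            part /= scale[:, None]
            log_scale += np.log(scale)
        partials[id(node)] = part
    root = partials[id(postorder_nodes(tree)[-1])]
    lik = root[:, 0] * (1.0 - bias) + root[:, 1] * bias
    with np.errstate(divide="ignore"):
        log_lik = np.log(lik) + log_scale
    return partials, log_lik


def tree_log_likelihood(tree, column, params: Mk2Params, root_prior="stationary"):
    """Log P(tip states | tree, params) by the pruning recursion.

    MISSING tips contribute the all-ones partial; the root is weighted by the
    stationary distribution (1-bias, bias) or a flat prior when
    ``root_prior="flat"``.
    """
    partials, log_lik = grid_partials(
        tree, column, np.array([params.theta]), np.array([params.bias])
    )
    if root_prior == "stationary":
        return float(log_lik[0])
    if root_prior != "flat":
        raise ValueError("root_prior must be 'stationary' or 'flat'")
    root = partials[id(postorder_nodes(tree)[-1])]
    scale_correction = log_lik[0] - np.log(
        root[0, 0] * (1.0 - params.bias) + root[0, 1] * params.bias
    )
    return float(np.log(0.5 * root[0].sum()) + scale_correction)
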