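"""Posterior (stochastic) mapping of a binary character over a tree sample.

One realization proceeds in three stages:

1. draw (rate category, bias category) from their joint discrete posterior —
   the prior puts mass 1/(K*K_B) on each grid cell, so the posterior over
   cells is proportional to the pruning likelihood at the cell's
   conditional-mean representatives (likelihoods are computed once per tree
   and reused across realizations);
2. sample a joint assignment of ancestral states from the posterior of node
   states given the tips and the drawn parameters (root from prior times
   partials, then each child in pre-order conditioned on its parent);
3. simulate an endpoint-conditioned path of the two-state chain along every
   branch (rejection sampling with a forced first event when the endpoints
   differ; exact uniformization sampling as fallback), recording every
   change as a timed event.

Randomness is driven by one master seed through per-(tree, realization)
streams, so realizations are reproducible and independent of scheduling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mk2 import Mk2Params, grid_partials, postorder_nodes, transition_probabilities
from .trees import MISSING

REJECTION_RETRY_CAP = 10_000


@dataclass(frozen=True)
class ModelDraw:
    """One draw of (rate category, bias category) and their representatives."""

    tree_index: int
    rate_category: int  # 1-based
    bias_category: int  # 1-based
    theta: float
    bias: float


@dataclass(frozen=True)
class BranchEvent:
    """A single state change; time runs rootward-to-tipward from the branch's
    parent end."""

    branch_id: int
    time: float
    from_state: int
    to_state: int


@dataclass
class CharacterHistory:
    draw: ModelDraw
    node_states: dict  # postorder node index -> state
    events: list
    n01: int
    n10: int

    @property
    def total(self) -> int:
        return self.n01 + self.n10


def node_indices(tree):
    """Postorder node list with ._pm_index assigned (see postorder_nodes)."""
    return postorder_nodes(tree)


def node_labels(tree):
    """Map postorder node index -> leaf label (None for internal nodes)."""
    return {
        n._pm_index: (n.taxon.label if n.is_leaf() else None)
        for n in node_indices(tree)
    }


class GridPosterior:
    """Joint discrete posterior over the (rate, bias) category grid for one
    tree and character, with the per-cell pruning partials kept for reuse."""

    def __init__(self, tree, column, rate_prior, bias_prior):
        self.tree = tree
        self.column = column
        self.K = rate_prior.K
        self.K_B = bias_prior.K
        self.theta = np.repeat(rate_prior.representatives, bias_prior.K)
        self.bias = np.tile(bias_prior.representatives, rate_prior.K)
        node_indices(tree)
        self.partials, self.log_lik = grid_partials(
            tree, column, self.theta, self.bias
        )
        finite = np.isfinite(self.log_lik)
        if not finite.any():
            raise ValueError(
                "likelihood is zero on every (rate, bias) grid cell"
            )
        shifted = np.where(finite, self.log_lik - self.log_lik[finite].max(), -np.inf)
        weights = np.exp(shifted)
        self.posterior = weights / weights.sum()

    def draw_cells(self, n_draws, rng):
        return rng.choice(self.posterior.size, size=n_draws, p=self.posterior)

    def cell_to_draw(self, cell, tree_index=0) -> ModelDraw:
        return ModelDraw(
            tree_index=tree_index,
            rate_category=int(cell) // self.K_B + 1,
            bias_category=int(cell) % self.K_B + 1,
            theta=float(self.theta[cell]),
            bias=float(self.bias[cell]),
        )

    def sample_states(self, cell, rng):
        """Joint ancestral-state sample for the parameters of one grid cell."""
        params = Mk2Params(float(self.theta[cell]), float(self.bias[cell]))
        states = {}
        nodes = postorder_nodes(self.tree)
        root = nodes[-1]
        p = self.partials[id(root)][cell] * np.array(
            [1.0 - params.bias, params.bias]
        )
        states[root._pm_index] = int(rng.random() * p.sum() < p[1])
        for node in self.tree.preorder_node_iter():
            if node is root:
                continue
            P = transition_probabilities(params, node.edge.length)
            parent_state = states[node.parent_node._pm_index]
            p = P[parent_state] * self.partials[id(node)][cell]
            states[node._pm_index] = int(rng.random() * p.sum() < p[1])
        return states, params


def _as_rng(rng_seed):
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def draw_model_parameters(
    tree, column, rate_prior, bias_prior, n_draws, rng_seed, tree_index=0
):
    """Sample (rate category, bias category) pairs from their joint posterior
    on the discretized grid for one tree."""
    grid = GridPosterior(tree, column, rate_prior, bias_prior)
    rng = _as_rng(rng_seed)
    return [
        grid.cell_to_draw(cell, tree_index=tree_index)
        for cell in grid.draw_cells(n_draws, rng)
    ]


def sample_node_states(tree, column, params: Mk2Params, rng_seed):
    """One joint posterior sample of ancestral (and missing-tip) states.

    Returns a map from postorder node index to state; observed tips keep
    their scored state with probability one.
    """
    from .priors import DiscretizedPrior

    single = DiscretizedPrior(
        K=1,
        boundaries=np.array([0.0, np.inf]),
        representatives=np.array([params.theta]),
        widths=np.array([np.inf]),
        mean=params.theta,
    )
    single_b = DiscretizedPrior(
        K=1,
        boundaries=np.array([0.0, 1.0]),
        representatives=np.array([params.bias]),
        widths=np.array([1.0]),
        mean=params.bias,
    )
    grid = GridPosterior(tree, column, single, single_b)
    states, _ = grid.sample_states(0, _as_rng(rng_seed))
    return states


# ---------------------------------------------------------------------------
# Endpoint-conditioned path simulation along a single branch
# ---------------------------------------------------------------------------

def _events_from_times(times, start, branch_id):
    events = []
    state = start
    for t in times:
        events.append(
            BranchEvent(branch_id=branch_id, time=t, from_state=state, to_state=1 - state)
        )
        state = 1 - state
    return events


def simulate_branch_history(
    start,
    end,
    length,
    params: Mk2Params,
    rng_seed,
    branch_id=0,
    retry_cap=REJECTION_RETRY_CAP,
):
    """Sample a two-state CTMC path on [0, length] conditioned on its endpoints.

    Rejection sampling: when the endpoints differ the first event time is
    drawn from the exponential truncated to the branch, then the path is
    completed by forward simulation and accepted only if it lands in ``end``.
    After ``retry_cap`` failures an exact uniformization sampler takes over.
    """
    if length <= 0:
        raise ValueError("branch length must be positive")
    rng = _as_rng(rng_seed)
    rates = (2.0 * params.theta * params.bias, 2.0 * params.theta * (1.0 - params.bias))
    for _ in range(retry_cap):
        times = []
        state = start
        t = 0.0
        if start != end:
            r = rates[start]
            u = rng.random()
            t = -math.log1p(-u * -math.expm1(-r * length)) / r
            times.append(t)
            state = 1 - start
        while True:
            t += rng.exponential() / rates[state]
            if t >= length:
                break
            times.append(t)
            state = 1 - state
        if state == end:
            return _events_from_times(times, start, branch_id)
    return _uniformization_path(start, end, length, params, rng, branch_id)


def _uniformization_path(start, end, length, params, rng, branch_id):
    """Exact endpoint-conditioned path via the dominating-Poisson construction."""
    q01 = 2.0 * params.theta * params.bias
    q10 = 2.0 * params.theta * (1.0 - params.bias)
    mu = max(q01, q10)
    R = np.array([[1.0 - q01 / mu, q01 / mu], [q10 / mu, 1.0 - q10 / mu]])
    p_end = transition_probabilities(params, length)[start, end]
    if p_end <= 0:
        raise RuntimeError("endpoint pair has zero probability")
    # number of uniformized steps m ~ Poisson(mu*length) weighted by R^m[start,end]
    mu_t = mu * length
    R_powers = [np.eye(2)]
    log_pois = -mu_t
    weights = []
    total = 0.0
    m = 0
    while total < (1.0 - 1e-12) * p_end and m < 100_000:
        w = math.exp(log_pois) * R_powers[m][start, end]
        weights.append(w)
        total += w
        m += 1
        R_powers.append(R_powers[-1] @ R)
        log_pois += math.log(mu_t) - math.log(m)
    u = rng.random() * total
    acc = 0.0
    m_draw = len(weights) - 1
    for i, w in enumerate(weights):
        acc += w
        if u <= acc:
            m_draw = i
            break
    # bridge through the uniformized chain, then drop virtual (self) jumps
    states = [start]
    for j in range(1, m_draw + 1):
        prev = states[-1]
        p = R[prev] * R_powers[m_draw - j][:, end]
        states.append(int(rng.random() * p.sum() < p[1]))
    jump_times = np.sort(rng.random(m_draw)) * length
    times = [t for t, a, b in zip(jump_times, states[:-1], states[1:]) if a != b]
    return _events_from_times(times, start, branch_id)


# ---------------------------------------------------------------------------
# Full realizations over a tree sample
# ---------------------------------------------------------------------------

def _stream(master_seed, tree_index, realization):
    """Counter-based per-(tree, realization) RNG stream."""
    return np.random.default_rng(
        [int(master_seed) & 0x7FFFFFFF, tree_index, realization]
    )


def _realize_one(grid: GridPosterior, tree_index, rng) -> CharacterHistory:
    cell = int(grid.draw_cells(1, rng)[0])
    draw = grid.cell_to_draw(cell, tree_index=tree_index)
    states, params = grid.sample_states(cell, rng)
    events = []
    n01 = n10 = 0
    for node in postorder_nodes(grid.tree):
        if node is grid.tree.seed_node:
            continue
        if node.edge.length == 0.0:
            # zero-length branch: states cannot differ (P(0) = I), no events
            continue
        branch_events = simulate_branch_history(
            states[node.parent_node._pm_index],
            states[node._pm_index],
            node.edge.length,
            params,
            rng,
            branch_id=node._pm_index,
        )
        for ev in branch_events:
            if ev.from_state == 0:
                n01 += 1
            else:
                n10 += 1
        events.extend(branch_events)
    return CharacterHistory(draw=draw, node_states=states, events=events, n01=n01, n10=n10)


def realize_histories(
    sample, column, rate_prior, bias_prior, realizations_per_tree, rng_seed
):
    """Realize ``realizations_per_tree`` character histories on every tree.

    Model parameters are redrawn from their grid posterior for every
    realization; the grid likelihoods are computed once per tree.
    """
    histories = []
    for tree_index, tree in enumerate(sample):
        grid = GridPosterior(tree, column, rate_prior, bias_prior)
        for r in range(realizations_per_tree):
            rng = _stream(rng_seed, tree_index, r)
            histories.append(_realize_one(grid, tree_index, rng))
    return histories


def histories_to_tsv(histories, path) -> None:
    """Flat realization log: the substrate for all downstream summaries."""
    with open(path, "w") as fh:
        fh.write(
            "realization\ttree_index\trate_category\tbias_category\ttheta\tbias\tn01\tn10\n"
        )
        for i, h in enumerate(histories):
            fh.write(
                "%d\t%d\t%d\t%d\t%.12g\t%.12g\t%d\t%d\n"
                % (
                    i,
                    h.draw.tree_index,
                    h.draw.rate_category,
                    h.draw.bias_category,
                    h.draw.theta,
                    h.draw.bias,
                    h.n01,
                    h.n10,
                )
            )


def events_to_tsv(histories, path) -> None:
    with open(path, "w") as fh:
        fh.write("realization\tbranch_id\ttime\tfrom_state\tto_state\n")
        for i, h in enumerate(histories):
            for ev in h.events:
                fh.write(
                    "%d\t%d\t%.12g\t%d\t%d\n"
                    % (i, ev.branch_id, ev.time, ev.from_state, ev.to_state)
                )
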