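"""Posterior draws, ancestral-state sampling and endpoint-conditioned paths."""

import math
from collections import Counter

import numpy as np
import pytest
from scipy.stats import chisquare, ks_2samp

from _oracles import (
    change_count_distribution,
    directional_split,
    enumeration_node_marginals,
)
from conftest import tree_from_newick
from priormap.mapping import (
    draw_model_parameters,
    node_indices,
    realize_histories,
    sample_node_states,
    simulate_branch_history,
)
from priormap.mk2 import Mk2Params
from priormap.parsimony import fitch_length
from priormap.priors import BetaPrior, discretize_beta, discretize_gamma, moments_to_shape_rate
from priormap.trees import MISSING, CharacterColumn


def flat_priors(K, K_B):
    return (
        discretize_gamma(moments_to_shape_rate(1.0, 1.0), K),
        discretize_beta(BetaPrior(1, 1), K_B),
    )


class TestDrawModelParameters:
    def test_flat_likelihood_samples_grid_uniformly(self, quartet_tree):
        column = CharacterColumn({t: MISSING for t in "ABCD"})
        rate_prior, bias_prior = flat_priors(6, 4)
        draws = draw_model_parameters(
            quartet_tree, column, rate_prior, bias_prior, 10_000, rng_seed=0
        )
        counts = Counter((d.rate_category, d.bias_category) for d in draws)
        observed = [counts.get((r + 1, b + 1), 0) for r in range(6) for b in range(4)]
        assert chisquare(observed).pvalue > 0.01

    def test_two_cell_grid_with_known_likelihood_ratio(self):
        # single tip in state 1: likelihood equals the bias representative,
        # so the flat 2-category bias grid (0.25, 0.75) has posterior (0.25, 0.75)
        tree = tree_from_newick("A:1;")
        column = CharacterColumn({"A": 1})
        rate_prior, bias_prior = flat_priors(1, 2)
        n = 10_000
        draws = draw_model_parameters(tree, column, rate_prior, bias_prior, n, rng_seed=3)
        freq = sum(d.bias_category == 2 for d in draws) / n
        se = math.sqrt(0.75 * 0.25 / n)
        assert abs(freq - 0.75) < 3 * se

    def test_fixed_seed_reproduces_draws(self, quartet_tree, quartet_column):
        rate_prior, bias_prior = flat_priors(5, 5)
        a = draw_model_parameters(quartet_tree, quartet_column, rate_prior, bias_prior, 50, 42)
        b = draw_model_parameters(quartet_tree, quartet_column, rate_prior, bias_prior, 50, 42)
        assert a == b

    def test_draw_representatives_match_prior_entries(self, quartet_tree, quartet_column):
        rate_prior, bias_prior = flat_priors(5, 4)
        for d in draw_model_parameters(quartet_tree, quartet_column, rate_prior, bias_prior, 20, 1):
            assert d.theta == rate_prior.representatives[d.rate_category - 1]
            assert d.bias == bias_prior.representatives[d.bias_category - 1]


class TestSampleNodeStates:
    def test_no_change_limit_fixes_root(self):
        tree = tree_from_newick("(A:1,B:1);")
        node_indices(tree)
        column = CharacterColumn({"A": 1, "B": 1})
        params = Mk2Params(1e-9, 0.5)
        root_index = tree.seed_node._pm_index
        hits = sum(
            sample_node_states(tree, column, params, seed)[root_index]
            for seed in range(2000)
        )
        assert hits / 2000 > 0.999

    def test_matches_enumeration_on_triplet(self, triplet_tree):
        column = CharacterColumn({"A": 1, "B": 0, "C": 1})
        params = Mk2Params(1.0, 0.5)
        internals, exact = enumeration_node_marginals(triplet_tree, column, params)
        node_indices(triplet_tree)
        n = 10_000
        counts = Counter()
        for seed in range(n):
            states = sample_node_states(triplet_tree, column, params, seed)
            counts[tuple(states[node._pm_index] for node in internals)] += 1
        for assignment, p in exact.items():
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts[assignment] / n - p) < 3 * se + 1e-3

    def test_all_missing_root_follows_prior(self):
        tree = tree_from_newick("(A:1,B:1);")
        node_indices(tree)
        column = CharacterColumn({"A": MISSING, "B": MISSING})
        params = Mk2Params(1.0, 0.7)
        root_index = tree.seed_node._pm_index
        n = 5000
        hits = sum(
            sample_node_states(tree, column, params, seed)[root_index]
            for seed in range(n)
        )
        assert abs(hits / n - 0.7) < 3 * math.sqrt(0.7 * 0.3 / n)


class TestSimulateBranchHistory:
    def test_no_change_limit_yields_empty_path(self):
        params = Mk2Params(1e-9, 0.5)
        empty = sum(
            not simulate_branch_history(0, 0, 1.0, params, seed) for seed in range(500)
        )
        assert empty / 500 > 0.999

    def test_parity_odd_when_endpoints_differ(self):
        params = Mk2Params(0.7, 0.3)
        for seed in range(300):
            events = simulate_branch_history(0, 1, 1.2, params, seed)
            assert len(events) % 2 == 1

    def test_parity_even_when_endpoints_match(self):
        params = Mk2Params(1.5, 0.6)
        for seed in range(300):
            events = simulate_branch_history(1, 1, 0.8, params, seed)
            assert len(events) % 2 == 0

    def test_events_are_time_ordered_alternating(self):
        params = Mk2Params(2.0, 0.4)
        events = simulate_branch_history(0, 1, 2.0, params, 5)
        times = [e.time for e in events]
        assert times == sorted(times)
        state = 0
        for e in events:
            assert e.from_state == state and e.to_state == 1 - state
            state = e.to_state

    @pytest.mark.parametrize(
        "start, end, theta, bias",
        [(0, 0, 1.0, 0.5), (0, 1, 1.0, 0.5), (1, 0, 1.5, 0.3)],
    )
    def test_event_counts_match_uniformization_oracle(self, start, end, theta, bias):
        params = Mk2Params(theta, bias)
        length = 1.0
        expected = change_count_distribution(start, end, length, params)
        n = 5000
        rng = np.random.default_rng(17)
        counts = Counter(
            len(simulate_branch_history(start, end, length, params, rng))
            for _ in range(n)
        )
        for k in range(7):
            p = expected[k]
            if p < 1e-4:
                continue
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts.get(k, 0) / n - p) < 3 * se + 2e-3

    def test_uniformization_fallback_is_exact(self):
        # forcing retry_cap=0 exercises the fallback sampler directly
        params = Mk2Params(1.0, 0.5)
        expected = change_count_distribution(0, 1, 1.0, params)
        n = 5000
        rng = np.random.default_rng(23)
        counts = Counter(
            len(simulate_branch_history(0, 1, 1.0, params, rng, retry_cap=0))
            for _ in range(n)
        )
        for k in (1, 3, 5):
            p = expected[k]
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts.get(k, 0) / n - p) < 3 * se + 2e-3


class TestRealizeHistories:
    def test_history_count_is_trees_times_realizations(self, small_study):
        _, sample, _, fast = small_study
        rate_prior, bias_prior = flat_priors(4, 4)
        histories = realize_histories(sample[:3], fast, rate_prior, bias_prior, 4, 0)
        assert len(histories) == 12
        assert {h.draw.tree_index for h in histories} == {0, 1, 2}

    def test_invariants_on_single_history(self, small_study):
        _, sample, _, fast = small_study
        rate_prior, bias_prior = flat_priors(4, 4)
        (history,) = realize_histories(sample[:1], fast, rate_prior, bias_prior, 1, 5)
        assert history.n01 + history.n10 == len(history.events)
        tree = sample[0]
        by_branch = {}
        for event in history.events:
            by_branch.setdefault(event.branch_id, []).append(event)
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            events = sorted(by_branch.get(node._pm_index, []), key=lambda e: e.time)
            state = history.node_states[node.parent_node._pm_index]
            for event in events:
                assert event.from_state == state
                assert 0 <= event.time <= node.edge.length
                state = event.to_state
            assert state == history.node_states[node._pm_index]

    def test_total_changes_bounded_below_by_fitch(self, small_study):
        _, sample, _, fast = small_study
        rate_prior, bias_prior = flat_priors(6, 6)
        histories = realize_histories(sample[:4], fast, rate_prior, bias_prior, 25, 2)
        for h in histories:
            assert h.total >= fitch_length(sample[h.draw.tree_index], fast)

    def test_seed_reproducibility(self, small_study):
        _, sample, _, fast = small_study
        rate_prior, bias_prior = flat_priors(4, 4)
        a = realize_histories(sample[:2], fast, rate_prior, bias_prior, 3, 9)
        b = realize_histories(sample[:2], fast, rate_prior, bias_prior, 3, 9)
        assert [(h.n01, h.n10) for h in a] == [(h.n01, h.n10) for h in b]
        assert [h.events for h in a] == [h.events for h in b]

    def test_identical_trees_exchangeable(self):
        tree_a = tree_from_newick("((A:0.5,B:0.8):0.4,(C:0.6,D:0.3):0.7);")
        tree_b = tree_from_newick("((A:0.5,B:0.8):0.4,(C:0.6,D:0.3):0.7);")
        column = CharacterColumn({"A": 1, "B": 0, "C": 0, "D": 1})
        rate_prior, bias_prior = flat_priors(5, 5)
        histories = realize_histories([tree_a, tree_b], column, rate_prior, bias_prior, 5000, 3)
        totals_a = [h.total for h in histories if h.draw.tree_index == 0]
        totals_b = [h.total for h in histories if h.draw.tree_index == 1]
        assert ks_2samp(totals_a, totals_b).pvalue > 0.01
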