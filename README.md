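# priormap

Posterior (stochastic) mapping of binary morphological characters on samples
of phylogenetic trees, with explicit control over — and tooling to probe —
the gamma prior placed on the character's transformation rate.

## The problem

Stochastic character mapping samples complete character histories (ancestral
states at nodes *and* timed change events along branches) from their
posterior distribution given tip states, a sample of trees, and a two-state
continuous-time Markov model. The model has an overall transformation rate θ
and a directional bias Л; θ carries a gamma prior specified by its mean E(T)
and standard deviation SD(T), Л a beta prior (flat here). Because the gamma
prior cannot be made uninformative, the choice of (E(T), SD(T)) can shape
the headline outputs — average numbers of changes, the posterior probability
PP_c of each character-history class (n<sub>0⇒1</sub>, n<sub>1⇒0</sub>), and
the posterior over discretized rate categories. This package implements the
whole pipeline and the prior-sensitivity sweep, for systematists who want to
know what their priors are doing before interpreting a mapping.

The moving parts:

* **Mk2 model** — generator q01 = 2θЛ, q10 = 2θ(1−Л); stationary
  distribution (1−Л, Л); closed-form transition probabilities
  P(t) = Π + e<sup>−2θt</sup>(I − Π); pruning likelihood with missing tips
  marginalized.
* **Prior discretization** — the gamma (and beta) prior is split into K
  equal-probability categories by quantiles; each category is represented by
  the conditional mean of the distribution inside it, computable in closed
  form through the shape+1 distribution function.
* **Mapping engine** — per realization: draw (rate, bias) categories from
  their joint discrete posterior on the K × K_B grid, sample ancestral
  states jointly, then simulate an endpoint-conditioned path along every
  branch (rejection sampling with a forced first event; exact
  uniformization sampling as fallback).
* **Summaries** — means and 95% HPD of change counts, PP_c tables and
  −log10 grids, width-normalized rate-category histograms.
* **Parsimony references** — Fitch/Hartigan minimum length, directional
  counts from a fixed most-parsimonious reconstruction, consistency index
  c_i = m/s.
* **Synthetic data** — Yule tree samples with lognormal branch jitter and
  forward-simulated characters, certified slow/single-origin (c_i = 1) or
  fast/homoplastic (c_i ≤ 0.2) by construction.

I/O covers Newick and NEXUS tree samples (translate tables included), NEXUS
standard character matrices and CSV columns, and strict majority-rule
consensus trees with mean branch lengths.

## Worked example

```python
from priormap import (
    FixtureSpec, make_study_fixture, moments_to_shape_rate, discretize_gamma,
    discretize_beta, BetaPrior, realize_histories, summarize, ppc_table,
)

sample, slow, fast = make_study_fixture(FixtureSpec(n_trees=20, seed=42))
rate_prior = discretize_gamma(moments_to_shape_rate(E_T=1.0, SD_T=5.0), 60)
bias_prior = discretize_beta(BetaPrior(1, 1), 60)

histories = realize_histories(sample, fast, rate_prior, bias_prior,
                              realizations_per_tree=100, rng_seed=42)
s = summarize(histories)
print(s.mean_total, (s.hpd_low, s.hpd_high), ppc_table(histories).top(1))
```

prints (2,000 realizations of the fast character under the diffuse
low-rate prior)

```
17.956 (10, 37) [((4, 8), 0.031)]
```

i.e. on average ≈ 18 changes per history, a 95% HPD of [10, 37] total
changes, and (n01 = 4, n10 = 8) as the most probable history class at
PP_c = 0.031. The same fixture's slow character returns (1, 0) with
PP_c ≈ 0.85–0.95 regardless of the prior, while its average total still
climbs from 1.1 to 3.1 as E(T) goes 1 → 15 — the prior keeps influencing
the averages even when the best-supported history is stable.

The numbered scripts under `analysis/` run the full study: `01` builds the
66-taxon fixture, `02` tabulates all eight prior discretizations, `03` maps
both characters under the 4 × 2 (E(T), SD(T)) grid, `04` prints the summary
comparisons. Outputs land under `results/`.

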