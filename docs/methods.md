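# Methods

## Model

A binary character evolves along each tree under a two-state
continuous-time Markov chain with instantaneous rates

    q01 = 2 θ Л        q10 = 2 θ (1 − Л)

where θ > 0 is the overall transformation rate (expected changes per unit
branch length at Л = 0.5) and Л ∈ (0, 1) biases change toward state 1. This
convention reduces to the symmetric two-state Mk model with rate θ at
Л = 0.5 and has stationary distribution π = (1 − Л, Л). No canonical
scaling exists for this generator across software; the convention is
isolated in `mk2.rate_matrix` so it can be swapped wholesale, and absolute
θ values should not be compared across programs. Transition probabilities
have the closed form P(t) = Π + e^(−2θt)(I − Π) with Π the rank-one
stationary projector; likelihoods use the pruning recursion with per-node
rescaling, missing tips contributing the all-ones partial. The root state
prior is π (a flat root is available via `root_prior="flat"`); with the
stationary root and Л = 0.5 the chain is reversible and the likelihood is
invariant under rerooting, which the tests exploit.

Branch lengths are taken as given (expected substitutions per site of the
molecular trees the samples come from); θ is therefore a
morphology-to-molecule rate multiplier.

## Priors and their discretization

θ carries a gamma prior parametrized by mean E(T) and standard deviation
SD(T); the unique gamma with those moments has shape (E/SD)² and rate
E/SD². Л carries a beta prior, flat (α = β = 1) throughout the study
design. Both are discretized into K equal-probability categories whose
boundaries are the i/K quantiles; category i is represented by the
conditional mean of the distribution inside it, computed in closed form via
the shape+1 distribution function (so the probability-weighted mean of the
representatives equals E(T) exactly, up to quantile round-off). Defaults:
K = K_B = 60.

Equal-mass discretization makes category widths small near the bulk of the
prior and large in the tails; for a diffuse low-rate prior (E(T) = 1,
SD(T) = 5, shape 0.04) the lowest quantiles collapse numerically to zero
while the top category alone spans ≈ 144 rate units and is represented by
its conditional mean 32.24 (the next category by 11.76). Categories whose
representative falls below 1e−5 are reported with zero density by the
*plotting* layer only (`summaries.ZERO_RATE_THRESHOLD`); their probability
mass stays exactly 1/K. The unbounded last category records, for plotting
only, the distance from its lower boundary to the 99.999% quantile as its
"width".

## The mapping engine

One realization on one tree proceeds as:

1. **Parameter draw.** The prior puts mass 1/(K·K_B) on each (rate, bias)
   category pair, so the joint posterior over grid cells is proportional to
   the pruning likelihood at the cells' representatives. Likelihoods for
   all K·K_B cells are computed once per tree (vectorized across cells) and
   reused by every realization on that tree.
2. **Ancestral states.** A joint sample from the posterior of node states:
   the root from root-prior × partials, then each child in pre-order from
   transition-row × partials conditioned on its sampled parent. Missing
   tips are sampled like internal nodes and their branch changes count
   toward the totals (whether the original tooling counted those branches
   is unknowable; this choice is symmetric and keeps histories complete).
3. **Branch paths.** Each branch is an endpoint-conditioned path problem.
   Rejection sampling: when the endpoints differ, the first event time is
   drawn from the exponential truncated to the branch, the rest forward,
   accepted when the realized endpoint matches; after 10,000 failures an
   exact uniformization sampler takes over (dominating Poisson rate
   μ = max(q01, q10); number of uniformized steps drawn from the
   Poisson-weighted power series, the step chain bridged with backward
   R-powers, virtual jumps dropped). Event times run rootward-to-tipward
   from the parent end; the parity of a branch's event count always matches
   its endpoints.

Parameters are redrawn for every realization, not once per tree, so the
category sampling frequencies of the draws are themselves the posterior
over rate categories. Randomness comes from one master seed through
per-(tree, realization) `default_rng([seed, tree, r])` streams —
reproducible and independent of execution order. Zero-length branches carry
no events (P(0) = I makes differing endpoints impossible).

## Summaries

Per (prior, character) cell: arithmetic means of n01, n10 and totals; the
95% HPD on totals as the *shortest contiguous integer interval* holding
≥ 95% of realizations (ties to the smaller lower bound; an exhaustive scan,
since the estimator is otherwise underdetermined on discrete counts);
posterior parameter means as averages of the drawn representatives (what a
grid-based sampler can report); PP_c as occurrence frequency per (n01, n10)
class, ranked with ties broken by (total, n01) ascending; −log10 PP_c grids
omitting unobserved classes; and width-normalized category densities
(count/n/width, so density × width sums to one).

Directional counts are always reported as ordered pairs (n01, n10), never
as "gains"/"losses" — the latter wording depends on which state is derived
and invites exactly the label swaps it is meant to avoid.

## Parsimony references

Minimum changes come from a unit-cost dynamic program (Sankoff recursion),
exact on multifurcations, with missing tips free. Directional counts use
one fixed deterministic reconstruction: root ties resolve to state 0 and a
child keeps its parent's state whenever that is optimal — any fixed
minimum-length refinement is equally defensible since only the total is
identified. The consistency index is c_i = m/s with m = observed states − 1
(1 for binary characters); it is undefined (raises) for invariant
characters.

Majority-rule consensus keeps exactly the clades present in > 50% of the
rooted sample (ties at 50% excluded), with branch lengths averaged over the
trees containing the clade (mean, not median — the choice is essentially
unidentified and mean matches the averaging used everywhere else here).

## Synthetic data

The fixture generator stands in for a Bayesian tree sample plus character
scorings that cannot be shipped: one pure-birth (Yule) topology on
`n_taxa = 66` tips, rescaled to mean root-to-tip depth `tree_depth = 0.1`
expected substitutions per site (a realistic family-level chloroplast
depth), cloned into `n_trees = 201` trees whose branch lengths are each
multiplied by an independent lognormal factor with median 1 and log-sd 0.1
(emulating posterior branch-length spread without running an MCMC; topology
is held fixed, unlike a real posterior sample). Characters evolve forward
from a stationary root draw. The slow character (generating θ = 1) is
resimulated until it shows a single origin of the derived state on the base
tree (Fitch length 1, ≥ 2 derived taxa, c_i = 1); the fast character
(θ = 10) until Fitch length ≥ 5 (c_i ≤ 0.2), after which ~5% of its tips
are masked as missing. The θ scale was chosen so the two characters'
rates per unit branch length (~1 and ~10) sit on the same scale the prior
grid E(T) ∈ {1, 5, 10, 15} is meant to bracket — the slow character near
the bottom of the grid, the fast character inside every diffuse-prior
discretization.

What passing tests on this fixture do *not* show about real data: there is
no topological uncertainty between trees, no correlation structure in
branch-length errors, no character/tree co-estimation, and the two
characters are exchangeable draws from the assumed model rather than real
morphology (no hidden states, no rate heterogeneity across branches).

## Tunable parameters

| parameter | default | units / meaning |
|---|---|---|
| E(T), SD(T) | grid {1,5,10,15} × {1,5} | prior mean/sd of θ, changes per unit branch length |
| K, K_B | 60, 60 | rate / bias categories (equal mass 1/K) |
| α_B = β_B | 1 | flat bias prior |
| realizations per tree | 1,000 (full design) | histories per tree per cell |
| trees | last 201 of the sample | burn-in removal by `last_n` |
| posterior draws | 10,000 | category-frequency estimates (on the consensus tree — which tree the draws condition on is a free choice; the consensus is the single most defensible one) |
| rejection retry cap | 10,000 | before the exact uniformization fallback |

The analysis scripts and the acceptance tests run a desk-scale rendition of
the full design — 20 trees × 100 realizations per cell (2,000 histories)
and 10,000 parameter draws — which this package treats as its standard
reporting size; the full 201 × 1,000 design runs unchanged through the same
`SweepConfig`.

## Numerical choices and degenerate inputs

* Pruning partials are rescaled per node; all-zero likelihood rows map to
  −inf log-likelihood, and a grid whose every cell is −inf raises.
* Gamma quantiles and conditional means come from scipy's incomplete-gamma
  routines; boundaries are forced to [0, ∞) and must be strictly increasing
  on the interior or discretization raises.
* The uniformization series is truncated when the accumulated Poisson-power
  weight reaches 1 − 1e−12 of the endpoint probability.
* Branch lengths must be present (except the root edge, which is ignored)
  and non-negative; zero-length branches are legal and event-free.
* `?` and `-` both read as missing; any other symbol outside {0, 1} is an
  error naming the offending taxon.
* HPD/PP_c/consensus tie-breaks are fixed as described above so that equal
  seeds give byte-identical TSV output across runs and platforms.

## Known limitations

* Two states only; no per-branch rate multipliers or covarion behavior.
* Posterior parameter summaries are means over discrete representatives, so
  they inherit the discretization's granularity (coarse for small K).
* The rejection sampler's acceptance rate degrades on long branches with
  strongly asymmetric rates; the uniformization fallback is exact but
  slower, and extremely high μt (≫ 10⁴ expected events on one branch) would
  be impractical.
* The qualitative prior-sensitivity findings are asserted as seeded
  regressions on the fixture, not as universal laws. One finding is
  signal-dependent: under this fixture the tight priors E(T) = 1 and 5 both
  sit below the fast character's data-supported rate, so those two cells
  agree on the minimal-change top history, and the top history's
  prior-dependence is asserted across the grid extremes (E(T) = 1 vs 15)
  instead — with strong data signal the most probable history can be
  prior-invariant even for homoplastic characters.
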