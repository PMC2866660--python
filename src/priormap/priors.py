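"""Priors on the transformation rate and directional bias, and their
equal-probability discretizations.

The transformation rate theta carries a gamma prior parametrized by its mean
E(T) and standard deviation SD(T); the directional bias carries a beta prior
(flat, alpha=beta=1, throughout the study design).  For simulation both are
discretized into K categories of probability mass 1/K, each represented by
the conditional mean of the distribution inside the category — the category
boundaries are quantiles at i/K, so category widths are narrow near the bulk
of the prior and grow toward the tails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import gamma as gamma_dist


@dataclass(frozen=True)
class GammaPrior:
    """Gamma prior on theta; shape/rate derived from (mean, sd)."""

    E_T: float
    SD_T: float
    alpha_S: float
    beta_S: float


@dataclass(frozen=True)
class BetaPrior:
    alpha_B: float = 1.0
    beta_B: float = 1.0

    @property
    def is_flat(self) -> bool:
        return self.alpha_B == 1.0 and self.beta_B == 1.0


@dataclass(frozen=True)
class DiscretizedPrior:
    """K equal-mass categories of a continuous prior.

    boundaries[i] are the i/K quantiles (boundaries[0] is the lower support
    limit, boundaries[K] the upper, possibly +inf); representatives[i] is the
    conditional mean inside category i+1; widths are boundary differences,
    with an unbounded last category recorded as the distance to the 99.999%
    quantile (plotting support only — the probability mass stays exactly 1/K).
    """

    K: int
    boundaries: np.ndarray
    representatives: np.ndarray
    widths: np.ndarray
    mean: float

    @property
    def mass(self) -> float:
        return 1.0 / self.K

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("category\tlower\tupper\trepresentative\twidth\n")
            for i in range(self.K):
                fh.write(
                    "%d\t%.12g\t%.12g\t%.12g\t%.12g\n"
                    % (
                        i + 1,
                        self.boundaries[i],
                        self.boundaries[i + 1],
                        self.representatives[i],
                        self.widths[i],
                    )
                )


def moments_to_shape_rate(E_T: float, SD_T: float) -> GammaPrior:
    """Convert (mean, sd) of the rate prior to gamma (shape, rate).

    shape = (E/SD)^2 and rate = E/SD^2, the unique gamma with that mean and
    standard deviation.
    """
    if E_T <= 0 or SD_T <= 0:
        raise ValueError("E_T and SD_T must be positive")
    return GammaPrior(
        E_T=E_T, SD_T=SD_T, alpha_S=(E_T / SD_T) ** 2, beta_S=E_T / SD_T**2
    )


def gamma_density(prior: GammaPrior, x) -> np.ndarray:
    """Gamma prior density at x (vectorized)."""
    return gamma_dist.pdf(x, prior.alpha_S, scale=1.0 / prior.beta_S)


def discretize_gamma(prior: GammaPrior, K: int) -> DiscretizedPrior:
    """Split the gamma prior into K equal-mass categories with conditional-mean
    representatives.

    The conditional mean over (a, b] has the closed form
    ``mean * (F_{shape+1}(b) - F_{shape+1}(a)) * K`` where F_{shape+1} is the
    gamma CDF with shape alpha+1 and the same rate.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    shape, scale = prior.alpha_S, 1.0 / prior.beta_S
    boundaries = gamma_dist.ppf(np.arange(K + 1) / K, shape, scale=scale)
    boundaries[0], boundaries[-1] = 0.0, np.inf
    if not np.all(np.isfinite(boundaries[1:-1])) or np.any(
        np.diff(boundaries[:-1]) <= 0
    ):
        raise ValueError("gamma quantile computation failed for K=%d" % K)
    upper_cdf = gamma_dist.cdf(boundaries, shape + 1, scale=scale)
    upper_cdf[-1] = 1.0
    representatives = prior.E_T * np.diff(upper_cdf) * K
    widths = np.diff(boundaries)
    widths[-1] = gamma_dist.ppf(0.99999, shape, scale=scale) - boundaries[-2]
    return DiscretizedPrior(
        K=K,
        boundaries=boundaries,
        representatives=representatives,
        widths=widths,
        mean=prior.E_T,
    )


def discretize_beta(prior: BetaPrior, K_B: int) -> DiscretizedPrior:
    """Equal-mass discretization of the beta prior on (0, 1)."""
    if K_B < 1:
        raise ValueError("K_B must be >= 1")
    a, b = prior.alpha_B, prior.beta_B
    boundaries = beta_dist.ppf(np.arange(K_B + 1) / K_B, a, b)
    boundaries[0], boundaries[-1] = 0.0, 1.0
    mean = a / (a + b)
    upper_cdf = beta_dist.cdf(boundaries, a + 1, b)
    representatives = mean * np.diff(upper_cdf) * K_B
    widths = np.diff(boundaries)
    return DiscretizedPrior(
        K=K_B,
        boundaries=boundaries,
        representatives=representatives,
        widths=widths,
        mean=mean,
    )
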