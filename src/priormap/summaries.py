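"""Summary statistics over realization logs.

Reduces lists of character histories to the study's reporting quantities:
average transformation counts with a 95% HPD interval, posterior means of
the model parameters, the posterior probability of each character-history
class PP_c (occurrence frequency of each (n01, n10) pair), its -log10 grid,
and width-normalized rate-category sampling densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Categories whose representative falls below this are reported with zero
#: density — a plotting convention for priors whose lowest quantiles collapse
#: numerically to zero; their probability mass is untouched.
ZERO_RATE_THRESHOLD = 1e-5


@dataclass(frozen=True)
class MappingSummary:
    mean_total: float
    mean_n01: float
    mean_n10: float
    hpd_low: int
    hpd_high: int
    post_mean_theta: float
    post_mean_bias: float
    n_realizations: int


@dataclass(frozen=True)
class PPcTable:
    entries: dict  # (n01, n10) -> probability
    n_realizations: int

    def ranked(self):
        """Entries by decreasing probability; ties by (total, n01) ascending."""
        return sorted(
            self.entries.items(),
            key=lambda kv: (-kv[1], kv[0][0] + kv[0][1], kv[0][0]),
        )

    def top(self, n=6):
        return self.ranked()[:n]


@dataclass(frozen=True)
class CategoryFrequencies:
    counts: np.ndarray  # per category, length K
    densities: np.ndarray
    representatives: np.ndarray
    widths: np.ndarray
    n_draws: int


def hpd_interval(totals, mass=0.95):
    """Shortest contiguous integer interval holding at least ``mass`` of the
    values; ties go to the smaller lower bound (exhaustive scan)."""
    totals = np.asarray(totals, dtype=int)
    n = totals.size
    lo, hi = int(totals.min()), int(totals.max())
    counts = np.bincount(totals - lo, minlength=hi - lo + 1)
    cum = np.concatenate([[0], np.cumsum(counts)])
    needed = math.ceil(mass * n)
    best = None
    for a in range(hi - lo + 1):
        for b in range(a, hi - lo + 1):
            if cum[b + 1] - cum[a] >= needed:
                width = b - a
                if best is None or width < best[0]:
                    best = (width, a + lo, b + lo)
                break
    return best[1], best[2]


def summarize(histories) -> MappingSummary:
    """Table-style row for one (prior, character) combination."""
    if not histories:
        raise ValueError("no histories to summarize")
    n01 = np.array([h.n01 for h in histories], dtype=float)
    n10 = np.array([h.n10 for h in histories], dtype=float)
    totals = (n01 + n10).astype(int)
    low, high = hpd_interval(totals)
    return MappingSummary(
        mean_total=float((n01 + n10).mean()),
        mean_n01=float(n01.mean()),
        mean_n10=float(n10.mean()),
        hpd_low=low,
        hpd_high=high,
        post_mean_theta=float(np.mean([h.draw.theta for h in histories])),
        post_mean_bias=float(np.mean([h.draw.bias for h in histories])),
        n_realizations=len(histories),
    )


def ppc_table(histories) -> PPcTable:
    """Posterior probability of each character-history class (n01, n10)."""
    if not histories:
        raise ValueError("no histories")
    counts: dict = {}
    for h in histories:
        key = (h.n01, h.n10)
        counts[key] = counts.get(key, 0) + 1
    n = len(histories)
    return PPcTable(
        entries={k: c / n for k, c in counts.items()}, n_realizations=n
    )


def neglog10_grid(table: PPcTable) -> dict:
    """-log10(PP_c) keyed by (n01, n10); unobserved classes are omitted."""
    return {k: -math.log10(p) for k, p in table.entries.items()}


def category_frequencies(draws, prior) -> CategoryFrequencies:
    """Sampling counts and width-normalized densities of the rate categories.

    ``draws`` are ModelDraws referencing ``prior``'s categories.  Densities
    are (count/n)/width so that density x width sums to one; categories with
    representatives below ZERO_RATE_THRESHOLD are zeroed for plotting.
    """
    K = prior.K
    counts = np.zeros(K, dtype=int)
    for d in draws:
        if not 1 <= d.rate_category <= K:
            raise ValueError("rate category %d out of range 1..%d" % (d.rate_category, K))
        counts[d.rate_category - 1] += 1
    n = len(draws)
    densities = counts / n / prior.widths
    densities[prior.representatives < ZERO_RATE_THRESHOLD] = 0.0
    return CategoryFrequencies(
        counts=counts,
        densities=densities,
        representatives=prior.representatives.copy(),
        widths=prior.widths.copy(),
        n_draws=n,
    )


# ---------------------------------------------------------------------------
# TSV writers
# ---------------------------------------------------------------------------

def summary_rows_to_tsv(rows, path) -> None:
    """rows: iterable of (character, E_T, SD_T, MappingSummary)."""
    with open(path, "w") as fh:
        fh.write(
            "character\tE_T\tSD_T\tpost_mean_theta\tpost_mean_bias\t"
            "mean_total\thpd_low\thpd_high\tmean_n01\tmean_n10\tn_realizations\n"
        )
        for character, e, sd, s in rows:
            fh.write(
                "%s\t%g\t%g\t%.6g\t%.6g\t%.6g\t%d\t%d\t%.6g\t%.6g\t%d\n"
                % (
                    character, e, sd, s.post_mean_theta, s.post_mean_bias,
                    s.mean_total, s.hpd_low, s.hpd_high, s.mean_n01,
                    s.mean_n10, s.n_realizations,
                )
            )


def ppc_top_to_tsv(table: PPcTable, path, n=6) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tn01\tn10\tppc\n")
        for rank, ((a, b), p) in enumerate(table.top(n), start=1):
            fh.write("%d\t%d\t%d\t%.6g\n" % (rank, a, b, p))


def neglog10_grid_to_tsv(table: PPcTable, path) -> None:
    grid = neglog10_grid(table)
    with open(path, "w") as fh:
        fh.write("n01\tn10\tneglog10_ppc\n")
        for (a, b) in sorted(grid):
            fh.write("%d\t%d\t%.6g\n" % (a, b, grid[(a, b)]))


def category_frequencies_to_tsv(freqs: CategoryFrequencies, prior, path, gamma_prior=None) -> None:
    """Histogram TSV (Fig-style data layer) with optional prior-density column."""
    from .priors import gamma_density

    with open(path, "w") as fh:
        header = "category\trepresentative\twidth\tcount\tdensity"
        if gamma_prior is not None:
            header += "\tprior_density"
        fh.write(header + "\n")
        for i in range(freqs.counts.size):
            line = "%d\t%.12g\t%.12g\t%d\t%.12g" % (
                i + 1,
                freqs.representatives[i],
                freqs.widths[i],
                freqs.counts[i],
                freqs.densities[i],
            )
            if gamma_prior is not None:
                line += "\t%.12g" % gamma_density(gamma_prior, freqs.representatives[i])
            fh.write(line + "\n")
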