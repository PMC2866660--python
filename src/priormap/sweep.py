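"""Orchestration of the full prior-sensitivity experiment.

A sweep maps every configured character under every (E(T), SD(T)) cell of
the prior grid and writes, per character x cell: a summary row (posterior
parameter means, average transformation counts, 95% HPD), the top-6 PP_c
classes, the -log10 PP_c grid, a rate-category sampling histogram with the
prior density overlay, plus parsimony reference rows on the majority-rule
consensus tree and a run log.  Everything is reproducible from
(config, seed).

Default settings mirror the study design: K = K_B = 60 categories, a flat
bias prior, the grid E(T) in {1, 5, 10, 15} x SD(T) in {1, 5}, 201 trees x
1,000 realizations, and 10,000 posterior parameter draws.
"""

from __future__ import annotations

import os
import time
import traceback
from dataclasses import dataclass, field

from .mapping import draw_model_parameters, histories_to_tsv, realize_histories
from .parsimony import parsimony_result, parsimony_to_tsv
from .priors import BetaPrior, discretize_beta, discretize_gamma, moments_to_shape_rate
from .summaries import (
    category_frequencies,
    category_frequencies_to_tsv,
    neglog10_grid_to_tsv,
    ppc_table,
    ppc_top_to_tsv,
    summarize,
    summary_rows_to_tsv,
)
from .trees import majority_rule_consensus, read_character_column, read_tree_sample

PAPER_GRID = [(e, sd) for e in (1.0, 5.0, 10.0, 15.0) for sd in (1.0, 5.0)]


@dataclass
class SweepConfig:
    tree_file: str
    characters: list  # of (name, path, column-or-None)
    output_dir: str
    last_n: object = "all"
    grid: list = field(default_factory=lambda: list(PAPER_GRID))
    K: int = 60
    K_B: int = 60
    realizations_per_tree: int = 1000
    prior_draws: int = 10000
    seed: int = 0
    write_histories: bool = True


def parse_config(path) -> SweepConfig:
    """Flat key=value config; ``grid`` and ``character`` keys repeat."""
    values = {"grid": [], "characters": []}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "grid":
                e, sd = value.split(",")
                values["grid"].append((float(e), float(sd)))
            elif key == "character":
                parts = [p.strip() for p in value.split(",")]
                name, cpath = parts[0], parts[1]
                column = parts[2] if len(parts) > 2 else None
                values["characters"].append((name, cpath, column))
            elif key == "last_n":
                values["last_n"] = "all" if value == "all" else int(value)
            elif key in {"K", "K_B", "realizations_per_tree", "prior_draws", "seed"}:
                values[key] = int(value)
            elif key in {"tree_file", "output_dir"}:
                values[key] = value
            elif key == "write_histories":
                values[key] = value.lower() in {"1", "true", "yes"}
            else:
                raise ValueError("unknown config key %r" % key)
    if not values["grid"]:
        values.pop("grid")
    return SweepConfig(**values)


def validate_config(config: SweepConfig):
    """Diagnostics (empty list means the config is runnable)."""
    issues = []
    if not config.grid:
        issues.append("grid must be non-empty")
    if config.K < 2:
        issues.append("K must be >= 2")
    if config.K_B < 1:
        issues.append("K_B must be >= 1")
    if config.realizations_per_tree < 1:
        issues.append("realizations_per_tree must be >= 1")
    if config.prior_draws < 1:
        issues.append("prior_draws must be >= 1")
    if not config.characters:
        issues.append("at least one character is required")
    if not os.path.exists(config.tree_file):
        issues.append("tree file not found: %s" % config.tree_file)
    for name, path, _ in config.characters:
        if not os.path.exists(path):
            issues.append("character file not found: %s (%s)" % (path, name))
    if config.last_n != "all" and int(config.last_n) < 1:
        issues.append("last_n must be positive or 'all'")
    return issues


def _cell_seed(master, char_index, cell_index):
    return (int(master) * 1009 + char_index * 131 + cell_index + 1) & 0x7FFFFFFF


def run_sweep(config: SweepConfig) -> dict:
    """Run the experiment; returns {(character, E, SD): results} and writes
    the report bundle under config.output_dir."""
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid sweep config: %s" % "; ".join(issues))
    os.makedirs(config.output_dir, exist_ok=True)
    sample = read_tree_sample(config.tree_file, config.last_n)
    consensus = majority_rule_consensus(sample)
    bias_cats = discretize_beta(BetaPrior(1.0, 1.0), config.K_B)
    log_path = os.path.join(config.output_dir, "run_log.txt")
    results = {}
    summary_rows = []
    parsimony_rows = []
    with open(log_path, "w") as log:
        log.write("# sweep seed=%d trees=%d\n" % (config.seed, len(sample)))
        for char_index, (name, path, column_name) in enumerate(config.characters):
            column = read_character_column(path, column_name)
            column.name = name
            parsimony_rows.append((name, parsimony_result(consensus, column)))
            for cell_index, (e, sd) in enumerate(config.grid):
                tag = "%s_%g_%g" % (name, e, sd)
                seed = _cell_seed(config.seed, char_index, cell_index)
                t0 = time.perf_counter()
                try:
                    gamma_prior = moments_to_shape_rate(e, sd)
                    rate_cats = discretize_gamma(gamma_prior, config.K)
                    histories = realize_histories(
                        sample, column, rate_cats, bias_cats,
                        config.realizations_per_tree, seed,
                    )
                    summary = summarize(histories)
                    table = ppc_table(histories)
                    draws = draw_model_parameters(
                        consensus, column, rate_cats, bias_cats,
                        config.prior_draws, [seed, 999],
                    )
                    freqs = category_frequencies(draws, rate_cats)
                except Exception as exc:
                    log.write(
                        "cell %s seed=%d FAILED: %s\n%s\n"
                        % (tag, seed, exc, traceback.format_exc())
                    )
                    continue
                out = os.path.join(config.output_dir, tag)
                if config.write_histories:
                    histories_to_tsv(histories, out + "_histories.tsv")
                ppc_top_to_tsv(table, out + "_ppc_top.tsv")
                neglog10_grid_to_tsv(table, out + "_ppc_grid.tsv")
                category_frequencies_to_tsv(
                    freqs, rate_cats, out + "_categories.tsv", gamma_prior=gamma_prior
                )
                rate_cats.to_tsv(out + "_discretization.tsv")
                summary_rows.append((name, e, sd, summary))
                results[(name, e, sd)] = {
                    "summary": summary,
                    "ppc": table,
                    "category_frequencies": freqs,
                    "histories": histories,
                }
                log.write(
                    "cell %s seed=%d realizations=%d wall=%.1fs\n"
                    % (tag, seed, summary.n_realizations, time.perf_counter() - t0)
                )
    summary_rows_to_tsv(summary_rows, os.path.join(config.output_dir, "summary.tsv"))
    parsimony_to_tsv(parsimony_rows, os.path.join(config.output_dir, "parsimony.tsv"))
    return results
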