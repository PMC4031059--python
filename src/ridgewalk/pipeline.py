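"""Batch orchestration: from a RunConfig to landscapes, walks, and records.

Thin glue between the configuration layer and the scientific modules; the
CLI and the example scripts both run through here so that a (config,
master_seed) pair fully determines every output.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import RunConfig, landscape_rng, walk_rng
from .genotype import to_bitstring
from .landscapes import (
    FitnessDistributionSummary,
    Landscape,
    make_nk_landscape,
    make_rmf_landscape,
    quartile_bounds,
    sample_low_fitness_genotype,
    sample_uniform_genotype,
)
from .walks import Walk, run_walk

__all__ = ["SimulationBatch", "make_landscape", "simulate_batch", "walks_to_frame"]


@dataclass
class SimulationBatch:
    """Everything one batch produced, with walk->landscape pairing intact."""

    config: RunConfig
    landscapes: list[Landscape]
    summaries: list[FitnessDistributionSummary]
    walks: list[Walk]
    walk_landscapes: list[Landscape]


def make_landscape(config: RunConfig, index: int) -> Landscape:
    """Construct landscape ``index`` of a batch from its derived stream."""
    rng = landscape_rng(config.master_seed, index)
    if config.model == "nk":
        return make_nk_landscape(config.L, config.K, config.c_min, config.c_max, rng)
    return make_rmf_landscape(config.L, config.slope, config.noise_low,
                              config.noise_high, config.w_min, config.w_max, rng)


def simulate_batch(config: RunConfig) -> SimulationBatch:
    """Generate the full ensemble of landscapes and adaptive walks.

    Quartile/tail summaries use the Gaussian approximation for NK and
    empirical quantiles for RMF. Start genotypes follow ``start_rule``:
    the low-fitness tail (the study's default) or uniform.
    """
    landscapes: list[Landscape] = []
    summaries: list[FitnessDistributionSummary] = []
    walks: list[Walk] = []
    walk_landscapes: list[Landscape] = []
    mode = "theoretical" if config.model == "nk" else "empirical"
    for i in range(config.n_landscapes):
        lnd = make_landscape(config, i)
        summary = quartile_bounds(lnd, mode)
        landscapes.append(lnd)
        summaries.append(summary)
        for j in range(config.walks_per_landscape):
            rng = walk_rng(config.master_seed, i, j)
            if config.start_rule == "low_tail":
                start = sample_low_fitness_genotype(lnd, summary, rng)
            else:
                start = sample_uniform_genotype(config.L, rng)
            walk = run_walk(lnd, start, config.scheme, rng,
                            landscape_id=f"{config.model}-{i}", seed=f"{i}.{j}")
            walks.append(walk)
            walk_landscapes.append(lnd)
    return SimulationBatch(config=config, landscapes=landscapes, summaries=summaries,
                           walks=walks, walk_landscapes=walk_landscapes)


def walks_to_frame(walks: list[Walk]) -> pd.DataFrame:
    """Flatten walks into a tidy table: one row per visited genotype."""
    rows = []
    for walk_id, walk in enumerate(walks):
        for step, (g, w) in enumerate(zip(walk.genotypes, walk.fitnesses)):
            rows.append({
                "walk_id": walk_id,
                "step_index": step,
                "genotype_bitstring": to_bitstring(g),
                "fitness": w,
                "scheme": walk.scheme,
                "landscape_id": walk.landscape_id,
            })
    return pd.DataFrame(
        rows,
        columns=["walk_id", "step_index", "genotype_bitstring",
                 "fitness", "scheme", "landscape_id"],
    )
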