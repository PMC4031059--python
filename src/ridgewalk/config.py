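"""Run configuration and reproducible random-stream management.

A batch run is fully specified by a :class:`RunConfig` plus its
``master_seed``: the config declares the landscape family and its
parameters, ensemble sizes, walk scheme, start rule, and epistasis scale.
Configs round-trip losslessly through YAML.

Random streams are derived hierarchically from the master seed with
``numpy.random.SeedSequence`` spawn keys: landscape i gets spawn key
``(i,)`` and walk j on landscape i gets ``(i, 1, j)``, so any single
landscape or walk can be replayed in isolation without regenerating the
rest of the batch.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Literal

import numpy as np
import yaml

__all__ = ["RunConfig", "landscape_rng", "walk_rng", "sampling_rng"]


@dataclass
class RunConfig:
    """Declarative description of one simulation batch."""

    model: Literal["nk", "rmf"] = "nk"
    L: int = 15
    # NK parameters
    K: int = 10
    c_min: float = 0.1
    c_max: float = 1.0
    # RMF parameters
    slope: float = 0.25
    noise_low: float = 0.0
    noise_high: float = 1.0
    w_min: float = 1.0
    w_max: float = 2.0
    # batch
    n_landscapes: int = 1000
    walks_per_landscape: int = 1
    scheme: Literal["sswm", "equal"] = "sswm"
    start_rule: Literal["low_tail", "uniform"] = "low_tail"
    scale: Literal["multiplicative", "additive"] = "multiplicative"
    master_seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = [
            (self.model in ("nk", "rmf"), "model must be 'nk' or 'rmf'"),
            (self.L >= 2, "L must be >= 2"),
            (self.n_landscapes >= 0, "n_landscapes must be >= 0"),
            (self.walks_per_landscape >= 0, "walks_per_landscape must be >= 0"),
            (self.scheme in ("sswm", "equal"), "scheme must be 'sswm' or 'equal'"),
            (self.start_rule in ("low_tail", "uniform"),
             "start_rule must be 'low_tail' or 'uniform'"),
            (self.scale in ("multiplicative", "additive"),
             "scale must be 'multiplicative' or 'additive'"),
        ]
        if self.model == "nk":
            checks += [
                (0 <= self.K <= self.L - 1, "K must be in [0, L-1]"),
                (0 < self.c_min < self.c_max, "require 0 < c_min < c_max"),
            ]
        else:
            checks += [
                (self.slope >= 0, "slope must be nonnegative"),
                (self.noise_low <= self.noise_high, "require noise_low <= noise_high"),
                (self.w_min < self.w_max, "require 0 < w_min < w_max"),
                (self.w_min > 0, "w_min must be positive"),
            ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("config document must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


def landscape_rng(master_seed: int, landscape_index: int) -> np.random.Generator:
    """Random stream for constructing landscape ``landscape_index``."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(landscape_index,))
    )


def walk_rng(master_seed: int, landscape_index: int, walk_index: int) -> np.random.Generator:
    """Random stream for walk ``walk_index`` on landscape ``landscape_index``.

    Covers both the start-genotype draw and the walk's step choices.
    """
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(landscape_index, 1, walk_index))
    )


def sampling_rng(master_seed: int, purpose: int = 2) -> np.random.Generator:
    """Random stream for batch-level sampling (quadruples, controls)."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(purpose, 7)))
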