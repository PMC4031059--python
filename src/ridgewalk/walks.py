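"""Adaptive walks under strong-selection-weak-mutation (SSWM) dynamics.

An adaptive walk is a path of mutational neighbors with strictly increasing
fitness, started from a chosen genotype and ended at a local optimum (a
genotype with no fitter neighbor). At each step the walker moves to one of
the fitter neighbors g' of the current genotype g:

* ``sswm`` — with probability proportional to the selection coefficient
  s = w(g')/w(g) - 1, the origin-fixation weighting of a monomorphic
  population in which each beneficial mutation fixes with probability
  proportional to s (first-order in s);
* ``equal`` — uniformly among the fitter neighbors, the ranking-only null
  that uses no quantitative fitness information.

Exact fitness ties are treated as non-beneficial and never taken; under the
continuous-fitness landscape models ties have probability zero, but the
rule is fixed so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .genotype import Genotype, hamming_distance, validate_genotype
from .landscapes import Landscape

__all__ = ["Walk", "fitter_neighbors", "fixation_probabilities", "run_walk", "validate_walk"]

Scheme = Literal["sswm", "equal"]


@dataclass(frozen=True)
class Walk:
    """One adaptive walk: the genotypes visited, their fitnesses, and provenance."""

    genotypes: tuple[Genotype, ...]
    fitnesses: tuple[float, ...]
    scheme: Scheme
    landscape_id: str = ""
    seed: str = ""

    def __len__(self) -> int:
        return len(self.genotypes)

    @property
    def n_steps(self) -> int:
        return len(self.genotypes) - 1


def fitter_neighbors(lnd: Landscape, g: Sequence[int]) -> list[tuple[Genotype, float]]:
    """Strictly fitter mutational neighbors of ``g`` with their selection coefficients.

    Returns (neighbor, s) pairs with s = w(g')/w(g) - 1 > 0, ordered by
    flipped-locus index. Neighbors of exactly equal fitness are excluded.
    """
    validate_genotype(g, lnd.L)
    g_arr = np.asarray(g, dtype=np.int64)
    nbrs = np.tile(g_arr, (lnd.L, 1))
    rows = np.arange(lnd.L)
    nbrs[rows, rows] = 1 - nbrs[rows, rows]
    w0 = lnd.fitness(g)
    w = lnd.fitness_many(nbrs)
    out: list[tuple[Genotype, float]] = []
    for i in np.flatnonzero(w > w0):
        out.append((tuple(int(a) for a in nbrs[i]), float(w[i] / w0 - 1.0)))
    return out


def fixation_probabilities(s: Sequence[float]) -> np.ndarray:
    """First-order SSWM step probabilities p_i = s_i / sum_j s_j.

    Valid when the selection coefficients are small enough that second and
    higher powers are negligible; no higher-order correction is applied.
    Raises ValueError on an empty list (a local optimum: no step possible)
    or on non-positive coefficients.
    """
    s_arr = np.asarray(s, dtype=np.float64)
    if s_arr.size == 0:
        raise ValueError("no beneficial mutations: genotype is a local optimum")
    if not (s_arr > 0).all():
        raise ValueError("selection coefficients must be strictly positive")
    return s_arr / s_arr.sum()


def run_walk(
    lnd: Landscape,
    start: Sequence[int],
    scheme: Scheme,
    rng: np.random.Generator,
    max_steps: int | None = None,
    landscape_id: str = "",
    seed: str = "",
) -> Walk:
    """Simulate one adaptive walk from ``start`` to a local optimum.

    ``max_steps`` (default 2^L) is a safety guard only: strictly increasing
    fitness on a finite genotype set always terminates, so exceeding it
    signals a logic error rather than a long walk.
    """
    if scheme not in ("sswm", "equal"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if max_steps is None:
        max_steps = 1 << lnd.L
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    g = tuple(int(a) for a in start)
    validate_genotype(g, lnd.L)
    genotypes = [g]
    fitnesses = [lnd.fitness(g)]
    for _ in range(max_steps):
        options = fitter_neighbors(lnd, genotypes[-1])
        if not options:
            break
        if scheme == "sswm":
            p = fixation_probabilities([s for _, s in options])
            choice = int(rng.choice(len(options), p=p))
        else:
            choice = int(rng.integers(len(options)))
        nxt, _ = options[choice]
        genotypes.append(nxt)
        fitnesses.append(lnd.fitness(nxt))
    else:
        raise RuntimeError("walk exceeded max_steps; fitness ordering is inconsistent")
    walk = Walk(
        genotypes=tuple(genotypes),
        fitnesses=tuple(float(w) for w in fitnesses),
        scheme=scheme,
        landscape_id=landscape_id,
        seed=seed,
    )
    validate_walk(walk, lnd)
    return walk


def validate_walk(walk: Walk, lnd: Landscape | None = None) -> None:
    """Assert the structural invariants of an adaptive walk.

    Fitness strictly increases, consecutive genotypes are mutational
    neighbors, consecutive steps flip distinct loci, and (when the landscape
    is supplied) the endpoint is a local optimum.
    """
    gs, ws = walk.genotypes, walk.fitnesses
    if len(gs) != len(ws) or not gs:
        raise ValueError("genotype and fitness lists must be non-empty and matched")
    for a, b in zip(ws, ws[1:]):
        if not b > a:
            raise ValueError("walk fitnesses must be strictly increasing")
    flipped = []
    for a, b in zip(gs, gs[1:]):
        if hamming_distance(a, b) != 1:
            raise ValueError("consecutive walk genotypes must be mutational neighbors")
        flipped.append(next(k for k in range(len(a)) if a[k] != b[k]))
    for i, j in zip(flipped, flipped[1:]):
        if i == j:
            raise ValueError("consecutive steps flip the same locus")
    if lnd is not None and fitter_neighbors(lnd, gs[-1]):
        raise ValueError("walk endpoint is not a local optimum")
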