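"""Synthetic fitness landscapes: NK and Rough Mt. Fuji models.

Two classical tunable-ruggedness families over the L-dimensional biallelic
hypercube:

* **NK** — each locus i contributes a value f_i that depends on its own
  allele and the alleles at K other randomly chosen loci; genotype fitness
  is the geometric mean (prod f_i)^(1/L) of the L contributions, each drawn
  i.i.d. Uniform(c_min, c_max). K = 0 gives a multiplicative (epistasis-free)
  landscape; K = L-1 gives mutually independent genotype fitnesses. The
  lower bound c_min > 0 keeps fitnesses positive and caps selection
  coefficients, which are fitness ratios.

* **Rough Mt. Fuji (RMF)** — an additive landscape, slope x (number of
  derived alleles), perturbed by i.i.d. Uniform(noise_low, noise_high) noise
  per genotype, then affinely rescaled to [w_min, w_max]. The slope:noise
  ratio tunes ruggedness analogously to K.

The module also provides the fitness-distribution summaries used downstream:
a central-limit Gaussian approximation of log-fitness for NK (quartile
boundaries, low-fitness tail threshold) and empirical quantiles for RMF,
plus samplers for low-fitness starting genotypes and a neighbor-fitness
correlation estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence, Union

import numpy as np
from scipy import stats

from .genotype import (
    Genotype,
    enumerate_genotypes,
    genotype_index,
    validate_genotype,
)

__all__ = [
    "NKLandscape",
    "RMFLandscape",
    "Landscape",
    "FitnessDistributionSummary",
    "LOW_TAIL_MASS",
    "make_nk_landscape",
    "make_rmf_landscape",
    "nk_log_fitness_moments",
    "quartile_bounds",
    "sample_low_fitness_genotype",
    "sample_uniform_genotype",
    "neighbor_fitness_correlation",
    "fitness_table_tsv",
]

#: Tail mass of the low-fitness starting pool: Phi(-1.5), the probability
#: below "mean minus 1.5 standard deviations" under the Gaussian model.
LOW_TAIL_MASS: float = float(stats.norm.cdf(-1.5))


@dataclass
class NKLandscape:
    """An NK fitness landscape.

    Attributes
    ----------
    L : locus count.
    K : number of additional interacting loci per locus, in [0, L-1].
    neighborhoods : (L, K) int array; row i lists the K loci (other than i)
        whose alleles enter locus i's contribution.
    contributions : (L, 2^(K+1)) float array; row i maps each joint state of
        (locus i, its neighborhood) to a contribution in [c_min, c_max].
        The state index packs locus i's allele as the least significant bit,
        then the neighborhood alleles in listed order.
    """

    L: int
    K: int
    neighborhoods: np.ndarray
    contributions: np.ndarray
    c_min: float
    c_max: float
    _sites: np.ndarray = field(init=False, repr=False)
    _weights: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.neighborhoods = np.asarray(self.neighborhoods, dtype=np.int64).reshape(self.L, self.K)
        self.contributions = np.asarray(self.contributions, dtype=np.float64).reshape(
            self.L, 1 << (self.K + 1)
        )
        for i in range(self.L):
            nbrs = self.neighborhoods[i]
            if len(set(nbrs.tolist())) != self.K or i in nbrs:
                raise ValueError(f"locus {i}: neighborhood must be {self.K} distinct other loci")
        if not (self.contributions > 0).all():
            raise ValueError("contributions must be strictly positive")
        # column j of _sites holds the locus whose allele supplies bit j
        self._sites = np.column_stack([np.arange(self.L), self.neighborhoods]).astype(np.int64)
        self._weights = (1 << np.arange(self.K + 1, dtype=np.int64))

    def _state_indices(self, G: np.ndarray) -> np.ndarray:
        return (G[..., self._sites] * self._weights).sum(axis=-1)

    def fitness(self, g: Sequence[int]) -> float:
        """Fitness of one genotype: geometric mean of its L locus contributions."""
        validate_genotype(g, self.L)
        g_arr = np.asarray(g, dtype=np.int64)
        idx = self._state_indices(g_arr)
        return float(np.exp(np.log(self.contributions[np.arange(self.L), idx]).mean()))

    def fitness_many(self, G: np.ndarray) -> np.ndarray:
        """Vectorized fitness for an (n, L) matrix of genotypes."""
        G = np.asarray(G, dtype=np.int64)
        idx = self._state_indices(G)
        contrib = self.contributions[np.arange(self.L)[None, :], idx]
        return np.exp(np.log(contrib).mean(axis=1))

    def fitness_table(self) -> np.ndarray:
        """Exhaustive (2^L,) fitness table; only sensible for small L."""
        return self.fitness_many(enumerate_genotypes(self.L))

    def to_json(self) -> str:
        """Serialize all parameters for exact reconstruction."""
        return json.dumps(
            {
                "model": "nk",
                "L": self.L,
                "K": self.K,
                "c_min": self.c_min,
                "c_max": self.c_max,
                "neighborhoods": self.neighborhoods.tolist(),
                "contributions": self.contributions.tolist(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "NKLandscape":
        d = json.loads(s)
        if d.get("model") != "nk":
            raise ValueError("not an NK landscape document")
        return cls(
            L=d["L"],
            K=d["K"],
            neighborhoods=np.array(d["neighborhoods"]),
            contributions=np.array(d["contributions"]),
            c_min=d["c_min"],
            c_max=d["c_max"],
        )


@dataclass
class RMFLandscape:
    """A Rough Mt. Fuji landscape, fully tabulated.

    ``fitness_table_`` holds the 2^L fitness values, indexed by
    :func:`ridgewalk.genotype.genotype_index` (locus 0 = most significant
    bit). Values are the affine rescaling of slope x d(g) + noise to
    [w_min, w_max], where d(g) counts derived alleles.
    """

    L: int
    slope: float
    noise_low: float
    noise_high: float
    fitness_table_: np.ndarray
    w_min: float
    w_max: float

    def __post_init__(self) -> None:
        self.fitness_table_ = np.asarray(self.fitness_table_, dtype=np.float64)
        if self.fitness_table_.shape != (1 << self.L,):
            raise ValueError("fitness table must have 2^L entries")
        if not (self.fitness_table_ > 0).all():
            raise ValueError("fitnesses must be strictly positive")

    def fitness(self, g: Sequence[int]) -> float:
        validate_genotype(g, self.L)
        return float(self.fitness_table_[genotype_index(g)])

    def fitness_many(self, G: np.ndarray) -> np.ndarray:
        G = np.asarray(G, dtype=np.int64)
        shifts = (1 << np.arange(self.L - 1, -1, -1, dtype=np.int64))
        idx = G @ shifts
        return self.fitness_table_[idx]

    def fitness_table(self) -> np.ndarray:
        return self.fitness_table_


Landscape = Union[NKLandscape, RMFLandscape]


@dataclass(frozen=True)
class FitnessDistributionSummary:
    """Quartile boundaries and log-fitness moments of a landscape.

    ``source`` records whether the boundaries come from the Gaussian
    (central-limit) approximation of log-fitness or from the empirical
    distribution of the full fitness table; the low-fitness start sampler
    applies the matching tail rule.
    """

    mu_log: float
    sigma_log: float
    quartile_bounds: tuple[float, float, float]
    source: Literal["theoretical", "empirical"]

    def __post_init__(self) -> None:
        q1, q2, q3 = self.quartile_bounds
        if not q1 < q2 < q3:
            raise ValueError("quartile bounds must be strictly increasing")

    def quartile_interval(self, quartile: int) -> tuple[float, float]:
        """Half-open fitness interval [lo, hi) of a quartile in 1..4."""
        if quartile not in (1, 2, 3, 4):
            raise ValueError("quartile must be in 1..4")
        edges = (-np.inf, *self.quartile_bounds, np.inf)
        return edges[quartile - 1], edges[quartile]


def make_nk_landscape(
    L: int,
    K: int,
    c_min: float = 0.1,
    c_max: float = 1.0,
    rng: np.random.Generator | None = None,
) -> NKLandscape:
    """Draw an NK landscape: random neighborhoods, Uniform(c_min, c_max) contributions.

    Each locus's K-neighborhood is drawn uniformly without replacement from
    the other L-1 loci, independently per locus; every contribution-table
    entry is an independent Uniform(c_min, c_max) draw.
    """
    if not 0 <= K <= L - 1:
        raise ValueError(f"K must be in [0, L-1], got K={K}, L={L}")
    if not 0 < c_min < c_max:
        raise ValueError("require 0 < c_min < c_max")
    rng = np.random.default_rng() if rng is None else rng
    neighborhoods = np.empty((L, K), dtype=np.int64)
    others = np.arange(L)
    for i in range(L):
        pool = np.delete(others, i)
        neighborhoods[i] = rng.choice(pool, size=K, replace=False)
    contributions = rng.uniform(c_min, c_max, size=(L, 1 << (K + 1)))
    return NKLandscape(L=L, K=K, neighborhoods=neighborhoods, contributions=contributions,
                       c_min=c_min, c_max=c_max)


def make_rmf_landscape(
    L: int,
    slope: float = 0.25,
    noise_low: float = 0.0,
    noise_high: float = 1.0,
    w_min: float = 1.0,
    w_max: float = 2.0,
    rng: np.random.Generator | None = None,
) -> RMFLandscape:
    """Draw a Rough Mt. Fuji landscape and rescale its fitnesses to [w_min, w_max].

    Raw value of genotype g is slope * d(g) + U with d(g) the derived-allele
    count and U ~ Uniform(noise_low, noise_high) i.i.d. per genotype; the
    table is then mapped affinely so its minimum is exactly w_min and its
    maximum exactly w_max. A degenerate raw table (zero range) cannot be
    rescaled and raises ValueError.
    """
    if not noise_low <= noise_high:
        raise ValueError("require noise_low <= noise_high")
    if not w_min < w_max:
        raise ValueError("require w_min < w_max")
    if slope < 0:
        raise ValueError("slope must be nonnegative")
    rng = np.random.default_rng() if rng is None else rng
    G = enumerate_genotypes(L)
    d = G.sum(axis=1).astype(np.float64)
    raw = slope * d + rng.uniform(noise_low, noise_high, size=1 << L)
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        raise ValueError("degenerate raw fitness range; cannot rescale")
    table = w_min + (raw - lo) * (w_max - w_min) / (hi - lo)
    return RMFLandscape(L=L, slope=slope, noise_low=noise_low, noise_high=noise_high,
                        fitness_table_=table, w_min=w_min, w_max=w_max)


def nk_log_fitness_moments(L: int, c_min: float, c_max: float) -> tuple[float, float]:
    """Mean and SD of log-fitness of a random NK genotype, by the CLT.

    log fitness is the mean of L contributions' logs, each log of a
    Uniform(c_min, c_max) draw, so mu_log = E[ln U] and
    sigma_log = SD[ln U] / sqrt(L), with the closed-form log-uniform moments

        E[ln U]   = (b ln b - a ln a) / (b - a) - 1
        E[ln^2 U] = (b (ln^2 b - 2 ln b + 2) - a (ln^2 a - 2 ln a + 2)) / (b - a)
    """
    if not 0 < c_min < c_max:
        raise ValueError("require 0 < c_min < c_max")
    a, b = c_min, c_max
    la, lb = np.log(a), np.log(b)
    mean = (b * lb - a * la) / (b - a) - 1.0
    second = (b * (lb * lb - 2 * lb + 2) - a * (la * la - 2 * la + 2)) / (b - a)
    var = max(second - mean * mean, 0.0)  # clamp fp cancellation near a == b
    return float(mean), float(np.sqrt(var / L))


def quartile_bounds(
    lnd: Landscape,
    mode: Literal["theoretical", "empirical"] = "theoretical",
) -> FitnessDistributionSummary:
    """Quartile boundaries of a landscape's fitness distribution.

    ``theoretical`` (NK only) exponentiates Gaussian quantiles of log-fitness
    with moments from :func:`nk_log_fitness_moments` — the cheap route when
    enumerating 2^L fitnesses is wasteful. ``empirical`` computes linear-
    interpolation sample quantiles of the full fitness table (always
    available for RMF; exhaustive enumeration for NK at small L).
    """
    if mode == "theoretical":
        if not isinstance(lnd, NKLandscape):
            raise ValueError("theoretical quartiles are defined for NK landscapes only")
        mu, sigma = nk_log_fitness_moments(lnd.L, lnd.c_min, lnd.c_max)
        q = np.exp(stats.norm.ppf([0.25, 0.5, 0.75], loc=mu, scale=sigma))
        return FitnessDistributionSummary(mu, sigma, tuple(float(x) for x in q), "theoretical")
    if mode == "empirical":
        table = lnd.fitness_table()
        logs = np.log(table)
        q = np.quantile(table, [0.25, 0.5, 0.75])
        return FitnessDistributionSummary(
            float(logs.mean()), float(logs.std()), tuple(float(x) for x in q), "empirical"
        )
    raise ValueError(f"unknown mode {mode!r}")


def sample_uniform_genotype(L: int, rng: np.random.Generator) -> Genotype:
    """A genotype drawn uniformly from the 2^L hypercube vertices."""
    return tuple(int(a) for a in rng.integers(0, 2, size=L))


def sample_low_fitness_genotype(
    lnd: Landscape,
    summary: FitnessDistributionSummary,
    rng: np.random.Generator,
    max_tries: int = 200_000,
) -> Genotype:
    """Sample a starting genotype from the low-fitness tail of the landscape.

    Under a theoretical summary (NK), genotypes are rejection-sampled
    uniformly until log-fitness < mu_log - 1.5 sigma_log. Under an empirical
    summary, the draw is uniform over the genotypes whose fitness falls in
    the bottom Phi(-1.5) ~ 6.68% of the full table — the same tail mass the
    Gaussian rule targets.

    Raises RuntimeError if the rejection budget is exhausted (e.g. a
    near-constant landscape with an empty tail).
    """
    if summary.source == "theoretical":
        threshold_log = summary.mu_log - 1.5 * summary.sigma_log
        batch = 256
        for _ in range(0, max_tries, batch):
            G = rng.integers(0, 2, size=(batch, lnd.L))
            w = lnd.fitness_many(G)
            hits = np.flatnonzero(np.log(w) < threshold_log)
            if hits.size:
                return tuple(int(a) for a in G[hits[0]])
        raise RuntimeError("rejection budget exhausted: no genotype below the fitness threshold")
    table = lnd.fitness_table()
    threshold = np.quantile(table, LOW_TAIL_MASS)
    pool = np.flatnonzero(table <= threshold)
    if pool.size == 0:
        raise RuntimeError("empty low-fitness tail")
    idx = int(rng.choice(pool))
    return tuple((idx >> (lnd.L - 1 - i)) & 1 for i in range(lnd.L))


def neighbor_fitness_correlation(
    lnd: Landscape, n_pairs: int, rng: np.random.Generator
) -> float:
    """Pearson correlation between the fitnesses of random mutational neighbors.

    Samples ``n_pairs`` genotypes uniformly, pairs each with a uniformly
    chosen single-locus mutant, and correlates the two fitness vectors.
    Raises ValueError on a zero-variance (constant) landscape sample.
    """
    if n_pairs < 2:
        raise ValueError("need at least two pairs")
    G = rng.integers(0, 2, size=(n_pairs, lnd.L))
    loci = rng.integers(0, lnd.L, size=n_pairs)
    G2 = G.copy()
    rows = np.arange(n_pairs)
    G2[rows, loci] = 1 - G2[rows, loci]
    w1 = lnd.fitness_many(G)
    w2 = lnd.fitness_many(G2)
    if w1.std() == 0 or w2.std() == 0:
        raise ValueError("constant landscape: correlation undefined")
    return float(np.corrcoef(w1, w2)[0, 1])


def fitness_table_tsv(lnd: Landscape) -> str:
    """Dump the exhaustive genotype -> fitness map as TSV (bitstring order)."""
    table = lnd.fitness_table()
    lines = ["genotype\tfitness"]
    for idx, w in enumerate(table):
        bits = format(idx, f"0{lnd.L}b")
        lines.append(f"{bits}\t{w:.12g}")
    return "\n".join(lines) + "\n"
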