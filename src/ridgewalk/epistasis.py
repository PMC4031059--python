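"""Quadruple-based epistasis classification.

Pairwise epistasis is measured on a quadruple {ab, Ab, aB, AB}: a base
genotype, the two single mutants at a pair of focal loci, and the double
mutant. All quadruples handled here follow the adaptive-walk convention
w_ab < w_Ab < w_AB — either because ab, Ab, AB are three consecutive
genotypes of a walk, or because a randomly sampled quadruple is relabeled
to satisfy it.

Under that convention the fitness rank of the remaining genotype aB among
the four decides sign epistasis outright: ranked first (fittest) or fourth
(least fit), some single-locus effect changes sign between backgrounds and
the quadruple has sign epistasis; ranked second or third, it does not, and
the sign of the interaction magnitude

    multiplicative:  eps = ln w_ab + ln w_AB - ln w_Ab - ln w_aB
    additive:        eps = w_ab + w_AB - w_Ab - w_aB

splits the remainder into synergistic (eps > 0: the double mutant beats the
null expectation) and antagonistic (eps < 0). Both scales are always
computed; the choice only matters for the synergistic/antagonistic split
and the qualitative trends are robust to it. Exact fitness ties make the
rank indeterminate and are reported as an explicit ``degenerate`` label
rather than silently mis-binned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .genotype import Quadruple, complement_genotype, flip_locus
from .landscapes import FitnessDistributionSummary, Landscape
from .walks import Walk

__all__ = [
    "EpistasisRecord",
    "Label",
    "Scale",
    "quadruple_from_walk",
    "epsilon",
    "classify",
    "sample_quadruples",
    "sample_stratified_quadruple",
    "all_quadruple_epsilons",
]

Scale = Literal["multiplicative", "additive"]
Label = Literal["sign", "synergistic", "antagonistic", "none", "degenerate"]


@dataclass(frozen=True)
class EpistasisRecord:
    """Classification of one quadruple.

    ``rank_of_aB`` is the fitness rank of aB among the four genotypes
    (1 = highest); it is None for degenerate (tied) quadruples. ``scale``
    names the scale whose eps sign produced the label; both eps values are
    kept. ``context`` tags where the quadruple came from (walk-step index
    or quartile stratum).
    """

    quadruple: Quadruple
    rank_of_aB: int | None
    epsilon_mult: float
    epsilon_add: float
    scale: Scale
    label: Label
    context: int | str | None = None

    @property
    def epsilon(self) -> float:
        return self.epsilon_mult if self.scale == "multiplicative" else self.epsilon_add


def quadruple_from_walk(walk: Walk, t: int, lnd: Landscape) -> Quadruple:
    """Quadruple spanned by walk positions t, t+1, t+2.

    The three consecutive genotypes are ab, Ab, AB; aB is their XOR
    complement, with fitness read from the landscape. A walk visiting n
    genotypes yields n - 2 quadruples (t = 0 .. n-3).
    """
    if not 0 <= t <= len(walk.genotypes) - 3:
        raise IndexError(f"walk has no quadruple at position {t}")
    ab, Ab, AB = walk.genotypes[t], walk.genotypes[t + 1], walk.genotypes[t + 2]
    aB = complement_genotype(ab, Ab, AB)
    i = next(k for k in range(len(ab)) if ab[k] != Ab[k])
    j = next(k for k in range(len(Ab)) if Ab[k] != AB[k])
    return Quadruple(
        ab=ab, Ab=Ab, aB=aB, AB=AB,
        w_ab=walk.fitnesses[t], w_Ab=walk.fitnesses[t + 1],
        w_aB=lnd.fitness(aB), w_AB=walk.fitnesses[t + 2],
        focal_loci=(i, j),
    )


def epsilon(q: Quadruple, scale: Scale = "multiplicative") -> float:
    """Epistasis magnitude of a quadruple on the chosen scale."""
    if scale == "multiplicative":
        return float(np.log(q.w_ab) + np.log(q.w_AB) - np.log(q.w_Ab) - np.log(q.w_aB))
    if scale == "additive":
        return float(q.w_ab + q.w_AB - q.w_Ab - q.w_aB)
    raise ValueError(f"unknown scale {scale!r}")


def classify(
    q: Quadruple,
    scale: Scale = "multiplicative",
    context: int | str | None = None,
    eps_tol: float = 1e-9,
) -> EpistasisRecord:
    """Classify a walk-convention quadruple by the rank of aB.

    Requires w_ab < w_Ab < w_AB. rank 1 or 4 -> sign epistasis; rank 2 or 3
    -> synergistic / antagonistic / none by the sign of eps on ``scale``,
    where |eps| <= eps_tol counts as no epistasis (so a numerically exact
    multiplicative landscape is classified "none" rather than picking up
    floating-point noise). A tie between w_aB and any of the other three
    fitnesses yields the ``degenerate`` label with rank None.
    """
    if not q.w_ab < q.w_Ab < q.w_AB:
        raise ValueError("quadruple does not satisfy the walk convention w_ab < w_Ab < w_AB")
    eps_mult = epsilon(q, "multiplicative")
    eps_add = epsilon(q, "additive")
    others = (q.w_ab, q.w_Ab, q.w_AB)
    if any(q.w_aB == w for w in others):
        return EpistasisRecord(q, None, eps_mult, eps_add, scale, "degenerate", context)
    rank = 1 + sum(w > q.w_aB for w in others)
    if rank in (1, 4):
        label: Label = "sign"
    else:
        eps = eps_mult if scale == "multiplicative" else eps_add
        if abs(eps) <= eps_tol:
            label = "none"
        else:
            label = "synergistic" if eps > 0 else "antagonistic"
    return EpistasisRecord(q, rank, eps_mult, eps_add, scale, label, context)


def sample_quadruples(
    lnd: Landscape,
    n: int,
    quartile: int | None,
    bounds: FitnessDistributionSummary | None,
    rng: np.random.Generator,
    max_batches: int = 5_000,
    batch_size: int = 2_048,
) -> list[Quadruple]:
    """Sample ``n`` random walk-convention quadruples, optionally quartile-stratified.

    Joint rejection sampling: each candidate is an independent draw of a
    uniform genotype ab, plus an ordered pair of distinct focal loci (i, j)
    defining Ab (locus i flipped) and AB (both flipped); the candidate is
    accepted iff ab's fitness lies in the requested quartile of ``bounds``
    (skipped when ``quartile`` is None) and the chain ordering
    w_ab < w_Ab < w_AB holds. The complement aB (locus j flipped) is never
    inspected during rejection, so its fitness stays unconditioned — on a
    landscape with independent genotype fitnesses its rank among the four
    is uniform. Raises RuntimeError when the rejection budget runs out.
    """
    if quartile is not None:
        if bounds is None:
            raise ValueError("quartile stratification requires fitness-distribution bounds")
        lo, hi = bounds.quartile_interval(quartile)
    out: list[Quadruple] = []
    rows = np.arange(batch_size)
    for _ in range(max_batches):
        G = rng.integers(0, 2, size=(batch_size, lnd.L))
        pairs = np.array([rng.choice(lnd.L, size=2, replace=False)
                          for _ in range(batch_size)])
        i_loc, j_loc = pairs[:, 0], pairs[:, 1]
        w0 = lnd.fitness_many(G)
        ok = np.ones(batch_size, dtype=bool)
        if quartile is not None:
            ok &= (w0 >= lo) & (w0 < hi)
        Gi = G.copy()
        Gi[rows, i_loc] = 1 - Gi[rows, i_loc]
        Gij = Gi.copy()
        Gij[rows, j_loc] = 1 - Gij[rows, j_loc]
        wi = lnd.fitness_many(Gi)
        wij = lnd.fitness_many(Gij)
        ok &= (w0 < wi) & (wi < wij)
        for k in np.flatnonzero(ok):
            ab = tuple(int(a) for a in G[k])
            Ab = tuple(int(a) for a in Gi[k])
            AB = tuple(int(a) for a in Gij[k])
            aB = flip_locus(ab, int(j_loc[k]))
            out.append(Quadruple(ab=ab, Ab=Ab, aB=aB, AB=AB,
                                 w_ab=float(w0[k]), w_Ab=float(wi[k]),
                                 w_aB=lnd.fitness(aB), w_AB=float(wij[k]),
                                 focal_loci=(int(i_loc[k]), int(j_loc[k]))))
            if len(out) == n:
                return out
    raise RuntimeError("rejection budget exhausted while sampling quadruples")


def sample_stratified_quadruple(
    lnd: Landscape,
    quartile: int | None,
    bounds: FitnessDistributionSummary | None,
    rng: np.random.Generator,
    batch_size: int = 256,
) -> Quadruple:
    """Sample one walk-convention quadruple; see :func:`sample_quadruples`."""
    return sample_quadruples(lnd, 1, quartile, bounds, rng, batch_size=batch_size)[0]


def all_quadruple_epsilons(lnd: Landscape, scale: Scale = "multiplicative") -> np.ndarray:
    """Epistasis magnitudes of every quadruple of a small landscape.

    Enumerates, for each unordered pair of focal loci, all 2^(L-2)
    backgrounds and returns the flat array of eps values (one per
    quadruple, L(L-1)/2 * 2^(L-2) in total). Exhaustive, so intended for
    L small enough to tabulate.
    """
    table = lnd.fitness_table()
    L = lnd.L
    vals = np.log(table) if scale == "multiplicative" else table
    # reshape the table into L binary axes; axis k is locus k's allele
    cube = vals.reshape((2,) * L)
    out = []
    for i in range(L):
        for j in range(i + 1, L):
            c = np.moveaxis(cube, (i, j), (0, 1))
            eps = c[0, 0] + c[1, 1] - c[0, 1] - c[1, 0]
            out.append(eps.reshape(-1))
    return np.concatenate(out)
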