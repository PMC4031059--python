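"""The three computational experiments and their aggregations.

Built on the landscape generators, walk simulator, and quadruple
classifier, this module runs the study-level analyses:

* **epistasis by walk step** — classify the quadruple at every two-step
  window of every walk and tabulate class frequencies per step index; the
  number of walks still alive at step t shrinks as walks hit local optima.
* **epistasis by fitness quartile** — sample walk-convention quadruples
  stratified by the quartile of the base genotype's fitness, across an
  ensemble of landscapes, and tabulate class frequencies per quartile. If
  the walk-step trends are driven by regression to the mean (walks move
  from low to high fitness while the complement genotype aB keeps an
  independent component), the quartile experiment must reproduce them
  without simulating any walks.
* **mean-regression percentile intervals** — for an early (positions 1-3)
  or late (positions 4-6) three-genotype window of each walk, the 2.5/50/
  97.5 fitness percentiles across walks of ab, Ab, AB, the complement aB,
  and a random-genotype control. Early windows sit below the control and
  pull aB down with them; late windows sit above it, and mean regression
  pulls aB below AB — the ridge effect.

Plus local diagnostics: in/out arrow counts of the fitness graph at a
genotype, and export of the fitness subgraph spanned by the loci a walk
segment mutates (DOT format).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .epistasis import (
    EpistasisRecord,
    Scale,
    classify,
    quadruple_from_walk,
    sample_quadruples,
)
from .genotype import flip_locus, to_bitstring
from .landscapes import (
    FitnessDistributionSummary,
    Landscape,
    quartile_bounds,
    sample_uniform_genotype,
)
from .walks import Walk

__all__ = [
    "CLASS_LABELS",
    "PercentileIntervalSet",
    "classify_walk_quadruples",
    "frequency_table",
    "epistasis_by_step",
    "epistasis_by_quartile",
    "mean_regression_intervals",
    "arrow_summary",
    "local_subgraph",
    "subgraph_to_dot",
    "two_proportion_test",
    "ant_syn_ratio",
]

CLASS_LABELS = ("sign", "synergistic", "antagonistic", "none", "degenerate")


def classify_walk_quadruples(
    walks: Sequence[Walk],
    landscapes: Sequence[Landscape],
    scale: Scale = "multiplicative",
) -> list[EpistasisRecord]:
    """Classify every two-step quadruple of every walk.

    ``landscapes[k]`` must be the landscape ``walks[k]`` was simulated on;
    each record's ``context`` is its step index t (the quadruple spans walk
    positions t, t+1, t+2).
    """
    if len(walks) != len(landscapes):
        raise ValueError("need one landscape per walk")
    records: list[EpistasisRecord] = []
    for walk, lnd in zip(walks, landscapes):
        for t in range(len(walk.genotypes) - 2):
            q = quadruple_from_walk(walk, t, lnd)
            records.append(classify(q, scale=scale, context=t))
    return records


def frequency_table(records: Iterable[EpistasisRecord], by: str = "context") -> pd.DataFrame:
    """Tabulate class counts and frequencies grouped by record context.

    Returns a DataFrame indexed by the context value (walk step or
    quartile) with one count column per class, ``n`` (total quadruples),
    and ``freq_*`` columns normalized over the non-degenerate classes;
    the degenerate share is reported separately as ``freq_degenerate`` of n.
    """
    rows = [(r.context, r.label) for r in records]
    if not rows:
        cols = [*CLASS_LABELS, "n", *(f"freq_{c}" for c in CLASS_LABELS)]
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows, columns=[by, "label"])
    counts = df.groupby([by, "label"]).size().unstack(fill_value=0)
    for c in CLASS_LABELS:
        if c not in counts:
            counts[c] = 0
    counts = counts[list(CLASS_LABELS)].sort_index()
    counts["n"] = counts[list(CLASS_LABELS)].sum(axis=1)
    valid = counts["n"] - counts["degenerate"]
    for c in CLASS_LABELS[:-1]:
        counts[f"freq_{c}"] = np.where(valid > 0, counts[c] / valid.replace(0, np.nan), np.nan)
    counts["freq_degenerate"] = counts["degenerate"] / counts["n"]
    return counts


def epistasis_by_step(
    walks: Sequence[Walk],
    landscapes: Sequence[Landscape],
    scale: Scale = "multiplicative",
) -> pd.DataFrame:
    """Per-step epistasis class frequencies along adaptive walks.

    Row t summarizes the quadruples starting at walk position t; ``n`` is
    the number of walks that survived long enough to contribute there, so
    it is non-increasing in t.
    """
    records = classify_walk_quadruples(walks, landscapes, scale=scale)
    table = frequency_table(records, by="step")
    table.index.name = "step"
    return table


def epistasis_by_quartile(
    landscapes: Sequence[Landscape],
    n_per_stratum: int,
    scale: Scale = "multiplicative",
    rng: np.random.Generator | None = None,
    bounds_mode: Literal["theoretical", "empirical"] | None = None,
) -> pd.DataFrame:
    """Epistasis class frequencies of stratified random quadruples.

    Draws ``n_per_stratum`` walk-convention quadruples per fitness quartile,
    spreading draws round-robin across the landscape ensemble; the base
    genotype ab of each quadruple lies in the stratum's quartile.
    ``bounds_mode`` defaults to theoretical for NK and empirical for RMF.
    """
    if n_per_stratum < 1:
        raise ValueError("n_per_stratum must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    modes = [
        bounds_mode or ("theoretical" if hasattr(lnd, "K") else "empirical")
        for lnd in landscapes
    ]
    all_bounds = [quartile_bounds(lnd, mode) for lnd, mode in zip(landscapes, modes)]
    n_lnd = len(landscapes)
    records: list[EpistasisRecord] = []
    for quartile in (1, 2, 3, 4):
        for idx in range(n_lnd):
            share = n_per_stratum // n_lnd + (1 if idx < n_per_stratum % n_lnd else 0)
            if share == 0:
                continue
            for q in sample_quadruples(landscapes[idx], share, quartile,
                                       all_bounds[idx], rng):
                records.append(classify(q, scale=scale, context=quartile))
    table = frequency_table(records, by="quartile")
    table.index.name = "quartile"
    return table


@dataclass(frozen=True)
class PercentileIntervalSet:
    """(2.5, 50, 97.5) fitness percentiles per quadruple role across walks."""

    intervals: dict[str, tuple[float, float, float]]
    window: Literal["early", "late"]
    n_walks: int

    def __post_init__(self) -> None:
        for role, (lo, med, hi) in self.intervals.items():
            if not lo <= med <= hi:
                raise ValueError(f"interval for {role} is not ordered")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intervals, index=["p2.5", "median", "p97.5"]).T
        df.index.name = "role"
        return df


def mean_regression_intervals(
    walks: Sequence[Walk],
    landscapes: Sequence[Landscape],
    window: Literal["early", "late"],
    control_n: int = 1000,
    rng: np.random.Generator | None = None,
) -> PercentileIntervalSet:
    """Fitness percentile intervals of the quadruple roles in a walk window.

    ``early`` reads walk positions 1-3 (the first three genotypes visited),
    ``late`` positions 4-6; walks too short for the window are dropped, and
    an empty surviving set raises ValueError. For each surviving walk the
    window's three genotypes are ab, Ab, AB and aB is the quadruple
    complement; the control is ``control_n`` uniformly random genotypes
    drawn from the surviving walks' landscapes.
    """
    if len(walks) != len(landscapes):
        raise ValueError("need one landscape per walk")
    rng = np.random.default_rng() if rng is None else rng
    offset = {"early": 0, "late": 3}[window]
    role_fitness: dict[str, list[float]] = {"ab": [], "Ab": [], "AB": [], "aB": []}
    surviving: list[Landscape] = []
    for walk, lnd in zip(walks, landscapes):
        if len(walk.genotypes) < offset + 3:
            continue
        q = quadruple_from_walk(walk, offset, lnd)
        role_fitness["ab"].append(q.w_ab)
        role_fitness["Ab"].append(q.w_Ab)
        role_fitness["AB"].append(q.w_AB)
        role_fitness["aB"].append(q.w_aB)
        surviving.append(lnd)
    if not surviving:
        raise ValueError(f"no walk reaches the {window} window")
    controls = []
    for _ in range(control_n):
        lnd = surviving[int(rng.integers(len(surviving)))]
        controls.append(lnd.fitness(sample_uniform_genotype(lnd.L, rng)))
    role_fitness["control"] = controls
    intervals = {
        role: tuple(float(x) for x in np.percentile(vals, [2.5, 50, 97.5]))
        for role, vals in role_fitness.items()
    }
    return PercentileIntervalSet(intervals=intervals, window=window,
                                 n_walks=len(surviving))


def arrow_summary(lnd: Landscape, g: Sequence[int]) -> tuple[int, int, int]:
    """Fitness-graph arrow counts at a genotype: (n_in, n_out, n_tie).

    ``n_in`` counts neighbors of strictly lower fitness (arrows pointing in
    toward g), ``n_out`` neighbors of strictly higher fitness; exact ties
    are counted separately so n_in + n_out + n_tie = L. A local optimum has
    n_out = 0; a high n_in/L along a walk is the ridge signature.
    """
    g_arr = np.asarray(g, dtype=np.int64)
    nbrs = np.tile(g_arr, (lnd.L, 1))
    rows = np.arange(lnd.L)
    nbrs[rows, rows] = 1 - nbrs[rows, rows]
    w0 = lnd.fitness(g)
    w = lnd.fitness_many(nbrs)
    n_in = int((w < w0).sum())
    n_out = int((w > w0).sum())
    return n_in, n_out, lnd.L - n_in - n_out


def local_subgraph(
    lnd: Landscape,
    walk: Walk,
    from_step: int,
    n_steps: int = 5,
) -> nx.DiGraph:
    """Fitness subgraph spanned by the loci mutated in a walk segment.

    Takes the walk positions [from_step, from_step + n_steps], collects the
    loci flipped there, and builds the induced fitness graph on all
    genotypes that differ from the segment's first genotype only at those
    loci (2^m vertices for m affected loci). Edges are directed toward the
    fitter genotype; edges traversed by the walk carry ``on_walk=True``.
    Node attributes: ``fitness`` and ``on_walk``.
    """
    if from_step < 0 or from_step + n_steps > walk.n_steps:
        raise ValueError("walk segment out of range")
    segment = walk.genotypes[from_step: from_step + n_steps + 1]
    base = segment[0]
    loci = sorted({next(k for k in range(len(a)) if a[k] != b[k])
                   for a, b in zip(segment, segment[1:])})
    m = len(loci)
    graph = nx.DiGraph()
    vertices = []
    for mask in range(1 << m):
        g = list(base)
        for bit, locus in enumerate(loci):
            if (mask >> (m - 1 - bit)) & 1:
                g[locus] = 1 - g[locus]
        g = tuple(g)
        vertices.append(g)
        graph.add_node(to_bitstring(g), fitness=lnd.fitness(g),
                       on_walk=g in segment)
    walk_edges = {(to_bitstring(a), to_bitstring(b)) for a, b in zip(segment, segment[1:])}
    for g in vertices:
        for locus in loci:
            h = flip_locus(g, locus)
            wg, wh = lnd.fitness(g), lnd.fitness(h)
            if wg < wh:
                u, v = to_bitstring(g), to_bitstring(h)
                graph.add_edge(u, v, on_walk=(u, v) in walk_edges)
    return graph


def subgraph_to_dot(graph: nx.DiGraph) -> str:
    """Render a local fitness subgraph as a DOT document.

    Walk nodes and edges are highlighted; node labels carry the genotype
    bitstring and its fitness.
    """
    lines = ["digraph fitness_subgraph {", "  rankdir=BT;"]
    for node, data in graph.nodes(data=True):
        style = ' style=filled fillcolor="lightblue"' if data.get("on_walk") else ""
        lines.append(
            f'  "{node}" [label="{node}\\n{data["fitness"]:.4f}"{style}];'
        )
    for u, v, data in graph.edges(data=True):
        attr = ' [color="blue" penwidth=2]' if data.get("on_walk") else ""
        lines.append(f'  "{u}" -> "{v}"{attr};')
    lines.append("}")
    return "\n".join(lines) + "\n"


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int,
    alternative: Literal["two-sided", "less", "greater"] = "two-sided",
) -> float:
    """Fisher exact p-value comparing success proportions k1/n1 vs k2/n2.

    ``greater`` tests whether group 1's proportion exceeds group 2's.
    """
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(stats.fisher_exact(table, alternative=alternative)[1])


def ant_syn_ratio(table: pd.DataFrame, index_value) -> float:
    """Antagonistic:synergistic count ratio at one row of a frequency table."""
    row = table.loc[index_value]
    syn = float(row["synergistic"])
    if syn == 0:
        return float("inf") if row["antagonistic"] > 0 else float("nan")
    return float(row["antagonistic"]) / syn
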