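# ridgewalk

Simulation toolkit for studying how the prevalence of **sign**,
**synergistic**, and **antagonistic** epistasis changes along adaptive
walks in fitness landscapes — and for testing the explanation that the
change is driven by **regression to the mean**, not by any intrinsic
property of adaptive walks.

## The science

A fitness landscape assigns a positive fitness *w(g)* to every genotype
*g* ∈ {0,1}^L on the L-dimensional biallelic hypercube. Pairwise epistasis
is defined on a quadruple {ab, Ab, aB, AB}: a base genotype, its two
single mutants at a pair of focal loci, and the double mutant. When three
consecutive genotypes of an adaptive walk are labelled ab, Ab, AB (so
*w_ab* < *w_Ab* < *w_AB*), the fitness rank of the complement aB among the
four settles the classification:

- rank 1 or 4 → **sign epistasis** (a mutation's effect changes direction
  across backgrounds);
- rank 2 or 3 → no sign epistasis; the sign of
  ε = ln *w_ab* + ln *w_AB* − ln *w_Ab* − ln *w_aB* (multiplicative scale)
  or ε = *w_ab* + *w_AB* − *w_Ab* − *w_aB* (additive scale) splits the
  rest into **synergistic** (ε > 0) and **antagonistic** (ε < 0).

Walks are simulated under strong-selection–weak-mutation (SSWM): a
monomorphic population takes one beneficial mutation per step, fixing
neighbor *i* with probability *p_i* = *s_i* / Σ_j *s_j* where
*s* = *w'*/*w* − 1, until a local optimum is reached; an equal-weight
variant chooses uniformly among beneficial neighbors. Two landscape
families with tunable ruggedness are provided:

- **NK**: *w(g)* = (∏_i f_i)^(1/L), each contribution *f_i* ~
  Uniform(c_min, c_max) depending on locus *i* and K random other loci
  (K = 0: multiplicative, epistasis-free; K = L−1: independent fitnesses);
- **Rough Mt. Fuji**: slope × (derived-allele count) plus i.i.d. uniform
  noise, rescaled to [w_min, w_max].

Starting genotypes are drawn from the low-fitness tail (below the mean
minus 1.5 SD of log-fitness, via a central-limit Gaussian approximation
for NK or empirical quantiles for RMF). The package then runs three
analyses: epistasis class frequencies per walk step; the same frequencies
for random quadruples stratified by the base genotype's fitness quartile
(the walk-free mirror that isolates the mean-regression mechanism); and
2.5/50/97.5 fitness percentile intervals of the quadruple roles in early
vs late walk windows against a random-genotype control.

## Worked example

```python
import ridgewalk as rw

cfg = rw.RunConfig(model="nk", L=15, K=10, n_landscapes=500,
                   scheme="sswm", master_seed=42)
batch = rw.simulate_batch(cfg)
table = rw.epistasis_by_step(batch.walks, batch.walk_landscapes)
print(table[["n", "freq_sign", "freq_synergistic", "freq_antagonistic"]].round(3))
```

```
label    n  freq_sign  freq_synergistic  freq_antagonistic
step
0      481      0.154             0.245              0.601
1      383      0.499             0.245              0.256
2      243      0.675             0.185              0.140
3      126      0.833             0.095              0.071
4       55      0.873             0.091              0.036
```

Each row is one walk step; `n` counts the walks still running there (it
shrinks as walks hit local optima). At the first step only 15% of
traversed quadruples show sign epistasis and antagonistic epistasis
dominates the rest; by step 4 sign epistasis is at 87% and the balance
has flipped toward synergy. The quartile-stratified experiment
(`rw.epistasis_by_quartile`, see `examples/04_quartile_mirror.py`)
reproduces the same trend from fitness strata alone, with no walks —
the mean-regression signature.

The `examples/` directory holds one short script per capability
(landscape construction, a single annotated walk, the step table, the
quartile mirror, the percentile intervals). A thin CLI covers batch use:
`ridgewalk simulate`, `ridgewalk sample-quadruples`, `ridgewalk summarize`,
`ridgewalk export-graph` (all plain-text TSV/DOT outputs; see
`ridgewalk --help`).

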