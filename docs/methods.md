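# Methods

## Model and procedure

Genotypes are length-L binary vectors (0 = ancestral, 1 = derived; locus
indices 0-based; bitstrings are serialized most-significant locus first).
A landscape maps all 2^L genotypes to strictly positive fitnesses. An
adaptive walk starts at a chosen genotype and repeatedly moves to a
strictly fitter mutational neighbor until none exists. Under the SSWM
scheme the step distribution is the first-order origin–fixation weighting
p_i = s_i / Σ_j s_j over the beneficial neighbors' selection coefficients
s_i = w_i/w − 1; this linear form ignores terms of order s², which is the
standard approximation for small selection coefficients and is used
as-is. The equal-weight scheme draws uniformly among beneficial
neighbors; it represents an observer who knows only the fitness ranking.
Neighbors of exactly equal fitness are never taken — exact ties have
probability zero under both landscape models, but the rule is fixed so
that runs are reproducible.

Every two consecutive steps of a walk traverse ab → Ab → AB; the
complement aB = ab ⊕ Ab ⊕ AB completes the quadruple. Classification is
by the fitness rank of aB among the four (rank 1 or 4 → sign epistasis;
rank 2 or 3 → synergistic/antagonistic/none by the sign of ε). Both the
multiplicative ε (log scale) and additive ε are always computed; the
label uses one declared scale, defaulting to multiplicative for NK
(whose construction is multiplicative) and additive for RMF (whose
construction is additive). The qualitative trends are insensitive to
this choice, and the test suite checks both on both families. A |ε| at
or below 1e-9 counts as "none" so that numerically exact multiplicative
landscapes are not classified by floating-point noise. Exact fitness
ties make the rank indeterminate; such quadruples get an explicit
`degenerate` label, are excluded from frequency denominators, and are
reported in their own column (the zero-noise RMF limit consists entirely
of them, since both single mutants always tie).

## Landscape generators and their defaults

**NK.** Each locus's contribution table has 2^(K+1) entries drawn i.i.d.
Uniform(c_min, c_max); neighborhoods are K loci drawn uniformly without
replacement among the other loci, independently per locus and per
landscape (random, not adjacent, neighborhoods). Fitness is the
geometric mean of the L contributions. Defaults c_min = 0.1,
c_max = 1.0: the positive floor bounds selection coefficients (fitness
ratios) away from infinity, and only the ratio c_max/c_min matters for
the walk dynamics since s values are scale-invariant.

**Rough Mt. Fuji.** Raw value slope·d(g) + Uniform(noise_low,
noise_high) with d(g) the derived-allele count, affinely rescaled so the
minimum and maximum fitnesses are exactly w_min and w_max. Defaults:
noise Uniform(0, 1), rescale to [1, 2] (keeps fitness positive and
selection coefficients moderate), slope 0.25. The slope default places
the landscape in the rugged-but-correlated regime the study targets: a
full sweep of L = 15 derived alleles contributes 3.75 in raw units
against a noise width of 1.0, giving a neighbor-fitness correlation
around 0.6 — comparable to mid-range K in the NK family. Ruggedness is
monotone in K and in noise:slope; the neighbor-fitness correlation
estimator (Pearson r over random genotype/neighbor pairs) quantifies it.

**Fitness-distribution summaries.** For NK, log-fitness is the mean of
L i.i.d. log-uniform contributions, so a central-limit Gaussian with
closed-form moments (mu = E[ln U], sigma = SD[ln U]/√L) approximates the
fitness distribution; quartile boundaries are exponentiated Gaussian
quantiles, avoiding 2^L enumeration. For RMF the full table exists by
construction, so empirical quantiles (linear interpolation of order
statistics — the convention is fixed and documented, nothing downstream
is sensitive to it) are used. The theoretical bounds agree with
exhaustive enumeration averaged over landscapes to within about 2% at
L = 10; individual landscapes deviate by a few percent more because a
single landscape's table is a finite, correlated sample.

**Low-fitness starts.** NK: uniform genotypes are rejection-sampled
until log-fitness < mu − 1.5·sigma (tail mass Φ(−1.5) ≈ 6.68%). RMF:
a uniform draw from the genotypes in the bottom Φ(−1.5) of the empirical
distribution — the same tail mass, computed empirically. The rejection
budget is bounded; smooth or small landscapes can have an empty
theoretical tail (every genotype above the marginal threshold), in which
case the sampler raises instead of looping. Batch runs on K = 0
landscapes therefore use uniform starts.

## Sampling conventions

Stratified quadruples impose the same ordering convention as walk
quadruples so the two experiments are directly comparable: ab fixed in
its fitness quartile and w_ab < w_Ab < w_AB. The sampler is a joint
rejection over independent candidates (uniform genotype ab, ordered pair
of distinct focal loci); a candidate is accepted iff ab lies in the
stratum and the chain through the first locus ascends. The complement aB
is never inspected during rejection. This matters: any scheme that
chooses among *valid orientations* of a locus pair implicitly conditions
on aB's fitness (both orientations are valid exactly when aB is ranked
2–3) and destroys the benchmark law that on a K = L−1 landscape the rank
of aB is uniform on {1,2,3,4}. The joint-rejection sampler reproduces
that law exactly (chi-square p ≈ 0.95 at n = 10^4). Note the law holds
for *unstratified* sampling; conditioning ab's quartile shifts the other
three fitnesses and hence the rank distribution of the still-independent
aB, so pooling equal-sized strata does not recover uniformity.

The walk-position windows for the percentile-interval analysis are
positions 1–3 ("early": the first three genotypes visited) and 4–6
("late"); walks shorter than a window are dropped, and the
random-genotype control is drawn uniformly from the surviving walks'
landscapes.

## Ensembles, reproducibility, and problem sizes

A batch is specified by a `RunConfig` (model, L, K or slope/noise,
ensemble sizes, scheme, start rule, scale, master seed). Defaults mirror
the study configuration: L = 15, K = 10, 1000 landscapes with one SSWM
walk each from a low-fitness start. Random streams are derived from the
master seed with `SeedSequence` spawn keys per landscape and per walk, so
any single walk replays in isolation and every output table is a pure
function of (config, master seed).

The test suite runs the walk-trend and scheme-comparison checks on 6000
walks per scheme: past step 4 nearly every traversed quadruple shows
sign epistasis, so the antagonistic:synergistic comparison at late steps
needs a large ensemble to accumulate non-sign quadruples (survivorship
also thins the late steps — most walks end within about four steps).
The acceptance script uses 2000 walks per scheme, 20 landscapes × 500
quadruples for the rank-uniformity law, and 60 landscapes × 1500
quadruples per quartile; these sizes give stable two-decimal frequencies
while keeping a full run to a few minutes on one CPU.

## What the generators do and do not emulate

The synthetic landscapes reproduce the structural features the analysis
depends on — tunable neighbor-fitness correlation, a low-fitness tail to
start from, strictly positive fitnesses, and the two analytic limits
(K = 0 multiplicative, zero-noise additive) used as oracles. They do not
emulate empirical features such as measurement error (hence "possible"
sign epistasis under uncertainty is out of scope), multi-allelic loci,
correlated noise, or the specific distribution of real mutational
effects. Passing tests therefore demonstrate the mean-regression
mechanism within these model families, not calibration of any real
organism's landscape.

## Known limitations

- The SSWM fixation weighting is first-order in s; landscapes with large
  fitness ratios stretch the approximation (the NK contribution floor
  exists to limit this).
- Statistical checks (Fisher exact, chi-square) are tooling on top of the
  simulations, with significance fixed at 99%; late walk steps have few
  surviving walks, so per-step late-stage frequencies are noisy even at
  large ensemble sizes.
- Theoretical quartiles describe the marginal fitness distribution over
  landscapes; for a single landscape the empirical quartiles can differ
  by a few percent, which slightly blurs stratum boundaries in the
  quartile experiment on NK (RMF uses exact empirical bounds).
- Single and reciprocal sign epistasis are collapsed into one "sign"
  class, as in the analyses this package supports.
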