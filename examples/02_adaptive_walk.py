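"""Run one SSWM adaptive walk and classify the epistasis it traverses.

A walk starts from a genotype in the low-fitness tail (below the mean minus
1.5 SD of log-fitness) and climbs strictly uphill, choosing each beneficial
mutation with probability proportional to its selection coefficient, until
it reaches a local optimum. Every two consecutive steps span a quadruple
{ab, Ab, aB, AB}; the fitness rank of the complement aB decides whether the
quadruple shows sign epistasis (rank 1 or 4) or synergistic/antagonistic
epistasis (rank 2 or 3, split by the sign of epsilon).
"""

import numpy as np

import ridgewalk as rw

rng = np.random.default_rng(7)
lnd = rw.make_nk_landscape(L=15, K=10, rng=rng)
summary = rw.quartile_bounds(lnd, "theoretical")
start = rw.sample_low_fitness_genotype(lnd, summary, rng)
walk = rw.run_walk(lnd, start, "sswm", rng)

print(f"walk of {walk.n_steps} steps from a low-fitness start:")
for step, (g, w) in enumerate(zip(walk.genotypes, walk.fitnesses)):
    print(f"  {step}: {rw.to_bitstring(g)}  w = {w:.4f}")

print("\nquadruples along the walk:")
for t in range(len(walk.genotypes) - 2):
    q = rw.quadruple_from_walk(walk, t, lnd)
    rec = rw.classify(q)
    print(f"  steps {t}-{t + 2}: rank(aB) = {rec.rank_of_aB}, "
          f"eps_mult = {rec.epsilon_mult:+.4f} -> {rec.label}")

n_in, n_out, _ = rw.arrow_summary(lnd, walk.genotypes[-1])
print(f"\nendpoint arrow count: {n_in} in / {n_out} out "
      "(a local optimum has only inward arrows)")
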