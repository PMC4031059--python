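"""How the mix of epistasis classes changes along adaptive walks.

Simulates an ensemble of SSWM walks (one per landscape) on rugged NK
landscapes from low-fitness starts and tabulates, per walk step, the
frequencies of sign, synergistic, and antagonistic epistasis among the
quadruples traversed. The signature pattern: sign epistasis is rare at the
first step and dominates late steps, while the antagonistic:synergistic
balance flips toward synergy.
"""

import ridgewalk as rw

cfg = rw.RunConfig(model="nk", L=15, K=10, n_landscapes=500,
                   scheme="sswm", master_seed=42)
batch = rw.simulate_batch(cfg)
table = rw.epistasis_by_step(batch.walks, batch.walk_landscapes)

cols = ["n", "freq_sign", "freq_synergistic", "freq_antagonistic"]
print(table[cols].round(3).to_string())
print("\nn is the number of walks still running at each step; "
      "frequencies are over the non-degenerate quadruples at that step.")
print("Sign epistasis rises from "
      f"{table['freq_sign'].iloc[0]:.2f} at step 0 to "
      f"{table['freq_sign'].iloc[min(4, len(table) - 1)]:.2f} by step 4.")
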