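"""Calibrate the extreme-value null model from shuffled genomes.

The reference constants (u = 18, lambda = 0.1) were fitted for w = 50,
n = 30 on ~5-kb genomes; any other setting needs its own calibration.
Here each genome is shuffled (destroying order, preserving composition),
S is computed for every shuffled pair, and Gumbel parameters are fitted
by the method of moments.
"""

from pvgc import WmerParameters, calibrate_evd, evd_pvalue, random_genome

genomes = [random_genome(2000, seed=s, genome_id=f"g{s}") for s in range(8)]
params = WmerParameters(w=30, n=18)

result = calibrate_evd(genomes, params, pairs="all", seed=1)
m = result.model
print(f"fitted u = {m.u:.3f}, lambda = {m.lam:.4f}")
print(f"from {result.diagnostics['n_pairs']} randomized pairs, "
      f"score mean {result.diagnostics['mean']:.1f}, "
      f"variance {result.diagnostics['variance']:.1f}")

for x in (10, 50, 200):
    p, log10p = evd_pvalue(x, m)
    print(f"  p(S >= {x:4d}) = {p:.4g}   (log10 p = {log10p:.3f})")

print(
    "\nu is the typical chance score, lambda the tail decay rate; scores"
    "\nwell above u are significant under this null."
)
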