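"""Compare two related genomes with the w-mer pair-count statistic.

Builds a 5-kb ancestor, derives a relative at 5% divergence and an
unrelated genome, and scores both pairs.  S counts window pairs (w = 50,
step 1) sharing more than n = 30 identical aligned nucleotides: related
genomes score in the thousands, unrelated ones near zero.
"""

from pvgc import (
    DEFAULT_MODEL,
    best_orientation_score,
    evd_pvalue,
    mutate,
    random_genome,
)

ancestor = random_genome(5000, seed=1, genome_id="ancestor")
relative, _ = mutate(ancestor, divergence=0.05, seed=2, mutant_id="relative")
unrelated = random_genome(5000, seed=3, genome_id="unrelated")

for other in (relative, unrelated):
    score = best_orientation_score(ancestor, other)
    p, log10p = evd_pvalue(score.S, DEFAULT_MODEL)
    print(
        f"{score.id_a} vs {score.id_b}: S = {score.S} "
        f"({score.orientation_b}), log10 p = {log10p:.4g}"
    )

print(
    "\nS is the count of qualifying 50-nt window pairs; log10 p is its"
    "\nextreme-value significance (p near 1 means chance similarity)."
)
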