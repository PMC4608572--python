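# Methods

## The w-mer pair-count statistic

Given genomes A and B of lengths La, Lb, every length-*w* window of A
(step 1) is compared, ungapped, against every length-*w* window of B.
A window pair *qualifies* when its identity count is strictly greater
than the critical value *n* ("more than n of w positions identical").
Two counting modes are provided because "counting similar window
pairs" admits two readings:

* **all_pairs** (default): S is the number of qualifying ordered pairs
  (i, j). This is symmetric in A and B for fixed strands and is what
  the all-vs-all p-matrix uses.
* **best_pair**: S is the number of windows of A whose best partner in
  B qualifies; bounded by La − w + 1 and asymmetric. It is kept because
  per-query-window statistics are what the conservation profile needs,
  and downstream calibration is mode-aware.

Defaults w = 50, n = 30 follow the reference setting for ~5-kb
polyomavirus genomes. The strict inequality (> n, i.e. ≥ 31 identities)
is the default; `strict=False` switches to ≥ n for sensitivity
analysis. Ambiguity codes never match anything, including themselves
(each side of a comparison is encoded with a distinct non-base
sentinel). Genomes are treated as linear by default — deposited
circular genomes are linearised, and junction handling is a
convention, not data; `circular=True` extends each sequence by its
first w − 1 bases so windows wrap.

The production algorithm walks the La × Lb comparison space diagonal by
diagonal: along a diagonal the window identity is a length-w moving sum
of a binary match vector, updated in O(1) per step (vectorised with
cumulative sums), for O(La·Lb) total work — a 5 kb × 5 kb comparison
takes ~0.2 s. A naive window-by-window recount
(`count_wmer_pairs_naive`) is retained in the package and asserted
equal on hundreds of random pairs in the tests; it is the oracle the
fast path is judged against, never the production path.

## Extreme-value significance

Chance scores between randomized genomes follow a Gumbel law:
p(S ≥ x) = 1 − exp(−e^(−λ(x−u))). The shipped reference model is
u = 18, λ = 0.1, and is labeled valid only for w = 50, n = 30 on ~5-kb
genomes; `pairwise_pmatrix` accepts any model, and other settings
should be calibrated explicitly.

p-values are computed and propagated in log₁₀ space: meaningful cutoffs
reach 10⁻⁸⁶ and a self-comparison of a 5-kb genome sits near 10⁻²¹⁴,
far beyond double-precision underflow. Writing t = e^(−λ(x−u)), for
t < 10⁻⁴ we use log p = log t + log1p(−t/2 + t²/6), whose truncation
error is below double precision there; the tests verify 12-significant-
digit agreement with a 200-digit evaluation across the working range.
In double precision p saturates at 1.0 for x far below u (t > ~36), so
strict monotonicity of the linear-scale p holds on the numerically
resolvable range only; log₁₀ p is the quantity downstream code uses.

**Calibration.** Each genome is shuffled once per round — a uniform
permutation of positions, preserving mononucleotide composition
exactly. Dinucleotide-preserving shuffles are deliberately not the
default: the null is positional randomization. S is computed for an
explicit sampling plan of shuffled pairs ("all" or a random subset),
and parameters are fitted either by moments (λ = π/√(6·s²),
u = mean − γ/λ, with s² the n−1-denominator sample variance and γ the
Euler–Mascheroni constant) or by numerical maximum likelihood
(scipy's right-skewed Gumbel). Moments is the default: with hundreds
of sampled pairs it recovers λ to ~1% and is closed-form.

Composition matters: between independent *uniform* 5-kb genomes the
expected S at the default setting is ~0.6, but at a polyomavirus-like
AT-rich composition (0.30/0.20/0.20/0.30) it is ~2.2, and real genomes
shared composition pushes it higher still. This is precisely why the
null is built from shuffles of the actual input genomes rather than
assumed to be zero.

**Choosing n.** `select_critical_value` tabulates, per candidate n, the
mean shuffled-pair S (background) against the minimum real-pair S, and
recommends the smallest n whose background is ≤ 15% of the weakest real
signal. The full table is returned: in the low-n regime background and
real scores are both dominated by chance coincidences and their ratio
hovers near 1 (and need not be monotone); the rule only bites once n
clears that regime.

## Curation

* **Length window**: genomes shorter than 3500 or longer than 8000 nt
  are dropped (partial or integrated genomes); the bounds are
  inclusive — a genome of exactly 3500 or 8000 nt passes.
* **Ambiguity resolution**: each non-ACGT position is the centre of a
  41-nt context window (odd by construction, shrunk at sequence ends)
  slid over every reference genome; the replacement is the base aligned
  to the centre of the best-matching window. Ambiguous positions on
  either side count as mismatches in the context search. The acceptance
  threshold — best window must exceed 30/41 of the window length in
  identities — reuses the w-mer identity proportion, since no separate
  threshold is canonical; unresolved positions are kept, reported, and
  treated as mismatches downstream. Ties go to the most frequent centre
  base among tied windows, then alphabetically.
* **Strand correspondence**: the first genome (or a configured
  reference) stays forward; every other genome keeps whichever strand
  scores higher against the reference, ties keeping forward. This is
  deterministic and idempotent.
* **Deduplication** removes exact string duplicates only, keeping first
  occurrences. Rotation equivalence of circular genomes is *not*
  collapsed by default (deposited genomes share linearisation
  conventions); `canonical_rotation` opts in.

## Clustering

The all-vs-all matrix stores log₁₀ p per unordered pair at the better
strand of the second genome; the diagonal is −∞ and excluded from
edges, and values below −10000 are clamped (far beyond any cutoff in
use). Clusters at a cutoff are the connected components of the graph
with an edge wherever log₁₀ p ≤ cutoff — smaller p, stronger link. A
force-directed dynamic layout is provided for presentation, but cluster
*membership* is always the exact component structure: it is
deterministic, testable, and is the information a cutoff figure
reports. Component labels are the lexicographically smallest member id,
so outputs are diff-stable. Sweeping cutoffs loosest-first yields a
refinement chain (components only split), and per pair the loosest
cutoff at which the two genomes first land in different components is
reported as their separation level. Export formats: a CLANS-compatible
file (`sequences=N` header, `<seq>` FASTA block, `<hsp>` lines `i j:p`
with exponent-notation p safe below float underflow, p = 1 pairs
omitted) plus a plain edge-list TSV.

## Annotation conventions

All coordinates are 1-based inclusive on the forward strand.

* **ORFs** open at the first in-frame ATG or GTG after the previous
  in-frame stop and run to the next in-frame stop, which is included in
  `length_bp`; hence `protein_length_aa = length_bp/3 − 1` (the
  162 bp → 53 aa arithmetic). Nested starts are reported only in
  `all_starts` mode. A start with no downstream in-frame stop yields no
  ORF in linear mode. Circular mode scans the doubled sequence, keeps
  ORFs starting in the first copy with length ≤ L, and wraps
  coordinates.
* **Motifs** are matched IUPAC-aware with overlaps, both strands;
  minus-strand hits are reported at their forward-strand footprint.
* **Palindromes** are reverse-complement repeats: for every centre
  (loop placement, loop ≤ max_loop) arms are extended maximally and
  reported only if they reach `min_arm`; sub-arm hits of the same
  centre are not emitted.
* **Splice candidates** enumerate every GT..AG pair within intron
  length bounds; `donor_pos` is the G of GT, `acceptor_pos` the G of AG
  (the intron's last base), so `intron_length = acceptor − donor + 1`.
  Consensus scoring and protein-context filtering are the caller's
  concern.
* **SNPs** require pre-equalized sequences — there is no internal
  aligner, since cross-indel comparisons are an alignment problem, not
  a counting one. Coding SNPs are classified per codon; the notation is
  `ref_aa` + codon index + `alt_aa` (e.g. A327T).

## Synthetic data

Families derive from independent i.i.d. ancestors (default 5000 nt,
mildly AT-rich 0.30/0.20/0.20/0.30 to resemble polyomavirus genomes).
Members substitute each site with probability equal to the divergence,
to a uniformly chosen different base (Jukes–Cantor-like: the tests need
controlled identity levels, not realistic transition bias), optionally
with geometric-length indels, and every event is logged for exact
replay. A configured fraction of members is stored
reverse-complemented to exercise strand correction. Defaults emulate
the study conditions: families at ~5% divergence are unambiguous
relatives, while distinct-species identity sits near 81–84%.

What the generator does **not** emulate: shared ancestral composition
across families (between-family pairs are fully independent, so the
real-data background — elevated by shared composition and universal
conserved domains — is understated), recombination, selection-driven
rate variation along the genome, and real gene architecture. Passing
planted-partition tests therefore demonstrates the machinery
(counting, significance, components) is correct, not that any
particular cutoff generalises to real genome sets.

## Problem sizes and numerical choices

The test suite and the acceptance script run at sizes chosen to
exercise every code path at full fidelity while completing in minutes:
oracle equivalence on 200 random pairs of 100–400 nt at mixed (w, n);
Gumbel recovery from 10⁵ draws (moments recovers u within ±0.5 and λ
within ±0.005 there); planted-partition recovery on 3 families × 4
members of 5-kb genomes at 5% divergence (66 pairs, both strands).
Degenerate inputs are errors, not silent answers: genomes shorter than
w, zero-variance calibration scores, unequal-length SNP comparisons,
empty conservation databases. Tie-breaks are deterministic everywhere
(forward strand on score ties, smallest id as component label,
alphabetical base on ambiguity-resolution ties).

## Known limitations

* The reference (u, λ) applies to one parameter setting; the package
  enforces nothing beyond provenance labels if a user applies it
  elsewhere.
* `best_pair` mode shares the calibration machinery but its null
  distribution differs from all_pairs; calibrate within the mode used.
* No gapped alignment anywhere: SNP tools require equal lengths, and
  the similarity statistic is exact by definition — no sketching or
  seeding heuristics are provided.
* The force-directed layout is cosmetic; distances in it carry no
  calibrated meaning.
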