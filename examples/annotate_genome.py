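"""Annotate a small viral genome: ORFs, origin motifs, SNP effects.

Scans a synthetic genome for open reading frames starting at ATG/GTG,
LTag-binding GAGGC pentanucleotides, reverse-complement palindromes and
AT-rich tracts (the origin-of-replication signature of polyomaviruses),
then classifies coding SNPs between two ORF alleles.
"""

from pvgc import (
    at_rich_regions,
    classify_coding_snps,
    find_orfs,
    find_palindromes,
    orf_sequence,
    random_genome,
    scan_motif,
    translate,
)

genome = random_genome(3000, seed=7, genome_id="demo")

orfs = find_orfs(genome, min_length_bp=150)
print(f"{len(orfs)} ORFs of >= 150 bp; the longest:")
longest = max(orfs, key=lambda o: o.length_bp)
print(
    f"  {longest.start}..{longest.end} ({longest.strand}), "
    f"{longest.length_bp} bp -> {longest.protein_length_aa} aa, "
    f"starts {longest.start_codon}"
)

hits = scan_motif(genome, "GAGGC")
pals = find_palindromes(genome.sequence, min_arm=5, max_loop=3)
at = at_rich_regions(genome.sequence, window=10, min_fraction=0.9)
print(f"GAGGC pentanucleotides: {len(hits)} (both strands)")
print(f"palindromes (arm >= 5): {len(pals)}; AT-rich spans (>= 90%): {len(at)}")

# mutate one codon of the longest ORF and classify the SNP
cds_a = orf_sequence(genome, longest)
middle = (longest.protein_length_aa // 2) * 3
cds_b = cds_a[:middle] + "GCA" + cds_a[middle + 3 :]
records, summary = classify_coding_snps(cds_a, cds_b)
print(f"\nSNPs between alleles: {summary['total']} "
      f"({summary['nonsynonymous']} nonsynonymous)")
for r in records:
    print(f"  position {r.position}: {r.ref_base}>{r.alt_base} "
          f"codon {r.codon_index} {r.notation} ({r.effect})")
print(f"protein length check: {len(translate(cds_a).protein)} aa")
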