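"""ORF discovery, translation arithmetic, motif/palindrome/splice scanners,
and SNP classification."""

import numpy as np
import pytest

from pvgc import (
    Genome,
    at_rich_regions,
    classify_coding_snps,
    find_orfs,
    find_palindromes,
    hamming_snps,
    orf_sequence,
    random_genome,
    reverse_complement,
    scan_motif,
    splice_candidates,
    translate,
)
from pvgc.annotation import write_gff3

CODONS = ["GCA", "TGC", "GAT", "GAA", "TTT", "GGA", "CAT", "ATA", "AAA", "CTA"]


def _orf_of_length(length_bp: int, seed: int = 0) -> str:
    """ATG + filler codons + TAA, exactly length_bp nucleotides."""
    assert length_bp % 3 == 0 and length_bp >= 6
    rng = np.random.default_rng(seed)
    fill = "".join(rng.choice(CODONS) for _ in range(length_bp // 3 - 2))
    return "ATG" + fill + "TAA"


class TestFindOrfs:
    def test_minimal_orf(self):
        orfs = find_orfs("ATGTAA", min_length_bp=6)
        assert len(orfs) == 1
        o = orfs[0]
        assert (o.start, o.end, o.strand) == (1, 6, "+")
        assert o.length_bp == 6 and o.protein_length_aa == 1

    @pytest.mark.parametrize("length_bp,aa", [(162, 53), (189, 62), (426, 141)])
    def test_x_orf_length_arithmetic(self, length_bp, aa):
        # ORF lengths of the accessory X-ORF variants and their proteins
        seq = "CC" + _orf_of_length(length_bp) + "GG"
        orfs = [o for o in find_orfs(seq, min_length_bp=150) if o.strand == "+"]
        assert orfs and orfs[0].length_bp == length_bp
        assert orfs[0].protein_length_aa == aa
        cds = orf_sequence(seq, orfs[0])
        assert len(translate(cds).protein) == aa

    def test_start_without_stop_yields_nothing(self):
        assert find_orfs("ATGAAAAAAAAA", min_length_bp=6) == []

    def test_gtg_start_recognized(self):
        orfs = find_orfs("GTGAAATAA", min_length_bp=9)
        plus = [o for o in orfs if o.strand == "+"]
        assert plus and plus[0].start_codon == "GTG"

    def test_first_start_after_stop_opens_orf(self):
        # TAA ATG AAA ATG TAA: default reports the outer ORF only
        seq = "TAAATGAAAATGTAA"
        orfs = [o for o in find_orfs(seq, min_length_bp=6) if o.strand == "+"]
        assert [o.start for o in orfs] == [4]
        nested = [
            o
            for o in find_orfs(seq, min_length_bp=6, all_starts=True)
            if o.strand == "+"
        ]
        assert sorted(o.start for o in nested) == [4, 10]

    def test_reverse_strand_coordinates(self):
        fwd = "ATGAAATAA"
        seq = reverse_complement(fwd)
        orfs = find_orfs(seq, min_length_bp=9)
        assert len(orfs) == 1
        o = orfs[0]
        assert o.strand == "-" and (o.start, o.end) == (1, 9)
        assert orf_sequence(seq, o) == fwd

    def test_circular_orf_spans_junction(self):
        orf = _orf_of_length(30, seed=1)
        # cut the ORF 10 nt from its start and wrap it around the junction
        seq = orf[10:] + "TTTTTT" + orf[:10]
        linear = find_orfs(seq, min_length_bp=30)
        circular = find_orfs(
            Genome(id="c", sequence=seq, circular=True),
            min_length_bp=30,
            circular=True,
        )
        starts = {(o.strand, o.start, o.length_bp) for o in circular}
        assert ("+", len(orf) - 10 + 6 + 1, 30) in starts
        assert len(circular) >= len(linear)

    def test_reextraction_invariant(self):
        g = random_genome(900, seed=4, genome_id="g")
        for o in find_orfs(g, min_length_bp=60):
            cds = orf_sequence(g, o)
            assert len(cds) == o.length_bp == 3 * (o.protein_length_aa + 1)
            assert cds[:3] == o.start_codon
            assert cds[-3:] in {"TAA", "TAG", "TGA"}
            t = translate(cds)
            assert t.terminated and t.internal_stop_codon is None
            assert len(t.protein) == o.protein_length_aa

    def test_bad_min_length_rejected(self):
        with pytest.raises(ValueError):
            find_orfs("ATGTAA", min_length_bp=7)


class TestTranslate:
    def test_simple_peptide(self):
        assert translate("ATGGCA").protein == "MA"

    def test_terminator_excluded_from_protein(self):
        t = translate("ATGTAA")
        assert t.protein == "M" and t.terminated

    def test_internal_stop_truncates_with_flag(self):
        t = translate("ATGTAAGCATAA")
        assert t.protein == "M" and t.internal_stop_codon == 2

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            translate("ATGGC")

    def test_189_bp_orf_gives_62_aa(self):
        cds = _orf_of_length(189)
        assert len(translate(cds).protein) == 62


class TestScanMotif:
    def test_overlapping_hits_found(self):
        hits = scan_motif("GAGGCGAGGC", "GAGGC", both_strands=False)
        assert [h.start for h in hits] == [1, 6]

    def test_homopolymer_no_hits(self):
        assert scan_motif("A" * 50, "GAGGC") == []

    def test_five_pentanucleotides_in_ori_like_region(self):
        # an origin-like region carrying five LTag-binding pentanucleotides
        region = "TT" + "GAGGC" * 2 + "AATT" + "GCCTC" + "ATAT" + "GAGGC" * 2
        fwd = [h for h in scan_motif(region, "GAGGC") if h.strand == "+"]
        rev = [h for h in scan_motif(region, "GAGGC") if h.strand == "-"]
        assert len(fwd) == 4 and len(rev) == 1
        assert len(fwd) + len(rev) == 5

    def test_iupac_classes_match(self):
        hits = scan_motif("GAGGC", "GASGC", both_strands=False)
        assert len(hits) == 1

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            scan_motif("ACGT", "ACXG")

    def test_strand_symmetry(self):
        g = random_genome(400, seed=5, genome_id="g")
        motif = "GAGGC"
        fwd_on_rc = {
            h.start
            for h in scan_motif(reverse_complement(g.sequence), motif, False)
        }
        minus = {
            len(g) - (h.start + len(motif) - 1) + 1
            for h in scan_motif(g, motif)
            if h.strand == "-"
        }
        assert minus == fwd_on_rc

    def test_context_contains_motif(self):
        g = random_genome(300, seed=6, genome_id="g")
        for h in scan_motif(g, "GAGGC"):
            if h.strand == "+":
                assert "GAGGC" in h.context
            else:
                assert "GAGGC" in reverse_complement(h.context)


def _palindrome_oracle(seq, min_arm, max_loop):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    L = len(seq)
    found = set()
    for loop in range(max_loop + 1):
        for i in range(L + 1 - loop):
            arm = 0
            while (
                i - arm - 1 >= 0
                and i + loop + arm < L
                and seq[i - arm - 1] in comp
                and comp[seq[i - arm - 1]] == seq[i + loop + arm]
            ):
                arm += 1
            if arm >= min_arm:
                found.add((i - arm + 1, i + loop + arm, arm, loop))
    return found


class TestPalindromes:
    def test_ecori_site(self):
        hits = find_palindromes("GAATTC", min_arm=3, max_loop=0)
        assert [(h.start, h.end, h.arm, h.loop) for h in hits] == [(1, 6, 3, 0)]

    def test_homopolymer_empty(self):
        assert find_palindromes("AAAAAA", min_arm=3, max_loop=2) == []

    def test_arms_reverse_complement_each_other(self):
        g = random_genome(500, seed=7, genome_id="g")
        for h in find_palindromes(g.sequence, min_arm=4, max_loop=3):
            left = g.sequence[h.start - 1 : h.start - 1 + h.arm]
            right = g.sequence[h.end - h.arm : h.end]
            assert reverse_complement(left) == right

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_oracle(self, seed):
        g = random_genome(1000, seed=seed, genome_id="g")
        hits = {
            (h.start, h.end, h.arm, h.loop)
            for h in find_palindromes(g.sequence, min_arm=4, max_loop=2)
        }
        assert hits == _palindrome_oracle(g.sequence, 4, 2)


class TestAtRich:
    def test_pure_at_whole_span(self):
        spans = at_rich_regions("ATATATATAT", window=10, min_fraction=0.9)
        assert [(s.start, s.end) for s in spans] == [(1, 10)]

    def test_pure_gc_none(self):
        assert at_rich_regions("GCGCGCGCGC", window=10, min_fraction=0.5) == []

    def test_matches_sliding_count_oracle(self):
        g = random_genome(600, seed=8, genome_id="g")
        window, frac = 10, 0.8
        spans = at_rich_regions(g.sequence, window, frac)
        covered = set()
        for s in spans:
            covered.update(range(s.start, s.end + 1))
        expect = set()
        for i in range(len(g) - window + 1):
            win = g.sequence[i : i + window]
            if sum(b in "AT" for b in win) >= frac * window:
                expect.update(range(i + 1, i + window + 1))
        assert covered == expect


class TestSpliceCandidates:
    def test_hand_enumerated_example(self):
        # A A G T A A A G A A: the only GT starts at 3, the only AG ends
        # at 8, so the single intron candidate spans 3..8 (length 6)
        cands = splice_candidates("AAGTAAAGAA", min_intron=4)
        assert len(cands) == 1
        c = cands[0]
        assert (c.donor_pos, c.acceptor_pos, c.intron_length) == (3, 8, 6)
        assert c.phase_preserving

    def test_no_donor_empty(self):
        assert splice_candidates("AAAAAGAAAG", min_intron=4) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_double_loop_oracle(self, seed):
        g = random_genome(500, seed=seed + 50, genome_id="g")
        seq = g.sequence
        got = {
            (c.donor_pos, c.acceptor_pos)
            for c in splice_candidates(seq, min_intron=10, max_intron=100)
        }
        expect = set()
        for d in range(len(seq) - 1):
            if seq[d : d + 2] != "GT":
                continue
            for a in range(d + 1, len(seq)):
                if seq[a - 1 : a + 1] != "AG":
                    continue
                length = a - d + 1
                if 10 <= length <= 100:
                    expect.add((d + 1, a + 1))
        assert got == expect


class TestSnps:
    def test_identical_sequences(self):
        count, records = hamming_snps("ACGT", "ACGT")
        assert count == 0 and records == []

    def test_single_difference_position(self):
        count, records = hamming_snps("ACGT", "ACGA")
        assert count == 1
        assert (records[0].position, records[0].ref_base, records[0].alt_base) == (
            4, "T", "A",
        )

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(9)
        seqs = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(3)]
        d = lambda x, y: hamming_snps(x, y)[0]  # noqa: E731
        assert d(seqs[0], seqs[1]) == d(seqs[1], seqs[0])
        assert d(seqs[0], seqs[2]) <= d(seqs[0], seqs[1]) + d(seqs[1], seqs[2])

    def test_unequal_lengths_directed_to_align(self):
        with pytest.raises(ValueError, match="align or trim"):
            hamming_snps("ACGT", "ACG")

    def test_synonymous_classification(self):
        records, summary = classify_coding_snps("GGA", "GGG")
        assert summary == {"total": 1, "nonsynonymous": 0, "synonymous": 1}
        assert records[0].effect == "synonymous"

    def test_nonsynonymous_notation(self):
        records, summary = classify_coding_snps("GCAAAA", "ACAAAA")
        assert summary["nonsynonymous"] == 1
        assert records[0].notation == "A1T"

    def test_notation_at_codon_327(self):
        # a VP1-like CDS pair differing by one nonsynonymous SNP at codon 327
        cds_a = _orf_of_length(3 * 400, seed=3)
        i = 326 * 3
        cds_a = cds_a[:i] + "GCA" + cds_a[i + 3 :]
        cds_b = cds_a[:i] + "ACA" + cds_a[i + 3 :]
        records, summary = classify_coding_snps(cds_a, cds_b)
        assert summary == {"total": 1, "nonsynonymous": 1, "synonymous": 0}
        assert records[0].notation == "A327T"

    def test_effect_invariant_under_swap(self):
        a = _orf_of_length(90, seed=4)
        rng = np.random.default_rng(5)
        b = list(a)
        for pos in rng.choice(len(a), size=6, replace=False):
            b[pos] = rng.choice([c for c in "ACGT" if c != a[pos]])
        b = "".join(b)
        rec_ab, sum_ab = classify_coding_snps(a, b)
        rec_ba, sum_ba = classify_coding_snps(b, a)
        assert sum_ab["total"] == sum_ba["total"]
        assert sum_ab["nonsynonymous"] == sum_ba["nonsynonymous"]
        for x, y in zip(rec_ab, rec_ba):
            assert x.effect == y.effect


def test_gff3_output(tmp_path):
    g = random_genome(400, seed=10, genome_id="vg1")
    orfs = find_orfs(g, min_length_bp=60)
    motifs = scan_motif(g, "GAGGC")
    path = tmp_path / "annot.gff3"
    write_gff3(g, path, orfs=orfs, motifs=motifs)
    lines = path.read_text().splitlines()
    assert lines[0] == "##gff-version 3"
    feature_lines = [ln for ln in lines if not ln.startswith("#")]
    assert len(feature_lines) == len(orfs) + len(motifs)
    for ln in feature_lines:
        fields = ln.split("\t")
        assert len(fields) == 9
        assert 1 <= int(fields[3]) <= int(fields[4]) <= len(g)
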