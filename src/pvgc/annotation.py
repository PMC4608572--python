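"""Genome annotation: ORFs, motifs, palindromes, splice sites, SNPs.

Small circular dsDNA virus genomes carry early regulatory genes (large
and small T antigen) on one strand and late capsid genes (VP1/VP2/VP3)
on the other, separated by a non-coding control region whose origin of
replication is marked by GAGGC LTag-binding pentanucleotides, palindromic
repeats and an AT-rich tract.  The scanners here enumerate these signals
exhaustively; biological filtering (homology, splice-consensus scoring)
is the caller's concern.

All reported coordinates are 1-based inclusive on the forward strand
(GenBank convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from Bio.Seq import Seq

from .genomes import Genome, reverse_complement

STOP_CODONS = {"TAA", "TAG", "TGA"}
DEFAULT_STARTS = ("ATG", "GTG")

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class OrfRecord:
    """An open reading frame, stop codon included in its length."""

    start: int
    end: int
    strand: str
    frame: int
    start_codon: str
    length_bp: int

    @property
    def protein_length_aa(self) -> int:
        return self.length_bp // 3 - 1


def _scan_strand_orfs(
    seq: str,
    min_length_bp: int,
    starts: Sequence[str],
    all_starts: bool,
) -> list[tuple[int, int, int, str]]:
    """ORFs on one strand of a linear sequence.

    Returns (start0, end0_exclusive, frame, start_codon) tuples in local
    coordinates.  An ORF opens at the first in-frame start codon after
    the previous in-frame stop and runs to the next in-frame stop
    (included); a start with no downstream in-frame stop yields nothing.
    """
    out = []
    L = len(seq)
    for frame in range(3):
        open_starts: list[tuple[int, str]] = []
        for pos in range(frame, L - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                for s0, sc in open_starts:
                    length = pos + 3 - s0
                    if length >= min_length_bp:
                        out.append((s0, pos + 3, frame, sc))
                open_starts = []
            elif codon in starts:
                if all_starts or not open_starts:
                    open_starts.append((pos, codon))
    return out


def find_orfs(
    genome: Genome | str,
    min_length_bp: int = 150,
    starts: Sequence[str] = DEFAULT_STARTS,
    circular: bool = False,
    all_starts: bool = False,
) -> list[OrfRecord]:
    """Find ORFs beginning at traditional initiation codons (ATG/GTG).

    By default only the longest ORF per stop and frame is reported (the
    first in-frame start after the previous stop opens it); pass
    ``all_starts=True`` to report nested starts too.  In circular mode
    ORFs may span the junction and their end coordinate wraps.
    """
    if min_length_bp < 6 or min_length_bp % 3 != 0:
        raise ValueError("min_length_bp must be >= 6 and a multiple of 3")
    seq = genome.sequence if isinstance(genome, Genome) else genome.upper()
    L = len(seq)
    records: list[OrfRecord] = []
    seen: set[tuple[str, int, int]] = set()
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        scan_seq = s + s if circular else s
        for s0, e0, frame, sc in _scan_strand_orfs(
            scan_seq, min_length_bp, starts, all_starts
        ):
            if circular:
                if s0 >= L or e0 - s0 > L:
                    continue
            length = e0 - s0
            M = len(scan_seq)
            if strand == "+":
                start1, end1 = s0 + 1, e0
            else:
                # local reverse-strand coords -> forward coords: local q
                # (0-based) sits at forward position M - q (1-based)
                start1, end1 = M - e0 + 1, M - s0
            if circular:
                start1 = (start1 - 1) % L + 1
                end1 = (end1 - 1) % L + 1
            key = (strand, start1, length)
            if key in seen:
                continue
            seen.add(key)
            records.append(
                OrfRecord(
                    start=start1,
                    end=end1,
                    strand=strand,
                    frame=frame,
                    start_codon=sc,
                    length_bp=length,
                )
            )
    records.sort(key=lambda r: (r.strand, r.start, -r.length_bp))
    return records


def orf_sequence(genome: Genome | str, orf: OrfRecord) -> str:
    """Extract an ORF's coding sequence (start codon through stop)."""
    seq = genome.sequence if isinstance(genome, Genome) else genome.upper()
    L = len(seq)
    if orf.strand == "+":
        if orf.end >= orf.start:
            sub = seq[orf.start - 1 : orf.end]
        else:  # wraps the junction
            sub = seq[orf.start - 1 :] + seq[: orf.end]
        return sub
    if orf.start <= orf.end:
        sub = seq[orf.start - 1 : orf.end]
    else:
        sub = seq[orf.start - 1 :] + seq[: orf.end]
    return reverse_complement(sub)


class Translation(NamedTuple):
    """Result of translating a CDS with the standard nuclear code."""

    protein: str
    terminated: bool
    internal_stop_codon: int | None  # 1-based codon index, None if clean


def translate(cds: str) -> Translation:
    """Translate a CDS (standard code, table 1).

    The trailing stop is reported via ``terminated`` and excluded from
    ``protein``; an internal stop truncates the protein and is flagged
    with its codon index.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    aa = str(Seq(cds).translate(table=1))
    terminated = aa.endswith("*")
    body = aa[:-1] if terminated else aa
    internal = body.find("*")
    if internal >= 0:
        return Translation(body[:internal], terminated, internal + 1)
    return Translation(body, terminated, None)


@dataclass(frozen=True)
class MotifHit:
    """An exact/IUPAC motif occurrence; ``start`` is the 1-based forward
    coordinate of the motif's leftmost base."""

    motif: str
    start: int
    strand: str
    context: str


def _iupac_regex(motif: str) -> re.Pattern:
    parts = []
    for ch in motif.upper():
        if ch not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC code {ch!r} in motif")
        s = IUPAC_SETS[ch]
        parts.append(s if len(s) == 1 else f"[{s}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_motif(
    genome: Genome | str,
    motif: str,
    both_strands: bool = True,
    flank: int = 5,
) -> list[MotifHit]:
    """All (including overlapping) occurrences of an IUPAC motif."""
    if not motif:
        raise ValueError("motif must be non-empty")
    seq = genome.sequence if isinstance(genome, Genome) else genome.upper()
    pat = _iupac_regex(motif)
    L, m = len(seq), len(motif)
    hits: list[MotifHit] = []

    def context_at(start0: int) -> str:
        return seq[max(0, start0 - flank) : start0 + m + flank]

    for match in pat.finditer(seq):
        hits.append(
            MotifHit(
                motif=motif,
                start=match.start() + 1,
                strand="+",
                context=context_at(match.start()),
            )
        )
    if both_strands:
        rc = reverse_complement(seq)
        for match in pat.finditer(rc):
            start0 = L - match.start() - m  # leftmost base on forward strand
            hits.append(
                MotifHit(
                    motif=motif,
                    start=start0 + 1,
                    strand="-",
                    context=context_at(start0),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


@dataclass(frozen=True)
class PalindromeHit:
    """A reverse-complement palindrome: two ``arm``-long arms flanking a
    loop of ``loop`` unpaired bases.  Coordinates 1-based inclusive."""

    start: int
    end: int
    arm: int
    loop: int


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def find_palindromes(
    region: str, min_arm: int = 3, max_loop: int = 4
) -> list[PalindromeHit]:
    """Maximal reverse-complement palindromes in a region.

    For every centre (loop placement and length up to ``max_loop``) the
    arms are extended as far as they base-pair; only the maximal
    extension is reported, and only when the arm reaches ``min_arm``.
    Ambiguity codes never pair.
    """
    if min_arm < 3:
        raise ValueError("min_arm must be >= 3")
    seq = region.upper()
    L = len(seq)
    found: set[PalindromeHit] = set()
    for loop in range(0, max_loop + 1):
        for i in range(L + 1):  # loop occupies seq[i : i + loop]
            if i + loop > L:
                break
            arm = 0
            while (
                i - arm - 1 >= 0
                and i + loop + arm < L
                and seq[i - arm - 1] in _COMP
                and _COMP[seq[i - arm - 1]] == seq[i + loop + arm]
            ):
                arm += 1
            if arm >= min_arm:
                found.add(
                    PalindromeHit(
                        start=i - arm + 1, end=i + loop + arm, arm=arm, loop=loop
                    )
                )
    return sorted(found, key=lambda h: (h.start, h.end, h.loop))


@dataclass(frozen=True)
class Span:
    start: int
    end: int


def at_rich_regions(
    region: str, window: int = 10, min_fraction: float = 0.8
) -> list[Span]:
    """Maximal spans covered by windows with A+T fraction >= min_fraction."""
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    seq = region.upper()
    L = len(seq)
    if L < window:
        return []
    is_at = [1 if b in "AT" else 0 for b in seq]
    count = sum(is_at[:window])
    qualifying: list[int] = []
    for start in range(L - window + 1):
        if start > 0:
            count += is_at[start + window - 1] - is_at[start - 1]
        if count >= min_fraction * window:
            qualifying.append(start)
    spans: list[Span] = []
    for s in qualifying:
        lo, hi = s + 1, s + window
        if spans and lo <= spans[-1].end + 1:
            spans[-1] = Span(spans[-1].start, max(spans[-1].end, hi))
        else:
            spans.append(Span(lo, hi))
    return spans


@dataclass(frozen=True)
class SpliceCandidate:
    """A GT..AG intron candidate.  ``donor_pos`` is the 1-based position
    of the G of GT; ``acceptor_pos`` that of the G of AG (intron's last
    base); ``phase_preserving`` marks intron lengths divisible by 3."""

    donor_pos: int
    acceptor_pos: int
    strand: str
    intron_length: int

    @property
    def phase_preserving(self) -> bool:
        return self.intron_length % 3 == 0


def splice_candidates(
    region: str,
    strand: str = "+",
    min_intron: int = 4,
    max_intron: int | None = None,
) -> list[SpliceCandidate]:
    """All GT..AG donor/acceptor pairs within the intron length bounds.

    Coordinates refer to the given region on the given strand; filtering
    candidates by the proteins they would produce is the caller's
    concern.
    """
    if min_intron < 4:
        raise ValueError("min_intron must be >= 4")
    seq = region.upper()
    if strand == "-":
        seq = reverse_complement(seq)
    L = len(seq)
    max_intron = max_intron if max_intron is not None else L
    donors = [i for i in range(L - 1) if seq[i : i + 2] == "GT"]
    acceptors = [i + 1 for i in range(L - 1) if seq[i : i + 2] == "AG"]
    out: list[SpliceCandidate] = []
    for d in donors:
        for a in acceptors:
            length = a - d + 1
            if length < max(min_intron, 4):
                continue
            if length > max_intron:
                continue
            out.append(
                SpliceCandidate(
                    donor_pos=d + 1,
                    acceptor_pos=a + 1,
                    strand=strand,
                    intron_length=length,
                )
            )
    out.sort(key=lambda c: (c.donor_pos, c.acceptor_pos))
    return out


@dataclass(frozen=True)
class SnpRecord:
    """A single-nucleotide difference between two equal-length sequences."""

    position: int
    ref_base: str
    alt_base: str
    codon_index: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    effect: str | None = None

    @property
    def notation(self) -> str | None:
        if self.codon_index is None:
            return None
        return f"{self.ref_aa}{self.codon_index}{self.alt_aa}"


def hamming_snps(a: str, b: str) -> tuple[int, list[SnpRecord]]:
    """Count and locate mismatches between two equal-length sequences.

    Sequences must be pre-equalized (aligned or trimmed); comparisons
    across indels are out of scope here.
    """
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise ValueError(
            f"sequences differ in length ({len(a)} vs {len(b)}); "
            "align or trim them first"
        )
    records = [
        SnpRecord(position=i + 1, ref_base=x, alt_base=y)
        for i, (x, y) in enumerate(zip(a, b))
        if x != y
    ]
    return len(records), records


def classify_coding_snps(
    cds_a: str, cds_b: str
) -> tuple[list[SnpRecord], dict[str, int]]:
    """Classify SNPs between two in-frame CDSs as (non)synonymous.

    Each mismatch is annotated with its codon index (1-based), the amino
    acids encoded by the two codons and the substitution notation
    (e.g. A327T).  Returns the records and a summary
    ``{"total": ..., "nonsynonymous": ..., "synonymous": ...}``.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValueError("CDSs differ in length; align or trim them first")
    if len(cds_a) % 3 != 0:
        raise ValueError("CDS length is not a multiple of 3")
    _, raw = hamming_snps(cds_a, cds_b)
    records: list[SnpRecord] = []
    nonsyn = 0
    for snp in raw:
        ci = (snp.position - 1) // 3
        codon_a = cds_a[ci * 3 : ci * 3 + 3]
        codon_b = cds_b[ci * 3 : ci * 3 + 3]
        aa_a = str(Seq(codon_a).translate(table=1))
        aa_b = str(Seq(codon_b).translate(table=1))
        effect = "synonymous" if aa_a == aa_b else "nonsynonymous"
        if effect == "nonsynonymous":
            nonsyn += 1
        records.append(
            SnpRecord(
                position=snp.position,
                ref_base=snp.ref_base,
                alt_base=snp.alt_base,
                codon_index=ci + 1,
                ref_aa=aa_a,
                alt_aa=aa_b,
                effect=effect,
            )
        )
    summary = {
        "total": len(records),
        "nonsynonymous": nonsyn,
        "synonymous": len(records) - nonsyn,
    }
    return records, summary


def write_gff3(
    genome: Genome,
    path: str | Path,
    orfs: Iterable[OrfRecord] = (),
    motifs: Iterable[MotifHit] = (),
    palindromes: Iterable[PalindromeHit] = (),
    at_rich: Iterable[Span] = (),
    splices: Iterable[SpliceCandidate] = (),
) -> None:
    """Write annotation features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")

        def line(ftype, start, end, strand, attrs):
            fh.write(
                f"{genome.id}\tpvgc\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t"
                f"{attrs}\n"
            )

        for k, o in enumerate(orfs):
            line(
                "ORF",
                o.start,
                o.end,
                o.strand,
                f"ID=orf{k};start_codon={o.start_codon};"
                f"protein_length={o.protein_length_aa}",
            )
        for k, mh in enumerate(motifs):
            line(
                "motif",
                mh.start,
                mh.start + len(mh.motif) - 1,
                mh.strand,
                f"ID=motif{k};pattern={mh.motif}",
            )
        for k, p in enumerate(palindromes):
            line(
                "palindrome",
                p.start,
                p.end,
                "+",
                f"ID=pal{k};arm={p.arm};loop={p.loop}",
            )
        for k, sp in enumerate(at_rich):
            line("AT_rich", sp.start, sp.end, "+", f"ID=at{k}")
        for k, sc in enumerate(splices):
            line(
                "splice_candidate",
                sc.donor_pos,
                sc.acceptor_pos,
                sc.strand,
                f"ID=splice{k};intron_length={sc.intron_length}",
            )
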