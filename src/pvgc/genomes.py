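"""Genome containers, FASTA I/O and curation filters.

Input sets of small circular dsDNA virus genomes (polyomaviruses are
~5 kb) arrive as multi-FASTA with inconsistent case, occasional RNA-style
``U`` bases, IUPAC ambiguity codes and genomes deposited on either strand.
This module normalises them to a single internal alphabet, applies the
length-window curation filter, resolves ambiguous nucleotides against a
reference set via a centred context search, orients every genome onto a
common ("corresponding") strand and removes exact duplicates.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

IUPAC_CODES = set("ACGTRYSWKMBDHVN")
_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


class FastaParseError(ValueError):
    """Raised when a FASTA file is structurally malformed."""


@dataclass(frozen=True)
class Genome:
    """An identified, oriented nucleotide sequence.

    ``sequence`` is uppercase over the IUPAC nucleotide alphabet with U
    already mapped to T.  ``circular`` marks genomes whose coordinates may
    wrap (polyomavirus genomes are circular but deposited linearised).
    ``source_orientation`` records whether the stored sequence is the
    strand found in the input or its reverse complement.
    """

    id: str
    sequence: str
    circular: bool = False
    source_orientation: str = "forward"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = set(self.sequence) - IUPAC_CODES
        if bad:
            raise ValueError(
                f"genome {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "Genome":
        flipped = (
            "reverse_complemented"
            if self.source_orientation == "forward"
            else "forward"
        )
        return replace(
            self,
            sequence=self.sequence.translate(_COMPLEMENT)[::-1],
            source_orientation=flipped,
        )


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return sequence.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class CurationReport:
    """Per-genome record of what curation did.

    ``kept``, ``dropped_length`` and ``dropped_duplicates`` partition the
    input ids; ``replaced_ambiguities`` maps genome id to a list of
    ``(position_1based, original_code, replacement)`` tuples.
    """

    kept: list[str] = field(default_factory=list)
    dropped_length: dict[str, str] = field(default_factory=dict)
    replaced_ambiguities: dict[str, list[tuple[int, str, str]]] = field(
        default_factory=dict
    )
    dropped_duplicates: dict[str, str] = field(default_factory=dict)

    def merge(self, other: "CurationReport") -> "CurationReport":
        out = CurationReport(
            kept=list(other.kept) if other.kept else list(self.kept),
            dropped_length={**self.dropped_length, **other.dropped_length},
            replaced_ambiguities={
                **self.replaced_ambiguities,
                **other.replaced_ambiguities,
            },
            dropped_duplicates={
                **self.dropped_duplicates,
                **other.dropped_duplicates,
            },
        )
        return out

    def to_rows(self) -> list[tuple[str, str, str]]:
        rows: list[tuple[str, str, str]] = []
        for gid in self.kept:
            rows.append((gid, "kept", ""))
        for gid, why in self.dropped_length.items():
            rows.append((gid, "dropped_length", why))
        for gid, rep in self.dropped_duplicates.items():
            rows.append((gid, "dropped_duplicate", f"identical_to={rep}"))
        for gid, repl in self.replaced_ambiguities.items():
            detail = ";".join(f"{p}:{o}>{r}" for p, o, r in repl)
            rows.append((gid, "replaced_ambiguities", detail))
        return rows

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\taction\tdetail\n")
            for row in self.to_rows():
                fh.write("\t".join(row) + "\n")

    def write_json(self, path: str | Path) -> None:
        payload = {
            "kept": self.kept,
            "dropped_length": self.dropped_length,
            "replaced_ambiguities": {
                g: [list(t) for t in v]
                for g, v in self.replaced_ambiguities.items()
            },
            "dropped_duplicates": self.dropped_duplicates,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def read_fasta(path: str | Path, circular: bool = False) -> list[Genome]:
    """Read a multi-FASTA file into a list of :class:`Genome`.

    Sequences are uppercased and U is mapped to T.  Record order is
    preserved.  Duplicate headers and non-FASTA leading content raise
    :class:`FastaParseError`; an empty file yields an empty list with a
    warning.
    """
    path = Path(path)
    with open(path) as fh:
        lineno = 0
        for line in fh:
            lineno += 1
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected '>' header, "
                        f"got {line.strip()[:40]!r}"
                    )
                break
        else:
            warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
            return []

    genomes: list[Genome] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise FastaParseError(f"{path}: duplicate FASTA header {record.id!r}")
        seen.add(record.id)
        seq = str(record.seq).upper().replace("U", "T")
        genomes.append(Genome(id=record.id, sequence=seq, circular=circular))
    return genomes


def write_fasta(genomes: Iterable[Genome], path: str | Path, width: int = 60) -> None:
    """Write genomes as wrapped multi-FASTA (default 60-column lines)."""
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


def length_filter(
    genomes: Sequence[Genome],
    min_len: int = 3500,
    max_len: int = 8000,
) -> tuple[list[Genome], CurationReport]:
    """Keep genomes with min_len <= length <= max_len (inclusive bounds).

    The defaults discard partial and integrated genomes while keeping
    every complete polyomavirus genome; a sequence of exactly 3500 or
    8000 nt passes.
    """
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    report = CurationReport()
    kept: list[Genome] = []
    for g in genomes:
        L = len(g)
        if L < min_len:
            report.dropped_length[g.id] = f"too_short({L}<{min_len})"
        elif L > max_len:
            report.dropped_length[g.id] = f"too_long({L}>{max_len})"
        else:
            kept.append(g)
            report.kept.append(g.id)
    return kept, report


def _context_identity(window: str, candidate: str) -> int:
    # ambiguity codes (on either side) count as mismatches
    return sum(
        1
        for a, b in zip(window, candidate)
        if a == b and a in "ACGT"
    )


def resolve_ambiguous(
    genome: Genome,
    reference_set: Sequence[Genome],
    context: int = 41,
    min_identity_fraction: float = 30 / 41,
) -> tuple[Genome, list[tuple[int, str, str]], list[int]]:
    """Replace non-ACGT positions using the best-matching context window.

    For each ambiguous position a window of ``context`` nucleotides
    centred on it (shrunk at sequence ends) is slid over every reference
    genome; the replacement is the base at the aligned centre of the
    best-matching window.  Ties go to the most frequent base among tied
    best windows, remaining ties alphabetically.  Positions whose best
    window does not exceed ``min_identity_fraction`` of the window length
    in identities are left unchanged and returned as unresolved.

    Returns ``(genome, replacements, unresolved_positions)`` with
    1-based positions.
    """
    if context % 2 != 1:
        raise ValueError("context must be odd")
    if not reference_set:
        raise ValueError("reference_set must be non-empty")
    seq = list(genome.sequence)
    ambiguous = [i for i, b in enumerate(seq) if b not in "ACGT"]
    if not ambiguous:
        return genome, [], []
    if len(ambiguous) == len(seq):
        logger.warning("genome %s consists entirely of ambiguous bases", genome.id)
        return genome, [], [i + 1 for i in ambiguous]

    half = context // 2
    replacements: list[tuple[int, str, str]] = []
    unresolved: list[int] = []
    for pos in ambiguous:
        lo = max(0, pos - half)
        hi = min(len(seq), pos + half + 1)
        window = genome.sequence[lo:hi]
        center = pos - lo
        threshold = min_identity_fraction * len(window)
        best_score = -1
        best_bases: list[str] = []
        for ref in reference_set:
            rseq = ref.sequence
            for start in range(0, len(rseq) - len(window) + 1):
                cand = rseq[start : start + len(window)]
                score = _context_identity(window, cand)
                cb = cand[center]
                if cb not in "ACGT":
                    continue
                if score > best_score:
                    best_score = score
                    best_bases = [cb]
                elif score == best_score:
                    best_bases.append(cb)
        if best_score > threshold and best_bases:
            counts = {b: best_bases.count(b) for b in set(best_bases)}
            top = max(counts.values())
            choice = sorted(b for b, c in counts.items() if c == top)[0]
            replacements.append((pos + 1, seq[pos], choice))
            seq[pos] = choice
        else:
            unresolved.append(pos + 1)
    resolved = replace(genome, sequence="".join(seq))
    return resolved, replacements, unresolved


def build_corresponding_strands(
    genomes: Sequence[Genome],
    scorer: Callable[[Genome, Genome], int],
    reference_id: str | None = None,
) -> list[Genome]:
    """Orient all genomes onto the strand of a reference genome.

    The reference (first genome unless ``reference_id`` is given) stays
    forward; every other genome is kept on whichever strand scores higher
    against the reference under ``scorer`` (ties keep forward).  Running
    the function on its own output is a no-op.
    """
    if not genomes:
        raise ValueError("need at least one genome")
    if reference_id is None:
        ref = genomes[0]
    else:
        matches = [g for g in genomes if g.id == reference_id]
        if not matches:
            raise ValueError(f"reference id {reference_id!r} not in input")
        ref = matches[0]

    oriented: list[Genome] = []
    for g in genomes:
        if g.id == ref.id:
            oriented.append(g)
            continue
        fwd = scorer(ref, g)
        rc = g.reverse_complement()
        rev = scorer(ref, rc)
        if fwd == 0 and rev == 0:
            logger.warning(
                "genome %s scores 0 against reference on both strands", g.id
            )
        oriented.append(rc if rev > fwd else g)
    return oriented


def dedup_identical(
    genomes: Sequence[Genome],
) -> tuple[list[Genome], CurationReport]:
    """Remove exact sequence duplicates, keeping the first occurrence.

    Rotations of circular genomes are NOT collapsed: deposited genomes
    share linearisation conventions, and exact-identity removal is what
    the curation pipeline calls for.  Use :func:`canonical_rotation`
    first to opt into rotation-invariant deduplication.
    """
    report = CurationReport()
    seen: dict[str, str] = {}
    unique: list[Genome] = []
    for g in genomes:
        rep = seen.get(g.sequence)
        if rep is None:
            seen[g.sequence] = g.id
            unique.append(g)
            report.kept.append(g.id)
        else:
            report.dropped_duplicates[g.id] = rep
    return unique, report


def canonical_rotation(genome: Genome) -> Genome:
    """Rotate a circular genome to its lexicographically smallest rotation.

    Optional preprocessing that makes :func:`dedup_identical` collapse
    rotation-equivalent circular genomes.
    """
    s = genome.sequence
    doubled = s + s
    best = min(doubled[i : i + len(s)] for i in range(len(s)))
    return replace(genome, sequence=best)
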