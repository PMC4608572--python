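"""Synthetic genome families with controlled relatedness.

Every downstream operation — curation, w-mer counting, calibration,
clustering — is testable without downloads by generating families of
genomes that diverge from a common ancestor by a known per-site
substitution probability, optionally with indels and with some members
stored reverse-complemented (as deposited genomes often are).  Default
sizes mimic the study system: ~5-kb mildly AT-rich genomes, families at
a few percent divergence (distinct virus species sit near 81-84%
identity).  Every generator is reproducible from its seed and emits a
ground-truth log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genomes import Genome

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
#: mildly AT-rich, resembling polyomavirus genomes
DEFAULT_COMPOSITION = (0.30, 0.20, 0.20, 0.30)


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for one genome family derived from a random ancestor."""

    ancestor_length: int = 5000
    n_members: int = 4
    divergence: float = 0.05
    indel_rate: float = 0.0
    mean_indel_length: float = 3.0
    base_composition: tuple[float, float, float, float] = DEFAULT_COMPOSITION
    reverse_complement_fraction: float = 0.0

    def __post_init__(self) -> None:
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1) > 1e-9:
            raise ValueError("base_composition must be 4 probabilities summing to 1")
        if not (0 <= self.divergence < 0.75):
            raise ValueError("divergence must be in [0, 0.75)")
        if not (0 <= self.indel_rate < 1 and 0 <= self.reverse_complement_fraction <= 1):
            raise ValueError("rates must be valid probabilities")
        if self.ancestor_length < 1 or self.n_members < 1:
            raise ValueError("ancestor_length and n_members must be >= 1")


def random_genome(
    length: int,
    composition: Sequence[float] = DEFAULT_COMPOSITION,
    seed: int | None = None,
    genome_id: str = "random",
    circular: bool = False,
) -> Genome:
    """I.i.d. random genome with the given base composition."""
    if length < 1:
        raise ValueError("length must be >= 1")
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1) > 1e-9:
        raise ValueError("composition must be 4 probabilities summing to 1")
    rng = np.random.default_rng(seed)
    arr = rng.choice(BASES, size=length, p=comp)
    return Genome(
        id=genome_id, sequence=arr.tobytes().decode("ascii"), circular=circular
    )


@dataclass(frozen=True)
class MutationEvent:
    """One recorded mutation, in ancestor coordinates (1-based).

    kind "sub": ``detail`` is "old>new"; "ins": the inserted bases are
    placed after ``position``; "del": ``detail`` is the deleted length.
    """

    kind: str
    position: int
    detail: str


def mutate(
    genome: Genome,
    divergence: float,
    indel_rate: float = 0.0,
    seed: int | None = None,
    mean_indel_length: float = 3.0,
    mutant_id: str | None = None,
) -> tuple[Genome, list[MutationEvent]]:
    """Mutate a genome: per-site substitutions plus geometric indels.

    Each site substitutes to a uniformly chosen different base with
    probability ``divergence``; independently, an insertion or deletion
    (equal odds, geometric length with the given mean) starts at a site
    with probability ``indel_rate``.  The returned log supports exact
    replay via :func:`replay_mutations`.
    """
    if not (0 <= divergence < 1 and 0 <= indel_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    seq = genome.sequence
    L = len(seq)
    events: list[MutationEvent] = []

    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    sub_mask = rng.random(L) < divergence
    base_idx = {b: i for i, b in enumerate(BASES)}
    for pos in np.flatnonzero(sub_mask):
        old = arr[pos]
        if old not in base_idx:  # leave ambiguity codes untouched
            continue
        choices = BASES[BASES != old]
        new = rng.choice(choices)
        arr[pos] = new
        events.append(
            MutationEvent("sub", int(pos) + 1, f"{chr(old)}>{chr(new)}")
        )

    if indel_rate > 0:
        indel_mask = rng.random(L) < indel_rate
        for pos in np.flatnonzero(indel_mask):
            length = int(rng.geometric(1.0 / mean_indel_length))
            if rng.random() < 0.5:
                ins = rng.choice(BASES, size=length).tobytes().decode("ascii")
                events.append(MutationEvent("ins", int(pos) + 1, ins))
            else:
                events.append(MutationEvent("del", int(pos) + 1, str(length)))

    mutated = _apply_events(arr.tobytes().decode("ascii"), events)
    out = Genome(
        id=mutant_id or f"{genome.id}_mut",
        sequence=mutated,
        circular=genome.circular,
    )
    return out, events


def _apply_events(substituted: str, events: list[MutationEvent]) -> str:
    """Apply indel events (ancestor coordinates) to the substituted string."""
    dels: dict[int, int] = {}
    inss: dict[int, str] = {}
    for e in events:
        if e.kind == "del":
            dels[e.position] = int(e.detail)
        elif e.kind == "ins":
            inss[e.position] = e.detail
    out: list[str] = []
    skip = 0
    for i, ch in enumerate(substituted, start=1):
        if i in dels:
            skip = max(skip, dels[i])
        if skip > 0:
            skip -= 1
        else:
            out.append(ch)
        if i in inss:
            out.append(inss[i])
    return "".join(out)


def replay_mutations(ancestor: Genome, events: list[MutationEvent]) -> str:
    """Re-apply a mutation log to the ancestor; reproduces the mutant."""
    arr = list(ancestor.sequence)
    for e in events:
        if e.kind == "sub":
            old, new = e.detail.split(">")
            if arr[e.position - 1] != old:
                raise ValueError(
                    f"log inconsistent at {e.position}: expected {old}"
                )
            arr[e.position - 1] = new
    return _apply_events("".join(arr), events)


def simulate_families(
    specs: Sequence[FamilySpec],
    seed: int = 0,
    id_prefix: str = "fam",
) -> tuple[list[Genome], dict[str, str]]:
    """Generate labeled genome families from independent ancestors.

    Returns the genomes and a truth table mapping genome id to family
    label.  Members flagged by ``reverse_complement_fraction`` are
    stored on the opposite strand (their truth-table entry is the same;
    orientation correction is downstream's job).
    """
    if not specs:
        raise ValueError("need at least one family spec")
    rng = np.random.default_rng(seed)
    genomes: list[Genome] = []
    truth: dict[str, str] = {}
    for f, spec in enumerate(specs):
        label = f"{id_prefix}{f}"
        ancestor = random_genome(
            spec.ancestor_length,
            spec.base_composition,
            seed=int(rng.integers(0, 2**31 - 1)),
            genome_id=f"{label}_ancestor",
        )
        n_rc = int(round(spec.reverse_complement_fraction * spec.n_members))
        for m in range(spec.n_members):
            member, _ = mutate(
                ancestor,
                spec.divergence,
                spec.indel_rate,
                seed=int(rng.integers(0, 2**31 - 1)),
                mean_indel_length=spec.mean_indel_length,
                mutant_id=f"{label}_m{m}",
            )
            if m < n_rc:
                member = Genome(
                    id=member.id,
                    sequence=member.reverse_complement().sequence,
                    circular=member.circular,
                )
            genomes.append(member)
            truth[member.id] = label
    return genomes, truth
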