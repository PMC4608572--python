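"""Alignment-free w-mer pair-count similarity.

The similarity between two genomes is the count S of window pairs — one
window of length ``w`` from each genome, slid at step 1 — whose ungapped
identity exceeds a critical value ``n``.  With w = 50 and n = 30 (the
defaults) a qualifying pair needs at least 31 of 50 identical aligned
nucleotides, which captures conserved functional stretches (ATPase and
origin-binding domains, capsid cores) without any alignment.

Two counting modes exist because "pairs of similar windows" can be read
per-pair or per-query-window:

* ``all_pairs`` — S counts every qualifying ordered window pair (i, j);
  symmetric in the two genomes for fixed strands.
* ``best_pair`` — S counts query windows i whose best match in the other
  genome qualifies; bounded by the number of query windows.

The production algorithm walks the La x Lb comparison space one diagonal
at a time, updating window identity counts with a rolling sum, for
O(La * Lb) total work.  A naive window-by-window recount is retained as
an independent oracle for tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genomes import Genome

MODES = ("all_pairs", "best_pair")

# A/C/G/T -> 0..3; anything else gets a per-sequence sentinel so ambiguity
# codes never match anything, including themselves.
_LUT_BASE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT_BASE[_b] = _i


def encode_sequence(sequence: str, ambiguity_code: int = 4) -> np.ndarray:
    """Encode a nucleotide string as uint8 with A,C,G,T -> 0..3.

    Non-ACGT characters become ``ambiguity_code``; callers comparing two
    sequences must use distinct codes for each side so that ambiguous
    positions can never count as identities.
    """
    lut = _LUT_BASE.copy()
    lut[lut == 255] = ambiguity_code
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return lut[raw]


@dataclass(frozen=True)
class WmerParameters:
    """Knobs of the w-mer statistic.

    w: window length in nt; n: critical identity count (a pair qualifies
    when its identity is strictly greater than n); mode: counting mode;
    circular: let windows wrap the genome junction; strict: use > n
    (default, following "higher count than n"); set False for >= n.
    """

    w: int = 50
    n: int = 30
    mode: str = "all_pairs"
    circular: bool = False
    strict: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.n < self.w):
            raise ValueError(f"require 1 <= n < w, got w={self.w}, n={self.n}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    @property
    def threshold(self) -> int:
        """Minimum identity count a qualifying pair must reach."""
        return self.n + 1 if self.strict else self.n


@dataclass(frozen=True)
class SimilarityScore:
    """Outcome of one genome-pair comparison."""

    id_a: str
    id_b: str
    S: int
    orientation_b: str = "forward"
    params: WmerParameters = field(default_factory=WmerParameters)


def _prepare(genome: Genome, params: WmerParameters, code: int) -> np.ndarray:
    if len(genome) < params.w:
        raise ValueError(
            f"genome {genome.id!r} is shorter ({len(genome)} nt) than the "
            f"window length w={params.w}"
        )
    enc = encode_sequence(genome.sequence, ambiguity_code=code)
    if params.circular:
        enc = np.concatenate([enc, enc[: params.w - 1]])
    return enc


def _diagonal_scan(
    ea: np.ndarray,
    eb: np.ndarray,
    w: int,
    threshold: int,
    n_query_windows: int,
    need_positions: bool,
) -> tuple[int, np.ndarray | None]:
    """Count qualifying window pairs via per-diagonal rolling sums.

    Returns the all-pairs count and, when requested, a boolean array over
    query-window starts marking windows with at least one qualifying
    partner.  ``n_query_windows`` limits the marked starts (relevant in
    circular mode where the encoded array is extended past the junction).
    """
    La, Lb = len(ea), len(eb)
    total = 0
    hits = np.zeros(n_query_windows, dtype=bool) if need_positions else None
    for d in range(-(La - w), Lb - w + 1):
        i0 = max(0, -d)
        i1 = min(La, Lb - d)
        if i1 - i0 < w:
            continue
        m = (ea[i0:i1] == eb[i0 + d : i1 + d]).astype(np.int32)
        cs = np.cumsum(m)
        wsum = cs[w - 1 :].copy()
        wsum[1:] -= cs[:-w]
        q = wsum >= threshold
        if need_positions:
            stop = min(i0 + len(q), n_query_windows)
            if stop > i0:
                hits[i0:stop] |= q[: stop - i0]
            # pairs are still counted over all window starts below
        total += int(q.sum())
    return total, hits


def _n_windows(genome: Genome, params: WmerParameters) -> int:
    return len(genome) if params.circular else len(genome) - params.w + 1


def count_wmer_pairs(
    a: Genome, b: Genome, params: WmerParameters | None = None
) -> SimilarityScore:
    """Count qualifying w-mer pairs between two genomes (fixed strands).

    In ``all_pairs`` mode S is the number of window pairs whose identity
    exceeds the critical value; in ``best_pair`` mode S is the number of
    windows of ``a`` with at least one qualifying partner in ``b``.
    """
    params = params or WmerParameters()
    ea = _prepare(a, params, code=4)
    eb = _prepare(b, params, code=5)
    need_positions = params.mode == "best_pair"
    total, hits = _diagonal_scan(
        ea, eb, params.w, params.threshold, _n_windows(a, params), need_positions
    )
    S = int(hits.sum()) if need_positions else total
    return SimilarityScore(id_a=a.id, id_b=b.id, S=S, params=params)


def qualifying_window_starts(
    a: Genome, b: Genome, params: WmerParameters | None = None
) -> np.ndarray:
    """Boolean array over windows of ``a``: does window i have a
    qualifying partner anywhere in ``b``?"""
    params = params or WmerParameters()
    ea = _prepare(a, params, code=4)
    eb = _prepare(b, params, code=5)
    _, hits = _diagonal_scan(
        ea, eb, params.w, params.threshold, _n_windows(a, params), True
    )
    return hits


def count_wmer_pairs_naive(
    a: Genome, b: Genome, params: WmerParameters | None = None
) -> int:
    """Independent recount: compare every window of ``a`` against every
    window of ``b`` directly.  O(La * Lb * w); for testing the diagonal
    algorithm, not for production use."""
    params = params or WmerParameters()
    ea = _prepare(a, params, code=4)
    eb = _prepare(b, params, code=5)
    w = params.w
    wb = np.lib.stride_tricks.sliding_window_view(eb, w)
    count = 0
    best_count = 0
    for i in range(len(ea) - w + 1):
        ids = (wb == ea[i : i + w]).sum(axis=1)
        q = ids >= params.threshold
        count += int(q.sum())
        if q.any():
            best_count += 1
    return best_count if params.mode == "best_pair" else count


def best_orientation_score(
    a: Genome, b: Genome, params: WmerParameters | None = None
) -> SimilarityScore:
    """S at the better of b's two strands; ties keep forward."""
    params = params or WmerParameters()
    fwd = count_wmer_pairs(a, b, params)
    rev = count_wmer_pairs(a, b.reverse_complement(), params)
    if rev.S > fwd.S:
        return SimilarityScore(
            id_a=a.id,
            id_b=b.id,
            S=rev.S,
            orientation_b="reverse_complemented",
            params=params,
        )
    return fwd


@dataclass(frozen=True)
class ConservationProfile:
    """Per-window conservation of a query against a genome database.

    ``percent_similar[k]`` is the percentage of database genomes holding
    at least one qualifying w-mer partner for the query window starting
    at ``positions[k]`` (1-based).
    """

    query_id: str
    positions: np.ndarray
    percent_similar: np.ndarray
    params: WmerParameters
    n_database: int = 0


def conservation_profile(
    query: Genome,
    database: list[Genome],
    params: WmerParameters | None = None,
    both_strands: bool = True,
) -> ConservationProfile:
    """Sliding-window conservation profile of ``query`` vs a database.

    For every query window, the fraction of database genomes (query
    itself excluded by id) containing a qualifying partner window on
    either strand, as a percentage.
    """
    params = params or WmerParameters()
    db = [g for g in database if g.id != query.id]
    if not db:
        raise ValueError("database is empty (after excluding the query)")
    nw = _n_windows(query, params)
    counts = np.zeros(nw, dtype=np.int64)
    for g in db:
        hit = qualifying_window_starts(query, g, params)
        if both_strands:
            hit |= qualifying_window_starts(query, g.reverse_complement(), params)
        counts += hit
    percent = 100.0 * counts / len(db)
    return ConservationProfile(
        query_id=query.id,
        positions=np.arange(1, nw + 1),
        percent_similar=percent,
        params=params,
        n_database=len(db),
    )
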