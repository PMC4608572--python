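"""All-vs-all p-matrix, cutoff clustering, CLANS export and layout.

Genome relatedness is summarised as a symmetric matrix of log10
p-values; clusters at a cutoff are the connected components of the graph
whose edges join pairs with log10 p at or below the cutoff (smaller p =
stronger link).  Sweeping the cutoff from loose (p = 1e-10) to strict
(p = 1e-86) reveals nested groupings — genera split into lineages — and
each pair's separation level, the loosest cutoff at which the two
genomes first fall into different components.

Cluster membership is computed with exact connected components rather
than a stochastic force-directed simulation: the membership is what the
analysis reports, and components are deterministic and testable.  A
small force-directed layout is provided for presentation only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .genomes import Genome
from .significance import DEFAULT_MODEL, GumbelModel, evd_pvalue
from .wmer import WmerParameters, best_orientation_score

#: log10 p below this is clamped — far beyond any cutoff in use.
LOG10P_CLAMP = -10000.0


@dataclass
class PMatrix:
    """Symmetric matrix of log10 p-values over an ordered genome set.

    The diagonal is -inf (self-similarity, excluded from clustering
    edges); off-diagonal entries are finite or the clamp sentinel.
    """

    ids: list[str]
    log10p: np.ndarray
    orientations: dict[tuple[str, str], str] = field(default_factory=dict)
    params: WmerParameters = field(default_factory=WmerParameters)
    model: GumbelModel = DEFAULT_MODEL

    def __post_init__(self) -> None:
        N = len(self.ids)
        if self.log10p.shape != (N, N):
            raise ValueError("log10p shape must match ids")
        off = ~np.eye(N, dtype=bool)
        if not np.allclose(self.log10p.T[off], self.log10p[off]):
            raise ValueError("log10p must be symmetric")

    def entry(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.log10p[i, j])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, gid in enumerate(self.ids):
                row = "\t".join(f"{v:.6g}" for v in self.log10p[i])
                fh.write(f"{gid}\t{row}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, **kwargs) -> "PMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                rows.append([float(v) for v in line.rstrip("\n").split("\t")[1:]])
        return cls(ids=header, log10p=np.array(rows), **kwargs)


def pairwise_pmatrix(
    genomes: Sequence[Genome],
    params: WmerParameters | None = None,
    model: GumbelModel | None = None,
    both_strands: bool = True,
) -> PMatrix:
    """Compute the all-vs-all log10 p-value matrix.

    For each unordered pair, S is taken at the better strand of the
    second genome (unless ``both_strands`` is False, for inputs already
    strand-corresponded) and converted to log10 p under ``model``.
    """
    params = params or WmerParameters()
    model = model or DEFAULT_MODEL
    genomes = list(genomes)
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    too_short = [g.id for g in genomes if len(g) < params.w]
    if too_short:
        raise ValueError(f"genomes shorter than w={params.w}: {too_short}")
    N = len(genomes)
    mat = np.full((N, N), -np.inf)
    orientations: dict[tuple[str, str], str] = {}
    for i, j in itertools.combinations(range(N), 2):
        if both_strands:
            score = best_orientation_score(genomes[i], genomes[j], params)
        else:
            from .wmer import count_wmer_pairs

            score = count_wmer_pairs(genomes[i], genomes[j], params)
        _, log10p = evd_pvalue(score.S, model)
        log10p = max(log10p, LOG10P_CLAMP)
        mat[i, j] = mat[j, i] = log10p
        orientations[(genomes[i].id, genomes[j].id)] = score.orientation_b
    return PMatrix(
        ids=[g.id for g in genomes],
        log10p=mat,
        orientations=orientations,
        params=params,
        model=model,
    )


@dataclass
class ClusterSet:
    """Partition of genome ids at one p cutoff.

    ``components`` maps a deterministic label (the lexicographically
    smallest member id) to the sorted member list.
    """

    cutoff_log10p: float
    components: dict[str, list[str]]
    singletons: list[str]
    edge_count: int

    @property
    def n_components(self) -> int:
        return len(self.components)

    def component_of(self, genome_id: str) -> str:
        for label, members in self.components.items():
            if genome_id in members:
                return label
        raise KeyError(genome_id)


def _threshold_graph(matrix: PMatrix, cutoff_log10p: float) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(matrix.ids)
    N = len(matrix.ids)
    for i in range(N):
        for j in range(i + 1, N):
            if matrix.log10p[i, j] <= cutoff_log10p:
                G.add_edge(matrix.ids[i], matrix.ids[j])
    return G


def threshold_clusters(matrix: PMatrix, cutoff_log10p: float) -> ClusterSet:
    """Connected components of the graph of pairs with log10 p <= cutoff."""
    if not np.isfinite(cutoff_log10p):
        raise ValueError("cutoff must be finite")
    G = _threshold_graph(matrix, cutoff_log10p)
    components: dict[str, list[str]] = {}
    singletons: list[str] = []
    for comp in nx.connected_components(G):
        members = sorted(comp)
        components[members[0]] = members
        if len(members) == 1:
            singletons.append(members[0])
    components = dict(sorted(components.items()))
    return ClusterSet(
        cutoff_log10p=cutoff_log10p,
        components=components,
        singletons=sorted(singletons),
        edge_count=G.number_of_edges(),
    )


@dataclass
class SweepResult:
    """Cluster sets along a descending cutoff sweep plus, per genome
    pair, the loosest cutoff at which the pair first disconnects
    (None when the pair stays connected at every swept level)."""

    cluster_sets: list[ClusterSet]
    separation_level: dict[tuple[str, str], float | None]


def cutoff_sweep(matrix: PMatrix, cutoffs: Sequence[float]) -> SweepResult:
    """Cluster at each cutoff (loosest first) and track separations.

    ``cutoffs`` must be sorted descending in log10 p (loosest level
    first); components can then only refine along the sweep.
    """
    cutoffs = list(cutoffs)
    if cutoffs != sorted(cutoffs, reverse=True):
        raise ValueError("cutoffs must be sorted descending (loosest first)")
    sets: list[ClusterSet] = []
    separation: dict[tuple[str, str], float | None] = {
        tuple(sorted(p)): None
        for p in itertools.combinations(matrix.ids, 2)
    }
    for cutoff in cutoffs:
        cs = threshold_clusters(matrix, cutoff)
        sets.append(cs)
        label_of = {
            gid: label for label, members in cs.components.items() for gid in members
        }
        for pair, level in separation.items():
            if level is None and label_of[pair[0]] != label_of[pair[1]]:
                separation[pair] = cutoff
    return SweepResult(cluster_sets=sets, separation_level=separation)


def _p_string(log10p: float) -> str:
    """Linear-scale p with explicit exponent, safe below float underflow."""
    if log10p == -np.inf or log10p <= LOG10P_CLAMP:
        log10p = LOG10P_CLAMP
    exponent = int(np.floor(log10p))
    mantissa = 10.0 ** (log10p - exponent)
    return f"{mantissa:.6g}e{exponent:+03d}"


def clans_export(
    matrix: PMatrix,
    genomes: Sequence[Genome],
    path: str | Path,
    edge_list_path: str | Path | None = None,
) -> None:
    """Write a CLANS-format file and a plain edge-list TSV.

    CLANS layout: a ``sequences=N`` header, a ``<seq>`` block of FASTA
    entries in matrix order, and an ``<hsp>`` block of ``i j:p`` lines
    (0-based indices, linear-scale p); pairs with p = 1 are omitted.
    """
    by_id = {g.id: g for g in genomes}
    missing = [gid for gid in matrix.ids if gid not in by_id]
    if missing:
        raise ValueError(f"genomes missing for matrix ids: {missing}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"sequences={len(matrix.ids)}\n")
        fh.write("<seq>\n")
        for gid in matrix.ids:
            fh.write(f">{gid}\n{by_id[gid].sequence}\n")
        fh.write("</seq>\n<hsp>\n")
        N = len(matrix.ids)
        for i in range(N):
            for j in range(i + 1, N):
                lp = matrix.log10p[i, j]
                if lp >= 0:
                    continue
                fh.write(f"{i} {j}:{_p_string(lp)}\n")
        fh.write("</hsp>\n")
    if edge_list_path is None:
        edge_list_path = path.with_suffix(".edges.tsv")
    with open(edge_list_path, "w") as fh:
        fh.write("id_a\tid_b\tlog10p\n")
        N = len(matrix.ids)
        for i in range(N):
            for j in range(i + 1, N):
                fh.write(
                    f"{matrix.ids[i]}\t{matrix.ids[j]}\t"
                    f"{matrix.log10p[i, j]:.6g}\n"
                )


def read_edge_list(path: str | Path) -> dict[tuple[str, str], float]:
    """Parse the edge-list TSV written by :func:`clans_export`."""
    out: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            a, b, v = line.rstrip("\n").split("\t")
            out[(a, b)] = float(v)
    return out


@dataclass
class Layout2D:
    """2D coordinates from the force-directed layout (presentation only)."""

    ids: list[str]
    coordinates: np.ndarray
    iterations: int
    seed: int


def force_layout(
    matrix: PMatrix,
    cutoff_log10p: float = -10.0,
    iterations: int = 200,
    seed: int = 0,
    strength_cap: float = 200.0,
    step: float = 0.05,
) -> Layout2D:
    """Simple attraction/repulsion embedding of the p-matrix.

    Pairs with log10 p at or below the cutoff attract with strength
    min(-log10 p, cap)/cap; all pairs repel inversely with distance.
    Deterministic for a fixed seed; coordinates have no meaning beyond
    relative proximity.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    N = len(matrix.ids)
    rng = np.random.default_rng(seed)
    if N == 1:
        return Layout2D(
            ids=list(matrix.ids),
            coordinates=np.zeros((1, 2)),
            iterations=iterations,
            seed=seed,
        )
    pos = rng.standard_normal((N, 2))
    strength = np.clip(-matrix.log10p, 0.0, strength_cap) / strength_cap
    linked = (matrix.log10p <= cutoff_log10p) & ~np.eye(N, dtype=bool)
    attract = np.where(linked, strength, 0.0)
    for _ in range(iterations):
        delta = pos[None, :, :] - pos[:, None, :]  # delta[i,j] = pos[j]-pos[i]
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, 1.0)
        unit = delta / dist[..., None]
        pull = (attract * dist)[..., None] * unit
        push = (1.0 / dist)[..., None] * unit
        np.fill_diagonal(push[..., 0], 0.0)
        np.fill_diagonal(push[..., 1], 0.0)
        np.fill_diagonal(pull[..., 0], 0.0)
        np.fill_diagonal(pull[..., 1], 0.0)
        force = pull.sum(axis=1) - 0.1 * push.sum(axis=1)
        pos = pos + step * force
    return Layout2D(
        ids=list(matrix.ids), coordinates=pos, iterations=iterations, seed=seed
    )
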