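"""Extreme-value significance for w-mer pair counts.

Under the null of unrelated genomes, the count S of qualifying w-mer
pairs behaves like an extreme-value (Gumbel) statistic:

    p(S >= x) = 1 - exp(-e^(-lambda * (x - u)))

with characteristic (location) value ``u`` and scale ``lambda``.  The
reference constants u = 18, lambda = 0.1 were fitted from randomized
~5-kb genomes at w = 50, n = 30 and are valid only for that setting; any
other parameters call for explicit calibration from shuffled genomes.

p-values are carried in log10 space throughout: meaningful cutoffs reach
1e-86 and beyond, far below double-precision underflow for the survival
function evaluated naively.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genomes import Genome
from .wmer import WmerParameters, count_wmer_pairs

_LN10 = math.log(10.0)
EULER_GAMMA = float(np.euler_gamma)


@dataclass(frozen=True)
class GumbelModel:
    """Fitted (or reference) extreme-value significance model.

    ``u``: location; ``lam``: scale parameter lambda (> 0); ``w``, ``n``,
    ``mode``: the w-mer setting the model is valid for; ``provenance``:
    "paper_default" for the reference constants, "calibrated" for a model
    fitted by :func:`calibrate_evd`.
    """

    u: float
    lam: float
    w: int = 50
    n: int = 30
    mode: str = "all_pairs"
    provenance: str = "calibrated"
    calibration_seed: int | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.u) and math.isfinite(self.lam)):
            raise ValueError("u and lam must be finite")
        if self.lam <= 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")

    def matches(self, params: WmerParameters) -> bool:
        return (self.w, self.n, self.mode) == (params.w, params.n, params.mode)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "u": self.u,
            "lam": self.lam,
            "w": self.w,
            "n": self.n,
            "mode": self.mode,
            "provenance": self.provenance,
            "calibration_seed": self.calibration_seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GumbelModel":
        d = json.loads(Path(path).read_text())
        return cls(**d)


#: Reference model for w = 50, n = 30 on ~5-kb genomes.
DEFAULT_MODEL = GumbelModel(u=18.0, lam=0.1, provenance="paper_default")


def evd_pvalue(x: float, model: GumbelModel = DEFAULT_MODEL) -> tuple[float, float]:
    """p(S >= x) under the extreme-value model, with its log10.

    Returns ``(p, log10_p)``.  The log10 value is computed in the log
    domain so that scores far into the tail (p below 1e-300) keep full
    relative precision: there, log(p) = -lam (x - u) + log1p(-t/2 + t^2/6)
    with t = e^(-lam (x - u)).
    """
    if not math.isfinite(x):
        raise ValueError(f"score must be finite, got {x!r}")
    log_t = -model.lam * (x - model.u)  # natural log of the inner exponential
    if log_t > 700.0:  # e^t would overflow; p is 1 to double precision
        return 1.0 - 5e-324, math.log10(1.0 - 5e-324)
    t = math.exp(log_t)
    p = -math.expm1(-t)
    if t < 1e-4:
        # p = t (1 - t/2 + t^2/6 - ...); log-domain expansion, exact to
        # double precision for t this small
        log10_p = (log_t + math.log1p(-t / 2.0 + t * t / 6.0)) / _LN10
    else:
        log10_p = math.log10(p)
    return p, log10_p


def evd_log10_pvalues(
    scores: np.ndarray, model: GumbelModel = DEFAULT_MODEL
) -> np.ndarray:
    """Vectorised log10 p over an array of scores."""
    return np.array([evd_pvalue(float(s), model)[1] for s in np.ravel(scores)]).reshape(
        np.shape(scores)
    )


def shuffle_genome(genome: Genome, seed: int) -> Genome:
    """Uniform random permutation of the sequence's positions.

    Preserves mononucleotide composition exactly; deterministic per seed.
    A dinucleotide-preserving shuffle is deliberately not the default:
    the null model is positionally randomized genomes.
    """
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8)
    shuffled = rng.permutation(arr)
    return replace(genome, sequence=shuffled.tobytes().decode("ascii"))


def fit_gumbel(
    scores: Sequence[float], method: str = "moments"
) -> tuple[float, float]:
    """Fit Gumbel location/scale, returning ``(u, lam)``.

    moments: lam = pi / sqrt(6 * var) (sample variance, n-1 denominator)
    and u = mean - gamma / lam with gamma the Euler-Mascheroni constant.
    mle: numerical maximum likelihood via scipy's right-skewed Gumbel.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two scores to fit")
    var = float(np.var(arr, ddof=1))
    if var <= 0:
        raise ValueError(
            "sampled scores have zero variance; use more or longer genomes"
        )
    if method == "moments":
        lam = math.pi / math.sqrt(6.0 * var)
        u = float(np.mean(arr)) - EULER_GAMMA / lam
    elif method == "mle":
        loc, scale = stats.gumbel_r.fit(arr)
        u, lam = float(loc), 1.0 / float(scale)
    else:
        raise ValueError(f"unknown fit method {method!r}")
    return u, lam


@dataclass
class CalibrationResult:
    """Model fitted from randomized-genome comparisons, with diagnostics."""

    model: GumbelModel
    sample_scores: np.ndarray
    fit_method: str
    diagnostics: dict = field(default_factory=dict)


def _sample_pairs(
    n_genomes: int, plan: str | tuple[str, int], rng: np.random.Generator
) -> list[tuple[int, int]]:
    all_pairs = list(itertools.combinations(range(n_genomes), 2))
    if plan == "all":
        return all_pairs
    if isinstance(plan, tuple) and plan[0] == "random":
        k = min(plan[1], len(all_pairs))
        idx = rng.choice(len(all_pairs), size=k, replace=False)
        return [all_pairs[i] for i in idx]
    raise ValueError(f"unknown sampling plan {plan!r}")


def calibrate_evd(
    genomes: Sequence[Genome],
    params: WmerParameters | None = None,
    pairs: str | tuple[str, int] = "all",
    seed: int = 0,
    fit_method: str = "moments",
) -> CalibrationResult:
    """Calibrate (u, lambda) from comparisons of shuffled genomes.

    Each genome is shuffled once (seed-derived), S is computed for the
    sampled randomized pairs under ``params``, and a Gumbel model is
    fitted to the scores.  The sampling plan is explicit: "all" pairs or
    ("random", K) unordered pairs.
    """
    params = params or WmerParameters()
    if len(genomes) < 2:
        raise ValueError("need at least two genomes to calibrate")
    rng = np.random.default_rng(seed)
    shuffled = [
        shuffle_genome(g, seed=int(rng.integers(0, 2**31 - 1))) for g in genomes
    ]
    pair_idx = _sample_pairs(len(genomes), pairs, rng)
    scores = np.array(
        [count_wmer_pairs(shuffled[i], shuffled[j], params).S for i, j in pair_idx],
        dtype=float,
    )
    u, lam = fit_gumbel(scores, method=fit_method)
    model = GumbelModel(
        u=u,
        lam=lam,
        w=params.w,
        n=params.n,
        mode=params.mode,
        provenance="calibrated",
        calibration_seed=seed,
    )
    diagnostics = {
        "n_pairs": len(pair_idx),
        "mean": float(np.mean(scores)),
        "variance": float(np.var(scores, ddof=1)),
        "min": float(scores.min()),
        "max": float(scores.max()),
    }
    return CalibrationResult(
        model=model,
        sample_scores=scores,
        fit_method=fit_method,
        diagnostics=diagnostics,
    )


def select_critical_value(
    genomes: Sequence[Genome],
    w: int = 50,
    candidate_ns: Iterable[int] = range(20, 45, 2),
    seed: int = 0,
    background_fraction: float = 0.15,
    mode: str = "all_pairs",
) -> tuple[int | None, "pd.DataFrame"]:
    """Choose the critical value n from real vs randomized backgrounds.

    For each candidate n the mean S across shuffled-genome pairs
    (background) and the minimum S across real-genome pairs are
    tabulated; the recommendation is the smallest n whose background is
    at most ``background_fraction`` of the minimum real similarity
    (the 10-15% rule).  Returns ``(recommended_n_or_None, table)`` so
    callers can apply their own rule to the full table.
    """
    import pandas as pd

    genomes = list(genomes)
    if len(genomes) < 2:
        raise ValueError("need at least two real genomes")
    rng = np.random.default_rng(seed)
    shuffled = [
        shuffle_genome(g, seed=int(rng.integers(0, 2**31 - 1))) for g in genomes
    ]
    pair_idx = list(itertools.combinations(range(len(genomes)), 2))
    rows = []
    for n in candidate_ns:
        if not (0 < n < w):
            raise ValueError(f"candidate n={n} outside (0, w={w})")
        params = WmerParameters(w=w, n=n, mode=mode)
        bg = np.mean(
            [count_wmer_pairs(shuffled[i], shuffled[j], params).S for i, j in pair_idx]
        )
        real_min = min(
            count_wmer_pairs(genomes[i], genomes[j], params).S for i, j in pair_idx
        )
        ratio = float(bg / real_min) if real_min > 0 else math.inf
        rows.append(
            {
                "n": n,
                "background_mean_S": float(bg),
                "real_min_S": int(real_min),
                "background_fraction": ratio,
                "passes": ratio <= background_fraction,
            }
        )
    table = pd.DataFrame(rows)
    passing = table[table["passes"]]
    if passing.empty:
        import warnings

        warnings.warn(
            "no candidate n meets the background rule; returning table only",
            stacklevel=2,
        )
        return None, table
    return int(passing["n"].iloc[0]), table
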