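"""Infection-sign tallies combining PCR and serology screening.

A trapped animal shows a sign of infection when viral DNA is detected by
PCR in either screened tissue (e.g. chest-cavity fluid or kidney) or
when VP1-specific antibodies are found by ELISA.  Animals positive in
both tissues, or seropositive and PCR-positive, are counted once — the
union, not the sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal


@dataclass(frozen=True)
class ScreeningCounts:
    """Screening outcome counts for one host species.

    pcr_pos_tissue1 / pcr_pos_tissue2: animals PCR-positive in each
    tissue; pcr_pos_both_tissues: positive in both; sero_pos:
    antibody-positive; sero_pos_and_pcr_pos: antibody-positive animals
    also PCR-positive in some tissue; total_animals: screened animals.
    """

    pcr_pos_tissue1: int
    pcr_pos_tissue2: int
    pcr_pos_both_tissues: int
    sero_pos: int
    sero_pos_and_pcr_pos: int
    total_animals: int

    def __post_init__(self) -> None:
        for name in (
            "pcr_pos_tissue1",
            "pcr_pos_tissue2",
            "pcr_pos_both_tissues",
            "sero_pos",
            "sero_pos_and_pcr_pos",
            "total_animals",
        ):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
            if name != "total_animals" and v > self.total_animals:
                raise ValueError(f"{name} exceeds total_animals")
        if self.pcr_pos_both_tissues > min(
            self.pcr_pos_tissue1, self.pcr_pos_tissue2
        ):
            raise ValueError(
                "pcr_pos_both_tissues exceeds a single-tissue positive count"
            )
        if self.sero_pos_and_pcr_pos > self.sero_pos:
            raise ValueError("sero_pos_and_pcr_pos exceeds sero_pos")


def infection_sign_union(c: ScreeningCounts) -> int:
    """Animals with any sign of infection (PCR in either tissue, or
    serology), each counted once."""
    pcr_any = c.pcr_pos_tissue1 + c.pcr_pos_tissue2 - c.pcr_pos_both_tissues
    union = pcr_any + c.sero_pos - c.sero_pos_and_pcr_pos
    if union > c.total_animals:
        raise ValueError(
            f"union {union} exceeds total_animals {c.total_animals}; "
            "check overlap counts"
        )
    return union


def prevalence_percent(positive: int, total: int) -> float:
    """100 * positive / total, rounded half-away-from-zero to 1 decimal."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not (0 <= positive <= total):
        raise ValueError("positive must be in [0, total]")
    pct = Decimal(100) * Decimal(positive) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
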