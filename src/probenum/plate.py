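"""Plate-count quantification: countable window and CFU per gram.

Pour plates across a serial dilution yield colony counts; only plates in
the countable window (25–250 colonies, inclusive) are statistically
reliable.  CFU/g is the weighted mean across countable plates,
Σ colonies / Σ (plated volume × dilution level), scaled by the
suspension-to-gram factor — the ISO 7218-style pooled estimate rather
than the lowest countable dilution alone.  Per-plate values are retained
because replicate scatter feeds the coefficient-of-variation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .config import DilutionChain

__all__ = ["PlateSeriesRecord", "PlateEstimate", "select_countable", "cfu_per_g",
           "DEFAULT_COUNTABLE_WINDOW"]

DEFAULT_COUNTABLE_WINDOW = (25, 250)


@dataclass(frozen=True)
class PlateSeriesRecord:
    """Colony counts for one batch at one dilution level."""

    batch_id: str
    dilution_level: float  # fraction of the suspension, e.g. 1e-6
    plated_volume: float   # mL of diluted suspension per plate
    colony_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0 < self.dilution_level <= 1:
            raise ValueError("dilution_level must lie in (0, 1]")
        if self.plated_volume <= 0:
            raise ValueError("plated_volume must be positive")
        if any(c < 0 for c in self.colony_counts):
            raise ValueError("colony counts must be non-negative")
        object.__setattr__(self, "colony_counts", tuple(int(c) for c in self.colony_counts))


@dataclass(frozen=True)
class PlateEstimate:
    """Batch-level CFU/g with the per-plate replicate values retained."""

    batch_id: str
    count_per_g: float
    per_plate_cfu_per_g: tuple[float, ...]
    n_plates: int
    diagnostic: str = ""

    @property
    def missing(self) -> bool:
        return self.n_plates == 0


def select_countable(
    series: Sequence[PlateSeriesRecord],
    window: tuple[int, int] = DEFAULT_COUNTABLE_WINDOW,
) -> tuple[list[PlateSeriesRecord], str]:
    """Keep plates whose colony count falls inside the window (inclusive).

    Returns the filtered series plus a diagnostic string; an empty result
    is a flagged outcome ("too numerous to count" when every plate is
    overgrown, "too few to count" when every plate is below the window),
    never an exception.
    """
    if not series:
        raise ValueError("select_countable requires a non-empty series")
    low, high = window
    kept: list[PlateSeriesRecord] = []
    all_counts: list[int] = []
    for rec in series:
        all_counts.extend(rec.colony_counts)
        counts = tuple(c for c in rec.colony_counts if low <= c <= high)
        if counts:
            kept.append(PlateSeriesRecord(rec.batch_id, rec.dilution_level,
                                          rec.plated_volume, counts))
    if kept:
        return kept, ""
    if all(c > high for c in all_counts):
        return [], "too numerous to count"
    if all(c < low for c in all_counts):
        return [], "too few to count"
    return [], "no plate in countable window"


def cfu_per_g(
    countable: Sequence[PlateSeriesRecord],
    chain: DilutionChain = DilutionChain(),
) -> PlateEstimate:
    """Weighted-mean CFU/g across countable plates.

    Each plate contributes ``count / (plated_volume × dilution_level) ×
    ml_per_g``; the batch point estimate pools all countable plates:
    ``Σ counts / Σ (plated_volume × dilution_level) × ml_per_g``.
    """
    if not countable:
        raise ValueError("cfu_per_g requires at least one countable plate; "
                         "an empty selection is a flagged missing value upstream")
    batch_id = countable[0].batch_id
    total_colonies = 0.0
    total_vd = 0.0
    per_plate: list[float] = []
    for rec in countable:
        if rec.batch_id != batch_id:
            raise ValueError("all records must belong to the same batch")
        for c in rec.colony_counts:
            per_plate.append(chain.colonies_to_cfu_per_g(c, rec.plated_volume, rec.dilution_level))
            total_colonies += c
            total_vd += rec.plated_volume * rec.dilution_level
    estimate = total_colonies / total_vd * chain.ml_per_g
    return PlateEstimate(
        batch_id=batch_id,
        count_per_g=estimate,
        per_plate_cfu_per_g=tuple(per_plate),
        n_plates=len(per_plate),
    )
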