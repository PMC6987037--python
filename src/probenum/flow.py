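"""Flow-cytometry quantification: gated events to cells per gram.

Membrane-integrity staining (Syto24 / propidium iodide) splits cytometry
events into live, dead and total gates.  The instrument-level machinery is
abstracted to an analysed-volume factor: the input is gated event counts
per analysed volume, and cells/g is events / analysed volume × dilution
chain.  The 1:10 PBS dilution of the staining protocol folds into the
record's dilution factor.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import UL_PER_ML, DilutionChain

__all__ = ["FlowRecord", "cells_per_g", "GATES"]

GATES = ("live", "dead", "total")
GATE_TO_METHOD = {"live": "Flow.live", "dead": "Flow.dead", "total": "Flow.total"}


@dataclass(frozen=True)
class FlowRecord:
    """Gated event counts for one replicate acquisition."""

    batch_id: str
    replicate: int
    live_events: float
    dead_events: float
    total_events: float
    analyzed_volume: float  # µL
    dilution_factor: float  # fold, >= 1

    def __post_init__(self) -> None:
        if self.analyzed_volume <= 0:
            raise ValueError("analyzed_volume must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if min(self.live_events, self.dead_events, self.total_events) < 0:
            raise ValueError("event counts must be non-negative")
        # gating additivity, within rounding of the gate boundaries
        if abs(self.total_events - (self.live_events + self.dead_events)) > 1.5:
            raise ValueError("total_events must equal live_events + dead_events")


def cells_per_g(rec: FlowRecord, gate: str, chain: DilutionChain = DilutionChain()) -> float:
    """Convert one gate's events to cells per gram of powder.

    ``events / analyzed_volume`` is the concentration in the analysed
    (diluted) suspension; multiplying by the fold dilution and the
    suspension-to-gram factor recovers cells/g.  Additivity holds exactly:
    the total gate equals live + dead.
    """
    if gate not in GATES:
        raise ValueError(f"gate must be one of {GATES}")
    events = {"live": rec.live_events, "dead": rec.dead_events, "total": rec.total_events}[gate]
    per_ul = events / rec.analyzed_volume
    return per_ul * UL_PER_ML * rec.dilution_factor * chain.ml_per_g
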