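"""Shared unit conversions and configuration primitives.

All three enumeration methods start from the same physical chain: a
freeze-dried powder is rehydrated (``ml_per_g`` millilitres of suspension
per gram of powder, default 1:10 w/v) and then serially diluted before a
small volume enters the measuring instrument.  Every conversion between an
instrument-level concentration (copies per microlitre of reaction, colonies
per plate, events per analysed volume) and the reported cells-per-gram
value goes through :class:`DilutionChain` so that the simulator and the
quantifiers are exact inverses of each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json

__all__ = ["DilutionChain", "config_hash"]

#: microlitres per millilitre
UL_PER_ML = 1000.0


@dataclass(frozen=True)
class DilutionChain:
    """Conversion between instrument concentrations and counts per gram.

    Parameters
    ----------
    ml_per_g:
        Millilitres of rehydrated suspension per gram of powder.  Default
        10.0 (11 g of powder brought to 110 mL, a 1:10 w/v rehydration).
    copies_per_cell:
        Genomic target copies per cell.  Assays target single-copy unique
        sequences, so the default is 1.0; configurable for multi-copy
        targets.
    """

    ml_per_g: float = 10.0
    copies_per_cell: float = 1.0

    def __post_init__(self) -> None:
        if self.ml_per_g <= 0:
            raise ValueError("ml_per_g must be positive")
        if self.copies_per_cell <= 0:
            raise ValueError("copies_per_cell must be positive")

    # ---- ddPCR / flow style fold-dilutions (dilution_factor >= 1) ----
    def copies_per_ul_to_count_per_g(self, copies_per_ul: float, dilution_factor: float) -> float:
        """Map a reaction-level concentration (copies/µL) to cells per gram."""
        return copies_per_ul * UL_PER_ML * dilution_factor * self.ml_per_g / self.copies_per_cell

    def count_per_g_to_copies_per_ul(self, count_per_g: float, dilution_factor: float) -> float:
        """Inverse of :meth:`copies_per_ul_to_count_per_g`."""
        return count_per_g * self.copies_per_cell / (UL_PER_ML * dilution_factor * self.ml_per_g)

    # ---- plate style fractional dilution levels (dilution_level <= 1) ----
    def colonies_to_cfu_per_g(self, colonies: float, plated_volume_ml: float,
                              dilution_level: float) -> float:
        """CFU per gram from a colony count at a fractional dilution level."""
        return colonies / (plated_volume_ml * dilution_level) * self.ml_per_g

    def plated_grams_equivalent(self, plated_volume_ml: float, dilution_level: float) -> float:
        """Grams of original powder represented by one plated aliquot."""
        return plated_volume_ml * dilution_level / self.ml_per_g


def config_hash(obj) -> str:
    """Stable short hash of a (nested) dataclass/dict configuration."""
    if hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
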