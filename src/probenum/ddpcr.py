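"""Droplet digital PCR quantification via the Poisson occupancy model.

A ddPCR reaction partitions template into ~20,000 oil droplets; end-point
PCR classifies each droplet positive or negative.  Because template
molecules land in droplets at random, the number of copies per droplet is
Poisson with mean occupancy λ, and the observed positive fraction
p = positives / accepted estimates ``1 - exp(-λ)``, so

    λ = -ln(1 - p)

and the reaction concentration is ``λ / droplet_volume`` copies/µL.  The
dilution chain then converts that to cells per gram of powder.  Wells run
with the PEMAX viability dye report live cells only (``PCR.live``);
untreated wells report total cells (``PCR.total``).

This module also fits the dilution-series amplification efficiency
(regression of measured copies on theoretical copies, efficiency % = 100 ×
slope, acceptable window 90–105%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .config import DilutionChain

__all__ = [
    "DropletWellRecord",
    "ConcentrationEstimate",
    "EfficiencyFit",
    "quantify_well",
    "merge_wells",
    "estimate_ci",
    "fit_efficiency",
    "DEFAULT_DROPLET_VOLUME_UL",
    "DEFAULT_MIN_DROPLETS",
]

#: nominal QX200 droplet volume, microlitres
DEFAULT_DROPLET_VOLUME_UL = 8.5e-4
#: wells with fewer accepted droplets are flagged (not discarded)
DEFAULT_MIN_DROPLETS = 10_000

ARM_LIVE = "live-treated"
ARM_TOTAL = "untreated"
ARM_TO_METHOD = {ARM_LIVE: "PCR.live", ARM_TOTAL: "PCR.total"}


@dataclass(frozen=True)
class DropletWellRecord:
    """Positive/accepted droplet counts for a single ddPCR well."""

    batch_id: str
    well_id: str
    arm: str
    accepted_droplets: int
    positive_droplets: int
    dilution_factor: float
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL

    def __post_init__(self) -> None:
        if self.accepted_droplets < 0:
            raise ValueError("accepted_droplets must be non-negative")
        if not 0 <= self.positive_droplets <= self.accepted_droplets:
            raise ValueError(
                f"positive_droplets must lie in [0, accepted_droplets], got "
                f"{self.positive_droplets}/{self.accepted_droplets}"
            )
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.droplet_volume <= 0:
            raise ValueError("droplet_volume must be positive")
        if self.arm not in ARM_TO_METHOD:
            raise ValueError(f"arm must be one of {sorted(ARM_TO_METHOD)}")


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Quantified concentration for one well or a merged set of wells."""

    batch_id: str
    arm: str
    copies_per_droplet: float
    copies_per_ul_reaction: float
    count_per_g: float
    ci_low: float
    ci_high: float
    wells_used: int
    saturated: bool = False
    below_min_droplets: bool = False

    @property
    def method(self) -> str:
        return ARM_TO_METHOD[self.arm]


def _lambda_from_p(p: float) -> float:
    if p >= 1.0:
        return math.inf
    return -math.log1p(-p)


def quantify_well(
    rec: DropletWellRecord,
    chain: DilutionChain = DilutionChain(),
    min_droplets: int = DEFAULT_MIN_DROPLETS,
    ci_level: float = 0.95,
) -> ConcentrationEstimate:
    """Convert one well's droplet counts into a concentration estimate.

    Saturated wells (every droplet positive) get a censored point estimate
    (NaN) with a finite lower confidence bound only; wells with fewer than
    ``min_droplets`` accepted droplets are flagged but still quantified.
    """
    if rec.accepted_droplets == 0:
        raise ValueError("cannot quantify a well with zero accepted droplets")
    p = rec.positive_droplets / rec.accepted_droplets
    saturated = rec.positive_droplets == rec.accepted_droplets
    lam = _lambda_from_p(p)
    if saturated:
        copies_per_ul = math.nan
        count_per_g = math.nan
    else:
        copies_per_ul = lam / rec.droplet_volume
        count_per_g = chain.copies_per_ul_to_count_per_g(copies_per_ul, rec.dilution_factor)
    ci_low, ci_high = estimate_ci(rec, level=ci_level, chain=chain)
    return ConcentrationEstimate(
        batch_id=rec.batch_id,
        arm=rec.arm,
        copies_per_droplet=lam,
        copies_per_ul_reaction=copies_per_ul,
        count_per_g=count_per_g,
        ci_low=ci_low,
        ci_high=ci_high,
        wells_used=1,
        saturated=saturated,
        below_min_droplets=rec.accepted_droplets < min_droplets,
    )


def merge_wells(
    recs: Sequence[DropletWellRecord],
    chain: DilutionChain = DilutionChain(),
    min_droplets: int = DEFAULT_MIN_DROPLETS,
    ci_level: float = 0.95,
) -> ConcentrationEstimate:
    """Pool replicate wells (sum positives and accepted) before quantifying.

    Pooling matches the vendor "merged wells" convention and minimises the
    variance of the occupancy estimate.  All wells must share batch, arm,
    dilution factor and droplet volume.
    """
    if not recs:
        raise ValueError("merge_wells requires at least one well")
    first = recs[0]
    for r in recs[1:]:
        if r.batch_id != first.batch_id or r.arm != first.arm:
            raise ValueError("cannot merge wells from different batches or arms")
        if r.dilution_factor != first.dilution_factor:
            raise ValueError("cannot merge wells with mixed dilution factors")
        if r.droplet_volume != first.droplet_volume:
            raise ValueError("cannot merge wells with mixed droplet volumes")
    pooled = replace(
        first,
        well_id="+".join(r.well_id for r in recs),
        accepted_droplets=sum(r.accepted_droplets for r in recs),
        positive_droplets=sum(r.positive_droplets for r in recs),
    )
    est = quantify_well(pooled, chain=chain, min_droplets=min_droplets * len(recs), ci_level=ci_level)
    return replace(est, wells_used=len(recs))


def estimate_ci(
    rec: DropletWellRecord,
    level: float = 0.95,
    chain: DilutionChain = DilutionChain(),
) -> tuple[float, float]:
    """Wilson-score confidence interval mapped to the cells-per-gram scale.

    The Wilson interval on the positive fraction p is pushed through the
    monotone map p ↦ -ln(1-p)/Vd × dilution chain, so the bounds inherit
    the nominal coverage of the proportion interval.  For a saturated well
    the upper bound is infinite (one-sided interval).
    """
    p_low, p_high = proportion_confint(
        rec.positive_droplets, rec.accepted_droplets, alpha=1 - level, method="wilson"
    )

    def to_count(p: float) -> float:
        lam = _lambda_from_p(min(max(p, 0.0), 1.0))
        if math.isinf(lam):
            return math.inf
        return chain.copies_per_ul_to_count_per_g(lam / rec.droplet_volume, rec.dilution_factor)

    return to_count(p_low), to_count(p_high)


@dataclass(frozen=True)
class EfficiencyFit:
    """Dilution-series amplification efficiency from an OLS fit."""

    slope: float
    intercept: float
    efficiency_pct: float
    r_squared: float
    within_limits: bool

    #: acceptable efficiency window, percent
    LIMITS = (90.0, 105.0)


def fit_efficiency(
    series: Iterable[tuple[float, float]],
    reference: float,
    include_intercept: bool = True,
) -> EfficiencyFit:
    """Fit measured copies against theoretical copies for a dilution series.

    Parameters
    ----------
    series:
        Pairs ``(dilution_fraction, measured_copies)`` with fractions in
        (0, 1]; the theoretical value at fraction f is ``reference × f``.
    reference:
        Copies measured (or expected) at fraction 1 — the anchor of the
        theoretical yield.
    include_intercept:
        Fit ``measured = slope × theoretical + intercept`` (default) or
        force the line through the origin.

    Efficiency % is 100 × slope; ``within_limits`` applies the 90–105%
    acceptance window.
    """
    pts = list(series)
    if len(pts) < 3:
        raise ValueError("efficiency fit requires at least 3 series points")
    fractions = np.array([f for f, _ in pts], dtype=float)
    measured = np.array([m for _, m in pts], dtype=float)
    if np.any(fractions <= 0) or np.any(fractions > 1):
        raise ValueError("dilution fractions must lie in (0, 1]")
    theoretical = reference * fractions
    if np.allclose(theoretical, theoretical[0]):
        raise ValueError("degenerate fit: all theoretical values identical")
    if include_intercept:
        fit = stats.linregress(theoretical, measured)
        slope, intercept, r2 = fit.slope, fit.intercept, fit.rvalue**2
    else:
        slope = float(np.dot(theoretical, measured) / np.dot(theoretical, theoretical))
        intercept = 0.0
        resid = measured - slope * theoretical
        ss_tot = float(np.sum((measured - measured.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    eff = 100.0 * slope
    lo, hi = EfficiencyFit.LIMITS
    return EfficiencyFit(
        slope=float(slope),
        intercept=float(intercept),
        efficiency_pct=float(eff),
        r_squared=float(r2),
        within_limits=lo <= eff <= hi,
    )
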