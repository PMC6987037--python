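"""Synthetic study generator for the three enumeration processes.

Emulates a 50-batch production study of six probiotic strains measured by
plate count (17 replicate pour plates), droplet digital PCR (triplicate
wells in a viability-treated and an untreated arm) and flow cytometry
(triplicate live/dead/total gating), so every downstream quantification
and agreement stage can be tested without the deposited dataset.

The measurement-process models:

* **Plate** — colony counts are Poisson with mean equal to the plated
  grams-equivalent times the live concentration, inflated by a
  multiplicative lognormal replicate error (relative sd ``plate_rel_sd``,
  default 15%) representing dilution pipetting and plating variability.
* **ddPCR** — the effective template concentration is the live
  concentration plus, in the viability-treated arm, a fraction
  ``pemax_dead_carryover`` of the dead-cell template that survives the
  dye treatment (the untreated arm amplifies dead templates fully).  The
  mean occupancy per droplet follows the dilution chain; positives per
  well are binomial with success probability ``1 − exp(−m)``, with a small
  extra lognormal well-to-well error on m.
* **Flow** — live and dead gate concentrations mix through a symmetric
  misgating fraction and carry a multiplicative lognormal error
  (``flow_rel_sd``, default 3%); the total gate is live + dead exactly.

Each batch draws its own substream from the study seed via a stable hash
of the batch id, so results are deterministic and independent of batch
ordering.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import UL_PER_ML, DilutionChain
from .ddpcr import ARM_LIVE, ARM_TOTAL, DEFAULT_DROPLET_VOLUME_UL, DropletWellRecord
from .flow import FlowRecord
from .plate import DEFAULT_COUNTABLE_WINDOW, PlateSeriesRecord

__all__ = [
    "STRAINS",
    "BatchTruth",
    "StudyDesign",
    "NoiseModel",
    "PlateScheme",
    "generate_study",
    "simulate_plate_series",
    "simulate_ddpcr_wells",
    "simulate_flow",
]

#: the six study strains with their batch counts
STRAINS = ("NCFM", "Bi-07", "Lp-115", "HN019", "Bl-04", "La-14")
DEFAULT_BATCHES_PER_STRAIN = {
    "NCFM": 20, "Bi-07": 9, "Lp-115": 8, "HN019": 8, "Bl-04": 3, "La-14": 2,
}


@dataclass(frozen=True)
class BatchTruth:
    """Ground-truth live/dead cell concentrations for one production batch."""

    batch_id: str
    strain: str
    live_conc: float  # cells per gram
    dead_conc: float  # cells per gram

    def __post_init__(self) -> None:
        if self.live_conc < 0:
            raise ValueError("live_conc must be non-negative")
        if self.dead_conc < 0:
            raise ValueError("dead_conc must be non-negative")
        if self.strain not in STRAINS:
            raise ValueError(f"strain must be one of {STRAINS}")


@dataclass(frozen=True)
class StudyDesign:
    """Replicate structure of the study."""

    n_batches_per_strain: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_BATCHES_PER_STRAIN)
    )
    plate_replicates: int = 17
    well_replicates: int = 3
    flow_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_batches_per_strain:
            raise ValueError("design must include at least one strain")
        if any(n < 1 for n in self.n_batches_per_strain.values()):
            raise ValueError("batch counts must be >= 1")
        if min(self.plate_replicates, self.well_replicates, self.flow_replicates) < 1:
            raise ValueError("replicate counts must be >= 1")

    @property
    def n_batches(self) -> int:
        return sum(self.n_batches_per_strain.values())


@dataclass(frozen=True)
class NoiseModel:
    """Noise regimes of the three measurement processes.

    Defaults emulate the observed ordering plate ≫ flow > ddPCR;
    ``pemax_dead_carryover`` and ``dead_fraction_mean`` are calibration
    knobs of the simulator, not measured quantities.
    """

    plate_rel_sd: float = 0.15
    flow_rel_sd: float = 0.03
    ddpcr_extra_rel_sd: float = 0.01
    pemax_dead_carryover: float = 0.2
    flow_live_misgate: float = 0.02
    dead_fraction_mean: float = 0.15
    dead_fraction_rel_sd: float = 0.3

    def __post_init__(self) -> None:
        for name in ("pemax_dead_carryover", "flow_live_misgate", "dead_fraction_mean"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("plate_rel_sd", "flow_rel_sd", "ddpcr_extra_rel_sd", "dead_fraction_rel_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PlateScheme:
    """Serial-dilution description for pour plating."""

    dilution_levels: tuple[float, ...]  # fractions of the suspension, e.g. (1e-7, 1e-8)
    plated_volume: float = 1.0          # mL per plate

    def __post_init__(self) -> None:
        if not self.dilution_levels:
            raise ValueError("at least one dilution level required")
        if any(not 0 < d <= 1 for d in self.dilution_levels):
            raise ValueError("dilution levels must lie in (0, 1]")
        if self.plated_volume <= 0:
            raise ValueError("plated_volume must be positive")


# ---------------------------------------------------------------------------
# seeding helpers

def _batch_rng(seed: int, batch_id: str, stage: str) -> np.random.Generator:
    """Deterministic substream per (study seed, batch, stage)."""
    entropy = (int(seed), zlib.crc32(batch_id.encode()), zlib.crc32(stage.encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _lognormal_factor(rng: np.random.Generator, rel_sd: float, size=None):
    """Multiplicative error with mean 1 and relative sd ``rel_sd``."""
    if rel_sd == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = math.log1p(rel_sd**2)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# study generation

def generate_study(
    design: StudyDesign,
    noise: NoiseModel = NoiseModel(),
    conc_range: tuple[float, float] = (5e10, 5e11),
) -> list[BatchTruth]:
    """Draw ground-truth batches for the configured study design.

    Live concentrations are log-uniform on ``conc_range``; dead
    concentrations are ``live × dead-fraction`` with the fraction drawn
    lognormally around ``dead_fraction_mean``.
    """
    lo, hi = conc_range
    if lo <= 0 or hi < lo:
        raise ValueError("conc_range must be a positive interval")
    batches: list[BatchTruth] = []
    for strain in sorted(design.n_batches_per_strain):
        for i in range(design.n_batches_per_strain[strain]):
            batch_id = f"{strain}-{i + 1:03d}"
            rng = _batch_rng(design.seed, batch_id, "truth")
            live = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            frac = noise.dead_fraction_mean * _lognormal_factor(rng, noise.dead_fraction_rel_sd)
            batches.append(BatchTruth(batch_id, strain, live, live * float(frac)))
    return batches


def default_plate_scheme(
    truth: BatchTruth,
    chain: DilutionChain = DilutionChain(),
    window: tuple[int, int] = DEFAULT_COUNTABLE_WINDOW,
    plated_volume: float = 1.0,
) -> PlateScheme:
    """Decade dilution series bracketing the countable window.

    Picks the decade 10^-k whose expected colony count is closest to the
    geometric centre of the window, plus one decade either side, so the
    quantifier must apply the countable-window rule itself.
    """
    target = math.sqrt(window[0] * window[1])
    if truth.live_conc <= 0:
        return PlateScheme((1e-6,), plated_volume)
    # expected colonies at level d: live_conc * plated_volume * d / ml_per_g
    ideal = target * chain.ml_per_g / (truth.live_conc * plated_volume)
    k = round(-math.log10(ideal))
    levels = tuple(10.0 ** (-(k + off)) for off in (-1, 0, 1) if 0 < 10.0 ** (-(k + off)) <= 1)
    return PlateScheme(levels, plated_volume)


def simulate_plate_series(
    truth: BatchTruth,
    scheme: PlateScheme,
    n_plates: int,
    seed: int,
    noise: NoiseModel = NoiseModel(),
    chain: DilutionChain = DilutionChain(),
) -> list[PlateSeriesRecord]:
    """Poisson colony counts for every dilution level of the scheme.

    Each plate's Poisson mean is ``live_conc × plated grams-equivalent``
    times an independent lognormal replicate error; counts are reported
    for every level, countable or not, so the plate quantifier must apply
    the 25–250 window downstream.
    """
    if n_plates < 1:
        raise ValueError("n_plates must be >= 1")
    rng = _batch_rng(seed, truth.batch_id, "plate")
    records = []
    for level in scheme.dilution_levels:
        mean0 = truth.live_conc * chain.plated_grams_equivalent(scheme.plated_volume, level)
        factors = _lognormal_factor(rng, noise.plate_rel_sd, size=n_plates)
        counts = rng.poisson(mean0 * factors)
        records.append(
            PlateSeriesRecord(truth.batch_id, level, scheme.plated_volume,
                              tuple(int(c) for c in counts))
        )
    return records


def ddpcr_target_dilution(
    truth: BatchTruth,
    chain: DilutionChain = DilutionChain(),
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL,
    target_occupancy: float = 0.8,
) -> float:
    """Fold dilution putting the expected occupancy near its sweet spot."""
    total = truth.live_conc + truth.dead_conc
    m_undiluted = chain.count_per_g_to_copies_per_ul(total, 1.0) * droplet_volume
    return max(1.0, m_undiluted / target_occupancy)


def simulate_ddpcr_wells(
    truth: BatchTruth,
    arm: str,
    dilution_factor: float,
    n_wells: int,
    seed: int,
    droplets_per_well: int = 20_000,
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL,
    noise: NoiseModel = NoiseModel(),
    chain: DilutionChain = DilutionChain(),
) -> list[DropletWellRecord]:
    """Binomial positives per well under the Poisson occupancy model.

    The viability-treated arm amplifies ``live + carryover × dead``
    templates; the untreated arm amplifies ``live + dead``.  Saturation
    (all droplets positive) is permitted — the quantifier must flag it.
    """
    if droplets_per_well < 1:
        raise ValueError("droplets_per_well must be >= 1")
    if droplet_volume <= 0:
        raise ValueError("droplet_volume must be positive")
    if arm == ARM_LIVE:
        eff_conc = truth.live_conc + noise.pemax_dead_carryover * truth.dead_conc
    elif arm == ARM_TOTAL:
        eff_conc = truth.live_conc + truth.dead_conc
    else:
        raise ValueError(f"unknown arm {arm!r}")
    m0 = chain.count_per_g_to_copies_per_ul(eff_conc, dilution_factor) * droplet_volume
    rng = _batch_rng(seed, truth.batch_id, f"ddpcr-{arm}")
    wells = []
    for w in range(n_wells):
        m = m0 * float(_lognormal_factor(rng, noise.ddpcr_extra_rel_sd))
        p = -math.expm1(-m)  # 1 - exp(-m)
        positives = int(rng.binomial(droplets_per_well, p))
        wells.append(
            DropletWellRecord(
                batch_id=truth.batch_id,
                well_id=f"{truth.batch_id}-{arm}-w{w + 1}",
                arm=arm,
                accepted_droplets=droplets_per_well,
                positive_droplets=positives,
                dilution_factor=dilution_factor,
                droplet_volume=droplet_volume,
            )
        )
    return wells


def simulate_flow(
    truth: BatchTruth,
    dilution_factor: float,
    seed: int,
    n_replicates: int = 3,
    analyzed_volume: float = 50.0,
    noise: NoiseModel = NoiseModel(),
    chain: DilutionChain = DilutionChain(),
) -> list[FlowRecord]:
    """Gated live/dead/total event counts per replicate acquisition.

    A symmetric misgating fraction exchanges a small share of events
    between the live and dead gates; each gate concentration carries an
    independent lognormal error of relative sd ``flow_rel_sd``; the total
    gate is exactly live + dead.
    """
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    rng = _batch_rng(seed, truth.batch_id, "flow")
    mis = noise.flow_live_misgate
    live_gate0 = truth.live_conc * (1 - mis) + mis * truth.dead_conc
    dead_gate0 = truth.dead_conc * (1 - mis) + mis * truth.live_conc
    per_ul = 1.0 / (UL_PER_ML * dilution_factor * chain.ml_per_g)  # cells/g -> events/µL
    records = []
    for rep in range(1, n_replicates + 1):
        live_conc = live_gate0 * float(_lognormal_factor(rng, noise.flow_rel_sd))
        dead_conc = dead_gate0 * float(_lognormal_factor(rng, noise.flow_rel_sd))
        live_events = live_conc * per_ul * analyzed_volume
        dead_events = dead_conc * per_ul * analyzed_volume
        records.append(
            FlowRecord(
                batch_id=truth.batch_id,
                replicate=rep,
                live_events=live_events,
                dead_events=dead_events,
                total_events=live_events + dead_events,
                analyzed_volume=analyzed_volume,
                dilution_factor=dilution_factor,
            )
        )
    return records
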