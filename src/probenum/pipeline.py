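"""Pipeline orchestration: simulate → quantify → compare, with file I/O.

The interchange format is CSV throughout (no domain standard exists for
ddPCR well summaries).  Schemas:

* ``batches.csv`` — batch_id, strain
* ``plate_series.csv`` — batch_id, dilution_level, plated_volume,
  plate_index, colonies
* ``droplet_wells.csv`` — batch_id, well, arm, accepted_droplets,
  positive_droplets, dilution_factor, droplet_volume
* ``flow_records.csv`` — batch_id, replicate, live_events, dead_events,
  total_events, analyzed_volume, dilution_factor
* ``measurements.csv`` — batch_id, strain, method, replicate, count_per_g
  (the long-form measurement table consumed by the comparison stage)

Every simulation run writes a ``manifest.json`` recording the seed and a
hash of the configuration, and reruns with the same seed are
byte-identical.  Malformed raw rows are rejected and logged, never
silently coerced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import agreement, ddpcr, flow, plate, simulate
from .config import DilutionChain, config_hash

__all__ = ["PipelineConfig", "run_simulate", "run_quantify", "run_compare",
           "read_measurements", "write_measurements"]

logger = logging.getLogger("probenum")

MEASUREMENT_COLUMNS = ["batch_id", "strain", "method", "replicate", "count_per_g"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline in one place."""

    design: simulate.StudyDesign = field(default_factory=simulate.StudyDesign)
    noise: simulate.NoiseModel = field(default_factory=simulate.NoiseModel)
    chain: DilutionChain = field(default_factory=DilutionChain)
    conc_range: tuple[float, float] = (5e10, 5e11)
    droplets_per_well: int = 20_000
    droplet_volume: float = ddpcr.DEFAULT_DROPLET_VOLUME_UL
    min_droplets: int = ddpcr.DEFAULT_MIN_DROPLETS
    ci_level: float = 0.95
    target_occupancy: float = 0.8
    countable_window: tuple[int, int] = plate.DEFAULT_COUNTABLE_WINDOW
    plated_volume: float = 1.0
    flow_analyzed_volume: float = 50.0
    loa_level: float = 0.95

    @property
    def seed(self) -> int:
        return self.design.seed

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "design" in raw:
            kwargs["design"] = simulate.StudyDesign(**raw.pop("design"))
        if "noise" in raw:
            kwargs["noise"] = simulate.NoiseModel(**raw.pop("noise"))
        if "chain" in raw:
            kwargs["chain"] = DilutionChain(**raw.pop("chain"))
        for key in ("conc_range", "countable_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        kwargs.update(raw)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# simulation stage

def run_simulate(config: PipelineConfig, outdir: str | Path) -> pd.DataFrame:
    """Generate a synthetic study, write raw observations, and quantify.

    Returns the long-form measurement table (also written to
    ``measurements.csv``); raw per-instrument observations and a manifest
    with the seed and config hash land beside it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truths = simulate.generate_study(config.design, config.noise, config.conc_range)
    seed = config.seed

    batch_rows, plate_rows, well_rows, flow_rows = [], [], [], []
    for t in truths:
        batch_rows.append({"batch_id": t.batch_id, "strain": t.strain})
        scheme = simulate.default_plate_scheme(
            t, chain=config.chain, window=config.countable_window,
            plated_volume=config.plated_volume)
        for rec in simulate.simulate_plate_series(
                t, scheme, config.design.plate_replicates, seed,
                noise=config.noise, chain=config.chain):
            for idx, c in enumerate(rec.colony_counts, start=1):
                plate_rows.append({
                    "batch_id": rec.batch_id, "dilution_level": rec.dilution_level,
                    "plated_volume": rec.plated_volume, "plate_index": idx, "colonies": c,
                })
        dil = simulate.ddpcr_target_dilution(
            t, chain=config.chain, droplet_volume=config.droplet_volume,
            target_occupancy=config.target_occupancy)
        for arm in (ddpcr.ARM_LIVE, ddpcr.ARM_TOTAL):
            for w in simulate.simulate_ddpcr_wells(
                    t, arm, dil, config.design.well_replicates, seed,
                    droplets_per_well=config.droplets_per_well,
                    droplet_volume=config.droplet_volume,
                    noise=config.noise, chain=config.chain):
                well_rows.append({
                    "batch_id": w.batch_id, "well": w.well_id, "arm": w.arm,
                    "accepted_droplets": w.accepted_droplets,
                    "positive_droplets": w.positive_droplets,
                    "dilution_factor": w.dilution_factor,
                    "droplet_volume": w.droplet_volume,
                })
        flow_dil = max(1.0, (t.live_conc + t.dead_conc) / 1e8)  # keep events manageable
        for fr in simulate.simulate_flow(
                t, flow_dil, seed, n_replicates=config.design.flow_replicates,
                analyzed_volume=config.flow_analyzed_volume,
                noise=config.noise, chain=config.chain):
            flow_rows.append({
                "batch_id": fr.batch_id, "replicate": fr.replicate,
                "live_events": fr.live_events, "dead_events": fr.dead_events,
                "total_events": fr.total_events,
                "analyzed_volume": fr.analyzed_volume,
                "dilution_factor": fr.dilution_factor,
            })

    pd.DataFrame(batch_rows).to_csv(outdir / "batches.csv", index=False)
    pd.DataFrame(plate_rows).to_csv(outdir / "plate_series.csv", index=False)
    pd.DataFrame(well_rows).to_csv(outdir / "droplet_wells.csv", index=False)
    pd.DataFrame(flow_rows).to_csv(outdir / "flow_records.csv", index=False)
    pd.DataFrame(
        [{"batch_id": t.batch_id, "strain": t.strain,
          "live_conc": t.live_conc, "dead_conc": t.dead_conc} for t in truths]
    ).to_csv(outdir / "truth.csv", index=False)
    manifest = {"seed": seed, "config_hash": config_hash(config.to_dict()),
                "n_batches": len(truths)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    table = run_quantify(config, outdir)
    write_measurements(table, outdir / "measurements.csv")
    return table


# ---------------------------------------------------------------------------
# quantification stage

def _strain_map(indir: Path) -> dict[str, str]:
    df = pd.read_csv(indir / "batches.csv")
    return dict(zip(df["batch_id"], df["strain"]))


def run_quantify(config: PipelineConfig, indir: str | Path) -> pd.DataFrame:
    """Quantify raw observation CSVs into one long-form measurement table.

    Each ddPCR well is quantified separately (one replicate per well) so
    replicate scatter feeds the CV analysis; ``merge_wells`` remains
    available for pooled point estimates.  Malformed rows are rejected
    and counted in the log.
    """
    indir = Path(indir)
    strains = _strain_map(indir)
    rows: list[dict] = []

    # plate
    pdf = pd.read_csv(indir / "plate_series.csv")
    for batch_id, grp in pdf.groupby("batch_id", sort=True):
        series = [
            plate.PlateSeriesRecord(batch_id, lv, vol, tuple(g["colonies"]))
            for (lv, vol), g in grp.groupby(["dilution_level", "plated_volume"], sort=True)
        ]
        countable, diag = plate.select_countable(series, config.countable_window)
        if not countable:
            logger.warning("batch %s: no countable plates (%s); Plate flagged missing",
                           batch_id, diag)
            rows.append({"batch_id": batch_id, "strain": strains.get(batch_id, ""),
                         "method": "Plate", "replicate": 1, "count_per_g": math.nan})
            continue
        est = plate.cfu_per_g(countable, chain=config.chain)
        for rep, value in enumerate(est.per_plate_cfu_per_g, start=1):
            rows.append({"batch_id": batch_id, "strain": strains.get(batch_id, ""),
                         "method": "Plate", "replicate": rep, "count_per_g": value})

    # ddPCR
    wdf = pd.read_csv(indir / "droplet_wells.csv")
    n_bad = 0
    for _, r in wdf.iterrows():
        try:
            rec = ddpcr.DropletWellRecord(
                batch_id=str(r["batch_id"]), well_id=str(r["well"]), arm=str(r["arm"]),
                accepted_droplets=int(r["accepted_droplets"]),
                positive_droplets=int(r["positive_droplets"]),
                dilution_factor=float(r["dilution_factor"]),
                droplet_volume=float(r.get("droplet_volume", config.droplet_volume)),
            )
        except (ValueError, KeyError) as exc:
            n_bad += 1
            logger.warning("droplet well row rejected: %s", exc)
            continue
        est = ddpcr.quantify_well(rec, chain=config.chain,
                                  min_droplets=config.min_droplets,
                                  ci_level=config.ci_level)
        if est.saturated:
            logger.warning("well %s saturated; estimate censored", rec.well_id)
        rows.append({"batch_id": rec.batch_id, "strain": strains.get(rec.batch_id, ""),
                     "method": est.method,
                     "replicate": len([x for x in rows
                                       if x["batch_id"] == rec.batch_id
                                       and x["method"] == est.method]) + 1,
                     "count_per_g": est.count_per_g})
    if n_bad:
        logger.warning("%d droplet well rows rejected", n_bad)

    # flow
    fdf = pd.read_csv(indir / "flow_records.csv")
    for _, r in fdf.iterrows():
        try:
            rec = flow.FlowRecord(
                batch_id=str(r["batch_id"]), replicate=int(r["replicate"]),
                live_events=float(r["live_events"]), dead_events=float(r["dead_events"]),
                total_events=float(r["total_events"]),
                analyzed_volume=float(r["analyzed_volume"]),
                dilution_factor=float(r["dilution_factor"]),
            )
        except (ValueError, KeyError) as exc:
            logger.warning("flow row rejected: %s", exc)
            continue
        for gate in flow.GATES:
            rows.append({"batch_id": rec.batch_id, "strain": strains.get(rec.batch_id, ""),
                         "method": flow.GATE_TO_METHOD[gate], "replicate": rec.replicate,
                         "count_per_g": flow.cells_per_g(rec, gate, chain=config.chain)})

    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


# ---------------------------------------------------------------------------
# comparison stage

def run_compare(config: PipelineConfig, table: pd.DataFrame,
                outdir: str | Path | None = None,
                figures: bool = True) -> dict:
    """CV summaries, pairwise agreement, figures and a JSON report.

    With a single method in the table only the CV report is produced
    (agreement is skipped with a warning).
    """
    _validate_table(table)
    summaries, agreements = agreement.compare_table(table, loa_level=config.loa_level)
    if not agreements:
        logger.warning("fewer than two comparable methods; agreement analysis skipped")
    report = {
        "cv_summaries": [dataclasses.asdict(s) for s in summaries],
        "pair_agreements": [dataclasses.asdict(a) for a in agreements],
        "n_rows": int(len(table)),
        "config_hash": config_hash(config.to_dict()),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        pd.DataFrame(report["cv_summaries"]).to_csv(outdir / "cv_summaries.tsv",
                                                    sep="\t", index=False)
        pd.DataFrame(report["pair_agreements"]).to_csv(outdir / "pair_agreements.tsv",
                                                       sep="\t", index=False)
        if figures:
            _write_figures(table, agreements, outdir)
    return report


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    dup = table.duplicated(subset=["batch_id", "method", "replicate"])
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicate (batch, method, replicate) rows")
    neg = table["count_per_g"].dropna() <= 0
    if neg.any():
        raise ValueError("counts must be positive or flagged missing (NaN)")


def _write_figures(table: pd.DataFrame, agreements, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    focus = [m for m in ("Plate", "PCR.live", "Flow.live") if m in set(table["method"])]
    # per-batch boxplot of the focus methods
    fig, ax = plt.subplots(figsize=(8, 4))
    data = [table.loc[table["method"] == m, "count_per_g"].dropna() for m in focus]
    ax.boxplot(data, tick_labels=focus)
    ax.set_yscale("log")
    ax.set_ylabel("count per gram")
    ax.set_title("Distribution of counts by method")
    fig.tight_layout()
    fig.savefig(outdir / "method_boxplot.png", dpi=120)
    plt.close(fig)

    for pa in agreements:
        if pa.method_x not in focus or pa.method_y not in focus:
            continue
        bx = agreement.batch_means(table, pa.method_x)
        by = agreement.batch_means(table, pa.method_y)
        joined = pd.concat([bx, by], axis=1, keys=["x", "y"]).dropna()
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        ax1.scatter(joined["x"], joined["y"], s=14)
        lims = [joined.min().min(), joined.max().max()]
        ax1.plot(lims, lims, "k-", lw=1, label="y = x")
        xs = np.linspace(*lims, 50)
        ax1.plot(xs, pa.slope * xs + pa.intercept, "b--", lw=1,
                 label=f"fit (slope {pa.slope:.3f})")
        ax1.set_xlabel(pa.method_x)
        ax1.set_ylabel(pa.method_y)
        ax1.legend(fontsize=8)
        d = agreement.relative_differences(joined["x"], joined["y"])
        ax2.scatter((joined["x"] + joined["y"]) / 2, d, s=14)
        for yv, style in ((pa.mean_rel_diff_pct, "b-"),
                          (pa.loa_low_pct, "r--"), (pa.loa_high_pct, "r--")):
            ax2.axhline(yv, ls=style[1:], color=style[0], lw=1)
        ax2.set_xlabel("pair mean (count per gram)")
        ax2.set_ylabel("relative difference (%)")
        fig.suptitle(f"{pa.method_x} vs {pa.method_y}")
        fig.tight_layout()
        safe = f"{pa.method_x}_vs_{pa.method_y}".replace(".", "")
        fig.savefig(outdir / f"agreement_{safe}.png", dpi=120)
        plt.close(fig)


# ---------------------------------------------------------------------------
# measurement-table I/O

def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a long-form measurement CSV and validate its schema."""
    table = pd.read_csv(path)
    _validate_table(table)
    return table


def write_measurements(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
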