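"""Method consistency and agreement statistics.

Three analyses compare enumeration methods across production batches:

* **Consistency** — the per-batch coefficient of variation (CV, a.k.a.
  relative standard deviation) of replicate measurements, averaged over
  batches per method.  CVs are computed on the linear (non-log) scale,
  because product labels state counts in scientific notation and log
  transformation artificially deflates the CV.
* **Correlation / regression** — Pearson r between per-batch means of two
  methods, and an ordinary least-squares line of method 2 (y) on method 1
  (x), read against the y = x identity line.
* **Bland–Altman agreement** — the relative difference
  d = (Method1 − Method2) / (pair average) × 100 per batch, summarised by
  its mean and the 95% limits of agreement (mean ± 1.96 × sd).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "METHODS",
    "ConsistencySummary",
    "PairAgreement",
    "per_batch_cv",
    "method_cv_summary",
    "batch_means",
    "pearson",
    "regress_identity",
    "bland_altman",
    "compare_table",
]

#: canonical method labels, in report order
METHODS = ("Plate", "PCR.total", "PCR.live", "Flow.total", "Flow.live", "Flow.dead")

#: measurement-table column contract
TABLE_COLUMNS = ("batch_id", "strain", "method", "replicate", "count_per_g")

LOA_MULTIPLIER = 1.96  # 95% limits of agreement


@dataclass(frozen=True)
class ConsistencySummary:
    """Mean ± sd of per-batch CVs for one method within one stratum."""

    method: str
    stratum: str
    mean_cv_pct: float
    sd_cv_pct: float
    n_batches: int


@dataclass(frozen=True)
class PairAgreement:
    """Correlation, regression and Bland–Altman summary for a method pair.

    ``method_x`` is "Method 1": the abscissa of the scatter plot and the
    minuend of the relative difference.
    """

    method_x: str
    method_y: str
    pearson_r: float
    slope: float
    intercept: float
    mean_rel_diff_pct: float
    sd_rel_diff_pct: float
    loa_low_pct: float
    loa_high_pct: float
    n_pairs: int


def per_batch_cv(replicates: Iterable[float]) -> float:
    """CV% of one batch's replicates: sample sd (n−1) / mean × 100.

    Returns NaN (a flagged missing value) with fewer than two non-missing
    replicates or a zero mean.
    """
    vals = np.asarray([v for v in replicates if not (v is None or (isinstance(v, float) and math.isnan(v)))],
                      dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        return math.nan
    mean = vals.mean()
    if mean == 0:
        return math.nan
    return float(vals.std(ddof=1) / mean * 100.0)


def _stratum_mask(table: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "All":
        return pd.Series(True, index=table.index)
    if stratum == "Non-NCFM":
        return table["strain"] != "NCFM"
    return table["strain"] == stratum


def method_cv_summary(table: pd.DataFrame, method: str, stratum: str = "All") -> ConsistencySummary:
    """Mean and sd of per-batch CVs for one method across a batch stratum.

    ``stratum`` is "All", "Non-NCFM", or a strain name.
    """
    sub = table[(table["method"] == method) & _stratum_mask(table, stratum)]
    if sub.empty:
        raise ValueError(f"no rows for method={method!r} in stratum={stratum!r}")
    cvs = sub.groupby("batch_id")["count_per_g"].apply(per_batch_cv).dropna()
    if cvs.empty:
        raise ValueError(f"no batch with >=2 replicates for method={method!r}, stratum={stratum!r}")
    return ConsistencySummary(
        method=method,
        stratum=stratum,
        mean_cv_pct=float(cvs.mean()),
        sd_cv_pct=float(cvs.std(ddof=1)) if cvs.size > 1 else math.nan,
        n_batches=int(cvs.size),
    )


def batch_means(table: pd.DataFrame, method: str) -> pd.Series:
    """Arithmetic mean of replicates per batch, indexed by batch_id.

    Batches whose replicates are all missing propagate NaN.
    """
    sub = table[table["method"] == method]
    return sub.groupby("batch_id")["count_per_g"].mean()


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of paired per-batch values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson requires >= 3 paired values")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return math.nan
    return float(stats.pearsonr(x, y).statistic)


def regress_identity(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """OLS slope and intercept of y on x, read against the y = x line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("regression requires >= 3 pairs")
    if np.allclose(x, x[0]):
        raise ValueError("x is constant; regression undefined")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept)


def relative_differences(x: Sequence[float], y: Sequence[float]) -> np.ndarray:
    """Per-pair relative differences d = (x − y)/((x + y)/2) × 100.

    Pairs with a zero average are excluded (flagged upstream); every d
    lies in [−200, 200] for non-negative inputs by construction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    avg = (x + y) / 2.0
    ok = avg != 0
    return (x[ok] - y[ok]) / avg[ok] * 100.0


def bland_altman(
    x: Sequence[float],
    y: Sequence[float],
    method_x: str = "Method 1",
    method_y: str = "Method 2",
    level: float = 0.95,
) -> PairAgreement:
    """Full pairwise agreement summary with ``level`` limits of agreement.

    Also computes Pearson r and the OLS regression of y on x so one call
    yields a complete :class:`PairAgreement` row.  Antisymmetric under
    argument swap: the mean relative difference negates and the LOA bounds
    swap and negate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("agreement requires >= 3 complete pairs")
    d = relative_differences(x, y)
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    # the conventional 1.96 multiplier at the default 95% level
    z = LOA_MULTIPLIER if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2.0))
    r = pearson(x, y)
    slope, intercept = regress_identity(x, y)
    return PairAgreement(
        method_x=method_x,
        method_y=method_y,
        pearson_r=r,
        slope=slope,
        intercept=intercept,
        mean_rel_diff_pct=mean_d,
        sd_rel_diff_pct=sd_d,
        loa_low_pct=mean_d - z * sd_d,
        loa_high_pct=mean_d + z * sd_d,
        n_pairs=int(d.size),
    )


def compare_table(
    table: pd.DataFrame,
    methods: Sequence[str] | None = None,
    loa_level: float = 0.95,
) -> tuple[list[ConsistencySummary], list[PairAgreement]]:
    """Run the full comparison on a long-form measurement table.

    Returns Table-3-shaped CV summaries for the strata
    {All, NCFM, Non-NCFM, per-strain} and a :class:`PairAgreement` row for
    every method pair present; batches missing in either method of a pair
    are dropped pairwise.
    """
    present = [m for m in (methods or METHODS) if m in set(table["method"])]
    strains = sorted(table["strain"].unique())
    strata = ["All"]
    if "NCFM" in strains and len(strains) > 1:
        strata += ["NCFM", "Non-NCFM"]
    strata += [s for s in strains if s != "NCFM" or len(strains) == 1]
    summaries = []
    for m in present:
        for s in strata:
            if table[(table["method"] == m) & _stratum_mask(table, s)].empty:
                continue
            try:
                summaries.append(method_cv_summary(table, m, s))
            except ValueError:
                # no batch with >=2 replicates: CV undefined for this stratum
                continue
    agreements = []
    for mx, my in combinations(present, 2):
        bx, by = batch_means(table, mx), batch_means(table, my)
        joined = pd.concat([bx, by], axis=1, keys=["x", "y"]).dropna()
        if len(joined) < 3:
            continue
        agreements.append(
            bland_altman(joined["x"], joined["y"], method_x=mx, method_y=my, level=loa_level)
        )
    return summaries, agreements
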