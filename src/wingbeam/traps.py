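"""Trap counts per day and sensor-to-trap association.

Light-trap surveillance reports captured mosquitoes per collection (traps
are typically emptied twice a week), while the optical sensor reports a
continuous density series.  To compare the two, trap catches are
converted to counts per day (catch divided by the days since the
previous collection, averaged across traps reporting the same date), the
sensor density is averaged over each inter-collection interval, and the
paired series are correlated.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
import pandas as pd
from scipy import stats

from .density import DensitySeries

__all__ = [
    "trap_count_per_day",
    "align_to_trap_intervals",
    "correlate",
    "CorrelationResult",
]


def trap_count_per_day(records: pd.DataFrame) -> pd.Series:
    """Average trap count per day, indexed by collection date.

    ``records`` needs columns ``trap_id``, ``collection_date`` and
    ``count``, plus either ``days_since_previous`` or enough per-trap
    history to infer it from consecutive collection dates.
    """
    df = records.copy()
    df["collection_date"] = pd.to_datetime(df["collection_date"])
    if "days_since_previous" not in df:
        df = df.sort_values(["trap_id", "collection_date"])
        delta = df.groupby("trap_id")["collection_date"].diff().dt.days
        df["days_since_previous"] = delta
        df = df.dropna(subset=["days_since_previous"])
    if (df["days_since_previous"] <= 0).any():
        raise ValueError("collection intervals must be positive")
    if (df["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    df["per_day"] = df["count"] / df["days_since_previous"]
    return df.groupby("collection_date")["per_day"].mean()


def align_to_trap_intervals(
    series: DensitySeries,
    collection_dates: np.ndarray,
    origin: float = 0.0,
) -> pd.DataFrame:
    """Valid-time-weighted mean density per inter-collection interval.

    ``collection_dates`` are interval end points in seconds relative to
    the density series' own clock minus ``origin``; each interval runs
    from the previous collection to this one.  Intervals with no valid
    sensor time are dropped with a warning.  Returns a DataFrame with
    columns ``interval_end`` and ``mean_density``.
    """
    dates = np.sort(np.asarray(collection_dates, dtype=float)) - origin
    if dates.size < 2:
        raise ValueError("need at least two collection dates")
    centers = series.bin_start + series.resolution / 2.0
    weights = series.valid_fraction * series.resolution
    out_end, out_density = [], []
    for lo, hi in zip(dates[:-1], dates[1:]):
        sel = (centers >= lo) & (centers < hi)
        w = weights[sel]
        d = series.density[sel]
        ok = np.isfinite(d) & (w > 0)
        if not ok.any():
            warn(f"interval ending at {hi:g}s has no valid sensor coverage; dropped",
                 stacklevel=2)
            continue
        out_end.append(hi + origin)
        out_density.append(float(np.average(d[ok], weights=w[ok])))
    return pd.DataFrame({"interval_end": out_end, "mean_density": out_density})


@dataclass(frozen=True)
class CorrelationResult:
    r: float  # Pearson correlation
    r_squared: float  # r^2
    regression_r2: float  # coefficient of determination of the OLS fit
    p_value: float  # two-sided test of r = 0
    n: int


def correlate(trap_per_day: np.ndarray, sensor_density: np.ndarray) -> CorrelationResult:
    """Pearson association between paired trap and sensor series.

    Reports r, r^2 and the OLS coefficient of determination separately
    (for simple linear regression they coincide up to rounding; keeping
    both makes any discrepancy in reported figures explicit).
    """
    x = np.asarray(trap_per_day, dtype=float)
    y = np.asarray(sensor_density, dtype=float)
    if x.size != y.size:
        raise ValueError("paired series must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the series")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    reg_r2 = 1.0 - float(np.sum(resid**2)) / float(np.sum((y - y.mean()) ** 2))
    return CorrelationResult(float(r), float(r) ** 2, reg_r2, float(p), int(x.size))
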