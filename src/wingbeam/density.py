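"""Aerial density: absolute abundance from transit-time occupancy.

Counting transits biases abundance toward fast fliers: a fast insect
crosses the beam more often but spends less time in it.  Normalising the
*summed transit time* by observation time and probe volume removes that
bias and yields an absolute aerial density,

    rho_a = sum_i(dt_i) / (T * V)        [insects / m^3]

where ``dt_i`` is the transit time of event ``i``, ``V`` the surveyed
air volume (beam area x path length) and ``T`` the accumulation period,
which sets the temporal resolution (minutes for daily-activity studies,
days or weeks for seasonal trends).  Time lost to heavy rain is removed
from ``T`` rather than zero-filled, since no detection is possible then.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import TransitEvent
from .features import BeamGeometry

__all__ = ["DensitySeries", "probe_volume", "aerial_density", "resample_density"]


def probe_volume(geometry: BeamGeometry) -> float:
    """Surveyed air volume V = pi (d/2)^2 L in m^3."""
    return geometry.probe_volume


@dataclass
class DensitySeries:
    """Aerial density per contiguous time bin.

    ``density`` is NaN in bins with no valid observation time.
    ``valid_fraction`` accounts for time excluded (heavy rain).
    """

    bin_start: np.ndarray  # s, bin left edges
    resolution: float  # s, bin width T
    density: np.ndarray  # insects / m^3
    valid_fraction: np.ndarray
    occupancy: np.ndarray  # s, summed in-bin transit time (for resampling)
    probe_volume: float  # m^3
    cluster: str = "all"

    def __post_init__(self) -> None:
        n = len(self.bin_start)
        if not (len(self.density) == len(self.valid_fraction)
                == len(self.occupancy) == n):
            raise ValueError("field lengths disagree")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start_s": self.bin_start,
            "resolution_s": self.resolution,
            "cluster": self.cluster,
            "density_per_m3": self.density,
            "valid_fraction": self.valid_fraction,
        })


def aerial_density(
    events: list[TransitEvent],
    total_duration: float,
    volume: float,
    resolution: float = 60.0,
    valid_mask: np.ndarray | None = None,
    label: str = "insect",
    cluster: str = "all",
) -> DensitySeries:
    """Occupancy-based density over contiguous bins of width ``resolution``.

    Events are allocated to bins by overlap duration (an event spanning a
    bin edge contributes its overlap to each bin), so the estimate is the
    exact discretisation of the occupancy integral.  ``valid_mask`` gives
    one boolean per bin (True = usable time); invalid bins get NaN
    density, partially valid handling is delegated to the mask resolution.
    """
    if volume <= 0:
        raise ValueError("probe volume must be positive")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    nbins = max(int(np.ceil(total_duration / resolution)), 1)
    edges = np.arange(nbins + 1) * resolution
    occupancy = np.zeros(nbins)
    for ev in events:
        if label is not None and ev.label != label:
            continue
        t0, t1 = ev.start_time, ev.start_time + ev.duration
        b0 = max(int(t0 // resolution), 0)
        b1 = min(int(np.ceil(t1 / resolution)), nbins)
        for b in range(b0, b1):
            occupancy[b] += max(0.0, min(t1, edges[b + 1]) - max(t0, edges[b]))
    if valid_mask is None:
        valid = np.ones(nbins)
    else:
        valid = np.asarray(valid_mask, dtype=float)
        if valid.size != nbins:
            raise ValueError("valid_mask length must equal the number of bins")
    t_eff = valid * resolution
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(t_eff > 0, occupancy / (t_eff * volume), np.nan)
    return DensitySeries(edges[:-1], resolution, density, valid, occupancy,
                         volume, cluster)


def resample_density(series: DensitySeries, new_resolution: float) -> DensitySeries:
    """Aggregate to a coarser resolution (integer multiple of the native bin).

    Valid-time-weighted, so resampling commutes with computing the
    density at the coarse resolution directly.
    """
    factor = new_resolution / series.resolution
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError("new resolution must be an integer multiple of the native bin")
    m = int(round(factor))
    n = len(series.bin_start)
    ncoarse = int(np.ceil(n / m))
    pad = ncoarse * m - n
    occ = np.concatenate([series.occupancy, np.zeros(pad)]).reshape(ncoarse, m)
    vf = np.concatenate([series.valid_fraction, np.zeros(pad)]).reshape(ncoarse, m)
    occ_sum = occ.sum(axis=1)
    t_eff = vf.sum(axis=1) * series.resolution
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(t_eff > 0, occ_sum / (t_eff * series.probe_volume), np.nan)
    valid_fraction = vf.sum(axis=1) / m
    bin_start = series.bin_start[::m]
    return DensitySeries(bin_start, new_resolution, density, valid_fraction,
                         occ_sum, series.probe_volume, series.cluster)
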