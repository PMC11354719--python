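"""Stream and table I/O, pipeline configuration, and orchestration.

The raw stream container is a plain-text format: ``#``-prefixed header
lines carrying acquisition metadata followed by one voltage sample per
line.  Everything tabular (events, features, densities) moves as CSV so
runs remain auditable with standard tools.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import ClusterGate, assign_cluster, default_gates
from .density import DensitySeries, aerial_density
from .detect import (
    DetectionConfig,
    RawSignalSegment,
    detect_events,
    flag_invalid_intervals,
    label_events,
)
from .features import BeamGeometry, extract_features

__all__ = [
    "read_stream",
    "write_stream",
    "PipelineConfig",
    "RunLog",
    "run_pipeline",
    "features_to_frame",
]

log = logging.getLogger("wingbeam")

DEFAULT_SAMPLING_RATE = 30_517.0


# ---------------------------------------------------------------------------
# raw stream container
# ---------------------------------------------------------------------------

def write_stream(path: str | Path, segment: RawSignalSegment) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sampling_rate={segment.sampling_rate!r}\n")
        if segment.baseline_v0 is not None:
            fh.write(f"# baseline_v0={segment.baseline_v0!r}\n")
        fh.write(f"# start_time={segment.start_time!r}\n")
        fh.write(f"# n_samples={segment.samples.size}\n")
        np.savetxt(fh, segment.samples, fmt="%.9g")


def read_stream(path: str | Path) -> RawSignalSegment:
    """Load a raw stream; a missing sampling_rate header falls back to
    the instrument's 30,517 Hz digitiser rate with a warning, and a
    sample count disagreeing with the header is a hard error (no silent
    partial loads)."""
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            pos += len(line)
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
        fh.seek(pos)
        samples = np.loadtxt(fh, ndmin=1)
    if "sampling_rate" in meta:
        fs = float(meta["sampling_rate"])
    else:
        log.warning("stream %s lacks sampling_rate header; assuming %g Hz",
                    path, DEFAULT_SAMPLING_RATE)
        fs = DEFAULT_SAMPLING_RATE
    if "n_samples" in meta and int(meta["n_samples"]) != samples.size:
        raise ValueError(
            f"truncated stream {path}: header says {meta['n_samples']} samples, "
            f"found {samples.size}"
        )
    baseline = float(meta["baseline_v0"]) if "baseline_v0" in meta else None
    start = float(meta.get("start_time", 0.0))
    return RawSignalSegment(samples, fs, start_time=start, baseline_v0=baseline)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    geometry: BeamGeometry = field(default_factory=BeamGeometry)
    gates: tuple[ClusterGate, ...] = ()
    density_resolution: float = 60.0  # s, native bin of the density series
    rain_block: float = 60.0  # s, validity-mask block
    rain_saturation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_resolution <= 0 or self.rain_block <= 0:
            raise ValueError("time resolutions must be positive")

    def effective_gates(self) -> list[ClusterGate]:
        return list(self.gates) if self.gates else default_gates()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        det = DetectionConfig(**raw.get("detection", {}))
        geo = BeamGeometry(**raw.get("geometry", {}))
        gates = tuple(ClusterGate(**g) for g in raw.get("gates", []))
        return cls(
            detection=det,
            geometry=geo,
            gates=gates,
            density_resolution=float(raw.get("density_resolution", 60.0)),
            rain_block=float(raw.get("rain_block", 60.0)),
            rain_saturation=float(raw.get("rain_saturation", 0.5)),
            seed=int(raw.get("seed", 0)),
        )

    def digest(self) -> str:
        payload = json.dumps({
            "detection": vars(self.detection) | {},
            "geometry": {"beam_diameter": self.geometry.beam_diameter,
                         "path_length": self.geometry.path_length},
            "gates": [vars(g) | {} for g in self.effective_gates()],
            "density_resolution": self.density_resolution,
            "rain_block": self.rain_block,
            "rain_saturation": self.rain_saturation,
            "seed": self.seed,
        }, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunLog:
    """Per-stage tallies; counts must reconcile across stages."""

    n_raw_events: int = 0
    n_candidates: int = 0
    n_insect: int = 0
    n_non_insect: int = 0
    invalid_time_s: float = 0.0
    cluster_counts: dict[str, int] = field(default_factory=dict)
    config_digest: str = ""

    def check(self) -> None:
        if self.n_insect + self.n_non_insect != self.n_raw_events:
            raise AssertionError("label tallies do not reconcile with detections")


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def features_to_frame(features, clusters=None) -> pd.DataFrame:
    rows = [{
        "event_id": f.event_id,
        "start_time_s": f.start_time,
        "duration_s": f.duration,
        "fw_hz": f.fw,
        "sigma_w_m2": f.sigma_w,
        "sigma_b_m2": f.sigma_b,
        "ratio_wb": f.ratio_wb,
    } for f in features]
    df = pd.DataFrame(rows)
    if clusters is not None:
        df["cluster"] = clusters
    return df


def run_pipeline(
    segment: RawSignalSegment,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[pd.DataFrame, dict[str, DensitySeries], RunLog]:
    """Detect, discriminate, featurise, classify and bin one stream.

    Returns the per-event feature table (insect events only), density
    series per cluster plus ``all``, and a reconciled run log.  Fully
    deterministic given the segment and config.
    """
    events = detect_events(segment, config.detection)
    n_candidates = sum(1 for e in events if e.label == "candidate")
    label_events(events, config.detection)
    runlog = RunLog(
        n_raw_events=len(events),
        n_candidates=n_candidates,
        n_insect=sum(1 for e in events if e.label == "insect"),
        n_non_insect=sum(1 for e in events if e.label == "non_insect"),
        config_digest=config.digest(),
    )
    mask = flag_invalid_intervals(segment, events, config.rain_block,
                                  config.rain_saturation)
    runlog.invalid_time_s = float((~mask).sum()) * config.rain_block

    gates = config.effective_gates()
    insect_events = [e for e in events if e.label == "insect"]
    features = [extract_features(e, config.geometry, event_id=i)
                for i, e in enumerate(insect_events)]
    clusters = [assign_cluster(f, gates) for f in features]
    for c in clusters:
        runlog.cluster_counts[c] = runlog.cluster_counts.get(c, 0) + 1

    # density mask at the density resolution
    nbins = max(int(np.ceil(segment.duration / config.density_resolution)), 1)
    dmask = np.ones(nbins, dtype=bool)
    for b in range(nbins):
        lo = b * config.density_resolution
        hi = lo + config.density_resolution
        blocks = np.arange(int(lo // config.rain_block),
                           min(int(np.ceil(hi / config.rain_block)), mask.size))
        if blocks.size and not mask[blocks].all():
            dmask[b] = False

    volume = config.geometry.probe_volume
    series: dict[str, DensitySeries] = {
        "all": aerial_density(insect_events, segment.duration, volume,
                              config.density_resolution, dmask)
    }
    for name in sorted(set(clusters)):
        sub = [e for e, c in zip(insect_events, clusters) if c == name]
        series[name] = aerial_density(sub, segment.duration, volume,
                                      config.density_resolution, dmask,
                                      cluster=name)
    runlog.check()
    log.info("pipeline: %d events, %d insects, clusters=%s",
             runlog.n_raw_events, runlog.n_insect, runlog.cluster_counts)
    return features_to_frame(features, clusters), series, runlog
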