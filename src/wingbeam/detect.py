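"""Transit-event detection, duration filtering and insect discrimination.

The detector works on the transmitted-light voltage stream: a transit is
a contiguous run of samples falling below the slowly varying background
level ``V0`` by more than a noise-scaled threshold.  Runs shorter than
10 ms are discarded (too few wing cycles to analyse); runs approaching
1 s are kept but labelled non-insect.  A candidate is labelled an insect
only if, after removing the smooth body envelope, its spectrum shows a
prominent peak inside the insect wingbeat band (10-900 Hz by default) —
rain droplets and other smooth dips fail this test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks, get_window

__all__ = [
    "RawSignalSegment",
    "TransitEvent",
    "DetectionConfig",
    "estimate_baseline",
    "robust_noise_sd",
    "detect_events",
    "discriminate_insect",
    "label_events",
    "flag_invalid_intervals",
    "envelope_residual",
]


@dataclass
class RawSignalSegment:
    """A sampled voltage stream with acquisition metadata."""

    samples: np.ndarray  # volts
    sampling_rate: float  # Hz
    start_time: float = 0.0  # seconds since epoch (or stream-relative)
    baseline_v0: float | None = None  # nominal background; estimated if None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class TransitEvent:
    """One detected signal drop, half-open sample window [start, end)."""

    start_index: int
    end_index: int
    sampling_rate: float
    samples: np.ndarray
    baseline: np.ndarray  # per-sample background over the window
    label: str = "candidate"  # candidate | insect | non_insect
    valid: bool = True
    start_time: float = 0.0  # absolute start of the event, seconds

    @property
    def duration(self) -> float:
        return (self.end_index - self.start_index) / self.sampling_rate


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds and band limits for detection and discrimination."""

    threshold_k: float = 6.0  # drop threshold in robust noise SDs
    min_duration: float = 0.010  # s; shorter events are discarded
    max_duration: float = 1.0  # s; longer events labelled non_insect
    insect_band: tuple[float, float] = (10.0, 900.0)  # Hz
    # in-band peak over the noise-only bin magnitude; the envelope
    # residual of a smooth dip scores up to ~12 under noise, genuine
    # wing oscillations >= ~25 down to the optical detection limit
    band_power_ratio_min: float = 15.0
    bridge_gap: float = 0.002  # s; sub-threshold gaps bridged inside a transit
    min_threshold_v: float = 0.0  # optional absolute floor on the drop, volts
    extend_tails: bool = True  # widen bounds to the full occupancy of the dip

    def __post_init__(self) -> None:
        if not (0 < self.min_duration < self.max_duration):
            raise ValueError("require 0 < min_duration < max_duration")
        lo, hi = self.insect_band
        if not (0 < lo < hi):
            raise ValueError("insect band bounds must be positive, lower < upper")


# ---------------------------------------------------------------------------
# background level and noise
# ---------------------------------------------------------------------------

def estimate_baseline(
    segment: RawSignalSegment,
    window: float | None = None,
    max_event_duration: float = 1.0,
) -> np.ndarray:
    """Per-sample background estimate V0(t).

    Decimated rolling median: block medians (blocks of a quarter of the
    longest expected transit) smoothed by a rolling median spanning
    ``window`` seconds (default ten times the longest transit), then
    linearly interpolated back to sample resolution.  Transits occupy at
    most a few of the blocks inside the rolling window, so the median is
    unaffected by them while still tracking slow drift.
    """
    v = segment.samples
    if v.size < 16:
        raise ValueError("segment too short for baseline estimation")
    fs = segment.sampling_rate
    if window is None:
        window = 10.0 * max_event_duration
    block = max(int(round(max_event_duration * fs / 4.0)), 8)
    nblocks = int(np.ceil(v.size / block))
    if nblocks < 2:
        return np.full_like(v, float(np.median(v)))
    pads = nblocks * block - v.size
    padded = np.concatenate([v, np.full(pads, v[-1])]) if pads else v
    med = np.median(padded.reshape(nblocks, block), axis=1)
    span = max(int(round(window * fs / block)) | 1, 3)  # odd window, >= 3
    half = span // 2
    smoothed = np.empty_like(med)
    for i in range(nblocks):
        lo, hi = max(0, i - half), min(nblocks, i + half + 1)
        smoothed[i] = np.median(med[lo:hi])
    centers = (np.arange(nblocks) + 0.5) * block
    return np.interp(np.arange(v.size), centers, smoothed)


def robust_noise_sd(segment: RawSignalSegment) -> float:
    """Noise SD from the median absolute first difference.

    Insensitive to transits (which affect few samples' differences) and
    to slow drift; for white Gaussian noise E|diff| relates to sigma via
    the MAD constant and the sqrt(2) of differencing.
    """
    d = np.abs(np.diff(segment.samples))
    return float(1.4826 * np.median(d) / np.sqrt(2.0))


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True."""
    if not mask.any():
        return []
    starts = np.flatnonzero(mask & ~np.roll(mask, 1))
    if mask[0]:
        starts = np.unique(np.concatenate([[0], starts]))
    ends = np.flatnonzero(mask & ~np.roll(mask, -1)) + 1
    if mask[-1]:
        ends = np.unique(np.concatenate([ends, [mask.size]]))
    return list(zip(starts.tolist(), ends.tolist()))


def detect_events(
    segment: RawSignalSegment,
    config: DetectionConfig = DetectionConfig(),
    baseline: np.ndarray | None = None,
    noise_sd: float | None = None,
) -> list[TransitEvent]:
    """Locate candidate transits: runs below baseline - k * noise SD.

    Sub-threshold gaps shorter than ``bridge_gap`` are bridged so wing
    oscillations touching the baseline do not split one transit into
    several.  Events shorter than ``min_duration`` are discarded; events
    longer than ``max_duration`` are kept but labelled ``non_insect``.
    Simultaneous overlapping transits merge into a single run and are
    single-counted.
    """
    if segment.samples.size == 0:
        return []
    if baseline is None:
        baseline = estimate_baseline(segment, max_event_duration=config.max_duration)
    if noise_sd is None:
        noise_sd = robust_noise_sd(segment)
    fs = segment.sampling_rate
    thr = max(config.threshold_k * noise_sd, config.min_threshold_v)
    below = (baseline - segment.samples) > thr

    gap = int(round(config.bridge_gap * fs))
    spans = _runs(below)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s - merged[-1][1] <= gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    # a threshold crossing clips the soft tails of each dip; walk each
    # bound outward to where the (lightly smoothed) signal re-enters the
    # noise band so the event duration approximates the full occupancy
    # integral of the transit
    if not config.extend_tails:
        deep = np.zeros(segment.samples.size, dtype=bool)
    elif noise_sd > 0:
        smooth = gaussian_filter1d(segment.samples, max(0.0005 * fs, 1.0))
        deep = (baseline - smooth) > 0.3 * noise_sd
    else:
        deep = (baseline - segment.samples) > 0.0
    n = segment.samples.size
    extended: list[tuple[int, int]] = []
    for s, e in merged:
        limit = e - s  # never extend by more than the run itself
        s2 = s
        while s2 > max(0, s - limit) and deep[s2 - 1]:
            s2 -= 1
        e2 = e
        while e2 < min(n, e + limit) and deep[e2]:
            e2 += 1
        if extended and s2 <= extended[-1][1]:
            extended[-1] = (extended[-1][0], max(e2, extended[-1][1]))
        else:
            extended.append((s2, e2))
    merged = extended

    events: list[TransitEvent] = []
    for s, e in merged:
        dur = (e - s) / fs
        if dur < config.min_duration:
            continue
        label = "non_insect" if dur > config.max_duration else "candidate"
        events.append(
            TransitEvent(
                start_index=int(s),
                end_index=int(e),
                sampling_rate=fs,
                samples=segment.samples[s:e].copy(),
                baseline=baseline[s:e].copy(),
                label=label,
                start_time=segment.start_time + s / fs,
            )
        )
    return events


# ---------------------------------------------------------------------------
# insect / non-insect discrimination
# ---------------------------------------------------------------------------

def upper_envelope(window: np.ndarray, fs: float,
                   min_period: float | None = None) -> tuple[np.ndarray, int]:
    """Smooth upper envelope through the local voltage maxima.

    The local maxima of the transmitted voltage are the between-wingbeat
    instants where wing extinction vanishes; PCHIP interpolation through
    them (plus the window endpoints) tracks the body-only level.
    Returns ``(envelope, n_interior_anchors)``; a window without interior
    local maxima (a smooth dip) gets the straight chord and 0 anchors.
    """
    n = window.size
    if n < 4 or np.ptp(window) == 0:
        return window.copy(), 0
    if min_period is None:
        min_period = 1.0 / 900.0  # shortest insect wingbeat period
    dist = max(int(round(0.8 * min_period * fs)), 1)
    peaks, _ = find_peaks(window, distance=dist)
    anchors = np.unique(np.concatenate([[0], peaks, [n - 1]]))
    env = PchipInterpolator(anchors, window[anchors])(np.arange(n))
    return env, int(peaks.size)


def envelope_residual(window: np.ndarray, fs: float,
                      min_period: float | None = None) -> np.ndarray:
    """Oscillatory residual: upper envelope minus window.

    Isolates the wing oscillation from the smooth body dip; for a smooth
    dip (droplet) with noise, the envelope hugs the signal and the
    residual carries noise only.
    """
    env, _ = upper_envelope(window, fs, min_period)
    return env - window


def spectral_noise_floor(window: np.ndarray, taper: np.ndarray) -> float:
    """Expected magnitude of a noise-only rFFT bin for this window/taper.

    The sample noise SD comes from the median absolute first difference
    (robust to both the body dip and the wing oscillation); a white-noise
    bin magnitude is Rayleigh with mean sigma * sqrt(pi/2 * sum(w^2)/2).
    """
    sd = 1.4826 * float(np.median(np.abs(np.diff(window)))) / np.sqrt(2.0)
    return sd * np.sqrt(np.pi / 4.0 * float(np.sum(taper**2)))


def _band_peak(residual: np.ndarray, fs: float, band: tuple[float, float],
               noise_floor: float) -> tuple[float, float]:
    """(peak magnitude / noise floor, peak frequency) inside the band.

    Only genuine in-band local maxima count: the decaying low-frequency
    edge of a smooth dip's spectrum is not a peak.
    """
    n = residual.size
    nfft = int(2 ** np.ceil(np.log2(max(8 * n, 64))))
    w = get_window("hann", n)
    spec = np.abs(np.fft.rfft((residual - residual.mean()) * w, nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any() or noise_floor <= 0:
        return 0.0, 0.0
    mag = spec[sel]
    min_sep = max(int(round(fs / n / (freqs[1] - freqs[0]))), 1)
    peaks, _ = find_peaks(mag, distance=min_sep)
    if peaks.size == 0:
        return 0.0, 0.0
    i = peaks[np.argmax(mag[peaks])]
    return float(mag[i] / noise_floor), float(freqs[sel][i])


def discriminate_insect(
    event: TransitEvent, config: DetectionConfig = DetectionConfig()
) -> str:
    """Label one candidate event ``insect`` or ``non_insect``.

    Insect criterion: the window shows at least three between-beat
    envelope anchors (i.e., resolvable oscillation cycles) and the
    envelope-detrended spectrum has an in-band peak exceeding
    ``band_power_ratio_min`` times the expected noise-only bin magnitude.
    Smooth dips (rain droplets, leaves) fail the anchor count or the
    peak test; degenerate flat windows are non-insect.
    """
    w = event.samples
    if w.size < 8 or np.ptp(w) == 0:
        return "non_insect"
    env, n_anchors = upper_envelope(w, event.sampling_rate,
                                    min_period=1.0 / config.insect_band[1])
    if n_anchors < 3:
        return "non_insect"
    residual = env - w
    taper = get_window("hann", w.size)
    floor = spectral_noise_floor(w, taper)
    if floor <= 0:
        return "non_insect"
    ratio, _ = _band_peak(residual, event.sampling_rate, config.insect_band, floor)
    return "insect" if ratio >= config.band_power_ratio_min else "non_insect"


def label_events(
    events: list[TransitEvent], config: DetectionConfig = DetectionConfig()
) -> list[TransitEvent]:
    """Apply insect discrimination to every still-candidate event in place."""
    for ev in events:
        if ev.label == "candidate":
            ev.label = discriminate_insect(ev, config)
    return events


# ---------------------------------------------------------------------------
# valid-time accounting (heavy rain)
# ---------------------------------------------------------------------------

def flag_invalid_intervals(
    segment: RawSignalSegment,
    events: list[TransitEvent] | None = None,
    block_duration: float = 60.0,
    saturation: float = 0.5,
    config: DetectionConfig = DetectionConfig(),
    baseline: np.ndarray | None = None,
    noise_sd: float | None = None,
) -> np.ndarray:
    """Boolean validity mask over fixed blocks of the stream.

    During heavy rain a continuous stream of droplets keeps the signal
    away from its background level and insect transits cannot be
    identified.  A block is invalid when the fraction of its samples
    perturbed away from the estimated background (|V - V0| beyond the
    detection threshold, two-sided because continuous rain also drags
    the background estimate itself into the droplet level) exceeds
    ``saturation`` — raw sample occupancy rather than retained-event
    occupancy, because rain dips are mostly shorter than the event
    duration filter and would otherwise go unaccounted.  ``events``, if
    given, contribute their spans as well (so long saturating artefacts
    count fully).  Returns one bool per block (True = valid).
    """
    n = segment.samples.size
    fs = segment.sampling_rate
    nblocks = max(int(np.ceil(segment.duration / block_duration)), 1)
    if baseline is None:
        baseline = estimate_baseline(segment, max_event_duration=config.max_duration)
    if noise_sd is None:
        noise_sd = robust_noise_sd(segment)
    thr = max(config.threshold_k * noise_sd, config.min_threshold_v)
    below = np.abs(baseline - segment.samples) > thr
    if events:
        for ev in events:
            below[ev.start_index:ev.end_index] = True
    block = int(round(block_duration * fs))
    occupancy = np.empty(nblocks)
    for b in range(nblocks):
        chunk = below[b * block:(b + 1) * block]
        occupancy[b] = chunk.mean() if chunk.size else 0.0
    return occupancy <= saturation
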