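"""Synthetic transit-signal generator with exact ground truth.

A bistatic optical sensor records the light transmitted across an open-air
laser beam.  An insect crossing the beam removes light (scattering,
diffraction, absorption), producing a transient drop in the detector
voltage — a *transit signal* — on which the wingbeat superimposes a
harmonic-rich oscillation.  This module synthesises such signals from
known parameters so that every downstream stage (detection, wing/body
separation, frequency estimation, density estimation) can be tested
against exact ground truth.

Model
-----
A transit of duration ``D`` centred at ``tc`` is

    V(t) = V0 - Db * g(t) - Dw * g(t) * p(t)

where ``g`` is a Gaussian bump truncated at +/-3 sigma (sigma = D/6,
unit peak), ``Db``/``Dw`` are the peak body and wing extinction depths in
volts, and ``p`` is a non-negative periodic pulse train at the wingbeat
frequency ``fw`` built from ``n_harmonics`` cosine harmonics with 1/k
amplitudes, normalised to [0, 1] so it touches zero exactly once per
wingbeat period.  The zero-touching instants are the between-beat moments
at which the full signal equals the body-only signal; the separation
stage exploits exactly this structure, as does the real instrument.

Rain droplets are wingless transits (``Dw = 0``, ``fw = 0``): smooth dips
with no spectral content in the insect band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

__all__ = [
    "TransitParams",
    "StreamScenario",
    "LedgerEntry",
    "GroundTruthLedger",
    "simulate_transit",
    "simulate_stream",
    "simulate_season",
    "wing_depth_for_ratio",
    "true_transit_levels",
]

DEFAULT_SAMPLING_RATE = 30_517.0  # Hz, the instrument's digitiser rate
DEFAULT_BASELINE_V0 = 3.0  # V, detector background level (3 V digitiser range)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitParams:
    """Ground-truth parameters of a single beam transit.

    ``body_depth`` is the peak voltage drop attributable to the body,
    ``wing_depth`` the additional peak drop of the wing oscillation.
    ``wingbeat_freq = 0`` together with ``wing_depth = 0`` produces a
    wingless event (droplet, leaf, large pollen grain).
    """

    start_time: float  # s, within the parent stream
    duration: float  # s
    wingbeat_freq: float = 0.0  # Hz; 0 = wingless
    body_depth: float = 0.3  # V
    wing_depth: float = 0.0  # V
    n_harmonics: int = 4
    is_insect: bool = True

    def validate(self, baseline: float) -> None:
        if not (self.duration > 0):
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.body_depth < 0 or self.wing_depth < 0:
            raise ValueError("extinction depths must be non-negative")
        if self.wingbeat_freq < 0:
            raise ValueError("wingbeat frequency must be non-negative")
        if self.body_depth + self.wing_depth >= baseline:
            raise ValueError(
                "total extinction depth "
                f"{self.body_depth + self.wing_depth:g} V must stay below "
                f"the baseline {baseline:g} V"
            )
        if self.wing_depth > 0 and self.wingbeat_freq <= 0:
            raise ValueError("wing_depth > 0 requires wingbeat_freq > 0")


@dataclass(frozen=True)
class StreamScenario:
    """Recipe for one synthetic raw stream.

    Either supply an explicit ``events`` list or an ``event_rate``
    (events/s, Poisson-scheduled).  ``overlap_probability`` is the chance
    that a scheduled insect event receives a second, overlapping transit
    (field data show roughly one overlap per 800 events).
    """

    duration: float  # s
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    baseline_v0: float = DEFAULT_BASELINE_V0
    noise_sd: float = 0.0  # V, additive white Gaussian
    events: tuple[TransitParams, ...] = ()
    event_rate: float | None = None  # events/s, alternative to `events`
    rain_mode: str = "none"  # none | light | heavy
    overlap_probability: float = 1.0 / 800.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError("stream duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.rain_mode not in ("none", "light", "heavy"):
            raise ValueError(f"unknown rain_mode {self.rain_mode!r}")
        fmax = max(
            (e.wingbeat_freq * max(e.n_harmonics, 1) for e in self.events),
            default=0.0,
        )
        if fmax and self.sampling_rate <= 2 * fmax:
            raise ValueError("sampling rate below Nyquist for scheduled events")
        for ev in self.events:
            ev.validate(self.baseline_v0)
            if ev.start_time < 0 or ev.start_time + ev.duration > self.duration:
                raise ValueError(
                    f"event at t={ev.start_time:g}s extends past the stream end"
                )


@dataclass(frozen=True)
class LedgerEntry:
    """One injected event with its exact true feature values."""

    params: TransitParams
    start_index: int
    end_index: int  # half-open
    sigma_w: float  # m^2
    sigma_b: float  # m^2
    ratio_wb: float
    overlapped: bool = False


@dataclass
class GroundTruthLedger:
    entries: list[LedgerEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def insects(self) -> list[LedgerEntry]:
        return [e for e in self.entries if e.params.is_insect]


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

@lru_cache(maxsize=16)
def _pulse_train_bounds(n_harmonics: int) -> tuple[float, float]:
    """Min/max over one period of sum_{k<=n} cos(2 pi k x)/k (dense grid)."""
    x = np.linspace(0.0, 1.0, 8192, endpoint=False)
    k = np.arange(1, n_harmonics + 1)
    s = np.cos(2 * np.pi * np.outer(x, k)) @ (1.0 / k)
    return float(s.min()), float(s.max())


def _wing_pulse(t: np.ndarray, fw: float, n_harmonics: int) -> np.ndarray:
    """Normalised non-negative pulse train in [0, 1], zero between beats."""
    k = np.arange(1, n_harmonics + 1)
    s = np.cos(2 * np.pi * fw * np.outer(t, k)) @ (1.0 / k)
    lo, hi = _pulse_train_bounds(n_harmonics)
    # the grid-estimated minimum can sit a hair above the continuous one;
    # clip so the pulse train is exactly non-negative
    return np.maximum((s - lo) / (hi - lo), 0.0)


def _body_bump(t: np.ndarray, tc: float, duration: float) -> np.ndarray:
    """Unit-peak Gaussian bump truncated at +/-3 sigma (support = duration)."""
    sigma = duration / 6.0
    g = np.exp(-0.5 * ((t - tc) / sigma) ** 2)
    g[np.abs(t - tc) > 3 * sigma] = 0.0
    return g


def simulate_transit(
    params: TransitParams,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    baseline: float = DEFAULT_BASELINE_V0,
) -> np.ndarray:
    """Noise-free sampled voltage window of a single transit.

    The window spans exactly ``params.duration`` starting at the first
    sample at or after ``params.start_time`` (times are relative to the
    window itself when used standalone; pass ``start_time=0``).
    """
    params.validate(baseline)
    n = max(int(round(params.duration * sampling_rate)), 2)
    t = np.arange(n) / sampling_rate
    tc = params.duration / 2.0
    body, wing = transit_components(params, t, tc)
    return baseline - body - wing


def transit_components(
    params: TransitParams, t: np.ndarray, tc: float
) -> tuple[np.ndarray, np.ndarray]:
    """True (body, wing) extinction series in volts at sample times ``t``."""
    g = _body_bump(t, tc, params.duration)
    body = params.body_depth * g
    if params.wing_depth > 0 and params.wingbeat_freq > 0:
        wing = params.wing_depth * g * _wing_pulse(t - tc, params.wingbeat_freq, params.n_harmonics)
    else:
        wing = np.zeros_like(t)
    return body, wing


# ---------------------------------------------------------------------------
# ground-truth feature values
# ---------------------------------------------------------------------------

def _lowest_fraction_mean(values: np.ndarray, frac: float = 0.1) -> float:
    n = max(1, math.ceil(frac * values.size))
    return float(np.mean(np.sort(values)[:n]))


def true_transit_levels(
    params: TransitParams,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    baseline: float = DEFAULT_BASELINE_V0,
) -> tuple[float, float]:
    """Exact (Vw, VB): mean of the 10% lowest values of the wing-only and
    body-only voltage signals, computed from the noise-free components."""
    n = max(int(round(params.duration * sampling_rate)), 2)
    t = np.arange(n) / sampling_rate
    body, wing = transit_components(params, t, params.duration / 2.0)
    vb = _lowest_fraction_mean(baseline - body)
    vw = _lowest_fraction_mean(baseline - wing)
    return vw, vb


def wing_depth_for_ratio(
    ratio: float,
    body_depth: float,
    duration: float,
    wingbeat_freq: float,
    n_harmonics: int = 4,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> float:
    """Peak wing depth giving an exact true wing-to-body ratio.

    The wing-to-body ratio sigma_w / (sigma_w + sigma_b) is computed from
    the 10%-lowest-value levels of the separated signals; both levels
    scale linearly in their peak depths, so the required wing depth
    follows from the two waveform shape factors.
    """
    if not (0 <= ratio < 1):
        raise ValueError("ratio must lie in [0, 1)")
    if ratio == 0:
        return 0.0
    n = max(int(round(duration * sampling_rate)), 2)
    t = np.arange(n) / sampling_rate
    tc = duration / 2.0
    g = _body_bump(t, tc, duration)
    c_body = -_lowest_fraction_mean(-g)  # mean of the 10% largest
    pulse = g * _wing_pulse(t - tc, wingbeat_freq, n_harmonics)
    c_wing = -_lowest_fraction_mean(-pulse)
    # sigma_w / sigma_b = ratio/(1-ratio)  =>  Dw*c_wing = Db*c_body*ratio/(1-ratio)
    return body_depth * c_body * ratio / ((1.0 - ratio) * c_wing)


# ---------------------------------------------------------------------------
# stream assembly
# ---------------------------------------------------------------------------

# droplets per second; "heavy" overlaps droplets into a continuous
# perturbation of the received signal
_RAIN_RATES = {"none": 0.0, "light": 3.0, "heavy": 400.0}


def _schedule_random_events(
    scenario: StreamScenario, rng: np.random.Generator
) -> list[TransitParams]:
    """Poisson-schedule insect events at ``event_rate`` with field-like
    mosquito parameters; a fraction ``overlap_probability`` get a second
    transit on top."""
    n = rng.poisson(scenario.event_rate * scenario.duration)
    events: list[TransitParams] = []
    for _ in range(n):
        duration = float(np.clip(rng.normal(0.1, 0.02), 0.03, 0.4))
        start = float(rng.uniform(0.0, scenario.duration - duration))
        fw = float(np.clip(rng.uniform(150.0, 700.0), 10.0, None))
        body = float(rng.uniform(0.1, 0.5))
        wing = wing_depth_for_ratio(
            float(rng.uniform(0.1, 0.4)), body, duration, fw,
            sampling_rate=scenario.sampling_rate,
        )
        events.append(
            TransitParams(start, duration, fw, body, wing, is_insect=True)
        )
    return events


def simulate_stream(
    scenario: StreamScenario,
) -> tuple["RawSignalSegment", GroundTruthLedger]:
    """Render a full raw stream plus its exact event ledger.

    All randomness (scheduling, overlaps, rain, noise) derives from
    ``scenario.seed``; identical scenarios produce bit-identical streams.
    """
    from .detect import RawSignalSegment  # container lives with detection

    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    fs = scenario.sampling_rate
    n = int(round(scenario.duration * fs))
    v = np.full(n, scenario.baseline_v0)

    events = list(scenario.events)
    if scenario.event_rate is not None:
        events.extend(_schedule_random_events(scenario, rng))

    # mark overlaps: each scheduled insect event may receive a companion
    overlapped_flags = [False] * len(events)
    extra: list[TransitParams] = []
    for i, ev in enumerate(events):
        if ev.is_insect and rng.random() < scenario.overlap_probability:
            shift = float(rng.uniform(-0.3, 0.3)) * ev.duration
            start = float(np.clip(ev.start_time + shift, 0.0,
                                  scenario.duration - ev.duration))
            extra.append(replace(ev, start_time=start))
            overlapped_flags[i] = True
    events.extend(extra)
    overlapped_flags.extend([True] * len(extra))

    # rain droplets: short smooth wingless dips
    rate = _RAIN_RATES[scenario.rain_mode]
    if rate > 0:
        n_drops = rng.poisson(rate * scenario.duration)
        for _ in range(n_drops):
            duration = float(rng.uniform(0.002, 0.008))
            start = float(rng.uniform(0.0, scenario.duration - duration))
            depth = float(rng.uniform(0.05, 0.4))
            events.append(TransitParams(start, duration, 0.0, depth, 0.0,
                                        is_insect=False))
            overlapped_flags.append(False)

    ledger = GroundTruthLedger()
    for ev, over in zip(events, overlapped_flags):
        ev.validate(scenario.baseline_v0)
        i0 = int(round(ev.start_time * fs))
        i1 = min(i0 + max(int(round(ev.duration * fs)), 2), n)
        t = np.arange(i0, i1) / fs - ev.start_time
        body, wing = transit_components(ev, t, ev.duration / 2.0)
        v[i0:i1] -= body + wing
        vw, vb = true_transit_levels(ev, fs, scenario.baseline_v0)
        from .features import extinction_cross_sections, wing_body_ratio, BeamGeometry
        sw, sb = extinction_cross_sections(vw, vb, scenario.baseline_v0,
                                           BeamGeometry())
        ratio = wing_body_ratio(sw, sb) if (sw + sb) > 0 else 0.0
        ledger.entries.append(
            LedgerEntry(ev, i0, i1, sw, sb, ratio, overlapped=over)
        )

    if scenario.noise_sd > 0:
        v = v + rng.normal(0.0, scenario.noise_sd, size=n)

    segment = RawSignalSegment(
        samples=v,
        sampling_rate=fs,
        start_time=0.0,
        baseline_v0=scenario.baseline_v0,
    )
    return segment, ledger


# ---------------------------------------------------------------------------
# seasonal abundance
# ---------------------------------------------------------------------------

def simulate_season(model, days: int, seed: int = 0):
    """Daily abundance series from an exponential-cubic seasonal trend.

    The expected abundance on day ``t`` (1-based day of season) is
    ``exp(b0 + b1*t + b2*t^2)``; realised values are drawn from the
    model's error family (negative binomial for counts, lognormal for
    densities).  Returns a pandas DataFrame with columns ``day``,
    ``expected`` and ``value``.
    """
    import pandas as pd
    from .power import SeasonalModel  # noqa: F401 — type lives with the fitters

    if days < 1:
        raise ValueError("days must be >= 1")
    b0, b1, b2 = model.beta
    if not np.all(np.isfinite([b0, b1, b2])):
        raise ValueError("seasonal coefficients must be finite")
    rng = np.random.default_rng(seed)
    t = np.arange(1, days + 1, dtype=float)
    mu = np.exp(b0 + b1 * t + b2 * t * t)
    value = model.draw(mu, rng)
    return pd.DataFrame({"day": t.astype(int), "expected": mu, "value": value})
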