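"""Event detection: baseline tracking, thresholding, duration filtering,
insect discrimination and rain handling."""

import numpy as np
import pytest

import wingbeam as wb
from wingbeam.detect import RawSignalSegment

from conftest import FS, V0, make_transit, single_event_stream


def brute_force_events(samples, baseline, threshold, fs, bridge_gap,
                       min_duration):
    """Plain-Python reference scan: sub-threshold runs, gap bridging,
    duration filter."""
    below = [(baseline[i] - samples[i]) > threshold for i in range(len(samples))]
    runs = []
    i = 0
    while i < len(samples):
        if below[i]:
            j = i
            while j < len(samples) and below[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    gap = int(round(bridge_gap * fs))
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if (e - s) / fs >= min_duration]


class TestBaseline:
    def test_constant_stream(self):
        seg = RawSignalSegment(np.full(100_000, 3.0), FS)
        assert np.allclose(wb.estimate_baseline(seg), 3.0)

    def test_baseline_unaffected_by_transit(self):
        seg, _ = single_event_stream(make_transit(fw=0.0, duration=0.1,
                                                  body=0.5, wing=None),
                                     stream_duration=4.0, noise_sd=0.0)
        base = wb.estimate_baseline(seg)
        # inside the dip the baseline stays at the background level
        i0 = int(0.2 * FS)
        assert np.all(np.abs(base[i0:i0 + int(0.1 * FS)] - V0) < 0.01 * V0)

    def test_baseline_tracks_linear_drift(self):
        n = int(60 * FS / 10)  # 6 s at decimated cost
        drift = np.linspace(3.0, 3.1, n)
        rng = np.random.default_rng(0)
        seg = RawSignalSegment(drift + rng.normal(0, 0.003, n), FS)
        base = wb.estimate_baseline(seg, window=1.0)
        core = slice(n // 10, -n // 10)
        assert np.max(np.abs(base[core] - drift[core])) < 0.01

    def test_too_short_segment_raises(self):
        with pytest.raises(ValueError):
            wb.estimate_baseline(RawSignalSegment(np.ones(8), FS))


class TestDetectEvents:
    def test_flat_stream_has_no_events(self):
        seg = RawSignalSegment(np.full(50_000, 3.0), FS)
        assert wb.detect_events(seg) == []

    def test_empty_segment(self):
        seg = RawSignalSegment(np.array([]), FS)
        assert wb.detect_events(seg) == []

    def test_single_dip_bounds_match_ground_truth(self):
        seg, truth = single_event_stream(make_transit(fw=300.0, duration=0.1,
                                                      ratio=0.2),
                                         noise_sd=0.0, stream_duration=2.0)
        events = wb.detect_events(seg)
        assert len(events) == 1
        t = truth.entries[0]
        assert abs(events[0].start_index - t.start_index) / FS <= 0.001
        assert abs(events[0].end_index - t.end_index) / FS <= 0.001

    def test_sub_10ms_event_discarded(self):
        seg, _ = single_event_stream(make_transit(fw=500.0, duration=0.008,
                                                  ratio=0.2),
                                     noise_sd=0.0, stream_duration=2.0)
        assert wb.detect_events(seg) == []

    def test_overlong_event_labelled_non_insect(self):
        seg, _ = single_event_stream(
            make_transit(fw=300.0, duration=1.4, ratio=0.2),
            noise_sd=0.0, stream_duration=4.0, start=1.0)
        events = wb.detect_events(seg, wb.DetectionConfig(max_duration=1.0))
        assert len(events) == 1
        assert events[0].label == "non_insect"

    def test_matches_brute_force_scan(self):
        """On a short noisy stream with several dips the sub-threshold run
        set equals an independently coded plain-Python scan exactly, and
        tail extension only widens those runs."""
        rng = np.random.default_rng(5)
        n = 90_000
        noise_sd = 0.004
        samples = np.full(n, V0) + rng.normal(0, noise_sd, n)
        for start, dur in [(0.3, 0.05), (1.1, 0.02), (1.9, 0.3), (2.6, 0.012)]:
            i0, i1 = int(start * FS), int((start + dur) * FS)
            t = np.linspace(-3, 3, i1 - i0)
            samples[i0:i1] -= 0.25 * np.exp(-0.5 * t**2)
        seg = RawSignalSegment(samples, FS)
        cfg = wb.DetectionConfig(extend_tails=False)
        baseline = np.full(n, V0)
        got = wb.detect_events(seg, cfg, baseline=baseline, noise_sd=noise_sd)
        want = brute_force_events(samples, baseline,
                                  cfg.threshold_k * noise_sd, FS,
                                  cfg.bridge_gap, cfg.min_duration)
        assert [(ev.start_index, ev.end_index) for ev in got] == want
        wide = wb.detect_events(seg, wb.DetectionConfig(), baseline=baseline,
                                noise_sd=noise_sd)
        for s, e in want:
            assert any(ev.start_index <= s and ev.end_index >= e
                       for ev in wide)

    def test_lowering_threshold_never_loses_candidates(self):
        rng = np.random.default_rng(2)
        n = 60_000
        samples = np.full(n, V0) + rng.normal(0, 0.005, n)
        for start in (0.2, 0.8, 1.4):
            i0 = int(start * FS)
            i1 = i0 + int(0.05 * FS)
            t = np.linspace(-3, 3, i1 - i0)
            samples[i0:i1] -= rng.uniform(0.05, 0.3) * np.exp(-0.5 * t**2)
        seg = RawSignalSegment(samples, FS)
        counts = [
            len(wb.detect_events(seg, wb.DetectionConfig(threshold_k=k)))
            for k in (12.0, 9.0, 6.0, 4.0)
        ]
        assert counts == sorted(counts)

    def test_overlapping_transits_single_counted(self):
        a = wb.TransitParams(1.00, 0.1, 300.0, 0.3, 0.06)
        b = wb.TransitParams(1.03, 0.1, 500.0, 0.25, 0.05)
        sc = wb.StreamScenario(duration=3.0, events=(a, b), noise_sd=0.003,
                               overlap_probability=0.0, seed=0)
        seg, _ = wb.simulate_stream(sc)
        assert len(wb.detect_events(seg)) == 1


class TestDiscrimination:
    def test_droplet_is_non_insect(self):
        seg, _ = single_event_stream(make_transit(fw=0.0, duration=0.05,
                                                  body=0.3, wing=None),
                                     noise_sd=0.005, stream_duration=1.0)
        events = wb.label_events(wb.detect_events(seg))
        assert len(events) == 1
        assert events[0].label == "non_insect"

    def test_low_frequency_insect_detected(self):
        seg, _ = single_event_stream(make_transit(fw=200.0, duration=0.1,
                                                  ratio=0.3),
                                     noise_sd=0.005)
        events = wb.label_events(wb.detect_events(seg))
        assert [e.label for e in events] == ["insect"]

    def test_out_of_band_oscillation_rejected(self):
        cfg = wb.DetectionConfig(insect_band=(10.0, 900.0))
        seg, _ = single_event_stream(make_transit(fw=950.0, duration=0.1,
                                                  ratio=0.3),
                                     noise_sd=0.005)
        events = wb.label_events(wb.detect_events(seg, cfg), cfg)
        assert all(e.label == "non_insect" for e in events)

    def test_degenerate_flat_window_non_insect(self):
        ev = wb.TransitEvent(0, 400, FS, np.full(400, 2.5), np.full(400, 3.0))
        assert wb.discriminate_insect(ev) == "non_insect"


class TestRainHandling:
    def test_no_rain_fully_valid(self):
        sc = wb.StreamScenario(duration=10.0, noise_sd=0.005, seed=0)
        seg, _ = wb.simulate_stream(sc)
        events = wb.detect_events(seg)
        mask = wb.flag_invalid_intervals(seg, events, block_duration=10.0)
        assert mask.all()

    def test_heavy_rain_interval_invalid(self):
        sc = wb.StreamScenario(duration=10.0, noise_sd=0.005,
                               rain_mode="heavy", seed=3)
        seg, _ = wb.simulate_stream(sc)
        events = wb.detect_events(seg)
        mask = wb.flag_invalid_intervals(seg, events, block_duration=10.0)
        assert not mask.any()

    def test_light_rain_valid_and_droplets_rejected(self):
        sc = wb.StreamScenario(duration=10.0, noise_sd=0.005,
                               rain_mode="light", seed=4)
        seg, ledger = wb.simulate_stream(sc)
        events = wb.label_events(wb.detect_events(seg))
        mask = wb.flag_invalid_intervals(seg, events, block_duration=10.0)
        assert mask.all()
        assert all(e.label == "non_insect" for e in events)
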