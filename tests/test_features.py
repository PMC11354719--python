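"""Per-event feature extraction: wing/body separation, transit levels,
extinction cross-sections and wingbeat frequency."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wingbeam as wb
from wingbeam.simulate import transit_components

from conftest import FS, V0, make_transit


class TestSeparation:
    def test_wingless_event_has_zero_wing_component(self):
        p = make_transit(fw=0.0, wing=0.0, body=0.3)
        v = wb.simulate_transit(p, FS, V0)
        env, wing, degenerate = wb.separate_wing_body(v, FS)
        assert degenerate  # no oscillation to separate
        assert np.allclose(wing, 0.0)
        assert np.allclose(env, v)

    def test_recovers_injected_body_envelope(self):
        p = make_transit(fw=400.0, duration=0.1, ratio=0.25)
        v = wb.simulate_transit(p, FS, V0)
        env, wing, degenerate = wb.separate_wing_body(v, FS, fw=400.0)
        assert not degenerate
        t = np.arange(v.size) / FS
        body_true, _ = transit_components(p, t, 0.05)
        core = slice(int(0.02 * FS), int(0.08 * FS))
        rel = np.abs((V0 - env[core]) - body_true[core]) / body_true[core].max()
        assert np.max(rel) < 0.02  # within 2% of injected envelope

    def test_reconstruction_is_exact(self):
        p = make_transit(fw=300.0, duration=0.08, ratio=0.3)
        rng = np.random.default_rng(0)
        v = wb.simulate_transit(p, FS, V0) + rng.normal(0, 0.004, 2441)
        env, wing, _ = wb.separate_wing_body(v, FS, fw=300.0)
        assert np.allclose(env - wing, v, atol=0, rtol=0)

    def test_too_few_cycles_flagged_degenerate(self):
        p = make_transit(fw=100.0, duration=0.02, ratio=0.3)
        v = wb.simulate_transit(p, FS, V0)
        _, _, degenerate = wb.separate_wing_body(v, FS, fw=100.0)
        assert degenerate


class TestTransitLevels:
    def test_constant_dip_level_exact(self):
        w = np.full(1000, 2.7)
        vw, vb = wb.transit_levels(w, w, np.zeros_like(w), V0)
        assert vb == pytest.approx(2.7, abs=1e-12)
        assert vw == pytest.approx(V0, abs=1e-12)  # no wing contribution

    @given(st.integers(10, 400), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_sort_and_average_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        env = V0 - rng.uniform(0, 0.5, n)
        wing = rng.uniform(0, 0.3, n)
        window = env - wing
        vw, vb = wb.transit_levels(window, env, wing, V0)
        k = max(1, math.ceil(0.1 * n))
        assert vb == pytest.approx(np.mean(sorted(env)[:k]), abs=1e-12)
        assert vw == pytest.approx(np.mean(sorted(V0 - wing)[:k]), abs=1e-12)

    def test_window_shorter_than_10_samples_raises(self):
        w = np.full(5, 2.5)
        with pytest.raises(ValueError):
            wb.transit_levels(w, w, np.zeros(5), V0)


class TestCrossSections:
    A = math.pi * 0.0254**2  # beam area for the default 50.8 mm diameter

    def test_no_extinction_gives_zero(self, geometry):
        sw, sb = wb.extinction_cross_sections(V0, V0, V0, geometry)
        assert sw == 0.0 and sb == 0.0

    def test_hand_evaluated_body_cross_section(self, geometry):
        # (3.0 - 2.7)/3.0 * A = 0.1 * A
        _, sb = wb.extinction_cross_sections(3.0, 2.7, 3.0, geometry)
        assert sb == pytest.approx(0.1 * self.A, abs=1e-12)

    def test_hand_evaluated_wing_cross_section(self, geometry):
        sw, _ = wb.extinction_cross_sections(2.4, 3.0, 3.0, geometry)
        assert sw == pytest.approx(0.2 * self.A, abs=1e-12)

    def test_linearity_in_relative_drop(self, geometry):
        _, sb1 = wb.extinction_cross_sections(3.0, 2.85, 3.0, geometry)
        _, sb2 = wb.extinction_cross_sections(3.0, 2.70, 3.0, geometry)
        assert sb2 == pytest.approx(2.0 * sb1, rel=1e-12)

    def test_level_above_background_clamped_with_warning(self, geometry):
        with pytest.warns(UserWarning, match="clamped"):
            sw, _ = wb.extinction_cross_sections(3.1, 2.9, 3.0, geometry)
        assert sw == 0.0

    def test_non_positive_background_rejected(self, geometry):
        with pytest.raises(ValueError):
            wb.extinction_cross_sections(2.0, 2.0, 0.0, geometry)


class TestWingBodyRatio:
    def test_zero_wing_gives_zero(self):
        assert wb.wing_body_ratio(0.0, 1e-4) == 0.0

    def test_symmetry_gives_half(self):
        assert wb.wing_body_ratio(3e-4, 3e-4) == pytest.approx(0.5, abs=1e-12)

    def test_hand_value(self):
        assert wb.wing_body_ratio(2e-4, 6e-4) == pytest.approx(0.25, abs=1e-12)

    def test_both_zero_undefined(self):
        assert math.isnan(wb.wing_body_ratio(0.0, 0.0))

    @given(st.floats(0, 1e-2, allow_nan=False),
           st.floats(1e-12, 1e-2, allow_nan=False))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_in_unit_interval(self, sw, sb):
        r = wb.wing_body_ratio(sw, sb)
        assert 0.0 <= r <= 1.0


class TestWingbeatFrequency:
    def test_500hz_within_spectral_resolution(self):
        p = make_transit(fw=500.0, duration=0.1, ratio=0.2)
        rng = np.random.default_rng(1)
        v = wb.simulate_transit(p, FS, V0) + rng.normal(0, 0.005, 3052)
        f = wb.wingbeat_frequency_of_window(v, FS)
        assert f == pytest.approx(500.0, abs=10.0)

    def test_fundamental_chosen_over_dominant_second_harmonic(self):
        """A 300 Hz train whose 600 Hz harmonic is stronger must still be
        reported as 300 Hz."""
        t = np.arange(3052) / FS
        env = np.exp(-0.5 * ((t - 0.05) / (0.1 / 6)) ** 2)
        osc = 0.02 * np.cos(2 * np.pi * 300 * t) + 0.06 * np.cos(2 * np.pi * 600 * t)
        v = V0 - 0.3 * env - env * (0.09 + osc)
        f = wb.wingbeat_frequency_of_window(v, FS)
        assert f == pytest.approx(300.0, abs=10.0)

    def test_wingless_dip_undefined(self):
        p = make_transit(fw=0.0, wing=0.0, body=0.3)
        v = wb.simulate_transit(p, FS, V0)
        assert wb.wingbeat_frequency_of_window(v, FS) is None

    def test_population_recovery_uniform_100_700(self):
        """fw ~ U(100, 700) at high SNR: median error below the native
        spectral resolution and harmonic confusion in <= 1% of events."""
        rng = np.random.default_rng(10)
        errs, confusions, n = [], 0, 300
        for _ in range(n):
            fw = float(rng.uniform(100, 700))
            dur = float(np.clip(rng.normal(0.1, 0.02), 0.05, 0.2))
            p = make_transit(fw=fw, duration=dur,
                             ratio=float(rng.uniform(0.1, 0.5)),
                             body=float(rng.uniform(0.2, 0.4)))
            v = wb.simulate_transit(p, FS, V0)
            v = v + rng.normal(0, 0.005, v.size)
            f = wb.wingbeat_frequency_of_window(v, FS)
            assert f is not None
            errs.append(abs(f - fw))
            if abs(f - fw) > 0.3 * fw:
                confusions += 1
        assert np.median(errs) <= 1.0 / 0.05  # resolution of shortest window
        assert confusions <= 0.01 * n


class TestEndToEndRoundTrip:
    def test_noise_free_transit_features_recover_truth(self, geometry):
        """Noise-free round trip: injected frequency within resolution,
        true levels within 2%."""
        for fw, ratio in [(300.0, 0.27), (524.0, 0.19)]:
            p = make_transit(fw=fw, duration=0.1, ratio=ratio)
            v = wb.simulate_transit(p, FS, V0)
            ev = wb.TransitEvent(0, v.size, FS, v, np.full(v.size, V0))
            feats = wb.extract_features(ev, geometry)
            assert feats.fw == pytest.approx(fw, abs=10.0)
            vw_true, vb_true = wb.true_transit_levels(p, FS, V0)
            assert feats.vw == pytest.approx(vw_true, abs=0.02 * (V0 - vw_true))
            assert feats.vb == pytest.approx(vb_true, abs=0.02 * (V0 - vb_true))
            assert feats.ratio_wb == pytest.approx(ratio, abs=0.01)
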