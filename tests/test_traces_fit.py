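"""Beat detection, double-sigmoid and biexponential fitting, curve metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ectpipe.models import double_sigmoid
from ectpipe.synth import gen_ca_trace, gen_twitch_trace
from ectpipe.timeseries import TimeSeries
from ectpipe.traces import (
    detect_twitches,
    fit_biexponential,
    fit_double_sigmoid,
    peak_metrics,
)

from conftest import BIEXP, TWITCH, dense_pulse_oracle


class TestDetectTwitches:
    def test_flat_trace_yields_nothing(self):
        ts = TimeSeries(np.arange(500) / 100.0, np.zeros(500), 100.0)
        assert detect_twitches(ts, min_prominence=1.0) == []

    def test_programmed_beats_recovered_at_programmed_times(self):
        ts, gt = gen_twitch_trace([(1.0, 5.0), (0.0, 10.0), (1.0, 1.0)],
                                  TWITCH, noise_sd=0.0, fs=500)
        windows = detect_twitches(ts, min_prominence=10.0)
        assert len(windows) == 6
        # each window's max sits within 1 sample of the programmed peak
        oracle = dense_pulse_oracle(
            lambda t: double_sigmoid(t, 0, TWITCH["scale"], TWITCH["t_up"],
                                     TWITCH["tau_up"], TWITCH["t_down"],
                                     TWITCH["tau_down"]), 0.0, 1.0)
        expected = np.asarray(gt.params["stimulus_times"]) + oracle["t_peak"]
        found = [ts.t[lo + np.argmax(ts.y[lo:hi])] for lo, hi in windows]
        np.testing.assert_allclose(found, expected, atol=1.0 / 500 + 1e-9)

    def test_close_beats_merge_into_single_window(self):
        # two pulses 0.1 s apart with min_separation 0.5 s: the detector keeps
        # one window containing the more prominent merged event
        t = np.arange(2000) / 1000.0
        y = np.exp(-((t - 0.9) ** 2) / 1e-3) + np.exp(-((t - 1.0) ** 2) / 1e-3)
        ts = TimeSeries(t, y, 1000.0)
        windows = detect_twitches(ts, min_prominence=0.3, min_separation=0.5)
        assert len(windows) == 1

    def test_windows_are_disjoint_and_cover_one_peak_each(self):
        ts, _ = gen_twitch_trace([(2.0, 4.0)], TWITCH, noise_sd=0.0, fs=500)
        windows = detect_twitches(ts, min_prominence=10.0, min_separation=0.2)
        assert len(windows) == 8
        for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
            assert a1 <= b0


class TestDoubleSigmoidFit:
    def test_noiseless_round_trip_parameters(self):
        ts, _ = gen_twitch_trace([(1.0, 1.0)], TWITCH, noise_sd=0.0, fs=1000)
        fit = fit_double_sigmoid(ts)
        assert fit.converged
        for name, true in [("scale", 80.0), ("t_up", 0.05), ("tau_up", 0.01),
                           ("t_down", 0.25), ("tau_down", 0.02)]:
            assert getattr(fit, name) == pytest.approx(true, rel=1e-3), name

    def test_derived_metrics_match_dense_oracle(self):
        ts, _ = gen_twitch_trace([(1.0, 1.0)], TWITCH, noise_sd=0.0, fs=1000)
        fit = fit_double_sigmoid(ts)
        oracle = dense_pulse_oracle(
            lambda t: double_sigmoid(t, 0, 80.0, 0.05, 0.01, 0.25, 0.02), 0, 1)
        assert fit.amplitude == pytest.approx(oracle["peak"], abs=1e-3 * 80)
        assert fit.duration == pytest.approx(oracle["fwhm"], abs=oracle["grid_step"])
        assert fit.time_of_peak == pytest.approx(oracle["t_peak"], abs=oracle["grid_step"])

    def test_zero_amplitude_window_flagged(self):
        ts, _ = gen_twitch_trace([(1.0, 1.0)], {**TWITCH, "scale": 0.0},
                                 noise_sd=0.0, fs=500)
        fit = fit_double_sigmoid(ts)
        assert not fit.converged
        assert fit.amplitude is None

    def test_residual_rmse_below_1e6_of_amplitude(self):
        ts, _ = gen_twitch_trace([(1.0, 1.0)], TWITCH, noise_sd=0.0, fs=1000)
        fit = fit_double_sigmoid(ts)
        assert fit.rmse < 1e-6 * 80.0


class TestBiexponentialFit:
    def test_noiseless_round_trip(self):
        ts, _ = gen_ca_trace(BIEXP, [(1.0, 1.0)], noise_sd=0.0, fs=1000)
        fit = fit_biexponential(ts)
        assert fit.converged
        assert fit.tau_rise == pytest.approx(0.05, rel=1e-3)
        assert fit.tau_decay == pytest.approx(0.30, rel=1e-3)
        assert fit.scale == pytest.approx(50.0, rel=1e-3)

    def test_peak_time_closed_form(self):
        ts, _ = gen_ca_trace(BIEXP, [(1.0, 1.0)], noise_sd=0.0, fs=1000)
        fit = fit_biexponential(ts)
        assert fit.peak_time == pytest.approx(0.1075, abs=2e-4)

    def test_tau_ordering_invariant_held_under_noise(self):
        for seed in range(5):
            ts, _ = gen_ca_trace(BIEXP, [(1.0, 1.0)], noise_sd=5.0, fs=200,
                                 seed=seed)
            fit = fit_biexponential(ts)
            assert fit.tau_decay > fit.tau_rise > 0

    def test_noise_degrades_tau_estimates_monotonically(self):
        """Median |tau_decay error| is non-decreasing in the noise level."""
        med = []
        for noise in (0.5, 2.0, 8.0):
            errs = []
            for seed in range(15):
                ts, _ = gen_ca_trace(BIEXP, [(1.0, 1.5)], noise_sd=noise,
                                     fs=200, seed=seed)
                fit = fit_biexponential(ts)
                errs.append(abs(fit.tau_decay - 0.30))
            med.append(np.median(errs))
        assert med[0] <= med[1] <= med[2]


class TestPeakMetrics:
    def test_symmetric_triangle_geometry(self):
        W, A = 0.4, 10.0
        tri = lambda t: A * np.clip(1.0 - np.abs(t) / (W / 2), 0.0, None)
        m = peak_metrics(tri, -0.3, 0.3, baseline=0.0)
        assert m["duration"] == pytest.approx(W / 2, abs=1e-4)
        assert m["contraction_time"] == pytest.approx(0.45 * W, abs=1e-4)
        assert m["relaxation_time"] == pytest.approx(0.45 * W, abs=1e-4)

    def test_rectangular_limit_of_double_sigmoid(self):
        f = lambda t: double_sigmoid(t, 0.0, 10.0, 0.1, 1e-4, 0.4, 1e-4)
        m = peak_metrics(f, 0.0, 0.6, baseline=0.0)
        assert m["duration"] == pytest.approx(0.3, abs=2e-3)

    def test_level_never_reached_gives_null(self):
        # curve rises but never falls: descending crossings are null
        f = lambda t: 1.0 / (1.0 + np.exp(-(t - 0.5) / 0.05))
        m = peak_metrics(f, 0.0, 1.0, baseline=0.0)
        assert m["t10_desc"] is None
        assert m["duration"] is None

    @given(st.floats(0.005, 0.05), st.floats(0.005, 0.05),
           st.floats(0.15, 0.4))
    @settings(max_examples=25, deadline=None)
    def test_width_ordering_for_any_unimodal_twitch(self, tau_up, tau_down, gap):
        f = lambda t: double_sigmoid(t, 0.0, 10.0, 0.1, tau_up, 0.1 + gap, tau_down)
        m = peak_metrics(f, -0.5, 0.1 + gap + 0.5, baseline=0.0)
        w10, w50, w90 = m["width10"], m["duration"], m["width90"]
        if None not in (w10, w50, w90):
            assert w10 >= w50 >= w90
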