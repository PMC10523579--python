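"""Wire tracking, force calibration, and FFR/PRP protocol analysis."""

import numpy as np
import pytest

from ectpipe.contractility import (
    ForceCalibration,
    analyze_protocol,
    deflection_timeseries,
    deflection_to_force,
    track_wire,
)
from ectpipe.synth import gen_twitch_trace, gen_wire_video
from ectpipe.timeseries import TimeSeries


class TestTrackWire:
    def test_zero_deflection_video(self):
        stack, _ = gen_wire_video(np.zeros(10), snr=1e9, seed=0)
        tracks = track_wire(stack)
        assert all(t.deflection < 0.2 for t in tracks)

    def test_programmed_sinusoid_amplitude_recovered(self):
        sags = 6.0 * np.abs(np.sin(np.linspace(0, 2 * np.pi, 30)))
        stack, _ = gen_wire_video(sags, snr=1e9, seed=0)
        d = np.array([t.deflection for t in track_wire(stack)])
        assert d.max() == pytest.approx(6.0, abs=0.1)

    def test_rms_error_under_noise(self):
        sags = 5.0 * np.abs(np.sin(np.linspace(0, 4 * np.pi, 60)))
        stack, _ = gen_wire_video(sags, snr=10.0, seed=3)
        d = np.array([t.deflection for t in track_wire(stack)])
        assert np.sqrt(np.mean((d - sags) ** 2)) < 0.2

    def test_blank_frame_flagged_and_interpolated(self):
        sags = np.array([2.0, 2.0, 2.0, 2.0])
        stack, gt = gen_wire_video(sags, snr=100.0, seed=0)
        stack[2] = np.random.default_rng(0).normal(10, 1, stack[2].shape)
        tracks = track_wire(stack)
        assert tracks[2].flagged
        assert tracks[2].deflection == pytest.approx(2.0, abs=0.3)


class TestForceCalibration:
    def test_linear_conversion(self):
        cal = ForceCalibration("linear", [10.0])
        ts = TimeSeries(np.arange(3) / 10.0, np.array([0.0, 3.0, 6.0]), 10.0, "px")
        force = deflection_to_force(ts, cal)
        np.testing.assert_allclose(force.y, [0.0, 30.0, 60.0])
        assert force.units == "uN"

    def test_polynomial_matches_direct_evaluation(self):
        coeffs = [2.0, 0.3, 0.01]  # ascending powers, zero constant implied
        cal = ForceCalibration("polynomial", coeffs, max_deflection=20.0)
        x = np.linspace(0.1, 19.9, 50)
        direct = coeffs[0] * x + coeffs[1] * x**2 + coeffs[2] * x**3
        np.testing.assert_allclose(cal(x), direct, rtol=1e-12)

    def test_non_monotone_calibration_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            ForceCalibration("polynomial", [1.0, -0.2], max_deflection=10.0)

    def test_out_of_range_deflection_names_frame(self):
        cal = ForceCalibration("linear", [10.0], max_deflection=5.0)
        ts = TimeSeries(np.arange(3) / 10.0, np.array([1.0, 7.0, 2.0]), 10.0, "px")
        with pytest.raises(ValueError, match="frame 1"):
            deflection_to_force(ts, cal)

    def test_json_round_trip(self, tmp_path):
        cal = ForceCalibration("lookup", [[0.0, 5.0, 10.0], [0.0, 40.0, 100.0]])
        cal.to_json(tmp_path / "cal.json")
        back = ForceCalibration.from_json(tmp_path / "cal.json")
        assert back(np.array([2.5]))[0] == pytest.approx(20.0)


def _protocol_trace(amplitudes, prp_scale=None, fs=250.0):
    """Paced force trace with per-frequency programmed pulse scales."""
    twitch = dict(t_up=0.04, tau_up=0.008, t_down=0.15, tau_down=0.015)
    segments, beats = [], []
    for f, amp in amplitudes.items():
        dur = 8.0 / f  # 8 beats per segment
        segments.append((f, dur))
        beats += [dict(scale=amp, **twitch)] * 8
    if prp_scale is not None:
        segments += [(0.0, 10.0), (1.0, 2.0)]
        beats += [dict(scale=prp_scale, **twitch)] * 2
    ts, _ = gen_twitch_trace(segments, beats, noise_sd=0.0, fs=fs)
    return ts, segments


class TestAnalyzeProtocol:
    def test_ffr_ratios_of_programmed_amplitudes(self):
        ts, segs = _protocol_trace({1.0: 10.0, 2.0: 15.0, 3.0: 20.0, 4.0: 22.0})
        res = analyze_protocol(ts, segs)
        assert res.ffr[1.0] == pytest.approx(1.0, abs=1e-6)
        assert res.ffr[2.0] == pytest.approx(1.5, rel=0.02)
        assert res.ffr[3.0] == pytest.approx(2.0, rel=0.02)
        assert res.ffr[4.0] == pytest.approx(2.2, rel=0.02)

    def test_post_rest_potentiation_recovered(self):
        ts, segs = _protocol_trace({1.0: 10.0}, prp_scale=180.0)
        res = analyze_protocol(ts, segs)
        assert res.prp_norm == pytest.approx(18.0, rel=0.03)

    def test_uniform_amplitudes_give_flat_ffr(self):
        ts, segs = _protocol_trace({1.0: 12.0, 2.0: 12.0, 4.0: 12.0})
        res = analyze_protocol(ts, segs)
        for v in res.ffr.values():
            assert v == pytest.approx(1.0, rel=0.02)

    def test_missing_1hz_segment_is_error(self):
        ts, segs = _protocol_trace({2.0: 10.0})
        with pytest.raises(ValueError, match="1 Hz"):
            analyze_protocol(ts, segs)


def test_end_to_end_video_to_force_round_trip():
    """Force waveform -> deflection -> video -> tracking -> force recovery."""
    k = 10.0  # uN per px
    twitch = dict(scale=60.0, t_up=0.05, tau_up=0.01, t_down=0.25, tau_down=0.02)
    force_true, _ = gen_twitch_trace([(1.0, 2.0)], twitch, noise_sd=0.0, fs=100)
    stack, _ = gen_wire_video(
        TimeSeries(force_true.t, force_true.y / k, 100.0, "px"), snr=10.0, seed=4
    )
    tracks = track_wire(stack)
    force = deflection_to_force(deflection_timeseries(tracks, fs=100.0),
                                ForceCalibration("linear", [k]))
    from ectpipe.traces import detect_twitches, fit_double_sigmoid

    windows = detect_twitches(force, min_prominence=10.0)
    assert len(windows) == 2
    lo, hi = windows[0]
    fit = fit_double_sigmoid(
        TimeSeries(force.t[lo:hi], force.y[lo:hi], force.fs, "uN")
    )
    true_amp = force_true.y.max()  # realized peak of the programmed pulse
    assert fit.amplitude == pytest.approx(true_amp, rel=0.03)
    assert fit.duration == pytest.approx(0.2, abs=0.002)
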