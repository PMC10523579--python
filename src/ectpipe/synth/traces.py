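"""Synthetic force, Ca²⁺ and action-potential traces with analytic ground truth.

Stimulation protocols are frequency schedules — ordered ``(frequency_hz,
duration_s)`` segments, with ``frequency 0`` meaning a rest gap.  Pulse onsets
coincide with the scheduled stimulus times; when the tail of one pulse
overlaps the next beat the contributions sum linearly, and the generator
refuses protocols in which the residual at the next onset exceeds a
configurable fraction of the pulse amplitude (an unphysical pacing request
rather than a numerical problem).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ..models import biexp_pulse, double_sigmoid
from ..timeseries import TimeSeries
from .groundtruth import GroundTruth

__all__ = [
    "StimSchedule",
    "gen_twitch_trace",
    "gen_ca_trace",
    "gen_ap_trace",
]


@dataclass(frozen=True)
class StimSchedule:
    """Frequency schedule: ordered (frequency Hz, duration s) segments.

    ``frequency == 0`` denotes a rest gap.  Stimulus times are the pulse
    onsets ``segment_start + k / frequency`` for ``k = 0 .. floor(f*dur)-1``.
    """

    segments: tuple[tuple[float, float], ...]

    def __init__(self, segments: Sequence[tuple[float, float]]):
        segs = tuple((float(f), float(d)) for f, d in segments)
        for f, d in segs:
            if f < 0 or d <= 0:
                raise ValueError("segments need frequency >= 0 and duration > 0")
        object.__setattr__(self, "segments", segs)

    @property
    def duration(self) -> float:
        return sum(d for _, d in self.segments)

    def stimulus_times(self) -> np.ndarray:
        """All pulse-onset times, with the owning segment's frequency attached."""
        times = []
        t0 = 0.0
        for f, d in self.segments:
            if f > 0:
                n = int(np.floor(f * d * (1 + 1e-12)))
                times.extend(t0 + np.arange(n) / f)
            t0 += d
        return np.asarray(times)

    def segment_bounds(self) -> list[tuple[float, float, float]]:
        """List of (frequency, start, end) per segment."""
        out, t0 = [], 0.0
        for f, d in self.segments:
            out.append((f, t0, t0 + d))
            t0 += d
        return out


def _per_beat(params, n_beats: int) -> list[dict]:
    """Broadcast a single parameter dict, or validate a per-beat list."""
    if isinstance(params, dict):
        return [dict(params)] * n_beats
    params = list(params)
    if len(params) != n_beats:
        raise ValueError(
            f"protocol schedules {n_beats} beats but {len(params)} parameter sets given"
        )
    return [dict(p) for p in params]


def _check_overlap(residual: float, scale: float, tol: float) -> None:
    if abs(scale) > 0 and residual > tol * abs(scale):
        raise ValueError(
            "pulse tail at the next stimulus exceeds the overlap tolerance "
            f"({residual:.3g} > {tol:.3g} * {abs(scale):.3g}); the protocol packs "
            "beats too tightly for this pulse shape"
        )


def gen_twitch_trace(
    protocol: StimSchedule | Sequence[tuple[float, float]],
    twitch_params: dict | Sequence[dict],
    noise_sd: float = 0.0,
    fs: float = 100.0,
    seed: int = 0,
    baseline: float = 0.0,
    overlap_tol: float = 0.05,
) -> tuple[TimeSeries, GroundTruth]:
    """Force trace: per-beat double-sigmoid pulses on a constant baseline.

    ``twitch_params`` holds the pulse parameters ``scale`` (µN), ``t_up``,
    ``tau_up``, ``t_down``, ``tau_down`` (seconds, relative to the stimulus
    time), either one dict applied to every beat or one dict per beat (so
    force–frequency and post-rest protocols can program per-beat amplitudes).
    Gaussian noise of standard deviation ``noise_sd`` is added i.i.d.;
    rest gaps contain baseline (plus noise) only.
    """
    if fs < 100:
        raise ValueError("fs must be at least 100 Hz to resolve twitch kinetics")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    sched = protocol if isinstance(protocol, StimSchedule) else StimSchedule(protocol)
    stim = sched.stimulus_times()
    beats = _per_beat(twitch_params, len(stim))

    n = int(round(sched.duration * fs))
    t = np.arange(n) / fs
    y = np.full(n, float(baseline))
    for t0, p in zip(stim, beats):
        nxt = stim[stim > t0]
        if nxt.size:
            tail = double_sigmoid(
                np.array([nxt[0] - t0]), 0.0, p["scale"],
                p["t_up"], p["tau_up"], p["t_down"], p["tau_down"],
            )[0]
            _check_overlap(tail, p["scale"], overlap_tol)
        y += double_sigmoid(
            t - t0, 0.0, p["scale"], p["t_up"], p["tau_up"], p["t_down"], p["tau_down"]
        )
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    gt = GroundTruth(
        "twitch_trace",
        {
            "segments": sched.segments,
            "stimulus_times": stim,
            "beats": beats,
            "baseline": baseline,
            "noise_sd": noise_sd,
            "fs": fs,
        },
        seed,
    )
    return TimeSeries(t, y, fs, "uN"), gt


def gen_ca_trace(
    biexp_params: dict | Sequence[dict],
    protocol: StimSchedule | Sequence[tuple[float, float]],
    noise_sd: float = 0.0,
    fs: float = 100.0,
    seed: int = 0,
    baseline: float = 0.0,
    overlap_tol: float = 0.05,
) -> tuple[TimeSeries, GroundTruth]:
    """ΔF trace: per-beat biexponential transients on a constant baseline.

    ``biexp_params`` holds ``scale``, ``tau_rise``, ``tau_decay`` (s); pulse
    onset ``t0`` is the stimulus time.  Requires ``tau_decay > tau_rise``.
    """
    if fs < 100:
        raise ValueError("fs must be at least 100 Hz")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    sched = protocol if isinstance(protocol, StimSchedule) else StimSchedule(protocol)
    stim = sched.stimulus_times()
    beats = _per_beat(biexp_params, len(stim))

    n = int(round(sched.duration * fs))
    t = np.arange(n) / fs
    y = np.full(n, float(baseline))
    for t0, p in zip(stim, beats):
        nxt = stim[stim > t0]
        if nxt.size:
            tail = biexp_pulse(
                np.array([nxt[0]]), 0.0, p["scale"], t0, p["tau_rise"], p["tau_decay"]
            )[0]
            _check_overlap(tail, p["scale"], overlap_tol)
        y += biexp_pulse(t, 0.0, p["scale"], t0, p["tau_rise"], p["tau_decay"])
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    gt = GroundTruth(
        "ca_trace",
        {
            "segments": sched.segments,
            "stimulus_times": stim,
            "beats": beats,
            "baseline": baseline,
            "noise_sd": noise_sd,
            "fs": fs,
        },
        seed,
    )
    return TimeSeries(t, y, fs, "dF"), gt


def ap_waveform(
    t: np.ndarray,
    rmp: float,
    peak: float,
    t_act: float,
    upstroke_dur: float,
    plateau_dur: float,
    plateau_drop: float,
    tau_repol: float,
) -> np.ndarray:
    """Piecewise action-potential waveform (one beat) evaluated at ``t``.

    Flat at ``rmp``; linear upstroke of duration ``upstroke_dur`` centered on
    ``t_act``; linear plateau declining by ``plateau_drop`` mV over
    ``plateau_dur``; then exponential repolarization toward ``rmp`` with time
    constant ``tau_repol``.
    """
    t = np.asarray(t, dtype=float)
    t_up0 = t_act - upstroke_dur / 2.0
    t_peak = t_up0 + upstroke_dur
    t_rep = t_peak + plateau_dur
    v_rep = peak - plateau_drop

    v = np.full_like(t, rmp)
    m = (t >= t_up0) & (t < t_peak)
    v[m] = rmp + (peak - rmp) * (t[m] - t_up0) / upstroke_dur
    m = (t >= t_peak) & (t < t_rep)
    if plateau_dur > 0:
        v[m] = peak - plateau_drop * (t[m] - t_peak) / plateau_dur
    m = t >= t_rep
    v[m] = rmp + (v_rep - rmp) * np.exp(-(t[m] - t_rep) / tau_repol)
    return v


def analytic_apd(
    level_frac: float,
    rmp: float,
    peak: float,
    upstroke_dur: float,
    plateau_dur: float,
    plateau_drop: float,
    tau_repol: float,
) -> float:
    """Closed-form APD at ``level_frac`` repolarization (e.g. 0.9 for APD₉₀).

    Measured from the activation time (upstroke midpoint) to the first
    crossing of ``peak - level_frac * (peak - rmp)``.  Returned in seconds.
    """
    amplitude = peak - rmp
    level = peak - level_frac * amplitude
    v_rep = peak - plateau_drop
    t_peak = upstroke_dur / 2.0  # relative to activation
    if level >= v_rep and plateau_dur > 0:
        return t_peak + plateau_dur * (peak - level) / plateau_drop
    t_rep = t_peak + plateau_dur
    if level >= v_rep:  # degenerate: no plateau, level at its start
        return t_rep
    if level <= rmp:
        raise ValueError("repolarization level at or below RMP is never crossed")
    return t_rep + tau_repol * float(np.log((v_rep - rmp) / (level - rmp)))


def gen_ap_trace(
    rmp: float = -80.0,
    peak: float = 30.0,
    upstroke_dur: float = 1e-3,
    plateau_dur: float = 0.15,
    plateau_drop: float = 25.0,
    tau_repol: float = 0.04,
    n_beats: int = 3,
    period: float = 1.0,
    fs: float = 10_000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    pre_s: float = 0.2,
) -> tuple[TimeSeries, GroundTruth]:
    """Sharp-electrode style voltage trace of ventricular-like APs.

    Each beat is the piecewise waveform of :func:`ap_waveform`; activation
    times are ``pre_s + k * period``.  Ground truth records the analytic
    APD₃₀/₅₀/₉₀ (ms), maximal upstroke velocity ``(peak-rmp)/upstroke_dur``
    (V/s), amplitude and RMP.
    """
    if peak <= rmp:
        raise ValueError("peak must exceed rmp")
    if plateau_drop < 0 or tau_repol <= 0 or plateau_drop >= (peak - rmp):
        raise ValueError("repolarization parameters must be monotone toward RMP")
    n = int(round((pre_s + n_beats * period) * fs))
    t = np.arange(n) / fs
    v = np.full(n, float(rmp))
    t_acts = pre_s + np.arange(n_beats) * period
    for ta in t_acts:
        v += ap_waveform(
            t, 0.0, peak - rmp, ta, upstroke_dur, plateau_dur, plateau_drop, tau_repol
        )
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=n)
    apds = {
        f"apd{int(100 * f)}_ms": 1e3
        * analytic_apd(f, rmp, peak, upstroke_dur, plateau_dur, plateau_drop, tau_repol)
        for f in (0.3, 0.5, 0.9)
    }
    gt = GroundTruth(
        "ap_trace",
        {
            "rmp": rmp,
            "peak": peak,
            "amplitude": peak - rmp,
            "upstroke_dur": upstroke_dur,
            "plateau_dur": plateau_dur,
            "plateau_drop": plateau_drop,
            "tau_repol": tau_repol,
            "dvdt_max_v_per_s": (peak - rmp) / (upstroke_dur * 1e3),
            "activation_times": t_acts,
            "noise_sd": noise_sd,
            "fs": fs,
            **apds,
        },
        seed,
    )
    return TimeSeries(t, v, fs, "mV"), gt
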