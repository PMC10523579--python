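"""Sharp-electrode action-potential parameterization.

Per beat: resting membrane potential (RMP, mean of the 50 ms window before
the upstroke), peak, amplitude, maximal upstroke velocity (dV/dt_max from a
Savitzky–Golay-smoothed derivative), activation time (center of the run of
near-maximal derivative samples) and APD₃₀/₅₀/₉₀ — the time from activation
until the voltage first falls below ``peak − x% * amplitude``, with the
repolarization level referenced to the amplitude measured from RMP and a
one-sample hysteresis against noise re-crossings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .timeseries import TimeSeries

__all__ = ["APParams", "extract_ap_params", "ap_params_table"]


@dataclass
class APParams:
    """Parameters of a single action potential (times s, durations ms)."""

    activation_time: float
    rmp: float
    peak: float
    amplitude: float
    dvdt_max: float  # V/s
    apd30: float | None
    apd50: float | None
    apd90: float | None

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("AP amplitude must be positive")
        apds = [a for a in (self.apd30, self.apd50, self.apd90) if a is not None]
        if any(b < a - 1e-9 for a, b in zip(apds, apds[1:])):
            raise AssertionError("APD ordering violated: APD30 <= APD50 <= APD90")


def _derivative(y: np.ndarray, fs: float, window_ms: float = 0.5) -> np.ndarray:
    """Savitzky–Golay first derivative in mV/s."""
    win = max(5, int(round(window_ms * 1e-3 * fs)) | 1)
    if win >= y.size:
        win = max(5, (y.size - 1) | 1)
    return signal.savgol_filter(y, win, 2, deriv=1, delta=1.0 / fs)


def _crossing_time(t: np.ndarray, v: np.ndarray, i_from: int, level: float) -> float | None:
    """First sub-sample down-crossing of ``level`` at/after ``i_from``.

    One-sample hysteresis: the sample after the crossing must also sit below
    the level, so single-sample noise dips are ignored.
    """
    below = v[i_from:] < level
    idx = np.flatnonzero(below[:-1] & below[1:])
    if idx.size == 0:
        idx = np.flatnonzero(below)
        if idx.size == 0:
            return None
    j = i_from + int(idx[0])
    if j == 0 or v[j - 1] <= level:
        return float(t[j])
    frac = (v[j - 1] - level) / (v[j - 1] - v[j])
    return float(t[j - 1] + frac * (t[j] - t[j - 1]))


def extract_ap_params(
    ts: TimeSeries,
    stim_times: np.ndarray | None = None,
    min_amplitude: float = 20.0,
    rmp_window_s: float = 0.05,
    dvdt_threshold_frac: float = 0.99,
) -> list[APParams]:
    """Parameterize every action potential in a voltage trace (mV).

    Beats are located from the smoothed derivative: runs of samples whose
    dV/dt exceeds 20% of the global maximum seed one beat each; beats whose
    peak does not rise ``min_amplitude`` mV above the local RMP are dropped.
    The activation time is the center of the contiguous run of samples whose
    derivative is within ``dvdt_threshold_frac`` of the beat's maximum — for
    a linear upstroke this is the upstroke midpoint, independent of the
    smoothing window.
    """
    if ts.fs < 1000:
        raise ValueError("AP analysis requires fs >= 1 kHz")
    t, v, fs = ts.t, ts.y, ts.fs
    dv = _derivative(v, fs)
    dv_max_global = float(dv.max())
    if dv_max_global <= 0:
        return []
    hot = dv > 0.2 * dv_max_global
    # contiguous hot runs -> candidate upstrokes
    runs = []
    i = 0
    while i < len(v):
        if hot[i]:
            j = i
            while j < len(v) and hot[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1

    out: list[APParams] = []
    for k, (i0, i1) in enumerate(runs):
        seg_dv = dv[i0:i1]
        dv_max = float(seg_dv.max())
        near = np.flatnonzero(seg_dv >= dvdt_threshold_frac * dv_max)
        i_act = i0 + int(round(0.5 * (near[0] + near[-1])))
        t_act = float(t[i_act])
        # RMP from the 50 ms window ending just before the upstroke run
        r1 = max(i0 - int(0.002 * fs), 1)
        r0 = max(r1 - int(rmp_window_s * fs), 0)
        rmp = float(np.mean(v[r0:r1]))
        # search window: to the next upstroke (or trace end)
        i_end = runs[k + 1][0] if k + 1 < len(runs) else len(v)
        seg = v[i0:i_end]
        peak = float(seg.max())
        amp = peak - rmp
        if amp < min_amplitude:
            continue
        i_peak = i0 + int(np.argmax(seg))
        apds = {}
        for frac in (0.3, 0.5, 0.9):
            level = peak - frac * amp
            tc = _crossing_time(t[:i_end], v[:i_end], i_peak, level)
            apds[frac] = None if tc is None else 1e3 * (tc - t_act)
        out.append(
            APParams(
                activation_time=t_act,
                rmp=rmp,
                peak=peak,
                amplitude=amp,
                dvdt_max=dv_max / 1e3,  # mV/s -> V/s
                apd30=apds[0.3],
                apd50=apds[0.5],
                apd90=apds[0.9],
            )
        )
    return out


def ap_params_table(params: list[APParams]) -> pd.DataFrame:
    """Flat table (one row per beat) of AP parameters."""
    return pd.DataFrame([vars(p) for p in params])
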