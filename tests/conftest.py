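import numpy as np
import pytest

from ectpipe.synth import StimSchedule

# canonical twitch pulse used across tests: realistic 1 Hz kinetics
TWITCH = dict(scale=80.0, t_up=0.05, tau_up=0.01, t_down=0.25, tau_down=0.02)
BIEXP = dict(scale=50.0, tau_rise=0.05, tau_decay=0.30)


@pytest.fixture
def single_beat_schedule():
    return StimSchedule([(1.0, 1.0)])


def dense_pulse_oracle(fun, t_lo, t_hi, fs=10_000.0):
    """Dense-grid numeric oracle: peak value/time and FWHM of a pulse.

    Evaluates the closed form on a 10 kHz grid and reads off the maximum and
    the half-maximum crossings by linear interpolation — independent of the
    package's bisection-based metric code.
    """
    t = np.arange(t_lo, t_hi, 1.0 / fs)
    y = fun(t)
    ip = int(np.argmax(y))
    peak, t_peak = float(y[ip]), float(t[ip])
    base = float(min(y[0], y[-1]))
    half = base + 0.5 * (peak - base)

    def _interp(i0, i1):
        y0, y1 = y[i0], y[i1]
        return t[i0] + (half - y0) / (y1 - y0) * (t[i1] - t[i0])

    asc = np.flatnonzero(y[: ip + 1] < half)[-1]
    desc = ip + np.flatnonzero(y[ip:] < half)[0]
    return {
        "peak": peak,
        "t_peak": t_peak,
        "fwhm": _interp(desc - 1, desc) - _interp(asc, asc + 1),
        "grid_step": 1.0 / fs,
    }
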