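"""Uniformly sampled time series, the common currency of all trace analyses.

A :class:`TimeSeries` carries a force (µN), fluorescence (ΔF) or voltage (mV)
signal on a strictly uniform time grid.  All fitters and metric extractors in
the package accept and return this type; CSV round-tripping is provided so
traces exported by acquisition software (two columns: time in seconds, value)
can be loaded directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TimeSeries"]


@dataclass
class TimeSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing, uniform grid.
    y : ndarray
        Sample values in ``units``.
    fs : float
        Sampling rate in Hz.  Must satisfy ``|dt - 1/fs| < 1e-9`` for every
        grid step.
    units : str
        Label for the value axis (e.g. ``"uN"``, ``"dF"``, ``"mV"``).
    """

    t: np.ndarray
    y: np.ndarray
    fs: float
    units: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.y.shape:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("t must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.fs)) >= 1e-9:
                raise ValueError("t is not uniform at the declared sampling rate")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.y))):
            raise ValueError("TimeSeries requires finite values")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Span of the time grid in seconds."""
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    def slice_time(self, t0: float, t1: float) -> "TimeSeries":
        """Return the sub-series with ``t0 <= t <= t1`` (inclusive)."""
        m = (self.t >= t0) & (self.t <= t1)
        return TimeSeries(self.t[m], self.y[m], self.fs, self.units)

    def to_csv(self, path: str | Path) -> None:
        """Write as two-column CSV (time_s, value) with stable formatting."""
        df = pd.DataFrame({"time_s": self.t, "value": self.y})
        df.to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path: str | Path, units: str = "") -> "TimeSeries":
        """Load a two-column CSV (time, value); sampling rate inferred."""
        df = pd.read_csv(path)
        t = df.iloc[:, 0].to_numpy(dtype=float)
        y = df.iloc[:, 1].to_numpy(dtype=float)
        if t.size < 2:
            raise ValueError("need at least two samples to infer fs")
        fs = 1.0 / float(np.median(np.diff(t)))
        # snap to the inferred uniform grid to absorb CSV rounding
        t = t[0] + np.arange(t.size) / fs
        return cls(t, y, fs, units)
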