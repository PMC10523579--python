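"""Wire-deflection contractility: tracking, force conversion, FFR and PRP.

Tissue force is transduced by the bending of an elastomeric wire.  Each
video frame is reduced to a quadratic centerline fitted through per-column
intensity centroids; the scalar deflection is the maximal perpendicular
distance between the centerline and the chord through its endpoints (the
at-rest reference line).  Deflections are converted to µN through a
user-supplied monotone calibration (the displacement→force relationship is
measured per wire lot and is an input artifact, not a constant of this
package).  Protocol analysis derives per-frequency steady-state amplitudes,
the force–frequency relationship (FFR, normalized to 1 Hz) and post-rest
potentiation (PRP).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .synth.traces import StimSchedule
from .timeseries import TimeSeries
from .traces import detect_twitches, fit_double_sigmoid

__all__ = [
    "WireFrameTrack",
    "ForceCalibration",
    "ProtocolResult",
    "track_wire",
    "deflection_timeseries",
    "deflection_to_force",
    "analyze_protocol",
]


@dataclass
class WireFrameTrack:
    """Per-frame wire centerline and scalar deflection."""

    frame: int
    anchors: tuple[tuple[float, float], tuple[float, float]]
    coeffs: tuple[float, float, float]  # quadratic: y = c2 x^2 + c1 x + c0
    deflection: float  # px, >= 0
    quality: float  # fraction of columns with a valid centroid
    flagged: bool = False


def _frame_centerline(
    frame: np.ndarray, x_lo: int, x_hi: int, halfwidth: float
) -> tuple[np.ndarray, np.ndarray]:
    """Intensity-weighted per-column wire centroid within columns [x_lo, x_hi).

    Two passes: a coarse centerline from the row-argmax of the along-wire
    smoothed image, then a background-subtracted centroid restricted to a
    ``±halfwidth`` band around the coarse position (so off-wire noise cannot
    pull the centroid).  Columns without significant mass return NaN.
    """
    from scipy import ndimage as ndi

    sub = frame[:, x_lo:x_hi].astype(float)
    n_rows, n_cols = sub.shape
    bg = float(np.median(sub))
    mad = float(np.median(np.abs(sub - bg)))
    noise_sd = 1.4826 * mad if mad > 0 else 0.0

    smooth = ndi.gaussian_filter(sub, sigma=(1.0, 5.0))
    coarse = ndi.median_filter(np.argmax(smooth, axis=0).astype(float), size=9)

    ys = np.arange(n_rows, dtype=float)
    cent = np.full(n_cols, np.nan)
    for c in range(n_cols):
        lo = int(max(0, np.floor(coarse[c] - halfwidth)))
        hi = int(min(n_rows, np.ceil(coarse[c] + halfwidth + 1)))
        w = np.clip(sub[lo:hi, c] - (bg + noise_sd), 0.0, None)
        mass = w.sum()
        if mass > 3.0 * noise_sd * np.sqrt(hi - lo) + 1e-12:
            cent[c] = float((w * ys[lo:hi]).sum() / mass)
    return np.arange(x_lo, x_hi, dtype=float), cent


def _chord_deflection(
    coeffs: np.ndarray, x0: float, x1: float, reduce: str
) -> tuple[float, tuple[tuple[float, float], tuple[float, float]]]:
    y0 = float(np.polyval(coeffs, x0))
    y1 = float(np.polyval(coeffs, x1))
    xs = np.linspace(x0, x1, 201)
    ys = np.polyval(coeffs, xs)
    chord = y0 + (y1 - y0) * (xs - x0) / (x1 - x0)
    perp = np.abs(ys - chord) / np.sqrt(1.0 + ((y1 - y0) / (x1 - x0)) ** 2)
    d = float(perp[len(xs) // 2]) if reduce == "midspan" else float(perp.max())
    return d, ((x0, y0), (x1, y1))


def track_wire(
    stack: np.ndarray,
    roi: tuple[int, int] | None = None,
    halfwidth: float = 8.0,
    min_valid_frac: float = 0.5,
    reduce: str = "max",
) -> list[WireFrameTrack]:
    """Track the wire centerline and deflection across a (frames, H, W) stack.

    ``roi`` restricts the column range ``(x_lo, x_hi)`` containing the wire
    (default: full width).  Per frame, the intensity-weighted centroid of
    each column above a background-relative threshold is fitted with a
    quadratic; the deflection is the max (or, with ``reduce="midspan"``, the
    mid-span) perpendicular distance to the chord through the centerline
    endpoints.  ``halfwidth`` is the search band around the coarse wire
    position, in px.  Frames with fewer than ``min_valid_frac`` valid
    columns are flagged and their deflection linearly interpolated from
    neighbors.
    """
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, rows, cols)")
    x_lo, x_hi = roi if roi is not None else (0, stack.shape[2])
    tracks: list[WireFrameTrack] = []
    for i, frame in enumerate(stack):
        xs, cent = _frame_centerline(frame, x_lo, x_hi, halfwidth)
        ok = np.isfinite(cent)
        quality = float(ok.mean())
        if quality < min_valid_frac:
            tracks.append(
                WireFrameTrack(i, ((x_lo, np.nan), (x_hi - 1, np.nan)),
                               (np.nan, np.nan, np.nan), np.nan, quality, True)
            )
            continue
        coeffs = np.polyfit(xs[ok], cent[ok], 2)
        d, anchors = _chord_deflection(coeffs, xs[ok][0], xs[ok][-1], reduce)
        tracks.append(WireFrameTrack(i, anchors, tuple(coeffs), d, quality))
    # interpolate flagged frames from valid neighbors
    defl = np.array([tr.deflection for tr in tracks])
    bad = np.isnan(defl)
    if bad.all():
        raise ValueError("no frame yielded a usable wire centerline")
    if bad.any():
        defl[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(~bad), defl[~bad])
        for i in np.flatnonzero(bad):
            tracks[i].deflection = float(defl[i])
    return tracks


def deflection_timeseries(tracks: Sequence[WireFrameTrack], fs: float) -> TimeSeries:
    """Assemble per-frame deflections into a TimeSeries (px)."""
    y = np.array([tr.deflection for tr in tracks], dtype=float)
    t = np.arange(len(y)) / fs
    return TimeSeries(t, y, fs, "px")


@dataclass
class ForceCalibration:
    """Monotone displacement→force map with ``f(0) = 0``.

    ``model`` is ``"linear"`` (``coefficients = [k]``, µN/px),
    ``"polynomial"`` (ascending-power coefficients with zero constant term)
    or ``"lookup"`` (``coefficients = [[px...], [uN...]]`` interpolation
    table through the origin).  Monotonicity on ``[0, max_deflection]`` is
    verified at construction; violating calibrations are rejected.
    """

    model: str
    coefficients: list
    max_deflection: float = 50.0
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.model not in ("linear", "polynomial", "lookup"):
            raise ValueError(f"unknown calibration model {self.model!r}")
        if self.model == "lookup":
            # the admissible range cannot exceed the measured table
            self.max_deflection = min(self.max_deflection, float(max(self.coefficients[0])))
        grid = np.linspace(0.0, self.max_deflection, 512)
        f = self._eval(grid)
        if abs(f[0]) > 1e-9:
            raise ValueError("calibration must map zero deflection to zero force")
        if np.any(np.diff(f) <= 0) or np.any(f[1:] < 0):
            raise ValueError("calibration must be strictly monotone and non-negative")

    def _eval(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.model == "linear":
            return self.coefficients[0] * x
        if self.model == "polynomial":
            return np.polyval(list(reversed(self.coefficients)) + [0.0], x)
        xp, fp = self.coefficients
        return np.interp(x, xp, fp)

    def __call__(self, deflection_px: np.ndarray) -> np.ndarray:
        return self._eval(deflection_px)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "model": self.model,
                    "coefficients": self.coefficients,
                    "max_deflection": self.max_deflection,
                    "provenance": self.provenance,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ForceCalibration":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def deflection_to_force(track: TimeSeries, cal: ForceCalibration) -> TimeSeries:
    """Apply the calibration pointwise; units become µN.

    Raises if any frame's deflection exceeds the calibration range, naming
    the first offending frame.
    """
    over = np.flatnonzero((track.y < 0) | (track.y > cal.max_deflection))
    if over.size:
        raise ValueError(
            f"deflection {track.y[over[0]]:.3g} px at frame {over[0]} outside "
            f"calibration range [0, {cal.max_deflection}]"
        )
    return TimeSeries(track.t, cal(track.y), track.fs, "uN")


@dataclass
class ProtocolResult:
    """Per-frequency steady-state amplitudes plus FFR and PRP summaries."""

    amplitudes: dict[float, float]  # frequency Hz -> steady-state amplitude uN
    ffr: dict[float, float]  # frequency Hz -> amplitude / 1 Hz amplitude
    prp_abs: float | None = None  # first post-rest beat amplitude, uN
    prp_norm: float | None = None  # prp_abs / 1 Hz amplitude


def _segment_amplitudes(
    force: TimeSeries, f: float, t0: float, t1: float, n_beats: int,
    min_prominence: float,
) -> list[float]:
    """Fitted amplitudes of the last ``n_beats`` beats in [t0, t1]."""
    seg = force.slice_time(t0, min(t1, force.t[-1]))
    if len(seg) < 2:
        return []
    windows = detect_twitches(seg, min_prominence, min_separation=0.4 / f)
    amps = []
    for lo, hi in windows[-n_beats:]:
        w = TimeSeries(seg.t[lo:hi], seg.y[lo:hi], seg.fs, seg.units)
        fit = fit_double_sigmoid(w)
        if fit.converged and fit.amplitude is not None:
            amps.append(fit.amplitude)
    return amps


def analyze_protocol(
    force: TimeSeries,
    schedule: StimSchedule | Sequence[tuple[float, float]],
    n_steady: int = 5,
    min_prominence: float | None = None,
) -> ProtocolResult:
    """Steady-state amplitude per pacing frequency, FFR and PRP.

    For each paced segment the last ``n_steady`` beats are individually
    fitted and their mean amplitude taken as steady state (a paced segment
    immediately following a rest gap is treated as the post-rest probe and
    only its first beat is used).  FFR divides each steady-state amplitude
    by the 1 Hz value; PRP divides the post-rest beat amplitude by the 1 Hz
    value.  A protocol without a 1 Hz segment is an error (the
    normalization is undefined).
    """
    sched = schedule if isinstance(schedule, StimSchedule) else StimSchedule(schedule)
    amplitudes: dict[float, float] = {}
    prp_abs = None
    prev_f = None
    for f, t0, t1 in sched.segment_bounds():
        if f <= 0:
            prev_f = 0.0
            continue
        seg_prom = (
            min_prominence
            if min_prominence is not None
            else 0.2 * float(np.ptp(force.slice_time(t0, min(t1, force.t[-1])).y))
        )
        if prev_f == 0.0:  # post-rest probe segment: first beat only
            seg = force.slice_time(t0, min(t1 + 0.5 / f, force.t[-1]))
            windows = detect_twitches(seg, seg_prom, min_separation=0.4 / f)
            if windows:
                lo, hi = windows[0]
                fit = fit_double_sigmoid(
                    TimeSeries(seg.t[lo:hi], seg.y[lo:hi], seg.fs, seg.units)
                )
                if fit.converged and fit.amplitude is not None:
                    prp_abs = float(fit.amplitude)
        else:
            amps = _segment_amplitudes(force, f, t0, t1, n_steady, seg_prom)
            if amps:
                amplitudes[f] = float(np.mean(amps))
        prev_f = f
    if 1.0 not in amplitudes:
        raise ValueError("protocol lacks a 1 Hz segment; FFR/PRP normalization undefined")
    a1 = amplitudes[1.0]
    ffr = {f: a / a1 for f, a in amplitudes.items()}
    return ProtocolResult(
        amplitudes=amplitudes,
        ffr=ffr,
        prp_abs=prp_abs,
        prp_norm=None if prp_abs is None else prp_abs / a1,
    )
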