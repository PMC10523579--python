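"""Closed-form waveform and curve models shared by the generators and fitters.

The same parametric forms are used to synthesize ground-truth data and to fit
measured traces, so they live in one place:

* twitch force pulse — product of a rising and a falling logistic
  ("double sigmoid"):  ``F(t) = B + A * s((t-t_up)/tau_up) * s(-(t-t_down)/tau_down)``
  with ``s(z) = 1/(1+exp(-z))``;
* Ca²⁺ transient — difference of exponentials (biexponential) with
  ``tau_decay > tau_rise``;
* four-parameter logistic (4PL) concentration–response curve.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "double_sigmoid",
    "biexp_pulse",
    "biexp_peak_time",
    "four_pl",
    "four_pl_inverse",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # clip to keep exp() finite; saturation is exact at double precision
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))


def double_sigmoid(
    t: np.ndarray,
    baseline: float,
    scale: float,
    t_up: float,
    tau_up: float,
    t_down: float,
    tau_down: float,
) -> np.ndarray:
    """Twitch pulse: rising logistic at ``t_up`` times falling logistic at ``t_down``.

    ``scale`` is the plateau amplitude of the product before the two edges
    interact; the realized peak is slightly below ``baseline + scale`` when
    the edges overlap.
    """
    t = np.asarray(t, dtype=float)
    up = _sigmoid((t - t_up) / tau_up)
    down = _sigmoid(-(t - t_down) / tau_down)
    return baseline + scale * up * down


def biexp_pulse(
    t: np.ndarray,
    baseline: float,
    scale: float,
    t0: float,
    tau_rise: float,
    tau_decay: float,
) -> np.ndarray:
    """Biexponential transient: 0 before ``t0``, difference of exponentials after.

    ``F(t) = B + A*(exp(-(t-t0)/tau_decay) - exp(-(t-t0)/tau_rise))`` for
    ``t >= t0``.  Requires ``tau_decay > tau_rise > 0`` for an upward pulse.
    """
    if not (tau_decay > tau_rise > 0):
        raise ValueError("biexponential requires tau_decay > tau_rise > 0")
    t = np.asarray(t, dtype=float)
    dt = np.maximum(t - t0, 0.0)
    pulse = np.exp(-dt / tau_decay) - np.exp(-dt / tau_rise)
    return baseline + scale * np.where(t >= t0, pulse, 0.0)


def biexp_peak_time(t0: float, tau_rise: float, tau_decay: float) -> float:
    """Analytic peak time of the biexponential pulse.

    ``t_peak = t0 + tau_d*tau_r/(tau_d - tau_r) * ln(tau_d/tau_r)``.
    """
    return t0 + tau_decay * tau_rise / (tau_decay - tau_rise) * np.log(
        tau_decay / tau_rise
    )


def four_pl(
    x: np.ndarray, bottom: float, top: float, ec50: float, hill: float
) -> np.ndarray:
    """Four-parameter logistic response at concentration ``x``.

    ``y = bottom + (top - bottom) / (1 + (ec50/x)**hill)``.  ``hill > 0``
    gives an ascending (agonist) curve from ``bottom`` at x→0 to ``top`` at
    x→∞; ``hill < 0`` gives a descending (inhibitor) curve from ``top`` to
    ``bottom``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    # evaluate in log space for numerical stability at extreme ratios
    z = hill * (np.log(ec50) - np.log(x))
    return bottom + (top - bottom) / (1.0 + np.exp(np.clip(z, -500.0, 500.0)))


def four_pl_inverse(
    y: float, bottom: float, top: float, ec50: float, hill: float
) -> float:
    """Concentration at which the 4PL curve takes response ``y``.

    ``x = ec50 * ((top - bottom)/(y - bottom) - 1)**(-1/hill)``.  ``y`` must
    lie strictly between ``bottom`` and ``top``.
    """
    lo, hi = min(bottom, top), max(bottom, top)
    if not (lo < y < hi):
        raise ValueError(f"response {y} outside the open range ({lo}, {hi})")
    ratio = (top - bottom) / (y - bottom) - 1.0
    return float(ec50 * ratio ** (-1.0 / hill))
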