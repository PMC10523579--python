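"""Ca²⁺ dye-video trace extraction with artifact-excluding ROI logic.

The region of interest keeps pixels whose temporal-mean intensity lies
between a low percentile (background) and a high percentile (saturated hot
spots from debris or dye aggregates); a morphological opening removes
isolated specks.  The per-frame ROI mean is reported as ΔF = F − F₀ with F₀
the pre-stimulus baseline (ΔF/F₀ available by flag).  Transient kinetics
are delegated to :func:`ectpipe.traces.fit_biexponential`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import morphology

from .timeseries import TimeSeries

__all__ = ["RoiSpec", "build_roi", "extract_trace"]


@dataclass
class RoiSpec:
    """Inclusion mask plus the percentile cuts that produced it."""

    mask: np.ndarray
    lo_pct: float
    hi_pct: float

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError("ROI mask is empty")


def build_roi(
    stack: np.ndarray,
    lo_pct: float = 10.0,
    hi_pct: float = 99.5,
    min_speck_px: int = 4,
) -> RoiSpec:
    """ROI from the temporal-mean image: keep (P_lo, P_hi) percentile band.

    Pixels below the ``lo_pct`` percentile of the temporal mean are treated
    as background, pixels above ``hi_pct`` as bright artifacts; both are
    excluded.  Opening with a ``min_speck_px``-pixel footprint removes
    specks.  Raises with suggested looser bounds if the mask comes out
    empty.
    """
    if stack.ndim != 3 or stack.shape[0] < 10:
        raise ValueError("need a (frames, H, W) stack with at least 10 frames")
    if lo_pct >= hi_pct:
        raise ValueError("lo_pct must be below hi_pct")
    mean_img = stack.mean(axis=0)
    if np.ptp(mean_img) == 0:
        # degenerate uniform image: no tails to cut
        return RoiSpec(np.ones(mean_img.shape, bool), lo_pct, hi_pct)
    lo, hi = np.percentile(mean_img, [lo_pct, hi_pct])
    # upper cut only bites when something actually exceeds the percentile;
    # otherwise a tie at the maximum would empty the mask
    upper = mean_img < hi if (mean_img > hi).any() else mean_img <= hi
    mask = (mean_img > lo) & upper
    mask = morphology.opening(mask, morphology.disk(1))
    mask = morphology.remove_small_objects(mask, max_size=min_speck_px)
    if not mask.any():
        raise ValueError(
            f"empty ROI with percentiles ({lo_pct}, {hi_pct}); "
            "try a lower lo_pct or higher hi_pct"
        )
    return RoiSpec(mask, lo_pct, hi_pct)


def extract_trace(
    stack: np.ndarray,
    roi: RoiSpec,
    fs: float = 100.0,
    baseline_frames: int = 10,
    normalize: bool = False,
) -> TimeSeries:
    """Per-frame ROI mean intensity as a ΔF time series.

    F₀ is the mean of the first ``baseline_frames`` frames (the pre-stimulus
    quiescent period).  With ``normalize=True`` the trace is ΔF/F₀ instead
    of ΔF.
    """
    if stack.ndim != 3:
        raise ValueError("need a (frames, H, W) stack")
    if stack.shape[1:] != roi.mask.shape:
        raise ValueError("ROI mask shape does not match the stack frames")
    f = stack[:, roi.mask].mean(axis=1)
    f0 = float(f[:baseline_frames].mean())
    y = (f - f0) / f0 if normalize else f - f0
    t = np.arange(len(f)) / fs
    return TimeSeries(t, y, fs, "dF/F0" if normalize else "dF")
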