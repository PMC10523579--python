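"""Four-parameter logistic (4PL) concentration–response analysis.

``y = bottom + (top - bottom) / (1 + (EC50/x)^hill)``, fitted by least
squares in log-concentration space.  The Hill coefficient is signed:
positive for ascending (agonist) curves, negative for descending
(inhibitor) curves, so EC₅₀ and IC₅₀ come out of the same parameterization.
When several replicate tissues are fitted, the potency is aggregated as the
geometric mean of the per-replicate EC₅₀ values.  The inverse map supports
standard-curve interpolation (e.g. immunoassay concentrations from measured
responses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import four_pl, four_pl_inverse

__all__ = ["DoseResponseFit", "fit_4pl", "fit_4pl_grouped", "invert_4pl"]


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters with standard errors and diagnostics."""

    bottom: float
    top: float
    ec50: float
    hill: float
    se: dict[str, float]
    rmse: float
    converged: bool = True

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return four_pl(x, self.bottom, self.top, self.ec50, self.hill)


def _model_log(logx, bottom, top, logec50, hill):
    z = hill * (logec50 - logx) * np.log(10.0)
    return bottom + (top - bottom) / (1.0 + np.exp(np.clip(z, -500, 500)))


def fit_4pl(
    conc: np.ndarray,
    response: np.ndarray,
    direction: str = "auto",
    fix_bottom: float | None = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit on log10 concentration.

    ``direction`` seeds the Hill sign: ``"ascending"`` (agonist),
    ``"descending"`` (inhibitor) or ``"auto"`` (from the correlation of
    response with log concentration).  ``fix_bottom`` constrains the lower
    asymptote (useful for full inhibitors).  Requires at least four
    distinct positive concentrations; data with no dose dependence raise an
    error.
    """
    x = np.asarray(conc, dtype=float)
    y = np.asarray(response, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    logx = np.log10(x)
    if np.ptp(y) <= 1e-12 * max(1.0, abs(np.mean(y))):
        raise ValueError("no dose dependence: responses are flat")

    rho = stats.spearmanr(logx, y).statistic
    if direction == "auto":
        direction = "descending" if rho < 0 else "ascending"
    sgn = 1.0 if direction == "ascending" else -1.0

    ylo, yhi = float(y.min()), float(y.max())
    b0 = ylo if fix_bottom is None else fix_bottom
    t0 = yhi
    p0 = [b0, t0, float(np.median(logx)), sgn * 1.0]
    lb = [-np.inf, -np.inf, logx.min() - 3, -20.0 if sgn < 0 else 1e-3]
    ub = [np.inf, np.inf, logx.max() + 3, -1e-3 if sgn < 0 else 20.0]
    if fix_bottom is not None:
        lb[0], ub[0] = fix_bottom - 1e-12, fix_bottom + 1e-12

    try:
        popt, pcov = optimize.curve_fit(
            _model_log, logx, y, p0=np.clip(p0, lb, ub), bounds=(lb, ub), maxfev=20000
        )
    except RuntimeError as e:
        raise RuntimeError(f"4PL fit failed to converge: {e}") from None
    bottom, top, logec50, hill = popt
    perr = np.sqrt(np.diag(pcov))
    resid = _model_log(logx, *popt) - y
    fit = DoseResponseFit(
        bottom=float(bottom),
        top=float(top),
        ec50=float(10.0**logec50),
        hill=float(hill),
        se={"bottom": float(perr[0]), "top": float(perr[1]),
            "log10_ec50": float(perr[2]), "hill": float(perr[3])},
        rmse=float(np.sqrt(np.mean(resid**2))),
    )
    return fit


def fit_4pl_grouped(
    table: pd.DataFrame,
    direction: str = "auto",
    pooled: bool = False,
    conc_col: str = "concentration",
    resp_col: str = "response",
    rep_col: str = "replicate",
) -> tuple[float, list[DoseResponseFit]]:
    """Fit per replicate tissue and aggregate EC₅₀ as the geometric mean.

    With ``pooled=True`` a single fit over all rows is returned instead
    (its EC₅₀ as the aggregate).  Returns ``(ec50_geomean, fits)``.
    """
    if pooled:
        fit = fit_4pl(table[conc_col].to_numpy(), table[resp_col].to_numpy(), direction)
        return fit.ec50, [fit]
    fits = [
        fit_4pl(g[conc_col].to_numpy(), g[resp_col].to_numpy(), direction)
        for _, g in table.groupby(rep_col)
    ]
    ec50s = np.array([f.ec50 for f in fits])
    return float(np.exp(np.mean(np.log(ec50s)))), fits


def invert_4pl(fit: DoseResponseFit, y: float) -> float:
    """Concentration at which the fitted curve takes response ``y``.

    ``y`` must lie strictly between the fitted asymptotes; the round trip
    ``invert_4pl(fit, fit(x)) == x`` holds to numerical precision.
    """
    return four_pl_inverse(y, fit.bottom, fit.top, fit.ec50, fit.hill)
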