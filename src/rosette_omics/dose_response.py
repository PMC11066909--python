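"""Four-parameter logistic dose-response fitting and IC50 comparison.

Model: ``y = bottom + (top - bottom) / (1 + (x / ic50)^hill)`` with concentration
``x`` in molar.  The reported IC50 is the curve's midpoint parameter (relative
EC50 convention): the fitted response at x = ic50 is exactly (top + bottom) / 2.
Fitting is least squares on log10 concentration with data-quantile
initialization and a small restart schedule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .core_io import DoseResponseTable, ValidationError

__all__ = ["four_pl", "DoseResponseFit", "fit_4pl", "ic50_compare"]


def four_pl(x, bottom: float, top: float, hill: float, ic50: float):
    """Evaluate the 4PL curve at concentration(s) ``x``."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


def _four_pl_logx(logx, bottom, top, hill, log_ic50):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logx - log_ic50)))


@dataclass
class DoseResponseFit:
    cell_line: str
    bottom: float
    top: float
    hill: float
    ic50: float
    sse: float
    converged: bool
    stderr: dict[str, float] = field(default_factory=dict)
    message: str = ""

    def predict(self, x) -> np.ndarray:
        return four_pl(x, self.bottom, self.top, self.hill, self.ic50)


def fit_4pl(table: DoseResponseTable, n_restarts: int = 3) -> DoseResponseFit:
    """Least-squares 4PL fit with quantile initialization and restarts.

    Initialization: bottom/top from the smallest/largest per-concentration mean
    response, ic50 from the concentration whose mean response is nearest the
    half-maximum, hill = 1.  Up to ``n_restarts`` perturbed re-initializations
    are tried before declaring non-convergence.  Parameters are canonicalized
    so that top >= bottom (the hill sign flips accordingly).
    """
    x = table.concentrations
    y = table.responses
    if not np.all(np.isfinite(y)):
        raise ValidationError("responses must be finite")
    if np.allclose(y, y[0]):
        raise ValidationError("responses are constant; 4PL fit is undefined")
    logx = np.log10(x)
    means = pd.Series(y).groupby(pd.Series(x)).mean()
    b0, t0 = float(means.min()), float(means.max())
    half = (b0 + t0) / 2.0
    ic0 = float(means.index[np.argmin(np.abs(means.to_numpy() - half))])
    p0 = np.array([b0, t0, 1.0, np.log10(ic0)])

    rng = np.random.default_rng(0)
    best = None
    for attempt in range(n_restarts + 1):
        start = p0 if attempt == 0 else p0 + rng.normal(
            0.0, [0.1 * (t0 - b0 + 1e-12)] * 2 + [0.5, 0.5], size=4
        )
        try:
            with warnings.catch_warnings():
                # a perfect fit makes the covariance singular; stderr is NaN then
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, pcov = curve_fit(
                    _four_pl_logx, logx, y, p0=start, maxfev=20000, xtol=1e-14, ftol=1e-14
                )
        except RuntimeError:
            continue
        resid = y - _four_pl_logx(logx, *popt)
        sse = float(resid @ resid)
        if best is None or sse < best[2]:
            best = (popt, pcov, sse)

    if best is None:
        return DoseResponseFit(
            table.cell_line, np.nan, np.nan, np.nan, np.nan, np.inf, False,
            message="optimizer failed to converge after restart schedule",
        )
    popt, pcov, sse = best
    bottom, top, hill, log_ic50 = (float(v) for v in popt)
    if top < bottom:  # canonical orientation: top >= bottom
        bottom, top, hill = top, bottom, -hill
    ic50 = float(10.0**log_ic50)
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(4, np.nan)
    stderr = {
        "bottom": float(perr[0]),
        "top": float(perr[1]),
        "hill": float(perr[2]),
        "ic50": float(np.log(10.0) * ic50 * perr[3]),  # delta method from log10 scale
    }
    return DoseResponseFit(table.cell_line, bottom, top, hill, ic50, sse, True, stderr)


def ic50_compare(fits: list[DoseResponseFit]) -> pd.DataFrame:
    """Rank converged fits by IC50 with fold differences versus the most potent.

    Non-converged fits are dropped with a warning; at least two converged fits
    are required.  Ties are broken by cell line id for a stable order.
    """
    kept = [f for f in fits if f.converged]
    dropped = [f.cell_line for f in fits if not f.converged]
    if dropped:
        warnings.warn(f"excluding non-converged fit(s): {dropped}", stacklevel=2)
    if len(kept) < 2:
        raise ValidationError("need >= 2 converged fits to compare IC50s")
    df = pd.DataFrame(
        {
            "cell_line": [f.cell_line for f in kept],
            "ic50": [f.ic50 for f in kept],
            "bottom": [f.bottom for f in kept],
            "top": [f.top for f in kept],
            "hill": [f.hill for f in kept],
        }
    ).sort_values(["ic50", "cell_line"], kind="mergesort").reset_index(drop=True)
    df["fold_vs_min"] = df["ic50"] / df["ic50"].iloc[0]
    return df
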