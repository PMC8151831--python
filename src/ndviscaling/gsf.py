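"""Generalized structure functions (GSF).

The q-th order structure function of a series x is the ensemble average
of absolute increments, M_q(tau) = < |x(i+tau) - x(i)|^q > over all n-tau
overlapping pairs. For a scale-invariant process M_q(tau) ~ C_q tau^zeta(q);
the scaling exponent zeta(q) is the log-log slope over a chosen lag range
and H(q) = zeta(q)/q is the generalized Hurst exponent. q = 2 gives the
second-order variogram; only positive q are supported (negative moments of
increments diverge).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import EvenSeries
from .spectrum import DEFAULT_Q_GRID, R2_FLOOR, FitError, ScalingSpectrum, delta_h_from, loglog_slope

__all__ = ["MomentTable", "structure_function", "fit_scaling", "DEFAULT_LAGS"]

#: Default lag grid, 1..8 samples = 8..64 days at the 8-day cadence.
DEFAULT_LAGS = np.arange(1, 9)


@dataclass
class MomentTable:
    """Structure-function moments M(q, tau) on a q x lag grid."""

    q_grid: np.ndarray
    lags: np.ndarray
    moments: np.ndarray  # shape (len(q_grid), len(lags))
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.moments, index=pd.Index(self.q_grid, name="q"),
                          columns=pd.Index(self.lags, name="lag"))
        return df


def structure_function(series, q_grid=DEFAULT_Q_GRID, lags=DEFAULT_LAGS) -> MomentTable:
    """Compute M(q, tau) over all overlapping increments at each lag."""
    if isinstance(series, EvenSeries):
        x = series.require_complete("structure functions")
    else:
        x = np.asarray(series, dtype=float)
    q_grid = np.asarray(q_grid, dtype=float)
    lags = np.asarray(lags, dtype=int)
    if np.any(q_grid <= 0):
        raise ValueError("structure functions require q > 0")
    if np.any(lags < 1) or lags.max() > len(x) // 4:
        raise ValueError(f"lags must lie in [1, n/4] = [1, {len(x) // 4}]")

    moments = np.empty((len(q_grid), len(lags)))
    for j, tau in enumerate(lags):
        inc = np.abs(x[tau:] - x[:-tau])
        # power once per q; increments reused across the q grid
        moments[:, j] = [np.mean(inc**q) for q in q_grid]
    degenerate = bool(np.all(moments == 0.0))
    if degenerate:
        warnings.warn("constant series: all structure-function moments are zero", stacklevel=2)
    return MomentTable(q_grid=q_grid, lags=lags, moments=moments, degenerate=degenerate)


def fit_scaling(table: MomentTable, fit_lags=None) -> ScalingSpectrum:
    """Fit zeta(q) per q as the log-log slope of M(q, tau) over ``fit_lags``.

    H(q) = zeta(q)/q; DeltaH = H(0.25) - H(4). Fits with R^2 below 0.97
    are kept but warned about (scaling is then doubtful at those q).
    """
    if fit_lags is None:
        fit_lags = table.lags
    fit_lags = np.asarray(fit_lags, dtype=int)
    sel = np.isin(table.lags, fit_lags)
    if sel.sum() < 4:
        raise FitError("need at least 4 lags in the fit range")
    lags = table.lags[sel]
    moments = table.moments[:, sel]
    if np.any(moments <= 0):
        raise FitError("non-positive moment in the fit range; cannot take logs")

    zeta = np.empty(len(table.q_grid))
    r2 = np.empty(len(table.q_grid))
    for i in range(len(table.q_grid)):
        zeta[i], _, r2[i] = loglog_slope(lags, np.log(moments[i]))
    h = zeta / table.q_grid
    if np.any(r2 < R2_FLOOR):
        bad = table.q_grid[r2 < R2_FLOOR]
        warnings.warn(f"structure-function fit R^2 < {R2_FLOOR} at q = {bad}", stacklevel=2)
    return ScalingSpectrum(
        q_grid=table.q_grid, zeta=zeta, h=h,
        delta_h=delta_h_from(table.q_grid, h),
        fit_r2=r2, method="gsf",
        notes={"fit_lags": lags.tolist()},
    )
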