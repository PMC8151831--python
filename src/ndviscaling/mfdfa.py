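"""Multifractal detrended fluctuation analysis (MF-DFA).

The series is integrated into a profile y(i) = sum_{k<=i} (x(k) - mean),
the profile is cut into floor(N/s) non-overlapping segments of length s
from the start and the same number from the end (2*Ns segments in all, so
the trailing remainder is not discarded), a least-squares polynomial
(linear by default) is removed from each segment, and the q-th order
fluctuation function is the generalized power mean of the segment
variances:

    F_q(s) = ( (1/(2 Ns)) * sum_nu [F^2(s, nu)]^(q/2) )^(1/q)

H(q) is the log-log slope of F_q(s) against s over the chosen scale
range; zeta(q) = q*H(q), DeltaH = H(0.25) - H(4). q = 0 is excluded (the
power mean degenerates); only positive q are used here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import EvenSeries
from .spectrum import DEFAULT_Q_GRID, R2_FLOOR, FitError, ScalingSpectrum, delta_h_from, loglog_slope

__all__ = [
    "FluctuationTable",
    "MfdfaConfig",
    "profile",
    "fluctuation_function",
    "fit_hq",
    "mfdfa_spectrum",
    "default_scales",
]


@dataclass
class FluctuationTable:
    """Fluctuation functions F_q(s) on a q x scale grid."""

    q_grid: np.ndarray
    scales: np.ndarray
    fluct: np.ndarray        # shape (len(q_grid), len(scales))
    detrend_order: int
    n_segments: np.ndarray   # Ns = floor(N/s) per scale (2*Ns segments used)
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fluct, index=pd.Index(self.q_grid, name="q"),
                            columns=pd.Index(self.scales, name="scale"))


@dataclass
class MfdfaConfig:
    """Scale/q configuration for one MF-DFA run.

    Defaults follow the 8-day-composite use: dyadic scales 4..64 samples
    (32 to 512 days), linear detrending, q from 0.25 to 4.
    """

    q_grid: np.ndarray = field(default_factory=lambda: DEFAULT_Q_GRID.copy())
    scales: np.ndarray = field(default_factory=lambda: np.array([4, 8, 16, 32, 64]))
    fit_scales: np.ndarray | None = None
    detrend_order: int = 1


def default_scales(n: int, min_scale: int = 4, max_frac: int = 4) -> np.ndarray:
    """Dyadic scale grid min_scale..n/max_frac."""
    scales = []
    s = min_scale
    while s <= n // max_frac:
        scales.append(s)
        s *= 2
    return np.asarray(scales, dtype=int)


def profile(series) -> np.ndarray:
    """Integrated profile: cumulative sum of mean-centered values."""
    if isinstance(series, EvenSeries):
        x = series.require_complete("MF-DFA")
    else:
        x = np.asarray(series, dtype=float)
    return np.cumsum(x - x.mean())


def _segment_variances(y: np.ndarray, s: int, order: int) -> np.ndarray:
    """Detrended variances F^2(s, nu) for 2*Ns segments (both profile ends)."""
    n = len(y)
    ns = n // s
    fwd = y[: ns * s].reshape(ns, s)
    bwd = y[n - ns * s:].reshape(ns, s)
    segs = np.concatenate([fwd, bwd], axis=0)
    # polynomial detrend via one least-squares solve for all segments
    t = np.arange(s, dtype=float)
    design = np.vander(t, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(design, segs.T, rcond=None)
    resid = segs - (design @ coef).T
    return np.mean(resid**2, axis=1)


def fluctuation_function(series, q_grid=DEFAULT_Q_GRID, scales=None,
                         detrend_order: int = 1) -> FluctuationTable:
    """Compute F_q(s) on a q x scale grid."""
    y = profile(series)
    n = len(y)
    q_grid = np.asarray(q_grid, dtype=float)
    if np.any(q_grid == 0):
        raise ValueError("q = 0 is not admissible in the fluctuation function")
    if np.any(q_grid < 0):
        raise ValueError("only positive q are supported")
    if scales is None:
        scales = default_scales(n)
    scales = np.asarray(scales, dtype=int)
    if scales.min() < detrend_order + 2:
        raise ValueError(f"min scale must be >= detrend_order + 2 = {detrend_order + 2}")
    if scales.max() > n // 4:
        raise ValueError(f"max scale must be <= n/4 = {n // 4}")

    fluct = np.empty((len(q_grid), len(scales)))
    n_segments = np.empty(len(scales), dtype=int)
    degenerate = False
    # variances are "zero" when at rounding-noise level relative to the profile
    tiny = max(np.abs(y).max() ** 2, 1.0) * 1e-24
    for j, s in enumerate(scales):
        f2 = _segment_variances(y, int(s), detrend_order)
        n_segments[j] = n // s
        if np.all(f2 <= tiny):
            degenerate = True
            fluct[:, j] = 0.0
            continue
        fluct[:, j] = [np.mean(f2 ** (q / 2.0)) ** (1.0 / q) for q in q_grid]
    if degenerate:
        warnings.warn(
            "profile exactly matches the segment trend model; fluctuations vanish",
            stacklevel=2,
        )
    return FluctuationTable(q_grid=q_grid, scales=scales, fluct=fluct,
                            detrend_order=detrend_order, n_segments=n_segments,
                            degenerate=degenerate)


def fit_hq(table: FluctuationTable, fit_scales=None) -> ScalingSpectrum:
    """H(q) as the per-q log-log slope of F_q(s) over ``fit_scales``."""
    if fit_scales is None:
        fit_scales = table.scales
    fit_scales = np.asarray(fit_scales, dtype=int)
    sel = np.isin(table.scales, fit_scales)
    if sel.sum() < 4:
        raise FitError("need at least 4 scales in the fit range")
    scales = table.scales[sel]
    fluct = table.fluct[:, sel]
    if np.any(fluct <= 0):
        raise FitError("non-positive fluctuation in the fit range; cannot take logs")

    h = np.empty(len(table.q_grid))
    r2 = np.empty(len(table.q_grid))
    for i in range(len(table.q_grid)):
        h[i], _, r2[i] = loglog_slope(scales, np.log(fluct[i]))
    zeta = table.q_grid * h
    if np.any(r2 < R2_FLOOR):
        bad = table.q_grid[r2 < R2_FLOOR]
        warnings.warn(f"MF-DFA fit R^2 < {R2_FLOOR} at q = {bad}", stacklevel=2)
    return ScalingSpectrum(
        q_grid=table.q_grid, zeta=zeta, h=h,
        delta_h=delta_h_from(table.q_grid, h),
        fit_r2=r2, method="mfdfa",
        notes={"fit_scales": scales.tolist(), "detrend_order": table.detrend_order},
    )


def mfdfa_spectrum(series, config: MfdfaConfig | None = None) -> ScalingSpectrum:
    """One-call MF-DFA: fluctuation table + H(q) fit under a config."""
    config = config or MfdfaConfig()
    table = fluctuation_function(series, q_grid=config.q_grid, scales=config.scales,
                                 detrend_order=config.detrend_order)
    return fit_hq(table, fit_scales=config.fit_scales)
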