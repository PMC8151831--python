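"""Shared scaling-spectrum container for GSF and MF-DFA results."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: q grid used throughout: 0.25 to 4 in steps of 0.25. The multifractality
#: width DeltaH = H(0.25) - H(4) uses the grid's endpoints.
DEFAULT_Q_GRID = np.round(np.arange(1, 17) * 0.25, 10)
DELTA_H_Q = (0.25, 4.0)

#: R^2 floor below which a per-q log-log fit is flagged as poorly scaling.
R2_FLOOR = 0.97


class FitError(ValueError):
    pass


@dataclass
class ScalingSpectrum:
    """Generalized Hurst exponents H(q), scaling exponents zeta(q) and DeltaH.

    For the structure-function route zeta(q) is fitted and H(q) = zeta(q)/q;
    for MF-DFA H(q) is fitted and zeta(q) = q*H(q). ``delta_h`` is
    H(0.25) - H(4): zero for a monofractal, growing with the spread
    between the scaling of small and large fluctuations.
    """

    q_grid: np.ndarray
    zeta: np.ndarray
    h: np.ndarray
    delta_h: float
    fit_r2: np.ndarray
    method: str  # "gsf" | "mfdfa"
    notes: dict = field(default_factory=dict)

    def h_at(self, q: float) -> float:
        idx = np.flatnonzero(np.isclose(self.q_grid, q))
        if not len(idx):
            raise KeyError(f"q={q} not on the spectrum's grid")
        return float(self.h[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"q": self.q_grid, "zeta": self.zeta, "h": self.h, "fit_r2": self.fit_r2})


def delta_h_from(q_grid: np.ndarray, h: np.ndarray) -> float:
    """H(0.25) - H(4); NaN (with a warning) if the endpoints are off-grid."""
    lo, hi = DELTA_H_Q
    try:
        i_lo = int(np.flatnonzero(np.isclose(q_grid, lo))[0])
        i_hi = int(np.flatnonzero(np.isclose(q_grid, hi))[0])
    except IndexError:
        warnings.warn(f"q grid lacks {lo} and/or {hi}; DeltaH undefined", stacklevel=2)
        return float("nan")
    return float(h[i_lo] - h[i_hi])


def loglog_slope(x: np.ndarray, logy: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and R^2 of logy against log(x)."""
    lx = np.log(np.asarray(x, dtype=float))
    slope, icpt = np.polyfit(lx, logy, 1)
    pred = slope * lx + icpt
    ss_tot = np.sum((logy - logy.mean()) ** 2)
    r2 = 1.0 - np.sum((logy - pred) ** 2) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(icpt), float(r2)
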