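"""Monotonic-trend and change-point tests for evenly sampled series.

Mann-Kendall: S = sum over pairs i<j of sign(x_j - x_i); Kendall's tau-b
with the standard tie corrections; two-sided p from the continuity-
corrected normal approximation of S.

Pettitt: the rank-based change-point test. U_t = sum_{i<=t} sum_{j>t}
sign(x_j - x_i); the split maximizing |U_t| is the candidate change
point, with the classical tail approximation
p = 2 exp(-6 K^2 / (n^3 + n^2)), K = max_t |U_t|.

Both are two-sided and rank-based (invariant under strictly monotone
transformations of the values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .series import EvenSeries

__all__ = ["TrendResult", "ChangePointResult", "mann_kendall", "pettitt"]


@dataclass
class TrendResult:
    s_statistic: int
    kendall_tau: float
    z_score: float
    p_value: float
    direction: str  # increasing | decreasing | none

    def summary_row(self) -> dict:
        return {
            "trend": self.direction,
            "kendalls_tau": round(self.kendall_tau, 4),
            "p_value": self.p_value,
        }


@dataclass
class ChangePointResult:
    u_statistics: np.ndarray  # U_t for t = 1..n-1
    k_statistic: int
    change_index: int  # samples in the pre-change segment (1-based split t)
    p_value: float


def _as_values(series, min_n: int, test: str) -> np.ndarray:
    if isinstance(series, EvenSeries):
        x = series.require_complete(test)
    else:
        x = np.asarray(series, dtype=float)
        if np.any(~np.isfinite(x)):
            raise ValueError(f"{test} requires a series without missing values")
    if len(x) < min_n:
        raise ValueError(f"{test} requires at least {min_n} samples, got {len(x)}")
    return x


def mann_kendall(series, alpha: float = 0.05) -> TrendResult:
    """Two-sided Mann-Kendall monotonic trend test."""
    x = _as_values(series, 10, "Mann-Kendall test")
    n = len(x)
    sgn = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(sgn, k=1).sum())

    # tie-corrected variance and tau-b denominator
    _, counts = np.unique(x, return_counts=True)
    t = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(t * (t - 1) * (2 * t + 5))) / 18.0
    n_pairs = n * (n - 1) / 2.0
    tie_pairs = np.sum(t * (t - 1) / 2.0)
    denom = np.sqrt(n_pairs * (n_pairs - tie_pairs))
    tau = s / denom if denom > 0 else 0.0

    if var_s <= 0 or s == 0:
        z = 0.0
    else:
        z = (s - np.sign(s)) / np.sqrt(var_s)  # continuity correction
    p = min(1.0, 2.0 * norm.sf(abs(z))) if z != 0 else 1.0
    if p < alpha and s != 0:
        direction = "increasing" if s > 0 else "decreasing"
    else:
        direction = "none"
    return TrendResult(s_statistic=s, kendall_tau=float(tau), z_score=float(z),
                       p_value=float(p), direction=direction)


def pettitt(series) -> ChangePointResult:
    """Pettitt single change-point test.

    ``change_index`` is the split t in 1..n-1 maximizing |U_t| (number of
    samples before the candidate change); ties take the earliest split.
    """
    x = _as_values(series, 20, "Pettitt test")
    n = len(x)
    r = rankdata(x)  # midranks; equals the sign double-sum for distinct values
    u = 2.0 * np.cumsum(r)[:-1] - np.arange(1, n) * (n + 1)
    k = float(np.max(np.abs(u)))
    split = int(np.argmax(np.abs(u))) + 1
    p = min(1.0, 2.0 * np.exp(-6.0 * k * k / (n**3 + n**2)))
    return ChangePointResult(
        u_statistics=u.astype(np.int64) if np.allclose(u, np.round(u)) else u,
        k_statistic=int(round(k)),
        change_index=split,
        p_value=float(p),
    )
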