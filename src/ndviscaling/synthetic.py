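"""Synthetic series with known scaling structure.

Ground-truth inputs for the scaling estimators: Brownian motion (H = 0.5
reference), exact fractional Gaussian noise of tunable Hurst exponent
(monofractal reference), the deterministic binomial multiplicative cascade
(multifractal reference with closed-form generalized Hurst exponents), and
an NDVI-like series emulating an 18-year, 46-composites-per-year
vegetation-index record: annual seasonality, a slow monotone trend, one
abrupt level shift, long-range-correlated noise and sparse missing values.

Every generator is a pure function of its :class:`SimSpec` — identical
spec (seed included) gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .series import EvenSeries, SLOTS_PER_YEAR

__all__ = [
    "SimSpec",
    "SimSpecError",
    "generate",
    "gen_white_noise",
    "gen_brownian",
    "gen_fgn",
    "gen_binomial_cascade",
    "gen_ndvi_like",
    "cascade_h_theory",
    "fgn_autocovariance",
]

GENERATORS = ("white_noise", "brownian", "fgn", "binomial_cascade", "ndvi_like")

#: Default NDVI-like record: 18 years of 46 8-day composites.
DEFAULT_N = 18 * SLOTS_PER_YEAR  # 828


class SimSpecError(ValueError):
    """Invalid simulation specification."""


@dataclass(frozen=True)
class SimSpec:
    """Specification of one synthetic series.

    Only the fields relevant to ``generator`` are consulted. Defaults for
    the NDVI-like generator emulate the study conditions the package is
    built around: 828 samples (18 y x 46), seasonal amplitude 15 index
    units around a base level of 35, a slow trend, a single abrupt shift
    about a quarter of the way in, persistent (H = 0.7) noise of s.d. 3
    index units, and a vanishing fraction (<0.01 %) of missing values.
    """

    n_points: int = DEFAULT_N
    generator: str = "ndvi_like"
    hurst: float = 0.7            # fgn / ndvi_like noise persistence
    cascade_p: float = 0.3        # binomial cascade weight
    cascade_levels: int = 13      # cascade length = 2**levels
    base_level: float = 35.0      # ndvi_like mean level (0-100 NDVI scale)
    seasonal_amplitude: float = 15.0
    trend_slope: float = -0.005   # index units per sample
    changepoint_index: int = 5 * SLOTS_PER_YEAR
    changepoint_shift: float = -3.0
    noise_sd: float = 3.0
    gap_fraction: float = 0.0001  # fraction of samples masked missing
    seed: int = 0

    def validate(self) -> None:
        if self.generator not in GENERATORS:
            raise SimSpecError(f"unknown generator {self.generator!r}; choose from {GENERATORS}")
        if self.n_points < 16:
            raise SimSpecError(f"n_points must be >= 16, got {self.n_points}")
        if self.generator == "fgn" and not 0.0 < self.hurst < 1.0:
            raise SimSpecError(f"hurst must lie in (0, 1), got {self.hurst}")
        if self.generator == "binomial_cascade":
            if not 0.0 < self.cascade_p < 1.0:
                raise SimSpecError(f"cascade_p must lie in (0, 1), got {self.cascade_p}")
            if self.cascade_levels < 4:
                raise SimSpecError(f"cascade_levels must be >= 4, got {self.cascade_levels}")
        if self.generator == "ndvi_like":
            if not 0 <= self.changepoint_index < self.n_points:
                raise SimSpecError(
                    f"changepoint_index {self.changepoint_index} outside series of {self.n_points}"
                )
            if not 0.0 <= self.gap_fraction < 0.25:
                raise SimSpecError(f"gap_fraction must lie in [0, 0.25), got {self.gap_fraction}")
            if not 0.0 < self.hurst < 1.0:
                raise SimSpecError(f"hurst must lie in (0, 1), got {self.hurst}")

    def to_dict(self) -> dict:
        return asdict(self)


def generate(spec: SimSpec) -> EvenSeries:
    """Dispatch to the generator named in ``spec``."""
    spec.validate()
    return {
        "white_noise": gen_white_noise,
        "brownian": gen_brownian,
        "fgn": gen_fgn,
        "binomial_cascade": gen_binomial_cascade,
        "ndvi_like": gen_ndvi_like,
    }[spec.generator](spec)


def _rng(spec: SimSpec) -> np.random.Generator:
    return np.random.default_rng(spec.seed)


def gen_white_noise(spec: SimSpec) -> EvenSeries:
    """I.i.d. standard Gaussian samples (H = 0.5 stationary reference)."""
    spec.validate()
    return EvenSeries.from_values(_rng(spec).standard_normal(spec.n_points))


def gen_brownian(spec: SimSpec, increments: np.ndarray | None = None) -> EvenSeries:
    """Random walk: cumulative sum of i.i.d. standard Gaussian increments.

    ``increments`` is a test hook that bypasses the random draw (and with
    it the spec's length requirement).
    """
    if increments is None:
        spec.validate()
        increments = _rng(spec).standard_normal(spec.n_points)
    increments = np.asarray(increments, dtype=float)
    return EvenSeries.from_values(np.cumsum(increments))


def fgn_autocovariance(lags, hurst: float) -> np.ndarray:
    """Autocovariance of unit-variance fractional Gaussian noise.

    gamma(k) = (|k+1|^(2H) - 2|k|^(2H) + |k-1|^(2H)) / 2; in particular
    gamma(1) = 2^(2H-1) - 1.
    """
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * (np.abs(k + 1) ** h2 - 2.0 * k**h2 + np.abs(k - 1) ** h2)


def _fgn_values(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact-in-distribution fGn via Davies–Harte circulant embedding.

    The covariance of the length-n sample is embedded in a circulant
    matrix of order 2n whose eigenvalues (FFT of the first row) are
    non-negative for fGn; a complex Gaussian vector shaped by their square
    roots then yields an exact stationary Gaussian sample — no filter
    approximation.
    """
    if abs(hurst - 0.5) < 1e-12:
        return rng.standard_normal(n)
    gamma = fgn_autocovariance(np.arange(n + 1), hurst)
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, length 2n
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * lam.max():
        raise RuntimeError("circulant embedding not nonnegative definite")  # pragma: no cover
    lam = np.clip(lam, 0.0, None)
    m = len(row)
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    # Re(ifft(sqrt(lam) z)) * sqrt(m) has exactly the circulant covariance
    sample = np.sqrt(m) * np.fft.ifft(np.sqrt(lam) * z).real
    return sample[:n]


def gen_fgn(spec: SimSpec) -> EvenSeries:
    """Stationary fractional Gaussian noise with the spec's Hurst exponent."""
    spec.validate()
    if spec.generator != "fgn":
        raise SimSpecError("gen_fgn requires generator='fgn'")
    return EvenSeries.from_values(_fgn_values(spec.n_points, spec.hurst, _rng(spec)))


def gen_binomial_cascade(spec: SimSpec) -> EvenSeries:
    """Deterministic binomial multiplicative measure of length 2**levels.

    Value at index k is p^ones(k) * (1-p)^(levels-ones(k)) with ones(k)
    the number of 1-bits of k; the measure sums to one. For p != 0.5 this
    is the standard multifractal benchmark whose generalized Hurst
    exponents are :func:`cascade_h_theory`.
    """
    spec.validate()
    p, levels = spec.cascade_p, spec.cascade_levels
    k = np.arange(2**levels, dtype=np.uint64)
    ones = np.bitwise_count(k).astype(np.int64)
    values = p**ones * (1.0 - p) ** (levels - ones)
    return EvenSeries.from_values(values)


def cascade_h_theory(q: float, p: float) -> float:
    """Closed-form generalized Hurst exponent of the binomial measure.

    H(q) = 1/q - log2(p^q + (1-p)^q) / q, valid for q > 0. Independent of
    q at p = 0.5 (monofractal limit, H = 1).
    """
    q = float(q)
    if q == 0:
        raise ValueError("cascade_h_theory is undefined at q = 0")
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie in (0, 1), got {p}")
    return 1.0 / q - np.log2(p**q + (1.0 - p) ** q) / q


def gen_ndvi_like(spec: SimSpec) -> EvenSeries:
    """NDVI-like series: seasonality + trend + level shift + fGn noise + gaps.

    A single annual sinusoid (period 46 samples) carries the seasonality;
    the anomaly construction removes any calendar-periodic component
    whatever its shape, so a sinusoid suffices for testing it. Values are
    clipped to the 0-100 NDVI scale; a ``gap_fraction`` share of positions
    is masked missing (positions retained, matching the gap filler's
    contract).
    """
    spec.validate()
    if spec.generator != "ndvi_like":
        raise SimSpecError("gen_ndvi_like requires generator='ndvi_like'")
    rng = _rng(spec)
    n = spec.n_points
    i = np.arange(n)
    base = EvenSeries.from_values(np.zeros(n))
    season = spec.seasonal_amplitude * np.sin(2.0 * np.pi * (base.calendar_slot - 1) / SLOTS_PER_YEAR)
    trend = spec.trend_slope * i
    shift = np.where(i >= spec.changepoint_index, spec.changepoint_shift, 0.0)
    noise = spec.noise_sd * _fgn_values(n, spec.hurst, rng)
    values = np.clip(spec.base_level + season + trend + shift + noise, 0.0, 100.0)
    mask = np.zeros(n, dtype=bool)
    n_gaps = int(round(spec.gap_fraction * n))
    if n_gaps:
        mask[rng.choice(n, size=n_gaps, replace=False)] = True
    return base.with_values(values, missing_mask=mask)
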