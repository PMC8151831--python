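"""NDVI and NDVI-anomaly construction from surface reflectance.

Pipeline, in the order it must run: NDVI from RED/NIR with quality
screening -> running-average gap filling -> Savitzky-Golay smoothing ->
calendar-slot anomaly (NDVIa). NDVI is kept on the 0-100 scale,
NDVI = 100 * (NIR - RED) / (NIR + RED); the anomaly subtracts, from each
sample, the across-years mean of its calendar slot, which removes any
strictly calendar-periodic (seasonal) component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .series import EvenSeries, SeriesError

__all__ = [
    "ReflectancePair",
    "PreprocessingError",
    "compute_ndvi",
    "fill_gaps",
    "savgol_smooth",
    "compute_anomaly",
    "preprocess",
    "read_reflectance",
]


class PreprocessingError(ValueError):
    pass


@dataclass
class ReflectancePair:
    """RED/NIR surface reflectance with a per-sample quality verdict."""

    red: np.ndarray
    nir: np.ndarray
    quality_ok: np.ndarray

    def __post_init__(self):
        self.red = np.asarray(self.red, dtype=float)
        self.nir = np.asarray(self.nir, dtype=float)
        self.quality_ok = np.asarray(self.quality_ok, dtype=bool)
        if not len(self.red) == len(self.nir) == len(self.quality_ok):
            raise PreprocessingError("red, nir and quality_ok must have equal length")
        ok = self.quality_ok
        if np.any(self.red[ok] < 0) or np.any(self.nir[ok] < 0):
            raise PreprocessingError("negative reflectance at a quality-ok position")

    def __len__(self) -> int:
        return len(self.red)


def compute_ndvi(pair: ReflectancePair, start_year: int = 2002) -> EvenSeries:
    """NDVI = 100*(NIR-RED)/(NIR+RED); bad-quality samples become missing."""
    total = pair.nir + pair.red
    ok = pair.quality_ok
    if np.any(total[ok] <= 0):
        bad = int(np.flatnonzero(ok & (total <= 0))[0])
        raise PreprocessingError(f"NIR+RED <= 0 at retained position {bad}; NDVI undefined")
    values = np.full(len(pair), np.nan)
    values[ok] = 100.0 * (pair.nir[ok] - pair.red[ok]) / total[ok]
    return EvenSeries.from_values(values, start_year=start_year, missing_mask=~ok)


def fill_gaps(series: EvenSeries, window_dates: int = 7) -> EvenSeries:
    """Fill missing values with a centered running average of 7 dates.

    Each missing value is replaced by the mean of the available values
    within the centered ``window_dates`` window (3 dates each side for the
    default). Passes repeat — values filled in one pass can support a
    neighbour in the next — until no missing value remains; a gap no pass
    can fill raises, naming the position.
    """
    if window_dates < 3 or window_dates % 2 == 0:
        raise PreprocessingError("window_dates must be an odd count >= 3")
    frac = series.n_missing / len(series)
    if frac >= 0.25:
        warnings.warn(
            f"{frac:.1%} of values missing; running-average fills are unreliable "
            "above 25% missingness",
            stacklevel=2,
        )
    values = series.values.copy()
    missing = series.missing_mask.copy()
    half = window_dates // 2
    while missing.any():
        filled_this_pass = False
        new_values = values.copy()
        new_missing = missing.copy()
        for pos in np.flatnonzero(missing):
            lo, hi = max(0, pos - half), min(len(values), pos + half + 1)
            window = values[lo:hi][~missing[lo:hi]]
            if window.size:
                new_values[pos] = window.mean()
                new_missing[pos] = False
                filled_this_pass = True
        values, missing = new_values, new_missing
        if not filled_this_pass:
            pos = int(np.flatnonzero(missing)[0])
            raise PreprocessingError(
                f"unfillable gap at position {pos} ({series.timestamps[pos]}): "
                f"no available neighbour within the {window_dates}-date window"
            )
    return series.with_values(values)


def savgol_smooth(series: EvenSeries, window: int = 9, poly_order: int = 3) -> EvenSeries:
    """Savitzky-Golay least-squares polynomial smoothing (window 9 default).

    Edges are handled by fitting the polynomial on the truncated end
    windows (scipy's ``mode='interp'``). Requires a gap-free series.
    """
    series.require_complete("Savitzky-Golay smoothing")
    if window % 2 == 0 or window < 3:
        raise PreprocessingError("window must be an odd count >= 3")
    if poly_order >= window:
        raise PreprocessingError("poly_order must be smaller than window")
    if len(series) < window:
        raise PreprocessingError("series shorter than the smoothing window")
    smoothed = savgol_filter(series.values, window_length=window, polyorder=poly_order, mode="interp")
    return series.with_values(smoothed)


def compute_anomaly(series: EvenSeries) -> EvenSeries:
    """Anomaly: value minus the across-years mean of its calendar slot.

    Slots observed in a single year carry no across-years information;
    they are warned about and get anomaly 0. Per-slot means of the output
    are zero to machine precision, so the operation is idempotent.
    """
    values = series.require_complete("anomaly computation").copy()
    slots = series.calendar_slot
    out = np.empty_like(values)
    for slot in np.unique(slots):
        sel = slots == slot
        if sel.sum() < 2:
            warnings.warn(
                f"calendar slot {slot} observed only once; anomaly set to 0 there",
                stacklevel=2,
            )
            out[sel] = 0.0
        else:
            out[sel] = values[sel] - values[sel].mean()
    return series.with_values(out)


def preprocess(
    pair_or_series,
    gap_window: int = 7,
    sg_window: int = 9,
    sg_poly_order: int = 3,
    start_year: int = 2002,
) -> tuple[EvenSeries, EvenSeries]:
    """Run the full order-enforced pipeline; returns (smoothed NDVI, NDVIa)."""
    if isinstance(pair_or_series, ReflectancePair):
        series = compute_ndvi(pair_or_series, start_year=start_year)
    else:
        series = pair_or_series
    filled = fill_gaps(series, window_dates=gap_window)
    smooth = savgol_smooth(filled, window=sg_window, poly_order=sg_poly_order)
    return smooth, compute_anomaly(smooth)


def read_reflectance(path, sep: str = ",") -> tuple[ReflectancePair, int]:
    """Read a delimited (date, red, nir, quality) file.

    ``quality`` is truthy (1/true/ok) where the sample is ideal quality.
    Returns the pair plus the first calendar year (for the series origin).
    """
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    missing_cols = {"red", "nir", "quality"} - set(cols)
    if missing_cols:
        raise PreprocessingError(f"{path}: missing columns {sorted(missing_cols)}")
    quality = df[cols["quality"]].astype(str).str.strip().str.lower().isin({"1", "true", "ok", "ideal"})
    pair = ReflectancePair(
        red=df[cols["red"]].to_numpy(float),
        nir=df[cols["nir"]].to_numpy(float),
        quality_ok=quality.to_numpy(),
    )
    year = 2002
    if "date" in cols:
        year = int(pd.to_datetime(df[cols["date"]]).dt.year.iloc[0])
    return pair, year
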