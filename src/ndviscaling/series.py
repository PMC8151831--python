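"""Evenly sampled calendar-indexed series.

The analyses in this package operate on area-averaged vegetation-index
series sampled on the MODIS 8-day compositing calendar: 46 composites per
year, each year restarting on 1 January, so the 46th composite absorbs the
2- or 3-day year-end remainder. :class:`EvenSeries` stores the values
together with that calendar (timestamps, within-year slot 1..46) and an
explicit missing-value mask, so that quality screening and gap filling can
be expressed as mask operations rather than deletions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SLOTS_PER_YEAR = 46
COMPOSITE_DAYS = 8


class SeriesError(ValueError):
    """Raised for malformed or unusable series."""


def modis_calendar(n: int, start_year: int = 2002):
    """Timestamps and within-year slots for ``n`` successive 8-day composites.

    Composite ``k`` of a year starts on day-of-year ``1 + 8*(k-1)``; the
    year rolls over after slot 46, mirroring the MOD09A1 compositing rule.

    Returns
    -------
    timestamps : np.ndarray of datetime64[D]
    calendar_slot : np.ndarray of int, in 1..46
    """
    idx = np.arange(n)
    years = start_year + idx // SLOTS_PER_YEAR
    slots = idx % SLOTS_PER_YEAR + 1
    starts = np.array(
        [np.datetime64(f"{y}-01-01", "D") for y in range(start_year, start_year + max(1, -(-n // SLOTS_PER_YEAR)))]
    )
    timestamps = starts[years - start_year] + np.timedelta64(COMPOSITE_DAYS, "D") * (slots - 1)
    return timestamps, slots.astype(np.int64)


@dataclass
class EvenSeries:
    """A regularly sampled univariate series on the 46-slot annual calendar.

    Parameters
    ----------
    values : array of float
        Index values (NDVI on the 0-100 scale, anomalies, or any series
        handed to the scaling estimators).
    timestamps : array of datetime64, strictly increasing
    calendar_slot : array of int in [1, 46]
    missing_mask : array of bool, True where the value is missing
    """

    values: np.ndarray
    timestamps: np.ndarray
    calendar_slot: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[D]")
        self.calendar_slot = np.asarray(self.calendar_slot, dtype=np.int64)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n = len(self.values)
        if not (len(self.timestamps) == len(self.calendar_slot) == len(self.missing_mask) == n):
            raise SeriesError("values, timestamps, calendar_slot and missing_mask must have equal length")
        if n > 1 and not np.all(np.diff(self.timestamps) > np.timedelta64(0, "D")):
            raise SeriesError("timestamps must be strictly increasing")
        if np.any((self.calendar_slot < 1) | (self.calendar_slot > SLOTS_PER_YEAR)):
            raise SeriesError(f"calendar_slot must lie in [1, {SLOTS_PER_YEAR}]")
        # NaN values are implicitly missing
        self.missing_mask = self.missing_mask | ~np.isfinite(self.values)

    @classmethod
    def from_values(cls, values, start_year: int = 2002, missing_mask=None) -> "EvenSeries":
        values = np.asarray(values, dtype=float)
        ts, slots = modis_calendar(len(values), start_year=start_year)
        return cls(values=values, timestamps=ts, calendar_slot=slots, missing_mask=missing_mask)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def require_complete(self, what: str = "this operation") -> np.ndarray:
        """Return values, raising if any are missing (gap filling must run first)."""
        if self.n_missing:
            raise SeriesError(
                f"{what} requires a gap-free series; {self.n_missing} values are missing "
                "(run gap filling first)"
            )
        return self.values

    def with_values(self, values, missing_mask=None) -> "EvenSeries":
        """Copy of the series carrying new values on the same calendar."""
        out = replace(self, values=np.asarray(values, dtype=float))
        out.missing_mask = (
            np.zeros(len(out), dtype=bool) if missing_mask is None else np.asarray(missing_mask, bool)
        ) | ~np.isfinite(out.values)
        return out

    def to_frame(self) -> pd.DataFrame:
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame({"date": self.timestamps, "value": vals})


def write_series(series: EvenSeries, path, sep: str = ",") -> None:
    """Write a two-column (ISO date, value) delimited file; missing as empty."""
    series.to_frame().to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_series(path, sep: str = ",", start_year: int | None = None) -> EvenSeries:
    """Read a delimited (date, value) file into an :class:`EvenSeries`.

    Calendar slots are derived from the dates (day-of-year // 8 + 1,
    capped at 46). ``start_year`` overrides the calendar origin when dates
    are absent and the file carries a bare value column.
    """
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    if "value" not in cols:
        raise SeriesError(f"{path}: expected a 'value' column, found {list(df.columns)}")
    values = df[cols["value"]].to_numpy(dtype=float)
    if "date" in cols:
        ts = pd.to_datetime(df[cols["date"]]).to_numpy().astype("datetime64[D]")
        doy = (ts - ts.astype("datetime64[Y]").astype("datetime64[D]")).astype(int)
        slots = np.minimum(doy // COMPOSITE_DAYS + 1, SLOTS_PER_YEAR)
        return EvenSeries(values=values, timestamps=ts, calendar_slot=slots,
                          missing_mask=~np.isfinite(values))
    return EvenSeries.from_values(values, start_year=start_year or 2002,
                                  missing_mask=~np.isfinite(values))
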