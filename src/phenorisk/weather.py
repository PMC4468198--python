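"""Daily weather series and sub-daily temperature inference.

Stations record daily minimum and maximum temperature for one 365-day
year (leap days are ignored; day 1 = 1 January).  Hourly temperatures
are inferred from the daily extremes by a single full-period cosine with
its maximum at 14:00 and minimum at 02:00 — the simplest phase-anchored
choice, documented so runs are reproducible.  Future scenarios are
expressed as additive monthly deltas to tmin and tmax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DailyWeather",
    "WeatherSeries",
    "ScenarioDelta",
    "hourly_temperatures",
    "apply_scenario",
    "daily_mean",
    "month_of_day",
    "read_weather_csv",
    "write_weather_csv",
    "read_scenario_csv",
    "write_scenario_csv",
]

#: cumulative day-of-year at which each month starts (365-day calendar)
_MONTH_STARTS = np.array(
    [1, 32, 60, 91, 121, 152, 182, 213, 244, 274, 305, 335], dtype=int
)
_MONTH_LENGTHS = np.diff(np.append(_MONTH_STARTS, 366))

PEAK_HOUR = 14  # daily maximum at 14:00, minimum 12 h earlier at 02:00


@dataclass(frozen=True)
class DailyWeather:
    day_of_year: int
    tmin: float
    tmax: float

    def __post_init__(self):
        if not 1 <= self.day_of_year <= 365:
            raise ValueError("day_of_year must be in 1..365")
        if not np.isfinite(self.tmin) or not np.isfinite(self.tmax):
            raise ValueError("temperatures must be finite")
        if self.tmin > self.tmax:
            raise ValueError("tmin must not exceed tmax")


class WeatherSeries:
    """One georeferenced station-year of daily tmin/tmax.

    Internally stored as float arrays of length 365 indexed by
    day_of_year − 1.
    """

    def __init__(self, station_id: str, lon: float, lat: float, alt: float,
                 tmin: Sequence[float], tmax: Sequence[float]):
        tmin = np.asarray(tmin, dtype=float)
        tmax = np.asarray(tmax, dtype=float)
        if tmin.shape != (365,) or tmax.shape != (365,):
            raise ValueError("need exactly one record per day_of_year (365)")
        if not (np.all(np.isfinite(tmin)) and np.all(np.isfinite(tmax))):
            raise ValueError("temperatures must be finite")
        if np.any(tmin > tmax):
            raise ValueError("tmin must not exceed tmax on any day")
        if alt < 0:
            raise ValueError("altitude must be non-negative")
        self.station_id = str(station_id)
        self.lon = float(lon)
        self.lat = float(lat)
        self.alt = float(alt)
        self.tmin = tmin
        self.tmax = tmax

    @classmethod
    def from_records(cls, station_id, lon, lat, alt,
                     records: Sequence[DailyWeather]) -> "WeatherSeries":
        days = sorted(records, key=lambda r: r.day_of_year)
        doys = [r.day_of_year for r in days]
        if doys != list(range(1, 366)):
            raise ValueError("records must cover each day_of_year 1..365 once")
        return cls(station_id, lon, lat, alt,
                   [r.tmin for r in days], [r.tmax for r in days])

    def record(self, day_of_year: int) -> DailyWeather:
        return DailyWeather(day_of_year, float(self.tmin[day_of_year - 1]),
                            float(self.tmax[day_of_year - 1]))

    def daily_means(self) -> np.ndarray:
        return (self.tmin + self.tmax) / 2.0

    def __eq__(self, other):
        return (isinstance(other, WeatherSeries)
                and self.station_id == other.station_id
                and (self.lon, self.lat, self.alt) == (other.lon, other.lat, other.alt)
                and np.array_equal(self.tmin, other.tmin)
                and np.array_equal(self.tmax, other.tmax))

    def __repr__(self):
        return (f"WeatherSeries({self.station_id!r}, alt={self.alt:.0f} m, "
                f"mean T={self.daily_means().mean():.2f} C)")


@dataclass(frozen=True)
class ScenarioDelta:
    """Monthly warming deltas (degC) applied to tmin and tmax."""

    monthly_dtmin: tuple
    monthly_dtmax: tuple

    def __post_init__(self):
        dtn = np.asarray(self.monthly_dtmin, dtype=float)
        dtx = np.asarray(self.monthly_dtmax, dtype=float)
        if dtn.shape != (12,) or dtx.shape != (12,):
            raise ValueError("need 12 monthly deltas for tmin and tmax")
        if not (np.all(np.isfinite(dtn)) and np.all(np.isfinite(dtx))):
            raise ValueError("deltas must be finite")
        object.__setattr__(self, "monthly_dtmin", tuple(float(v) for v in dtn))
        object.__setattr__(self, "monthly_dtmax", tuple(float(v) for v in dtx))

    def negated(self) -> "ScenarioDelta":
        return ScenarioDelta(tuple(-v for v in self.monthly_dtmin),
                             tuple(-v for v in self.monthly_dtmax))


def month_of_day(day_of_year) -> np.ndarray:
    """0-based month index for each day_of_year on the 365-day calendar."""
    d = np.asarray(day_of_year, dtype=int)
    if np.any(d < 1) or np.any(d > 365):
        raise ValueError("day_of_year must be in 1..365")
    return np.searchsorted(_MONTH_STARTS, d, side="right") - 1


def hourly_temperatures(d: DailyWeather) -> np.ndarray:
    """24 hourly temperatures inferred from the daily extremes.

    T(h) = (tmax+tmin)/2 + (tmax-tmin)/2 * cos(2 pi (h - 14)/24), h = 0..23.
    The arithmetic mean over the 24 values equals (tmax+tmin)/2 exactly
    because the cosine completes one full period.
    """
    h = np.arange(24)
    mid = 0.5 * (d.tmax + d.tmin)
    amp = 0.5 * (d.tmax - d.tmin)
    return mid + amp * np.cos(2.0 * np.pi * (h - PEAK_HOUR) / 24.0)


def daily_mean(d: DailyWeather) -> float:
    """Daily mean temperature (tmin + tmax)/2."""
    return 0.5 * (d.tmin + d.tmax)


def apply_scenario(w: WeatherSeries, s: ScenarioDelta) -> WeatherSeries:
    """Shift each day's extremes by its calendar month's warming delta.

    Station metadata is unchanged.  If differential deltas invert a day's
    tmin/tmax ordering the two are swapped, with a warning.
    """
    months = month_of_day(np.arange(1, 366))
    tmin = w.tmin + np.asarray(s.monthly_dtmin)[months]
    tmax = w.tmax + np.asarray(s.monthly_dtmax)[months]
    bad = tmin > tmax
    if np.any(bad):
        warnings.warn(
            f"scenario deltas inverted tmin/tmax on {int(bad.sum())} day(s); swapped",
            stacklevel=2,
        )
        tmin[bad], tmax[bad] = tmax[bad], tmin[bad].copy()
    return WeatherSeries(w.station_id, w.lon, w.lat, w.alt, tmin, tmax)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_WEATHER_COLS = ["station_id", "lon", "lat", "alt_m", "day_of_year", "tmin_c", "tmax_c"]


def read_weather_csv(path) -> list[WeatherSeries]:
    """Read one or more station-years from a weather CSV.

    Columns: station_id, lon, lat, alt_m, day_of_year, tmin_c, tmax_c.
    """
    df = pd.read_csv(path)
    missing = set(_WEATHER_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"weather CSV missing columns: {sorted(missing)}")
    out = []
    for sid, grp in df.groupby("station_id", sort=False):
        grp = grp.sort_values("day_of_year")
        if list(grp["day_of_year"]) != list(range(1, 366)):
            raise ValueError(f"station {sid}: need days 1..365 exactly once")
        out.append(
            WeatherSeries(
                str(sid),
                float(grp["lon"].iloc[0]),
                float(grp["lat"].iloc[0]),
                float(grp["alt_m"].iloc[0]),
                grp["tmin_c"].to_numpy(),
                grp["tmax_c"].to_numpy(),
            )
        )
    return out


def write_weather_csv(series: Sequence[WeatherSeries], path) -> None:
    frames = []
    for w in series:
        frames.append(
            pd.DataFrame(
                {
                    "station_id": w.station_id,
                    "lon": w.lon,
                    "lat": w.lat,
                    "alt_m": w.alt,
                    "day_of_year": np.arange(1, 366),
                    "tmin_c": w.tmin,
                    "tmax_c": w.tmax,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_scenario_csv(path) -> ScenarioDelta:
    """Read a 12-row (month, dtmin_c, dtmax_c) scenario file."""
    df = pd.read_csv(path).sort_values("month")
    if list(df["month"]) != list(range(1, 13)):
        raise ValueError("scenario CSV needs months 1..12 exactly once")
    return ScenarioDelta(tuple(df["dtmin_c"]), tuple(df["dtmax_c"]))


def write_scenario_csv(s: ScenarioDelta, path) -> None:
    pd.DataFrame(
        {
            "month": np.arange(1, 13),
            "dtmin_c": s.monthly_dtmin,
            "dtmax_c": s.monthly_dtmax,
        }
    ).to_csv(path, index=False)
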