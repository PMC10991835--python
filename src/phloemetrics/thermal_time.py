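"""Growing-degree-day (GDD) thermal time.

Ripening computations in this package run on a thermal-time axis rather
than calendar time, because berry sugar accumulation tracks heat
accumulation much more closely than it tracks days.  A day's heat
contribution is the mean of its maximum and minimum temperature minus a
base threshold (10 °C is the viticulture default); negative contributions
are clamped to zero by convention, and the series is the running sum from
a chosen start date.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_T_BASE_C = 10.0

__all__ = [
    "DEFAULT_T_BASE_C",
    "GddSeries",
    "daily_gdd",
    "cumulative_gdd",
    "gdd_at",
    "read_weather_csv",
    "validate_weather",
]


class WeatherError(ValueError):
    """Invalid daily-weather table (bad temperatures, duplicate or missing days)."""


@dataclass
class GddSeries:
    """Cumulative growing degree days from ``start_date`` onward.

    ``entries`` has one row per calendar day with columns
    ``date``, ``daily_gdd`` and ``cumulative_gdd``.
    """

    start_date: pd.Timestamp
    t_base_c: float
    entries: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.start_date = pd.Timestamp(self.start_date)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def total(self) -> float:
        if self.entries.empty:
            return 0.0
        return float(self.entries["cumulative_gdd"].iloc[-1])

    def gdd_at(self, date) -> float:
        return gdd_at(self, date)


def daily_gdd(tmax_c, tmin_c, t_base_c: float = DEFAULT_T_BASE_C, clamp: bool = True):
    """Degree-days contributed by one day: max(0, (tmax+tmin)/2 - t_base).

    Accepts scalars or arrays.  With ``clamp=False`` sub-base days subtract
    (the textbook formula applied literally), which is never the convention
    used for heat summation in viticulture and is off by default.
    """
    tmax = np.asarray(tmax_c, dtype=float)
    tmin = np.asarray(tmin_c, dtype=float)
    if np.any(tmax < tmin):
        raise WeatherError("tmax_c < tmin_c in daily weather input")
    gdd = (tmax + tmin) / 2.0 - t_base_c
    if clamp:
        gdd = np.maximum(gdd, 0.0)
    if np.ndim(tmax_c) == 0 and np.ndim(tmin_c) == 0:
        return float(gdd)
    return gdd


def validate_weather(weather: pd.DataFrame) -> pd.DataFrame:
    """Check a daily weather table and return it with parsed dates.

    Requires columns ``date``, ``tmax_c``, ``tmin_c``; dates strictly
    increasing with no duplicates; tmax >= tmin on every day.
    """
    required = {"date", "tmax_c", "tmin_c"}
    missing = required - set(weather.columns)
    if missing:
        raise WeatherError(f"weather table missing columns: {sorted(missing)}")
    out = weather.copy()
    out["date"] = pd.to_datetime(out["date"])
    if out["date"].duplicated().any():
        dups = out.loc[out["date"].duplicated(), "date"].dt.date.tolist()
        raise WeatherError(f"duplicate weather dates: {dups}")
    if not out["date"].is_monotonic_increasing:
        raise WeatherError("weather dates are not sorted ascending")
    bad = out["tmax_c"] < out["tmin_c"]
    if bad.any():
        first = out.loc[bad, "date"].iloc[0].date()
        raise WeatherError(f"tmax_c < tmin_c on {first}")
    return out


def read_weather_csv(path) -> pd.DataFrame:
    """Read a weather CSV with columns date (ISO-8601), tmax_c, tmin_c."""
    return validate_weather(pd.read_csv(path))


def cumulative_gdd(
    weather: pd.DataFrame,
    start_date,
    t_base_c: float = DEFAULT_T_BASE_C,
    clamp: bool = True,
    end_date=None,
) -> GddSeries:
    """Running GDD sum from ``start_date`` (inclusive) through the weather table.

    The weather must contain ``start_date`` and be contiguous (daily, no
    gaps) from there through ``end_date`` (default: last day in the table).
    An empty date range yields an empty series.
    """
    weather = validate_weather(weather)
    start = pd.Timestamp(start_date)
    if end_date is not None:
        end = pd.Timestamp(end_date)
    elif weather.empty:
        end = start - pd.Timedelta(days=1)
    else:
        end = weather["date"].iloc[-1]

    if end < start:
        entries = pd.DataFrame(columns=["date", "daily_gdd", "cumulative_gdd"])
        return GddSeries(start_date=start, t_base_c=t_base_c, entries=entries)

    window = weather[(weather["date"] >= start) & (weather["date"] <= end)]
    expected = pd.date_range(start, end, freq="D")
    if len(window) != len(expected) or not window["date"].reset_index(drop=True).equals(
        pd.Series(expected, name="date")
    ):
        have = set(window["date"])
        gaps = [d.date() for d in expected if d not in have]
        raise WeatherError(f"weather has missing days in [{start.date()}, {end.date()}]: {gaps}")

    daily = daily_gdd(
        window["tmax_c"].to_numpy(), window["tmin_c"].to_numpy(), t_base_c, clamp=clamp
    )
    entries = pd.DataFrame(
        {
            "date": window["date"].to_numpy(),
            "daily_gdd": daily,
            "cumulative_gdd": np.cumsum(daily),
        }
    )
    return GddSeries(start_date=start, t_base_c=t_base_c, entries=entries)


def gdd_at(series: GddSeries, date) -> float:
    """Cumulative GDD on ``date`` (exact daily lookup, no interpolation)."""
    date = pd.Timestamp(date)
    if series.entries.empty:
        raise WeatherError("empty GDD series")
    if date < series.start_date:
        raise WeatherError(f"{date.date()} is before series start {series.start_date.date()}")
    last = series.entries["date"].iloc[-1]
    if date > last:
        raise WeatherError(f"{date.date()} is after series end {last.date()}")
    row = series.entries.loc[series.entries["date"] == date, "cumulative_gdd"]
    if row.empty:
        raise WeatherError(f"{date.date()} not present in GDD series")
    return float(row.iloc[0])
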