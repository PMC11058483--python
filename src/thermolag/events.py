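"""Heat-wave and cold-spell detection from daily mean temperature.

An extreme-temperature event is a run of consecutive days, inside a fixed
seasonal window, whose daily mean temperature meets a percentile threshold
(>= for heat, <= for cold) for at least a minimum duration.  The warm
window is May 15 - Sep 15; the cold window is Oct 1 - Mar 31 and wraps the
calendar year (Dec 31 -> Jan 1 are consecutive, Mar 31 -> Oct 1 are not).

Thresholds are sample percentiles (linear interpolation between order
statistics) of the daily mean temperature pooled over all *fully covered*
instances of the window in the study period, so a single threshold in
degC is attached to each definition.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureSeries",
    "SeasonWindow",
    "EventDefinition",
    "EventCalendar",
    "window_days",
    "percentile_threshold",
    "detect_events",
    "default_definitions",
    "build_catalog",
]

HEAT_PERCENTILES = (95, 97, 99)
COLD_PERCENTILES = (2, 5, 10)
DURATIONS = (2, 3, 5)
#: (percentile, min duration) for the 8 heat and 9 cold definitions.  The
#: (99th, 5 d) heat combination is omitted from the canonical catalog by
#: construction (it never occurred in the reference record).
HEAT_DEFS = [(p, d) for p in HEAT_PERCENTILES for d in DURATIONS
             if (p, d) != (99, 5)]
COLD_DEFS = [(p, d) for p in COLD_PERCENTILES for d in DURATIONS]


class TemperatureSeries:
    """Ordered daily mean temperatures.

    Parameters
    ----------
    data
        Mapping of calendar date to daily mean temperature in degC, given
        as a :class:`pandas.Series` with a datetime-like index, or anything
        ``pd.Series`` accepts.  Dates must be strictly increasing with no
        duplicates; gaps are permitted and flagged via :attr:`has_gaps`.
    """

    def __init__(self, data: pd.Series):
        s = pd.Series(data, dtype=float)
        idx = pd.DatetimeIndex(s.index).normalize()
        if len(idx) == 0:
            raise ValueError("temperature series is empty")
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0].date()
            raise ValueError(f"duplicate date in temperature series: {dup}")
        if not idx.is_monotonic_increasing:
            raise ValueError("temperature series dates must be increasing")
        s.index = idx
        self.data = s

    @property
    def start(self) -> dt.date:
        return self.data.index[0].date()

    @property
    def end(self) -> dt.date:
        return self.data.index[-1].date()

    @property
    def has_gaps(self) -> bool:
        n_span = (self.data.index[-1] - self.data.index[0]).days + 1
        return len(self.data) < n_span or self.data.isna().any()

    def __len__(self) -> int:
        return len(self.data)

    def at(self, dates) -> np.ndarray:
        """Temperatures at the given dates; NaN where absent."""
        return self.data.reindex(pd.DatetimeIndex(dates)).to_numpy()

    @classmethod
    def from_frame(cls, df: pd.DataFrame, date_col: str = "date",
                   temp_col: str = "t_mean_c") -> "TemperatureSeries":
        return cls(pd.Series(df[temp_col].to_numpy(),
                             index=pd.to_datetime(df[date_col])))


@dataclass(frozen=True)
class SeasonWindow:
    """Seasonal span given as (month, day) bounds, possibly wrapping Dec 31."""

    kind: str                 # "warm" | "cold"
    start: tuple[int, int]
    end: tuple[int, int]
    wraps_year: bool

    @classmethod
    def warm(cls) -> "SeasonWindow":
        return cls("warm", (5, 15), (9, 15), False)

    @classmethod
    def cold(cls) -> "SeasonWindow":
        return cls("cold", (10, 1), (3, 31), True)

    def contains(self, date: dt.date) -> bool:
        md = (date.month, date.day)
        if self.wraps_year:
            return md >= self.start or md <= self.end
        return self.start <= md <= self.end

    def instance(self, season_year: int) -> tuple[dt.date, dt.date]:
        """Concrete (first day, last day) of the window starting in ``season_year``."""
        first = dt.date(season_year, *self.start)
        last_year = season_year + 1 if self.wraps_year else season_year
        last = dt.date(last_year, *self.end)
        return first, last


def window_days(window: SeasonWindow, start_date: dt.date,
                end_date: dt.date) -> list[dt.date]:
    """All in-window calendar dates within ``[start_date, end_date]``."""
    if end_date < start_date:
        raise ValueError("end_date before start_date")
    days = pd.date_range(start_date, end_date, freq="D")
    return [d.date() for d in days if window.contains(d.date())]


def covered_instances(window: SeasonWindow, start_date: dt.date,
                      end_date: dt.date) -> list[tuple[dt.date, dt.date]]:
    """Window instances fully inside ``[start_date, end_date]``.

    Partial windows at the edges of the study period are excluded so that
    pooled percentiles and event percentages refer to whole seasons only.
    """
    out = []
    for year in range(start_date.year - 1, end_date.year + 1):
        first, last = window.instance(year)
        if first >= start_date and last <= end_date:
            out.append((first, last))
    return out


@dataclass(frozen=True)
class EventDefinition:
    id: str
    kind: str                 # "heat" | "cold"
    percentile: float
    min_duration: int
    window: SeasonWindow

    def __post_init__(self):
        if self.kind == "heat" and self.percentile <= 50:
            raise ValueError("heat percentile must exceed 50")
        if self.kind == "cold" and self.percentile >= 50:
            raise ValueError("cold percentile must be below 50")
        if self.min_duration < 2:
            raise ValueError("min_duration must be >= 2")


@dataclass
class EventCalendar:
    """Dated result of applying one definition to a temperature series."""

    definition: EventDefinition
    threshold_c: float
    event_days: frozenset = field(default_factory=frozenset)  # of dt.date
    n_window_days: int = 0
    coverage_start: dt.date | None = None
    coverage_end: dt.date | None = None

    @property
    def n_event_days(self) -> int:
        return len(self.event_days)

    @property
    def pct_of_window_days(self) -> float:
        if self.n_window_days == 0:
            return float("nan")
        return 100.0 * self.n_event_days / self.n_window_days


def _pooled_window_values(series: TemperatureSeries, window: SeasonWindow):
    """(dates, temps) over fully covered window instances, NaN-free."""
    instances = covered_instances(window, series.start, series.end)
    if not instances:
        first, last = window.instance(series.start.year)
        raise ValueError(
            f"series {series.start}..{series.end} does not cover any full "
            f"{window.kind} window (e.g. {first}..{last})")
    dates: list[dt.date] = []
    for first, last in instances:
        dates.extend(d.date() for d in pd.date_range(first, last, freq="D"))
    temps = series.at(dates)
    return np.asarray(dates), temps


def percentile_threshold(series: TemperatureSeries, window: SeasonWindow,
                         percentile: float, min_days: int = 30) -> float:
    """Pooled linear-interpolation percentile of window-day temperatures."""
    _, temps = _pooled_window_values(series, window)
    temps = temps[~np.isnan(temps)]
    if temps.size < min_days:
        raise ValueError(
            f"only {temps.size} {window.kind}-window days with data; "
            f"need >= {min_days} to estimate a percentile")
    return float(np.percentile(temps, percentile, method="linear"))


def detect_events(series: TemperatureSeries, definition: EventDefinition,
                  threshold: float | None = None) -> EventCalendar:
    """Flag every day of every qualifying run under ``definition``.

    A qualifying run is a maximal set of calendar-consecutive in-window
    days, all with data, all meeting the threshold, of length at least
    ``min_duration``.  Missing days and window boundaries break runs.
    ``threshold`` overrides the pooled percentile (absolute-threshold
    definitions).
    """
    if threshold is None:
        threshold = percentile_threshold(series, definition.window,
                                         definition.percentile)
    dates, temps = _pooled_window_values(series, definition.window)
    if definition.kind == "heat":
        hit = temps >= threshold
    else:
        hit = temps <= threshold
    hit &= ~np.isnan(temps)

    ords = np.array([d.toordinal() for d in dates])
    event_days: set[dt.date] = set()
    run_start = 0
    for i in range(len(dates) + 1):
        boundary = (
            i == len(dates)
            or not hit[i]
            or (i > run_start and ords[i] != ords[i - 1] + 1)
        )
        if i < len(dates) and hit[i] and not boundary:
            continue
        # close the run [run_start, i)
        if i > run_start and hit[run_start]:
            if i - run_start >= definition.min_duration:
                event_days.update(dates[run_start:i])
        if i < len(dates):
            run_start = i if hit[i] else i + 1

    return EventCalendar(
        definition=definition,
        threshold_c=threshold,
        event_days=frozenset(event_days),
        n_window_days=len(dates),
        coverage_start=series.start,
        coverage_end=series.end,
    )


def default_definitions() -> list[EventDefinition]:
    """The canonical 17-definition catalog (8 heat, 9 cold)."""
    defs = []
    warm, cold = SeasonWindow.warm(), SeasonWindow.cold()
    for i, (p, d) in enumerate(HEAT_DEFS, start=1):
        defs.append(EventDefinition(f"HW{i:02d}", "heat", p, d, warm))
    for i, (p, d) in enumerate(COLD_DEFS, start=1):
        defs.append(EventDefinition(f"CS{i:02d}", "cold", p, d, cold))
    return defs


def build_catalog(series: TemperatureSeries,
                  definitions: list[EventDefinition] | None = None,
                  ) -> list[tuple[EventDefinition, EventCalendar]]:
    """Detect events for every definition in the catalog."""
    if definitions is None:
        definitions = default_definitions()
    return [(d, detect_events(series, d)) for d in definitions]


def catalog_summary(catalog) -> pd.DataFrame:
    rows = []
    for d, cal in catalog:
        rows.append({
            "definition_id": d.id,
            "kind": d.kind,
            "percentile": d.percentile,
            "threshold_c": cal.threshold_c,
            "min_duration": d.min_duration,
            "n_event_days": cal.n_event_days,
            "pct_of_window_days": cal.pct_of_window_days,
        })
    return pd.DataFrame(rows)
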