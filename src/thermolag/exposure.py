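"""Individual exposure assignment.

Two jobs: (1) interpolate the monitoring-network PM2.5 field to each
residence by inverse-distance weighting (IDW) over great-circle distances;
(2) turn an event calendar into per-visit lagged exposures — single-day
indicators lag0..lag7 and cumulative exposures lag0-1..lag0-7, the latter
defined as the mean of the daily indicators over days 0..k before the
visit (so the regression coefficient stays in per-event-day units).
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

from .events import EventCalendar

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088
LAG_COLS = [f"x_lag{k}" for k in range(8)]
CUM_COLS = [f"x_cum0{k}" for k in range(1, 8)]


def haversine_km(point_a, point_b) -> float:
    """Great-circle distance in km between (lon, lat) points in degrees."""
    lon1, lat1 = point_a
    lon2, lat2 = point_b
    for lon, lat in ((lon1, lat1), (lon2, lat2)):
        if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
            raise ValueError(f"invalid coordinates lon={lon}, lat={lat}")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def idw(values, distances_km, power: float = 2.0, eps: float = 1e-6,
        max_km: float | None = None) -> float:
    """Inverse-distance-weighted mean with weights d**(-power).

    Stations with missing values are excluded.  A co-located station
    (distance < ``eps`` km) short-circuits interpolation and its value is
    returned (mean, if several).  With every value missing the result is
    NaN.  ``max_km`` optionally drops stations beyond a cutoff radius.
    """
    v = np.asarray(values, dtype=float)
    d = np.asarray(distances_km, dtype=float)
    if v.shape != d.shape:
        raise ValueError("values and distances must align")
    ok = ~np.isnan(v)
    if max_km is not None:
        ok &= d <= max_km
    if not ok.any():
        return float("nan")
    colocated = ok & (d < eps)
    if colocated.any():
        return float(v[colocated].mean())
    w = d[ok] ** (-power)
    return float(np.sum(w * v[ok]) / np.sum(w))


def station_distances_km(stations: pd.DataFrame, residence) -> np.ndarray:
    """Distance from one (lon, lat) residence to every station row."""
    return np.array([
        haversine_km(residence, (row.lon, row.lat))
        for row in stations.itertuples()
    ])


def daily_residence_series(network, residence, power: float = 2.0,
                           max_km: float | None = None) -> pd.Series:
    """Per-day IDW PM2.5 at one residence, indexed by date.

    ``network`` carries ``stations`` (station_id, lon, lat) and ``pm25``
    (wide frame, one column per station_id, DatetimeIndex).
    """
    stations = network.stations
    if len(stations) == 0:
        raise ValueError("empty station network")
    d = station_distances_km(stations, residence)
    vals = network.pm25[stations["station_id"]].to_numpy(dtype=float)

    ok = ~np.isnan(vals)
    dist = np.broadcast_to(d, vals.shape).copy()
    if max_km is not None:
        ok &= dist <= max_km
    w = np.where(ok, np.maximum(dist, 1e-12) ** (-power), 0.0)
    denom = w.sum(axis=1)
    num = np.where(ok, np.nan_to_num(vals) * w, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, num / denom, np.nan)

    colocated = d < 1e-6
    if colocated.any():
        sub = np.where(ok[:, colocated],
                       np.nan_to_num(vals[:, colocated]), 0.0)
        cnt = ok[:, colocated].sum(axis=1)
        has = cnt > 0
        out[has] = sub.sum(axis=1)[has] / cnt[has]
    n_missing = int(np.isnan(out).sum())
    if n_missing:
        logger.warning("IDW: %d days with no station data", n_missing)
    return pd.Series(out, index=network.pm25.index, name="pm25")


def lag_exposures(calendar: EventCalendar, visits: pd.DataFrame,
                  max_lag: int = 7) -> pd.DataFrame:
    """Per-visit single-day and cumulative lagged event exposures.

    x_lagk is 1 when (visit date - k days) was an event day; x_cum0k is
    the mean of x_lag0..x_lagk.  Visits whose lag window starts before
    the temperature series coverage are dropped (and counted in the log).
    """
    out = visits[["subject_id", "date"]].copy()
    dates = pd.to_datetime(out["date"])
    if calendar.coverage_start is not None:
        horizon = pd.Timestamp(calendar.coverage_start) + pd.Timedelta(days=max_lag)
        keep = dates >= horizon
        n_drop = int((~keep).sum())
        if n_drop:
            logger.warning("lag_exposures: dropped %d visits with lag window "
                           "before series start", n_drop)
            out = out[keep].reset_index(drop=True)
            dates = dates[keep].reset_index(drop=True)

    event_index = pd.DatetimeIndex(sorted(calendar.event_days))
    indicators = np.empty((len(out), max_lag + 1))
    for k in range(max_lag + 1):
        indicators[:, k] = (dates - pd.Timedelta(days=k)).isin(event_index)
    out["definition_id"] = calendar.definition.id
    for k in range(max_lag + 1):
        out[f"x_lag{k}"] = indicators[:, k]
    csum = indicators.cumsum(axis=1)
    for k in range(1, max_lag + 1):
        out[f"x_cum0{k}"] = csum[:, k] / (k + 1)
    return out


def visit_environment(visits: pd.DataFrame, weather: pd.DataFrame,
                      network=None, subjects: pd.DataFrame | None = None,
                      power: float = 2.0) -> pd.DataFrame:
    """Attach visit-date (lag0) meteorology and residence PM2.5 to visits.

    ``weather`` is a daily frame with date, rh_pct, pressure_mmhg.  When a
    station ``network`` and a ``subjects`` frame (subject_id, lon, lat)
    are given, pm25 is the residence-specific IDW value on the visit date.
    """
    out = visits.copy()
    out["date"] = pd.to_datetime(out["date"])
    met = weather.copy()
    met["date"] = pd.to_datetime(met["date"])
    out = out.merge(met[["date", "rh_pct", "pressure_mmhg"]],
                    on="date", how="left")
    if network is not None and subjects is not None:
        pm_cols = {}
        for row in subjects.itertuples():
            series = daily_residence_series(network, (row.lon, row.lat),
                                            power=power)
            pm_cols[row.subject_id] = series
        pm = pd.DataFrame(pm_cols)
        out["pm25"] = [
            pm.at[d, s] if d in pm.index else np.nan
            for d, s in zip(out["date"], out["subject_id"])
        ]
    return out
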