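"""File formats, configuration, and pipeline orchestration.

All tabular interchange is comma-separated UTF-8 with a header row and
ISO-8601 dates; results and manifests are JSON; configuration is YAML.
Column names are fixed:

* weather: ``date, t_mean_c, rh_pct, pressure_mmhg`` (or hourly:
  ``date, hour, t_c[, rh_pct, pressure_mmhg]``)
* stations: ``station_id, lon, lat``
* pollution: ``station_id, date, pm25``
* visits: ``subject_id, date, sex, age, education, bmi_cat, lon, lat,
  alt, wbc, rbc, hb, hct, plt`` (``height_cm``/``weight_kg`` may replace
  ``bmi_cat``)
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .events import TemperatureSeries, build_catalog, catalog_summary
from .exposure import visit_environment
from .inference import analyze_study, report
from .synthetic import (ClimateParams, CohortParams, Episode, ExposureEffect,
                        RESPONSES, StationNetwork, TruthSpec, default_truth,
                        simulate_study)

logger = logging.getLogger(__name__)

TEMP_PLAUSIBLE = (-60.0, 60.0)
MIN_HOURS_PER_DAY = 18

WEATHER_COLS = ["date", "t_mean_c", "rh_pct", "pressure_mmhg"]
VISIT_COLS = ["subject_id", "date", "sex", "age", "education", "bmi_cat",
              "lon", "lat"] + RESPONSES


def _require_columns(df: pd.DataFrame, cols, what: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file missing columns: {missing}")


def _check_temp_range(temps: pd.Series, what: str):
    lo, hi = TEMP_PLAUSIBLE
    bad = temps.index[(temps < lo) | (temps > hi)]
    if len(bad):
        rows = [int(i) + 2 for i in bad[:5]]  # 1-based incl. header
        raise ValueError(
            f"{what}: temperatures outside [{lo}, {hi}] degC at file "
            f"rows {rows}{'...' if len(bad) > 5 else ''}")


def read_weather(path) -> tuple[TemperatureSeries, pd.DataFrame]:
    """Read a daily or hourly weather CSV.

    Hourly files are reduced to daily means; the temperature mean
    requires at least 18 of 24 hours, otherwise the day is missing.
    Returns the temperature series plus the daily covariate frame.
    """
    df = pd.read_csv(path)
    if "hour" in df.columns:
        _require_columns(df, ["date", "hour", "t_c"], "hourly weather")
        _check_temp_range(df["t_c"], "hourly weather")
        df["date"] = pd.to_datetime(df["date"])
        g = df.groupby("date")
        t = g["t_c"].agg(["mean", "count"])
        t_mean = t["mean"].where(t["count"] >= MIN_HOURS_PER_DAY)
        daily = pd.DataFrame({"date": t.index, "t_mean_c": t_mean.to_numpy()})
        for c in ("rh_pct", "pressure_mmhg"):
            daily[c] = g[c].mean().to_numpy() if c in df.columns else np.nan
    else:
        _require_columns(df, WEATHER_COLS, "daily weather")
        _check_temp_range(df["t_mean_c"], "daily weather")
        daily = df.copy()
        daily["date"] = pd.to_datetime(daily["date"])
    daily = daily.sort_values("date").reset_index(drop=True)
    series = TemperatureSeries(
        pd.Series(daily["t_mean_c"].to_numpy(), index=daily["date"]))
    return series, daily


def write_weather(df: pd.DataFrame, path):
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[WEATHER_COLS].to_csv(path, index=False)


def bmi_category(bmi: float) -> str:
    """Lower-inclusive category bounds: [18.5, 25) normal, [25, 30)
    overweight, >=30 obese."""
    if bmi < 18.5:
        return "underweight"
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


@dataclass
class ExclusionLog:
    n_input: int = 0
    n_retained: int = 0
    excluded: dict = field(default_factory=dict)  # rule -> count

    def check(self):
        assert self.n_input == self.n_retained + sum(self.excluded.values())


def read_visits(path, min_visits: int = 3) -> tuple[pd.DataFrame, ExclusionLog]:
    """Read the visit table; exclude subjects with < ``min_visits`` rows.

    Duplicate (subject, date) rows are rejected; BMI category is derived
    from height/weight when the ``bmi_cat`` column is absent.
    """
    df = pd.read_csv(path)
    base_cols = [c for c in VISIT_COLS if c != "bmi_cat"]
    _require_columns(df, base_cols, "visits")
    try:
        df["date"] = pd.to_datetime(df["date"], format="%Y-%m-%d")
    except (ValueError, TypeError) as err:
        raise ValueError(f"visits: malformed date: {err}") from None
    if df["subject_id"].isna().any():
        rows = [int(i) + 2 for i in df.index[df["subject_id"].isna()][:5]]
        raise ValueError(f"visits: missing subject ids at rows {rows}")
    dup = df.duplicated(subset=["subject_id", "date"])
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup][:5]]
        raise ValueError(f"visits: duplicate (subject, date) rows at "
                         f"file rows {rows}")
    if "bmi_cat" not in df.columns:
        if not {"height_cm", "weight_kg"} <= set(df.columns):
            raise ValueError("visits: need bmi_cat or height_cm+weight_kg")
        bmi = df["weight_kg"] / (df["height_cm"] / 100.0) ** 2
        df["bmi_cat"] = [bmi_category(b) for b in bmi]

    log = ExclusionLog(n_input=len(df))
    counts = df.groupby("subject_id")["date"].transform("size")
    few = counts < min_visits
    log.excluded[f"fewer_than_{min_visits}_visits"] = int(few.sum())
    df = df[~few].reset_index(drop=True)
    log.n_retained = len(df)
    log.check()
    return df, log


def write_visits(df: pd.DataFrame, path):
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    cols = [c for c in VISIT_COLS if c in out.columns]
    out[cols].to_csv(path, index=False)


def read_stations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["station_id", "lon", "lat"], "stations")
    return df


def read_pollution(stations_path, pollution_path) -> StationNetwork:
    stations = read_stations(stations_path)
    df = pd.read_csv(pollution_path)
    _require_columns(df, ["station_id", "date", "pm25"], "pollution")
    df["date"] = pd.to_datetime(df["date"])
    wide = df.pivot(index="date", columns="station_id", values="pm25")
    wide = wide.sort_index()
    return StationNetwork(stations=stations, pm25=wide)


def write_network(network: StationNetwork, stations_path, pollution_path):
    network.stations.to_csv(stations_path, index=False)
    long = network.pm25.stack().rename("pm25").reset_index()
    long.columns = ["date", "station_id", "pm25"]
    long["date"] = pd.to_datetime(long["date"]).dt.strftime("%Y-%m-%d")
    long[["station_id", "date", "pm25"]].to_csv(pollution_path, index=False)


def write_calendars(catalog, path):
    rows = []
    for d, cal in catalog:
        for day in sorted(cal.event_days):
            rows.append({"definition_id": d.id, "date": day.isoformat()})
    pd.DataFrame(rows, columns=["definition_id", "date"]).to_csv(
        path, index=False)


def write_catalog_json(catalog, path):
    out = []
    for d, cal in catalog:
        out.append({
            "id": d.id, "kind": d.kind, "percentile": d.percentile,
            "threshold_c": cal.threshold_c, "min_duration": d.min_duration,
            "n_event_days": cal.n_event_days,
            "pct_of_window_days": cal.pct_of_window_days,
        })
    Path(path).write_text(json.dumps(out, indent=2))


def write_truth(truth: TruthSpec, path):
    Path(path).write_text(json.dumps(truth.to_jsonable(), indent=2))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Either real input paths or a ``simulate`` block, plus model/lag
    settings.  The seed is always recorded in the manifest."""

    seed: int = 0
    out_dir: str = "thermolag_out"
    weather_path: str | None = None
    stations_path: str | None = None
    pollution_path: str | None = None
    visits_path: str | None = None
    simulate: dict | None = None
    responses: tuple = ("hb", "plt")
    stratifiers: tuple = ("sex", "age_group", "bmi_group")
    idw_power: float = 2.0
    max_lag: int = 7
    smooth_k: int = 10
    time_smooth: bool = False
    make_plots: bool = False

    def __post_init__(self):
        has_paths = self.visits_path is not None
        if bool(self.simulate is not None) == has_paths:
            raise ValueError("config must specify exactly one of "
                             "input paths or a simulate: block")


def _parse_date(v):
    if isinstance(v, dt.date):
        return v
    return dt.date.fromisoformat(str(v))


def _climate_from_config(block: dict) -> ClimateParams:
    kw = dict(block or {})
    for key in ("start_date", "end_date"):
        if key in kw:
            kw[key] = _parse_date(kw[key])
    if "episodes" in kw:
        kw["episodes"] = [
            Episode(_parse_date(e["start"]), int(e["length_days"]),
                    float(e["offset_c"]))
            for e in kw["episodes"]]
    return ClimateParams(**kw)


def _cohort_from_config(block: dict, climate: ClimateParams) -> CohortParams:
    kw = dict(block or {})
    for key in ("start_date", "end_date"):
        if key in kw:
            kw[key] = _parse_date(kw[key])
    kw.setdefault("start_date", climate.start_date + dt.timedelta(days=7))
    kw.setdefault("end_date", climate.end_date)
    if "age_range" in kw:
        kw["age_range"] = tuple(kw["age_range"])
    return CohortParams(**kw)


def _truth_from_config(block: dict, responses) -> TruthSpec:
    effects = [
        ExposureEffect(e["response"], e["definition_id"], e["lag"],
                       float(e["effect"]))
        for e in (block or {}).get("exposure_effects", [])]
    truth = default_truth(responses=tuple(responses),
                          exposure_effects=effects)
    for key in ("random_intercept_sd", "residual_sd"):
        for r, v in (block or {}).get(key, {}).items():
            getattr(truth, key)[r] = float(v)
    return truth


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kw = {k: v for k, v in raw.items()
          if k in {f.name for f in dataclasses.fields(RunConfig)}}
    for key in ("responses", "stratifiers"):
        if key in kw:
            kw[key] = tuple(kw[key])
    return RunConfig(**kw)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True,
                      default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# pipeline


def _load_or_simulate(config: RunConfig):
    if config.simulate is not None:
        sim = config.simulate
        climate = _climate_from_config(sim.get("climate"))
        cohort = _cohort_from_config(sim.get("cohort"), climate)
        truth = _truth_from_config(sim.get("truth"), config.responses)
        study = simulate_study(
            climate=climate, cohort=cohort, truth=truth,
            n_stations=int(sim.get("n_stations", 21)),
            use_network=bool(sim.get("use_network", True)),
            seed=config.seed)
        return study
    series, weather = read_weather(config.weather_path)
    visits, log = read_visits(config.visits_path)
    logger.info("visits: retained %d of %d rows", log.n_retained,
                log.n_input)
    network = None
    if config.stations_path and config.pollution_path:
        network = read_pollution(config.stations_path, config.pollution_path)
    subjects = visits.drop_duplicates("subject_id")[
        ["subject_id", "lon", "lat"]]
    data = visit_environment(visits, weather, network, subjects,
                             power=config.idw_power)
    catalog = build_catalog(series)
    from .synthetic import SimulatedStudy
    return SimulatedStudy(weather=weather, series=series, network=network,
                          subjects=subjects, visits=data, catalog=catalog,
                          exposures=pd.DataFrame(), truth=TruthSpec())


def run_all(config: RunConfig) -> dict:
    """simulate/load -> detect -> expose -> scan -> select -> lags ->
    subgroups -> report.  Returns the manifest dict (also written)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate" if config.simulate is not None else "load"
    try:
        study = _load_or_simulate(config)
        stage = "detect"
        write_calendars(study.catalog, out / "event_calendar.csv")
        write_catalog_json(study.catalog, out / "event_catalog.json")
        catalog_summary(study.catalog).to_csv(out / "event_catalog.csv",
                                              index=False)
        write_weather(study.weather, out / "weather.csv")
        if study.network is not None:
            write_network(study.network, out / "stations.csv",
                          out / "pollution.csv")
        write_visits(study.visits, out / "visits.csv")
        if config.simulate is not None:
            write_truth(study.truth, out / "truth.json")
        stage = "analyze"
        from .gamm import ModelSpec
        spec = ModelSpec(response=config.responses[0],
                         smooth_terms={c: config.smooth_k for c in
                                       ("rh_pct", "pressure_mmhg", "pm25")},
                         time_smooth=config.time_smooth)
        results = analyze_study(study.visits, study.catalog,
                                responses=config.responses,
                                stratifiers=config.stratifiers, spec=spec)
        stage = "report"
        written = report(results, out, make_plots=config.make_plots)
    except Exception as err:
        logger.error("pipeline aborted at stage %r: %s", stage, err)
        raise RuntimeError(f"pipeline aborted at stage {stage!r}: {err}") \
            from err

    manifest = {
        "package": "thermolag",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "artifacts": written,
        "best_definitions": results.best,
    }
    if config.simulate is not None and study.truth.exposure_effects:
        recovery = []
        for eff in study.truth.exposure_effects:
            rows = results.lag_curves.get((eff.response, eff.definition_id))
            if rows:
                match = [r for r in rows if r.lag == eff.lag]
                if match:
                    r = match[0]
                    recovery.append({
                        "response": eff.response,
                        "definition_id": eff.definition_id,
                        "lag": eff.lag, "truth": eff.effect,
                        "estimate": r.beta, "ci_lo": r.ci95[0],
                        "ci_hi": r.ci95[1],
                        "covered": bool(r.ci95[0] <= eff.effect
                                        <= r.ci95[1]),
                    })
        manifest["truth_recovery"] = recovery
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
    return manifest
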