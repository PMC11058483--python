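"""Synthetic weather, pollution network, cohort, and outcomes.

The generator emulates a temperate-monsoon-climate blood-donor study:
a seasonal daily temperature with AR(1) noise (optionally with embedded
hot/cold episodes), a multi-station PM2.5 field that is log-normal and
higher in winter, a cohort of repeat donors with irregular visit dates
(>=3 visits, >=28 days apart), and six blood parameters generated from a
known linear predictor — covariate effects, smooth confounder effects,
a per-donor random intercept, and injected event effects at chosen lags.
Ground truth is carried alongside the data for recovery testing.

Defaults are calibrated to the descriptive statistics of the reference
cohort: warm-window (May 15 - Sep 15) mean temperature ~25.9 degC, cold
window (Oct - Mar) ~2.8 degC, 72.97% male, blood-parameter means/SDs as
tabulated, and a cold-season PM2.5 median above the warm-season median.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .events import TemperatureSeries, build_catalog
from .exposure import lag_exposures, visit_environment

__all__ = [
    "Episode", "ClimateParams", "PollutionParams", "CohortParams",
    "ExposureEffect", "TruthSpec", "StationNetwork", "SimulatedStudy",
    "gen_temperature_series", "gen_weather", "gen_pollution_network",
    "gen_cohort", "gen_outcomes", "default_truth", "simulate_study",
]

RESPONSES = ["alt", "wbc", "rbc", "hb", "hct", "plt"]

#: (mean, SD) of each blood parameter in the reference cohort.
OUTCOME_MEANS_SDS = {
    "alt": (18.9, 9.7),    # U/L
    "wbc": (6.1, 1.7),     # 1e9/L
    "rbc": (4.9, 0.4),     # 1e12/L
    "hb": (145.3, 14.0),   # g/L
    "hct": (0.40, 0.03),   # fraction
    "plt": (268.7, 56.7),  # 1e9/L
}

EDUCATION_LEVELS = ["junior_or_less", "high_school", "college_or_higher"]
BMI_LEVELS = ["underweight", "normal", "overweight", "obese"]

TIANJIN_BBOX = (116.7, 38.6, 117.8, 39.5)  # lon_min, lat_min, lon_max, lat_max

_DAYS_PER_YEAR = 365.2425


@dataclass(frozen=True)
class Episode:
    """A block of days with a fixed temperature offset added on top."""
    start: dt.date
    length_days: int
    offset_c: float


@dataclass
class ClimateParams:
    start_date: dt.date = dt.date(2013, 1, 1)
    end_date: dt.date = dt.date(2021, 6, 25)
    annual_mean: float = 12.7        # degC; with amplitude 16.0 and peak day
    annual_amplitude: float = 16.0   # 197 the warm/cold window means hit
    peak_day_of_year: int = 197      # ~25.9 / ~2.8 degC analytically
    ar1_rho: float = 0.7
    noise_sd: float = 2.8            # stationary (marginal) SD of the AR(1)
    episodes: list[Episode] = field(default_factory=list)
    rh_mean: float = 56.7            # in-phase with temperature
    rh_amplitude: float = 7.7
    rh_sd: float = 12.0
    pressure_mean: float = 762.7     # mmHg; anti-phase with temperature
    pressure_amplitude: float = 9.6
    pressure_sd: float = 3.0

    def __post_init__(self):
        if self.end_date <= self.start_date:
            raise ValueError("end_date must be after start_date")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not abs(self.ar1_rho) < 1:
            raise ValueError("|ar1_rho| must be < 1")
        if not 1 <= self.peak_day_of_year <= 366:
            raise ValueError("peak_day_of_year out of range")


def _seasonal(doy: np.ndarray, mean: float, amplitude: float,
              peak_doy: float) -> np.ndarray:
    return mean + amplitude * np.cos(2 * np.pi * (doy - peak_doy) / _DAYS_PER_YEAR)


def _ar1(n: int, rho: float, marginal_sd: float, rng) -> np.ndarray:
    if marginal_sd == 0 or n == 0:
        return np.zeros(n)
    innov_sd = marginal_sd * math.sqrt(1.0 - rho * rho)
    x = np.empty(n)
    x[0] = rng.normal(0.0, marginal_sd)
    shocks = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + shocks[i - 1]
    return x


def gen_temperature_series(params: ClimateParams, seed: int) -> TemperatureSeries:
    """Daily mean temperature: sinusoid + AR(1) noise + episode offsets."""
    rng = np.random.default_rng(seed)
    dates = pd.date_range(params.start_date, params.end_date, freq="D")
    doy = dates.dayofyear.to_numpy().astype(float)
    temps = _seasonal(doy, params.annual_mean, params.annual_amplitude,
                      params.peak_day_of_year)
    temps = temps + _ar1(len(dates), params.ar1_rho, params.noise_sd, rng)
    for ep in params.episodes:
        lo = pd.Timestamp(ep.start)
        hi = lo + pd.Timedelta(days=ep.length_days - 1)
        temps[(dates >= lo) & (dates <= hi)] += ep.offset_c
    return TemperatureSeries(pd.Series(temps, index=dates))


def gen_weather(params: ClimateParams, seed: int) -> pd.DataFrame:
    """Daily weather frame: date, t_mean_c, rh_pct, pressure_mmhg."""
    series = gen_temperature_series(params, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    dates = series.data.index
    doy = dates.dayofyear.to_numpy().astype(float)
    rh = _seasonal(doy, params.rh_mean, params.rh_amplitude,
                   params.peak_day_of_year)
    rh = np.clip(rh + rng.normal(0, params.rh_sd, len(dates)), 5.0, 100.0)
    # pressure runs opposite to temperature: low in summer, high in winter
    pres = _seasonal(doy, params.pressure_mean, -params.pressure_amplitude,
                     params.peak_day_of_year)
    pres = pres + rng.normal(0, params.pressure_sd, len(dates))
    return pd.DataFrame({
        "date": dates,
        "t_mean_c": series.data.to_numpy(),
        "rh_pct": rh,
        "pressure_mmhg": pres,
    })


@dataclass
class PollutionParams:
    start_date: dt.date = dt.date(2013, 1, 1)
    end_date: dt.date = dt.date(2021, 6, 25)
    log_median: float = 3.99         # exp -> ~54 ug/m3 annual median
    log_amplitude: float = 0.23      # winter-peaking seasonal cycle
    trough_day_of_year: int = 197    # PM2.5 lowest in high summer
    daily_log_sd: float = 0.50       # shared day-to-day shock (AR1)
    daily_rho: float = 0.6
    station_offset_sd: float = 0.10  # persistent between-station spread
    station_noise_sd: float = 0.15   # independent station-day noise


@dataclass
class StationNetwork:
    stations: pd.DataFrame           # station_id, lon, lat
    pm25: pd.DataFrame               # DatetimeIndex x station_id columns


def gen_pollution_network(n_stations: int = 21, bbox=TIANJIN_BBOX,
                          params: PollutionParams | None = None,
                          seed: int = 0) -> StationNetwork:
    """Multi-station daily PM2.5: seasonal log-normal, higher in winter."""
    if n_stations < 1:
        raise ValueError("n_stations must be >= 1")
    lon_min, lat_min, lon_max, lat_max = bbox
    if lon_max <= lon_min or lat_max <= lat_min:
        raise ValueError("empty bbox")
    if params is None:
        params = PollutionParams()
    rng = np.random.default_rng(seed)
    ids = [f"S{i:02d}" for i in range(1, n_stations + 1)]
    stations = pd.DataFrame({
        "station_id": ids,
        "lon": rng.uniform(lon_min, lon_max, n_stations),
        "lat": rng.uniform(lat_min, lat_max, n_stations),
    })
    dates = pd.date_range(params.start_date, params.end_date, freq="D")
    doy = dates.dayofyear.to_numpy().astype(float)
    shared = _seasonal(doy, params.log_median, -params.log_amplitude,
                       params.trough_day_of_year)
    shared = shared + _ar1(len(dates), params.daily_rho,
                           params.daily_log_sd, rng)
    offsets = rng.normal(0, params.station_offset_sd, n_stations)
    noise = rng.normal(0, params.station_noise_sd, (len(dates), n_stations))
    pm = np.exp(shared[:, None] + offsets[None, :] + noise)
    return StationNetwork(stations=stations,
                          pm25=pd.DataFrame(pm, index=dates, columns=ids))


@dataclass
class CohortParams:
    n_subjects: int = 2752
    male_fraction: float = 0.7297
    age_range: tuple[int, int] = (18, 58)
    #: weights of the 18-29 / 30-39 / 40-49 / 50+ age bands at baseline
    age_group_weights: tuple = (0.5298, 0.2453, 0.1704, 0.0545)
    education_probs: tuple = (0.2885, 0.2246, 0.4869)   # junior/high/college
    bmi_probs: tuple = (0.0334, 0.5632, 0.3238, 0.0796)  # under/norm/over/obese
    min_visits: int = 3
    min_gap: int = 28                # days between donations
    visit_rate: float = 8.0          # visits per year before gap-thinning
    #: donors are active inside a personal follow-up window (exponential
    #: length, mean ~1049 days, truncated to [56, 3078]), matching the
    #: reference cohort's 28-3078 day follow-up spread
    followup_mean_days: float = 1049.0
    followup_max_days: float = 3078.0
    start_date: dt.date = dt.date(2013, 1, 1)
    end_date: dt.date = dt.date(2021, 6, 25)
    bbox: tuple = TIANJIN_BBOX
    outcome_means_sds: dict = field(
        default_factory=lambda: dict(OUTCOME_MEANS_SDS))

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.min_visits < 3:
            raise ValueError("min_visits must be >= 3 (repeat-donor cohort)")
        if self.min_gap < 1:
            raise ValueError("min_gap must be >= 1 day")
        if not 0 <= self.male_fraction <= 1:
            raise ValueError("male_fraction must be a proportion")
        span = (self.end_date - self.start_date).days
        if span < (self.min_visits - 1) * self.min_gap:
            raise ValueError(
                f"date range of {span} days cannot hold {self.min_visits} "
                f"visits {self.min_gap} days apart")


def _visit_dates(params: CohortParams, rng) -> np.ndarray:
    """Poisson-process visit days inside a personal follow-up window,
    thinned to respect min_gap.  Returns day offsets from study start."""
    span = (params.end_date - params.start_date).days
    w_min = (params.min_visits - 1) * params.min_gap
    while True:
        w = rng.exponential(params.followup_mean_days)
        w = int(min(max(w, w_min), params.followup_max_days, span))
        w0 = int(rng.integers(0, span - w + 1))
        years = w / _DAYS_PER_YEAR
        n = rng.poisson(params.visit_rate * years)
        if n < params.min_visits:
            continue
        offs = np.sort(rng.integers(w0, w0 + w + 1, size=n))
        kept = [offs[0]]
        for o in offs[1:]:
            if o - kept[-1] >= params.min_gap:
                kept.append(o)
        if len(kept) >= params.min_visits:
            return np.asarray(kept)


def gen_cohort(params: CohortParams, seed: int):
    """Draw the cohort.

    Returns ``(subjects, visits)``: subjects with residence coordinates
    and baseline covariates; one visit row per donation with the
    (ageing) covariates and empty outcome columns.
    """
    rng = np.random.default_rng(seed)
    lon_min, lat_min, lon_max, lat_max = params.bbox
    lo, hi = params.age_range
    band_edges = [(lo, 30), (30, 40), (40, 50), (50, hi + 1)]

    sub_rows, visit_rows = [], []
    for i in range(params.n_subjects):
        sid = f"D{i + 1:05d}"
        sex = "male" if rng.random() < params.male_fraction else "female"
        band = rng.choice(4, p=np.asarray(params.age_group_weights)
                          / np.sum(params.age_group_weights))
        b_lo, b_hi = band_edges[band]
        age0 = rng.uniform(b_lo, min(b_hi, hi + 1))
        edu = EDUCATION_LEVELS[rng.choice(3, p=np.asarray(params.education_probs)
                                          / np.sum(params.education_probs))]
        bmi = BMI_LEVELS[rng.choice(4, p=np.asarray(params.bmi_probs)
                                    / np.sum(params.bmi_probs))]
        lon = rng.uniform(lon_min, lon_max)
        lat = rng.uniform(lat_min, lat_max)
        offs = _visit_dates(params, rng)
        sub_rows.append({"subject_id": sid, "sex": sex, "education": edu,
                         "bmi_cat": bmi, "lon": lon, "lat": lat,
                         "age_baseline": age0})
        for o in offs:
            date = params.start_date + dt.timedelta(days=int(o))
            visit_rows.append({
                "subject_id": sid,
                "date": pd.Timestamp(date),
                "sex": sex,
                "age": age0 + (o - offs[0]) / _DAYS_PER_YEAR,
                "education": edu,
                "bmi_cat": bmi,
                "lon": lon,
                "lat": lat,
            })
    subjects = pd.DataFrame(sub_rows)
    visits = pd.DataFrame(visit_rows)
    for r in RESPONSES:
        visits[r] = np.nan
    return subjects, visits


@dataclass(frozen=True)
class ExposureEffect:
    """One injected event effect: response shifts by ``effect`` per unit

    of the named lag exposure of the named definition."""
    response: str
    definition_id: str
    lag: str          # "lag0".."lag7" or "cum01".."cum07"
    effect: float

    @property
    def column(self) -> str:
        return f"x_{self.lag}"


@dataclass
class TruthSpec:
    """Ground truth of the outcome generator, kept for recovery testing."""

    exposure_effects: list[ExposureEffect] = field(default_factory=list)
    #: per response: {"female": b, "age": b, "education:<level>": b,
    #:                "bmi:<level>": b}; missing keys mean 0
    covariate_coefs: dict = field(default_factory=dict)
    #: per response: {column name -> callable}, centered by the generator
    smooth_effects: dict = field(default_factory=dict)
    random_intercept_sd: dict = field(default_factory=dict)
    residual_sd: dict = field(default_factory=dict)
    intercepts: dict = field(default_factory=dict)

    def __post_init__(self):
        for r, s in self.random_intercept_sd.items():
            if s < 0:
                raise ValueError(f"random_intercept_sd[{r}] must be >= 0")
        for r, s in self.residual_sd.items():
            if s <= 0:
                raise ValueError(f"residual_sd[{r}] must be > 0")

    def to_jsonable(self) -> dict:
        return {
            "exposure_effects": [
                {"response": e.response, "definition_id": e.definition_id,
                 "lag": e.lag, "effect": e.effect}
                for e in self.exposure_effects],
            "covariate_coefs": self.covariate_coefs,
            "smooth_effects": {
                r: {c: getattr(f, "__name__", "callable")
                    for c, f in d.items()}
                for r, d in self.smooth_effects.items()},
            "random_intercept_sd": self.random_intercept_sd,
            "residual_sd": self.residual_sd,
            "intercepts": self.intercepts,
        }


def default_truth(responses=("hb",),
                  exposure_effects: list[ExposureEffect] | None = None,
                  smooth_scale: float = 0.15) -> TruthSpec:
    """A realistic truth: modest covariate effects, mild nonlinear
    confounder effects, and a variance split of 0.80/0.45 of the
    marginal SD between the donor intercept and the residual.

    The split reflects the high intraclass correlation of repeated
    blood measurements (most variance is between-person; within-person
    repeatability of e.g. hemoglobin is a few g/L against a marginal SD
    of 14), and it reproduces the order of magnitude of the reference
    study's standard errors at its sample size.
    """
    cov, smooth, re_sd, res_sd, icpt = {}, {}, {}, {}, {}
    for r in responses:
        mean, sd = OUTCOME_MEANS_SDS[r]
        icpt[r] = mean
        cov[r] = {
            "female": -0.8 * sd,
            "age": 0.02 * sd,
            "education:high_school": 0.05 * sd,
            "education:college_or_higher": 0.05 * sd,
            "bmi:underweight": -0.1 * sd,
            "bmi:overweight": 0.1 * sd,
            "bmi:obese": 0.2 * sd,
        }
        a = smooth_scale * sd
        smooth[r] = {
            "rh_pct": _named(lambda x, a=a: a * np.sin((x - 55.0) / 18.0),
                             "sine_of_rh"),
            "pressure_mmhg": _named(
                lambda x, a=a: a * np.tanh((x - 762.0) / 6.0), "tanh_of_pressure"),
            "pm25": _named(lambda x, a=a: a * np.log1p(x / 50.0) - a * 0.7,
                           "log_of_pm25"),
        }
        re_sd[r] = 0.80 * sd
        res_sd[r] = 0.45 * sd
    return TruthSpec(
        exposure_effects=list(exposure_effects or []),
        covariate_coefs=cov, smooth_effects=smooth,
        random_intercept_sd=re_sd, residual_sd=res_sd, intercepts=icpt)


def _named(f, name):
    f.__name__ = name
    return f


def gen_outcomes(visits: pd.DataFrame, exposures: pd.DataFrame,
                 truth: TruthSpec, seed: int) -> pd.DataFrame:
    """Fill outcome columns from the truth's linear predictor.

    ``exposures`` is a long lag-exposure table (one row per visit and
    definition) as produced by :func:`thermolag.exposure.lag_exposures`,
    possibly concatenated over definitions.  Every visit must have an
    exposure row for each definition referenced by the truth.
    """
    rng = np.random.default_rng(seed)
    out = visits.copy()
    out["date"] = pd.to_datetime(out["date"])
    subjects = out["subject_id"].unique()
    sub_idx = pd.Series(np.arange(len(subjects)), index=subjects)

    responses = set(truth.intercepts) | set(truth.covariate_coefs) \
        | {e.response for e in truth.exposure_effects}
    for r in sorted(responses):
        mean, sd = OUTCOME_MEANS_SDS.get(r, (0.0, 1.0))
        mu = np.full(len(out), truth.intercepts.get(r, mean), dtype=float)
        coefs = truth.covariate_coefs.get(r, {})
        if "female" in coefs:
            mu += coefs["female"] * (out["sex"] == "female").to_numpy(float)
        if "age" in coefs:
            mu += coefs["age"] * (out["age"].to_numpy(float) - 32.0)
        for lev in EDUCATION_LEVELS[1:]:
            key = f"education:{lev}"
            if key in coefs:
                mu += coefs[key] * (out["education"] == lev).to_numpy(float)
        for lev in ["underweight", "overweight", "obese"]:
            key = f"bmi:{lev}"
            if key in coefs:
                mu += coefs[key] * (out["bmi_cat"] == lev).to_numpy(float)
        for col, f in truth.smooth_effects.get(r, {}).items():
            if col not in out.columns:
                raise ValueError(f"smooth effect references missing column {col}")
            vals = f(out[col].to_numpy(float))
            mu += vals - np.nanmean(vals)
        for eff in truth.exposure_effects:
            if eff.response != r:
                continue
            sub = exposures[exposures["definition_id"] == eff.definition_id]
            if len(sub) == 0 or eff.column not in exposures.columns:
                raise ValueError(
                    f"effect references exposure ({eff.definition_id}, "
                    f"{eff.lag}) absent from the exposure table")
            merged = out[["subject_id", "date"]].merge(
                sub[["subject_id", "date", eff.column]],
                on=["subject_id", "date"], how="left")
            if len(merged) != len(out):
                raise ValueError("duplicate (subject, date) rows in the "
                                 "exposure table")
            x = merged[eff.column].to_numpy(float)
            if np.isnan(x).any():
                raise ValueError(
                    f"visits lack exposure rows for {eff.definition_id}")
            mu += eff.effect * x
        u = rng.normal(0.0, truth.random_intercept_sd.get(r, 0.0),
                       len(subjects))
        e_sd = truth.residual_sd.get(r, 0.0)
        eps = rng.normal(0.0, e_sd, len(out)) if e_sd > 0 else 0.0
        out[r] = mu + u[sub_idx[out["subject_id"]].to_numpy()] + eps
    return out


@dataclass
class SimulatedStudy:
    weather: pd.DataFrame
    series: TemperatureSeries
    network: StationNetwork | None
    subjects: pd.DataFrame
    visits: pd.DataFrame             # environment + outcomes attached
    catalog: list                    # (EventDefinition, EventCalendar)
    exposures: pd.DataFrame          # long lag-exposure table
    truth: TruthSpec


def simulate_study(climate: ClimateParams | None = None,
                   cohort: CohortParams | None = None,
                   truth: TruthSpec | None = None,
                   pollution: PollutionParams | None = None,
                   n_stations: int = 21,
                   definitions=None,
                   use_network: bool = True,
                   seed: int = 0) -> SimulatedStudy:
    """End-to-end generation: weather -> events -> cohort -> outcomes.

    With ``use_network=False`` the PM2.5 residence assignment skips the
    station network and draws each visit's concentration directly from
    the same seasonal log-normal law (cheaper in replicated simulations;
    statistically equivalent for the downstream model).
    """
    max_lag = 7
    climate = climate or ClimateParams()
    cohort = cohort or CohortParams(
        start_date=climate.start_date + dt.timedelta(days=max_lag),
        end_date=climate.end_date)
    if cohort.start_date < climate.start_date + dt.timedelta(days=max_lag):
        cohort = replace(cohort, start_date=climate.start_date
                         + dt.timedelta(days=max_lag))
    truth = truth if truth is not None else default_truth()
    ss = np.random.SeedSequence(seed)
    s_weather, s_poll, s_cohort, s_out = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4)]

    weather = gen_weather(climate, s_weather)
    series = TemperatureSeries.from_frame(weather)
    catalog = build_catalog(series, definitions)

    subjects, visits = gen_cohort(cohort, s_cohort)

    if use_network:
        pparams = pollution or PollutionParams(
            start_date=climate.start_date, end_date=climate.end_date)
        network = gen_pollution_network(n_stations, TIANJIN_BBOX, pparams,
                                        s_poll)
        visits_env = visit_environment(visits, weather, network, subjects)
    else:
        network = None
        visits_env = visit_environment(visits, weather)
        pparams = pollution or PollutionParams(
            start_date=climate.start_date, end_date=climate.end_date)
        rng = np.random.default_rng(s_poll)
        doy = pd.to_datetime(visits_env["date"]).dt.dayofyear.to_numpy(float)
        logc = _seasonal(doy, pparams.log_median, -pparams.log_amplitude,
                         pparams.trough_day_of_year)
        visits_env["pm25"] = np.exp(
            logc + rng.normal(0, pparams.daily_log_sd, len(visits_env)))

    needed = {e.definition_id for e in truth.exposure_effects}
    cal_by_id = {d.id: cal for d, cal in catalog}
    missing = needed - set(cal_by_id)
    if missing:
        raise ValueError(f"truth references unknown definitions: {missing}")
    # exposure tables for the outcome generator: only the definitions the
    # truth references (analysis stages rebuild their own per definition)
    tables = [lag_exposures(cal_by_id[i], visits_env) for i in sorted(needed)]
    exposures = pd.concat(tables, ignore_index=True) if tables else \
        pd.DataFrame(columns=["subject_id", "date", "definition_id"])

    visits_out = gen_outcomes(visits_env, exposures, truth, s_out)
    return SimulatedStudy(weather=weather, series=series, network=network,
                          subjects=subjects, visits=visits_out,
                          catalog=catalog, exposures=exposures, truth=truth)
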