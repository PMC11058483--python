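"""Generator contracts: determinism, degenerate limits, calibration of
the stated climate/cohort, and outcome construction."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import thermolag as tl
from thermolag.events import SeasonWindow, _pooled_window_values
from thermolag.synthetic import OUTCOME_MEANS_SDS


class TestTemperature:
    def test_degenerate_constant(self):
        p = tl.ClimateParams(start_date=dt.date(2015, 1, 1),
                             end_date=dt.date(2015, 12, 31),
                             annual_mean=20.0, annual_amplitude=0.0,
                             noise_sd=0.0)
        s = tl.gen_temperature_series(p, seed=0)
        assert (s.data == 20.0).all()
        assert len(s) == 365

    def test_warm_and_cold_window_calibration(self):
        """Defaults were solved analytically so the warm-window mean is
        ~25.9 degC and the cold-window mean ~2.8 degC; Monte-Carlo check
        of the generator's own configuration."""
        s = tl.gen_temperature_series(tl.ClimateParams(), seed=123)
        _, tw = _pooled_window_values(s, SeasonWindow.warm())
        _, tc = _pooled_window_values(s, SeasonWindow.cold())
        assert np.nanmean(tw) == pytest.approx(25.9, abs=0.5)
        assert np.nanmean(tc) == pytest.approx(2.8, abs=0.5)

    def test_episode_additivity(self):
        base = tl.ClimateParams(start_date=dt.date(2015, 1, 1),
                                end_date=dt.date(2015, 12, 31),
                                noise_sd=0.0)
        ep = tl.Episode(dt.date(2015, 7, 20), 3, 8.0)
        with_ep = tl.ClimateParams(start_date=base.start_date,
                                   end_date=base.end_date, noise_sd=0.0,
                                   episodes=[ep])
        s0 = tl.gen_temperature_series(base, seed=5).data
        s1 = tl.gen_temperature_series(with_ep, seed=5).data
        diff = s1 - s0
        hot = pd.date_range("2015-07-20", periods=3)
        assert (diff[hot] == 8.0).all()
        assert (diff.drop(hot) == 0.0).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="end_date"):
            tl.ClimateParams(start_date=dt.date(2015, 1, 1),
                             end_date=dt.date(2014, 1, 1))
        with pytest.raises(ValueError, match="ar1_rho"):
            tl.ClimateParams(ar1_rho=1.0)

    def test_determinism(self):
        p = tl.ClimateParams()
        a = tl.gen_temperature_series(p, seed=9).data
        b = tl.gen_temperature_series(p, seed=9).data
        pd.testing.assert_series_equal(a, b)


class TestPollution:
    def test_single_station_idw_passthrough(self):
        net = tl.gen_pollution_network(n_stations=1, seed=3)
        out = tl.daily_residence_series(net, (117.0, 39.0))
        np.testing.assert_allclose(out.to_numpy(),
                                   net.pm25.iloc[:, 0].to_numpy())

    def test_cold_median_exceeds_warm_median(self):
        net = tl.gen_pollution_network(seed=4)
        doy = net.pm25.index.dayofyear
        warm = net.pm25[(doy >= 135) & (doy <= 258)].to_numpy()
        cold = net.pm25[(doy >= 274) | (doy <= 90)].to_numpy()
        assert np.median(cold) > np.median(warm)
        assert (net.pm25.to_numpy() > 0).all()

    def test_determinism_bit_identical(self):
        a = tl.gen_pollution_network(n_stations=4, seed=11)
        b = tl.gen_pollution_network(n_stations=4, seed=11)
        pd.testing.assert_frame_equal(a.stations, b.stations)
        pd.testing.assert_frame_equal(a.pm25, b.pm25)

    def test_empty_bbox_rejected(self):
        with pytest.raises(ValueError, match="bbox"):
            tl.gen_pollution_network(bbox=(117.0, 39.0, 117.0, 39.5))


class TestCohort:
    def test_visit_constraints(self):
        params = tl.CohortParams(n_subjects=80, visit_rate=3.0)
        _, visits = tl.gen_cohort(params, seed=1)
        counts = visits.groupby("subject_id").size()
        assert (counts >= 3).all()
        gaps = visits.groupby("subject_id")["date"].apply(
            lambda s: s.diff().dt.days.min())
        assert (gaps.dropna() >= 28).all()
        assert visits["date"].min() >= pd.Timestamp(params.start_date)
        assert visits["date"].max() <= pd.Timestamp(params.end_date)

    def test_male_fraction_within_binomial_bounds(self):
        """Binomial 99% interval oracle at n=2000, p=0.7297."""
        params = tl.CohortParams(n_subjects=2000, visit_rate=1.5)
        subjects, _ = tl.gen_cohort(params, seed=2)
        n_male = int((subjects["sex"] == "male").sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], 2000, 0.7297)
        assert lo <= n_male <= hi

    def test_range_too_short_rejected(self):
        with pytest.raises(ValueError, match="cannot hold"):
            tl.CohortParams(start_date=dt.date(2015, 1, 1),
                            end_date=dt.date(2015, 2, 1))

    def test_followup_span_matches_cohort_profile(self):
        params = tl.CohortParams(n_subjects=300)
        _, visits = tl.gen_cohort(params, seed=8)
        span = visits.groupby("subject_id")["date"].agg(
            lambda s: (s.max() - s.min()).days)
        assert 600 < span.mean() < 1400   # reference mean ~1049 days
        assert span.max() <= 3078


class TestOutcomes:
    def _frame(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        dates = pd.to_datetime("2015-06-01") + pd.to_timedelta(
            rng.integers(0, 90, n), unit="D")
        return pd.DataFrame({
            "subject_id": [f"D{i % 50:05d}" for i in range(n)],
            "date": dates,
            "sex": np.where(rng.random(n) < 0.7, "male", "female"),
            "age": rng.uniform(18, 58, n),
            "education": "college_or_higher",
            "bmi_cat": "normal",
            "rh_pct": rng.uniform(30, 90, n),
            "pressure_mmhg": rng.uniform(750, 775, n),
            "pm25": rng.uniform(20, 120, n),
        })

    def _exposures(self, visits, x):
        out = visits[["subject_id", "date"]].copy()
        out["definition_id"] = "HW05"
        for k in range(8):
            out[f"x_lag{k}"] = 0.0
        out["x_lag1"] = x
        for k in range(1, 8):
            out[f"x_cum0{k}"] = out[[f"x_lag{j}" for j in
                                     range(k + 1)]].mean(axis=1)
        return out

    def test_deterministic_when_variances_zero(self):
        visits = self._frame()
        expo = self._exposures(visits, 0.0)
        truth = tl.TruthSpec(
            covariate_coefs={"hb": {"female": -10.0, "age": 0.2}},
            random_intercept_sd={"hb": 0.0}, residual_sd={"hb": 1e-12},
            intercepts={"hb": 145.0})
        out = tl.gen_outcomes(visits, expo, truth, seed=0)
        mu = 145.0 - 10.0 * (visits["sex"] == "female") \
            + 0.2 * (visits["age"] - 32.0)
        np.testing.assert_allclose(out["hb"].to_numpy(), mu.to_numpy(),
                                   atol=1e-6)

    def test_injected_effect_shifts_exposed_mean(self):
        visits = self._frame(n=4000)
        visits["subject_id"] = [f"D{i:05d}" for i in range(4000)]
        rng = np.random.default_rng(1)
        x = (rng.random(4000) < 0.5).astype(float)
        expo = self._exposures(visits, x)
        truth = tl.TruthSpec(
            exposure_effects=[tl.ExposureEffect("hb", "HW05", "lag1", 2.6)],
            random_intercept_sd={"hb": 0.0}, residual_sd={"hb": 0.5},
            intercepts={"hb": 145.0})
        out = tl.gen_outcomes(visits, expo, truth, seed=2)
        diff = out.loc[x == 1, "hb"].mean() - out.loc[x == 0, "hb"].mean()
        assert diff == pytest.approx(2.6, abs=3 * 0.5 * np.sqrt(4 / 4000))

    def test_residual_moment(self):
        visits = self._frame(n=5000)
        expo = self._exposures(visits, 0.0)
        truth = tl.TruthSpec(random_intercept_sd={"hb": 0.0},
                             residual_sd={"hb": 3.0},
                             intercepts={"hb": 145.0})
        out = tl.gen_outcomes(visits, expo, truth, seed=3)
        assert out["hb"].std() == pytest.approx(3.0, rel=0.05)

    def test_missing_exposure_column_rejected(self):
        visits = self._frame()
        expo = self._exposures(visits, 0.0)
        truth = tl.TruthSpec(
            exposure_effects=[tl.ExposureEffect("hb", "CS07", "lag1", 1.0)],
            residual_sd={"hb": 1.0}, intercepts={"hb": 145.0})
        with pytest.raises(ValueError, match="absent"):
            tl.gen_outcomes(visits, expo, truth, seed=0)

    def test_truth_validation(self):
        with pytest.raises(ValueError, match="residual_sd"):
            tl.TruthSpec(residual_sd={"hb": 0.0})
        with pytest.raises(ValueError, match="random_intercept_sd"):
            tl.TruthSpec(random_intercept_sd={"hb": -1.0})


class TestSimulateStudy:
    def test_byte_identical_given_seed(self):
        kw = dict(
            climate=tl.ClimateParams(end_date=dt.date(2015, 12, 31)),
            cohort=tl.CohortParams(n_subjects=40, visit_rate=3.0,
                                   end_date=dt.date(2015, 12, 31)),
            truth=tl.default_truth(("hb",)),
            use_network=False, seed=77)
        a = tl.simulate_study(**kw)
        b = tl.simulate_study(**kw)
        pd.testing.assert_frame_equal(a.visits, b.visits)
        pd.testing.assert_frame_equal(a.weather, b.weather)
        csv_a = a.visits.to_csv(index=False)
        csv_b = b.visits.to_csv(index=False)
        assert csv_a == csv_b

    def test_outcome_marginals_near_reference(self, small_study):
        for r in ("hb",):
            mean, sd = OUTCOME_MEANS_SDS[r]
            got = small_study.visits[r]
            assert got.mean() == pytest.approx(mean, abs=0.15 * sd)
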