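"""Fitter checks: spline identities against an independent Cox-de Boor
recursion, closed-form limits (OLS, balanced one-way ANOVA REML), an
external mixed-model cross-check, Wald contracts, and AIC behavior."""

import numpy as np
import pandas as pd
import pytest

import thermolag as tl
from thermolag.gamm import (ModelSpec, fit_pamm, model_aic, smooth_to_mixed,
                            spline_basis, wald_joint_test, Z975)


def cox_de_boor(x, t, i, k):
    """Textbook B-spline recursion, independent of scipy."""
    if k == 0:
        # right-closed at the final knot so the last basis reaches 1
        if t[i] <= x < t[i + 1]:
            return 1.0
        if x == t[-1] and t[i] < t[i + 1] <= t[-1] \
                and t[i + 1] == t[-1]:
            return 1.0
        return 0.0
    out = 0.0
    if t[i + k] > t[i]:
        out += (x - t[i]) / (t[i + k] - t[i]) * cox_de_boor(x, t, i, k - 1)
    if t[i + k + 1] > t[i + 1]:
        out += (t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1]) \
            * cox_de_boor(x, t, i + 1, k - 1)
    return out


class TestSplineBasis:
    def test_partition_of_unity(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-3, 7, 300)
        B, S = spline_basis(x, k=10)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-10)
        assert B.shape == (300, 10)
        assert S.shape == (10, 10)

    def test_penalty_null_space_is_linear_in_knot_index(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 200)
        _, S = spline_basis(x, k=8)
        for coefs in (np.ones(8), np.arange(8.0), 3 - 0.5 * np.arange(8.0)):
            assert coefs @ S @ coefs == pytest.approx(0.0, abs=1e-10)
        bent = np.arange(8.0) ** 2
        assert bent @ S @ bent > 1.0

    def test_matches_cox_de_boor_recursion(self):
        rng = np.random.default_rng(2)
        x = np.sort(rng.uniform(0, 10, 60))
        k = 7
        B, _ = spline_basis(x, k=k)
        ux = np.unique(x)
        interior = np.quantile(ux, np.linspace(0, 1, k - 2)[1:-1])
        t = np.r_[[ux[0]] * 4, interior, [ux[-1]] * 4]
        for xi, row in zip(x[[0, 13, 27, 45, 59]], B[[0, 13, 27, 45, 59]]):
            expected = [cox_de_boor(float(xi), t, i, 3) for i in range(k)]
            np.testing.assert_allclose(row, expected, atol=1e-10)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            spline_basis(np.array([1.0, 2.0, 3.0] * 10), k=6)

    def test_mixed_form_dimensions(self):
        x = np.random.default_rng(3).uniform(0, 1, 150)
        Xn, Zr = smooth_to_mixed(x, k=10)
        assert Xn.shape == (150, 1)          # non-constant null direction
        assert Zr.shape == (150, 8)          # k - 2 range columns
        assert abs(Xn.mean()) < 1e-10


def _oneway(m=30, nper=8, seed=0):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, 2.0, m)
    y = 5 + np.repeat(u, nper) + rng.normal(0, 1.5, m * nper)
    return pd.DataFrame({
        "y": y,
        "subject_id": np.repeat([f"g{i}" for i in range(m)], nper)})


class TestClosedForms:
    def test_balanced_oneway_matches_anova_reml(self):
        """For the balanced one-way layout REML equals the ANOVA
        estimators sigma2 = MSW, sigma_u2 = (MSB - MSW) / n_per."""
        m, nper = 30, 8
        df = _oneway(m, nper)
        fit = fit_pamm(ModelSpec(response="y", exposure=None,
                                 linear_terms=(), smooth_terms={}), df)
        gm = df.groupby("subject_id")["y"].mean()
        msb = nper * ((gm - gm.mean()) ** 2).sum() / (m - 1)
        msw = ((df["y"] - df.groupby("subject_id")["y"]
                .transform("mean")) ** 2).sum() / (m * (nper - 1))
        assert fit.resid_sd ** 2 == pytest.approx(msw, rel=1e-6)
        assert fit.re_sd ** 2 == pytest.approx((msb - msw) / nper, rel=1e-6)

    def test_matches_external_mixed_model(self):
        """Independent cross-check against statsmodels MixedLM REML."""
        import statsmodels.api as sm
        rng = np.random.default_rng(4)
        n, m = 600, 60
        g = rng.integers(0, m, n)
        x = rng.normal(size=n)
        y = 1.0 + 0.7 * x + rng.normal(0, 1.1, m)[g] + rng.normal(0, 0.9, n)
        df = pd.DataFrame({"y": y, "x": x,
                           "subject_id": [f"s{i}" for i in g]})
        fit = fit_pamm(ModelSpec(response="y", exposure="x",
                                 linear_terms=(), smooth_terms={}), df)
        md = sm.MixedLM.from_formula("y ~ x", groups="subject_id",
                                     data=df).fit(reml=True)
        assert fit.beta == pytest.approx(md.params["x"], rel=1e-6)
        # se agrees up to the optimizers' slightly different theta
        assert fit.se == pytest.approx(md.bse["x"], rel=1e-3)
        assert fit.loglik_reml == pytest.approx(md.llf, abs=1e-5)
        assert fit.resid_sd ** 2 == pytest.approx(md.scale, rel=1e-5)

    def test_penalized_limit_equals_ols(self):
        rng = np.random.default_rng(5)
        n = 400
        x = rng.normal(size=n)
        z = rng.uniform(0, 1, n)
        y = 1 + 2 * x + np.sin(3 * z) + rng.normal(0, 1, n)
        df = pd.DataFrame({"y": y, "x": x, "z": z,
                           "subject_id": (np.arange(n) % 40).astype(str)})
        fit = fit_pamm(ModelSpec(response="y", exposure="x",
                                 linear_terms=(), smooth_terms={"z": 8}),
                       df, fixed_lambda=np.inf, fixed_re_var_ratio=0.0)
        Xn, _ = smooth_to_mixed(z, 8)
        X = np.column_stack([np.ones(n), x, Xn])
        b = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.beta == pytest.approx(b[1], rel=1e-8)


@pytest.fixture(scope="module")
def sim():
    rng = np.random.default_rng(6)
    n, m = 900, 90
    g = rng.integers(0, m, n)
    df = pd.DataFrame({
        "subject_id": [f"s{i:03d}" for i in g],
        "x": rng.binomial(1, 0.1, n).astype(float),
        "z": rng.uniform(0, 1, n),
        "sex": np.where(rng.random(n) < 0.7, "male", "female"),
        "age": rng.uniform(18, 58, n),
    })
    df["y"] = (2.0 * df["x"] + np.sin(2 * np.pi * df["z"])
               + 0.05 * df["age"]
               + rng.normal(0, 1.0, m)[g] + rng.normal(0, 1.0, n))
    return df


class TestFitContracts:
    def _spec(self):
        return ModelSpec(response="y", exposure="x",
                         linear_terms=("sex", "age"), smooth_terms={"z": 10})

    def test_ci_width_contract_and_edf_range(self, sim):
        fit = fit_pamm(self._spec(), sim)
        lo, hi = fit.ci95
        assert hi - lo == pytest.approx(2 * Z975 * fit.se, rel=1e-12)
        for s in fit.smooths:
            assert -1e-6 <= s.edf <= s.k - 2 + 1e-6
        assert fit.re_sd >= 0 and fit.resid_sd > 0

    def test_row_and_term_order_invariance(self, sim):
        fit1 = fit_pamm(self._spec(), sim)
        shuffled = sim.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit2 = fit_pamm(self._spec(), shuffled)
        spec3 = ModelSpec(response="y", exposure="x",
                          linear_terms=("age", "sex"),
                          smooth_terms={"z": 10})
        fit3 = fit_pamm(spec3, sim)
        assert fit1.beta == pytest.approx(fit2.beta, abs=1e-8)
        assert fit1.beta == pytest.approx(fit3.beta, abs=1e-8)
        assert fit1.aic == pytest.approx(fit2.aic, abs=1e-5)

    def test_missing_rows_dropped_and_counted(self, sim):
        df = sim.copy()
        df.loc[:9, "age"] = np.nan
        fit = fit_pamm(self._spec(), df)
        assert fit.n_dropped == 10
        assert fit.n_obs == len(df) - 10

    def test_singular_design_names_columns(self, sim):
        df = sim.copy()
        df["dup"] = df["x"]
        spec = ModelSpec(response="y", exposure="x",
                         linear_terms=("sex", "age"), smooth_terms={"z": 10},
                         extra_linear=("dup",))
        # either of the two collinear columns may be named by the QR
        with pytest.raises(ValueError, match="singular.*(dup|x)"):
            fit_pamm(spec, df)

    def test_smooth_recovery_improves_with_n(self):
        """Fitting y = sin(2 pi z) + noise recovers the curve with an
        in-sample RMSE that decreases from n=200 to n=2000."""
        def curve_rmse(n, seed):
            rng = np.random.default_rng(seed)
            z = rng.uniform(0, 1, n)
            truth = np.sin(2 * np.pi * z)
            y = truth + rng.normal(0, 0.5, n)
            df = pd.DataFrame({"y": y, "z": z,
                               "subject_id": (np.arange(n) % 20).astype(str)})
            fit = fit_pamm(ModelSpec(response="y", exposure=None,
                                     linear_terms=(),
                                     smooth_terms={"z": 10}), df,
                           fixed_re_var_ratio=0.0)
            return float(np.sqrt(np.mean((fit.fitted - truth) ** 2)))

        assert curve_rmse(2000, 7) < curve_rmse(200, 7)
        assert curve_rmse(2000, 7) < 0.12


class TestAic:
    def test_identical_fits_identical_aic(self, ):
        df = _oneway()
        spec = ModelSpec(response="y", exposure=None, linear_terms=(),
                         smooth_terms={})
        a = fit_pamm(spec, df)
        b = fit_pamm(spec, df)
        assert model_aic(a) == model_aic(b)

    def test_true_exposure_term_lowers_aic(self):
        rng = np.random.default_rng(8)
        n, m = 800, 80
        g = rng.integers(0, m, n)
        x = rng.binomial(1, 0.2, n).astype(float)
        y = 5.0 * x + rng.normal(0, 1, m)[g] + rng.normal(0, 1, n)
        df = pd.DataFrame({"y": y, "x": x,
                           "subject_id": [f"s{i}" for i in g]})
        with_x = fit_pamm(ModelSpec(response="y", exposure="x",
                                    linear_terms=(), smooth_terms={}), df)
        without = fit_pamm(ModelSpec(response="y", exposure=None,
                                     linear_terms=(), smooth_terms={}), df)
        assert with_x.aic < without.aic

    def test_noise_exposure_raises_aic_in_expectation(self):
        """A pure-noise regressor costs ~2 AIC and buys ~1 in fit, so
        the mean AIC difference over replicates is positive."""
        diffs = []
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            n, m = 240, 40
            g = rng.integers(0, m, n)
            y = rng.normal(0, 1, m)[g] + rng.normal(0, 1, n)
            x = rng.binomial(1, 0.2, n).astype(float)
            df = pd.DataFrame({"y": y, "x": x,
                               "subject_id": [f"s{i}" for i in g]})
            with_x = fit_pamm(ModelSpec(response="y", exposure="x",
                                        linear_terms=(), smooth_terms={}),
                              df)
            without = fit_pamm(ModelSpec(response="y", exposure=None,
                                         linear_terms=(), smooth_terms={}),
                               df)
            diffs.append(with_x.aic - without.aic)
        assert np.mean(diffs) > 0


def test_wald_joint_test_single_term_matches_z():
    df = _oneway(seed=9)
    rng = np.random.default_rng(9)
    df["x"] = rng.binomial(1, 0.3, len(df)).astype(float)
    fit = fit_pamm(ModelSpec(response="y", exposure="x", linear_terms=(),
                             smooth_terms={}), df)
    stat, ddf, p = wald_joint_test(fit, ["x"])
    assert ddf == 1
    assert stat == pytest.approx((fit.beta / fit.se) ** 2, rel=1e-10)
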