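"""Gaussian additive mixed model with penalized splines and a subject
random intercept.

Model
-----
    y_ij = x_ij' beta + sum_s f_s(c_sij) + u_i + e_ij,
    u_i ~ N(0, sigma_u^2),  e_ij ~ N(0, sigma^2)

Each smooth f_s is a cubic B-spline with a second-order difference
penalty (a P-spline).  The penalized smooth is re-expressed in mixed-model
form: the penalty's null space (constant + linear trend) joins the fixed
effects, and the range space becomes a block of i.i.d. random effects
with variance sigma^2 / lambda_s.  Variance ratios (one per smooth, one
for the subject intercept) are estimated by maximizing the profiled
restricted likelihood on the log scale with a quasi-Newton optimizer
started from a coarse grid; given the ratios, coefficients solve the
penalized normal equations.  The subject block of those equations is
diagonal, which the solver exploits, so a fit costs
O(n d + m d^2 + d^3) per deviance evaluation for d model columns and
m subjects.

Inference on the exposure coefficient is Wald: se from the fixed-effect
block of the inverse penalized information, ci95 = beta +/- 1.959964 se.
AIC uses the *maximum-likelihood* log-likelihood (REML likelihoods are
not comparable when the fixed-effect structure changes across an
exposure-definition scan) with complexity = fixed coefficients + summed
smooth edf + variance parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)

Z975 = 1.959964

__all__ = ["ModelSpec", "PammFit", "spline_basis", "smooth_to_mixed",
           "fit_pamm", "model_aic", "wald_joint_test"]

CATEGORICAL_LEVELS = {
    "sex": ["male", "female"],
    "education": ["junior_or_less", "high_school", "college_or_higher"],
    "bmi_cat": ["underweight", "normal", "overweight", "obese"],
}


@dataclass
class ModelSpec:
    """What to regress on what.

    ``smooth_terms`` maps a continuous column to its basis size k.
    ``extra_linear`` columns (e.g. exposure-by-stratum interactions) are
    appended to the fixed effects as given.
    """

    response: str
    exposure: str | None = None
    linear_terms: tuple = ("sex", "age", "education", "bmi_cat")
    smooth_terms: dict = field(default_factory=lambda: {
        "rh_pct": 10, "pressure_mmhg": 10, "pm25": 10})
    group: str = "subject_id"
    extra_linear: tuple = ()
    time_smooth: bool = False        # optional smooth of days-since-start
    time_k: int = 10


@dataclass
class SmoothInfo:
    name: str
    k: int
    lam: float
    edf: float        # penalized (range-space) edf, in [0, k-2]
    null_dim: int


@dataclass
class PammFit:
    beta: float
    se: float
    ci95: tuple
    p_value: float
    coefficients: pd.Series
    cov_fixed: np.ndarray
    smooths: list
    re_sd: float
    resid_sd: float
    loglik_ml: float
    loglik_reml: float
    aic: float
    n_obs: int
    n_dropped: int
    n_groups: int
    converged: bool
    theta: np.ndarray            # log variance ratios, subject first
    fitted: np.ndarray | None = None   # in-sample fixed+random fit
    spec: ModelSpec | None = None

    @property
    def edf_total(self) -> float:
        n_fixed = len(self.coefficients)
        n_var = len(self.smooths) + 2        # smooth lambdas + sigma_u + sigma
        return n_fixed + sum(s.edf for s in self.smooths) + n_var


def spline_basis(x: np.ndarray, k: int, degree: int = 3):
    """Cubic B-spline basis (n x k) on quantile knots + 2nd-difference
    penalty (k x k).  Rows of the basis sum to one (partition of unity)."""
    x = np.asarray(x, dtype=float)
    ux = np.unique(x[~np.isnan(x)])
    if k < 4:
        raise ValueError("basis size k must be >= 4")
    if ux.size < k:
        raise ValueError(f"need >= {k} distinct values, got {ux.size}")
    n_interior = k - degree - 1
    probs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(ux, probs)
    # nudge ties apart (possible with heavily discrete data)
    for i in range(1, len(interior)):
        if interior[i] <= interior[i - 1]:
            interior[i] = np.nextafter(interior[i - 1], np.inf)
    lo, hi = ux[0], ux[-1]
    t = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    B = BSpline.design_matrix(np.clip(x, lo, hi), t, degree).toarray()
    D = np.diff(np.eye(k), n=2, axis=0)
    S = D.T @ D
    return B, S


def smooth_to_mixed(x: np.ndarray, k: int):
    """Decompose a P-spline into fixed null-space and scaled range-space
    columns.

    Returns ``(X_null, Z_range)``: the penalty null space reduced to the
    non-constant direction (centered, unit-SD), and range-space columns
    scaled by the inverse square root of the penalty eigenvalues so the
    implied prior on their coefficients is i.i.d.  Columns are centered
    (sum-to-zero identifiability constraint against the intercept).
    """
    B, S = spline_basis(x, k)
    w, V = np.linalg.eigh(S)
    null = w < w[-1] * 1e-10
    Xn = B @ V[:, null]
    Zr = B @ V[:, ~null] / np.sqrt(w[~null])
    # the null space spans {constant, trend}; centering removes the
    # constant and leaves a rank-1 space -- keep one orthonormal column
    Xn = Xn - Xn.mean(axis=0)
    Q, R, _ = linalg.qr(Xn, mode="economic", pivoting=True)
    rank = int(np.sum(np.abs(np.diag(R)) > np.abs(R[0, 0]) * 1e-9))
    Xn = Q[:, :rank] * np.sqrt(len(x))     # unit-SD scaling
    Zr = Zr - Zr.mean(axis=0)
    return Xn, Zr


def _build_design(spec: ModelSpec, data: pd.DataFrame):
    """Assemble y, fixed matrix X, smooth random blocks, group codes."""
    cols = [spec.response, spec.group]
    if spec.exposure:
        cols.append(spec.exposure)
    cols += list(spec.linear_terms) + list(spec.extra_linear)
    cols += list(spec.smooth_terms)
    if spec.time_smooth:
        cols.append("date")
    cols = list(dict.fromkeys(cols))
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ValueError(f"model columns absent from data: {missing_cols}")
    frame = data[cols].dropna()
    n_dropped = len(data) - len(frame)

    y = frame[spec.response].to_numpy(float)
    names: list[str] = ["(intercept)"]
    Xparts = [np.ones((len(frame), 1))]
    if spec.exposure:
        Xparts.append(frame[[spec.exposure]].to_numpy(float))
        names.append(spec.exposure)
    for term in spec.linear_terms:
        if term in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[term]
            cat = pd.Categorical(frame[term], categories=levels)
            if cat.isna().any():
                bad = sorted(set(frame[term]) - set(levels))
                raise ValueError(f"unknown {term} levels: {bad}")
            d = pd.get_dummies(cat, drop_first=True)
            Xparts.append(d.to_numpy(float))
            names += [f"{term}[{lev}]" for lev in d.columns]
        else:
            Xparts.append(frame[[term]].to_numpy(float))
            names.append(term)
    for term in spec.extra_linear:
        Xparts.append(frame[[term]].to_numpy(float))
        names.append(term)

    zblocks = []     # (name, Z matrix) for smooth range spaces
    smooth_cfg = dict(spec.smooth_terms)
    if spec.time_smooth:
        t = (pd.to_datetime(frame["date"])
             - pd.to_datetime(frame["date"]).min()).dt.days.to_numpy(float)
        frame = frame.assign(_days=t)
        smooth_cfg["_days"] = spec.time_k
    for term, k in smooth_cfg.items():
        if k < 4:
            raise ValueError(f"smooth basis size for {term} must be >= 4")
        Xn, Zr = smooth_to_mixed(frame[term].to_numpy(float), k)
        Xparts.append(Xn)
        names += [f"s({term}):null{j + 1}" for j in range(Xn.shape[1])]
        zblocks.append((term, Zr, k))

    X = np.hstack(Xparts)
    # covariate levels absent from this subset yield all-constant dummy
    # columns; drop them instead of failing (the exposure never is)
    protect = {0}
    if spec.exposure:
        protect.add(names.index(spec.exposure))
    const = X.std(axis=0) < 1e-12
    const[list(protect)] = False
    if const.any():
        dropped = [names[j] for j in np.flatnonzero(const)]
        logger.debug("dropping constant design columns: %s", dropped)
        X = X[:, ~const]
        names = [nm for nm, c in zip(names, const) if not c]
    groups, levels = pd.factorize(frame[spec.group], sort=True)
    return y, X, names, zblocks, groups, len(levels), n_dropped


class _BlockedREML:
    """Profiled (RE)ML deviance for one grouped random intercept plus
    dense low-rank random blocks, exploiting the diagonal group block."""

    def __init__(self, y, X, zblocks, groups, n_groups):
        self.n, self.p = X.shape
        self.m = n_groups
        self.block_sizes = [Z.shape[1] for _, Z, _ in zblocks]
        self.r = int(sum(self.block_sizes))
        W = np.hstack([Z for _, Z, _ in zblocks] + [X]) if zblocks else X
        self.d = W.shape[1]
        self.W = W
        self.y = y
        self.groups = groups
        self.counts = np.bincount(groups, minlength=n_groups).astype(float)
        self.GW = np.zeros((n_groups, self.d))
        np.add.at(self.GW, groups, W)
        self.Gy = np.bincount(groups, weights=y, minlength=n_groups)
        self.WtW = W.T @ W
        self.Wty = W.T @ y
        self.yty = float(y @ y)
        # per-column variance-ratio slot: block j for smooth columns,
        # -1 for fixed columns
        slots = []
        for j, s in enumerate(self.block_sizes):
            slots += [j] * s
        slots += [-1] * self.p
        self.slots = np.asarray(slots)

    def _scales(self, theta):
        """Column scale sqrt(psi) per model column; theta[0] is the
        subject log-ratio, theta[1:] the smooth blocks'."""
        s = np.ones(self.d)
        for j in range(len(self.block_sizes)):
            s[self.slots == j] = np.exp(0.5 * theta[1 + j])
        return s, np.exp(theta[0])

    def _assemble(self, theta):
        s, psi_u = self._scales(theta)
        D = psi_u * self.counts + 1.0
        C = np.sqrt(psi_u) * self.GW * s           # m x d
        Swork = (self.WtW * s).T * s
        Swork[np.diag_indices(self.d)] += (self.slots >= 0).astype(float)
        Swork -= C.T @ (C / D[:, None])
        rhs_u = np.sqrt(psi_u) * self.Gy
        rhs_x0 = s * self.Wty
        rhs = rhs_x0 - C.T @ (rhs_u / D)
        return s, psi_u, D, C, Swork, rhs, rhs_u, rhs_x0

    def deviance(self, theta, reml=True):
        try:
            s, psi_u, D, C, Swork, rhs, rhs_u, rhs_x0 = self._assemble(theta)
            L, low = linalg.cho_factor(Swork, lower=True,
                                       check_finite=False)
        except (np.linalg.LinAlgError, ValueError):
            return 1e300          # finite sentinel keeps numdiff quiet
        c = linalg.cho_solve((L, low), rhs, check_finite=False)
        cu = (rhs_u - C @ c) / D
        rss = self.yty - rhs_u @ cu - rhs_x0 @ c
        rss = max(rss, 1e-300)
        ld = np.log(np.abs(np.diag(L)))
        logdet_q = float(np.sum(np.log(D)) + 2.0 * np.sum(ld[: self.r]))
        logdet_x = float(2.0 * np.sum(ld[self.r:]))
        if reml:
            nn = self.n - self.p
            return logdet_q + logdet_x + nn * (
                1.0 + np.log(2.0 * np.pi * rss / nn))
        return logdet_q + self.n * (1.0 + np.log(2.0 * np.pi * rss / self.n))

    def solve(self, theta):
        """Full solution pieces at theta (for estimates and covariance)."""
        s, psi_u, D, C, Swork, rhs, rhs_u, rhs_x0 = self._assemble(theta)
        L, low = linalg.cho_factor(Swork, lower=True, check_finite=False)
        c = linalg.cho_solve((L, low), rhs, check_finite=False)
        cu = (rhs_u - C @ c) / D
        rss = float(self.yty - rhs_u @ cu - rhs_x0 @ c)
        Sinv = linalg.cho_solve((L, low), np.eye(self.d), check_finite=False)
        beta = (s * c)[self.r:]        # fixed cols have scale 1 anyway
        u = np.sqrt(psi_u) * cu        # subject intercepts on data scale
        fitted = self.W @ (s * c) + u[self.groups]
        return {"coef_scaled": c, "beta": beta, "rss": max(rss, 1e-300),
                "Sinv": Sinv, "cu": cu, "D": D, "L": (L, low),
                "fitted": fitted, "u": u}


def _optimize_theta(dev, n_par, fixed_mask, fixed_vals, tol=1e-6,
                    max_iter=200, warm_start=None, fast=False):
    """Quasi-Newton on the free log-ratios, 3 coarse-grid restarts,
    then a Nelder-Mead polish for closed-form-level accuracy.

    ``fast`` with a warm start skips the grid restarts (same
    tolerances); used for successive refits on the same data where the
    variance ratios barely move between exposure columns."""
    free = ~fixed_mask
    n_free = int(free.sum())

    def full_theta(z):
        th = fixed_vals.copy()
        th[free] = z
        return th

    if n_free == 0:
        return fixed_vals, True

    def f(z):
        return dev(full_theta(z))

    starts = [np.full(n_free, v) for v in (-4.0, 0.0, 4.0)]
    if warm_start is not None:
        warm = np.asarray(warm_start, float)[free]
        starts = [warm] if fast else [warm] + starts[:2]
    best = None
    for z0 in starts:
        res = optimize.minimize(f, z0, method="L-BFGS-B",
                                options={"maxiter": max_iter,
                                         "ftol": tol * 1e-4,
                                         "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    polish_opts = {"xatol": 1e-6, "fatol": 1e-10, "maxiter": 60} if fast \
        else {"xatol": 1e-9, "fatol": 1e-12, "maxiter": 400}
    polish = optimize.minimize(f, best.x, method="Nelder-Mead",
                               options=polish_opts)
    if polish.fun <= best.fun:
        best = polish
    converged = bool(np.isfinite(best.fun) and best.fun < 1e299)
    return full_theta(np.clip(best.x, -30, 30)), converged


def fit_pamm(spec: ModelSpec, data: pd.DataFrame, *,
             fixed_lambda: float | None = None,
             fixed_re_var_ratio: float | None = None,
             warm_start: np.ndarray | None = None,
             fast: bool = False,
             tol: float = 1e-6, max_iter: int = 200) -> PammFit:
    """Fit the additive mixed model.

    ``fixed_lambda`` pins every smooth's lambda (``np.inf`` collapses the
    smooths to their linear null space); ``fixed_re_var_ratio`` pins the
    subject-intercept variance ratio (0 removes the random intercept).
    Rows with missing model columns are dropped listwise and counted.
    """
    y, X, names, zblocks, groups, n_groups, n_dropped = \
        _build_design(spec, data)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"{n} rows for {p} fixed coefficients")
    # singular design check, with the offending columns named
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"singular fixed-effect design; offending "
                         f"columns: {bad}")

    engine = _BlockedREML(y, X, zblocks, groups, n_groups)
    n_par = 1 + len(zblocks)
    fixed_mask = np.zeros(n_par, bool)
    fixed_vals = np.zeros(n_par)
    if fixed_re_var_ratio is not None:
        fixed_mask[0] = True
        fixed_vals[0] = -np.inf if fixed_re_var_ratio == 0 else \
            np.log(fixed_re_var_ratio)
    if fixed_lambda is not None:
        fixed_mask[1:] = True
        fixed_vals[1:] = -np.inf if np.isinf(fixed_lambda) else \
            -np.log(fixed_lambda)

    # -inf ratios are handled by a large negative cap (psi ~ e-60 ~ 0)
    fixed_vals = np.where(np.isneginf(fixed_vals), -60.0, fixed_vals)

    theta, converged = _optimize_theta(
        lambda th: engine.deviance(th, reml=True),
        n_par, fixed_mask, fixed_vals, tol=tol, max_iter=max_iter,
        warm_start=warm_start, fast=fast)

    sol = engine.solve(theta)
    nn = n - p
    sigma2 = sol["rss"] / nn
    dev_reml = engine.deviance(theta, reml=True)
    dev_ml = engine.deviance(theta, reml=False)
    loglik_reml = -0.5 * dev_reml
    loglik_ml = -0.5 * dev_ml

    Sinv = sol["Sinv"]
    r = engine.r
    cov_fixed = sigma2 * Sinv[r:, r:]
    beta_all = pd.Series(sol["beta"], index=names)
    if spec.exposure:
        j = names.index(spec.exposure)
        beta = float(beta_all.iloc[j])
        se = float(np.sqrt(cov_fixed[j, j]))
    else:
        beta, se = float("nan"), float("nan")
    ci = (beta - Z975 * se, beta + Z975 * se)
    pval = float(2 * stats.norm.sf(abs(beta) / se)) if se > 0 else float("nan")

    smooths = []
    offset = 0
    for (term, Z, k), lt in zip(zblocks, theta[1:]):
        cols = slice(offset, offset + Z.shape[1])
        edf = float(Z.shape[1] - np.trace(Sinv[cols, cols]))
        lam = float(np.exp(-lt))
        smooths.append(SmoothInfo(name=term, k=k, lam=lam, edf=edf,
                                  null_dim=1))
        offset += Z.shape[1]

    psi_u = float(np.exp(theta[0]))
    fit = PammFit(
        beta=beta, se=se, ci95=ci, p_value=pval,
        coefficients=beta_all, cov_fixed=cov_fixed, smooths=smooths,
        re_sd=float(np.sqrt(psi_u * sigma2)),
        resid_sd=float(np.sqrt(sigma2)),
        loglik_ml=loglik_ml, loglik_reml=loglik_reml, aic=float("nan"),
        n_obs=n, n_dropped=n_dropped, n_groups=n_groups,
        converged=converged, theta=theta, fitted=sol["fitted"], spec=spec)
    fit.aic = model_aic(fit)
    return fit


def model_aic(fit: PammFit) -> float:
    """-2 * ML log-likelihood + 2 * total effective df (marginal AIC)."""
    if not fit.converged:
        return float("nan")
    return -2.0 * fit.loglik_ml + 2.0 * fit.edf_total


def wald_joint_test(fit: PammFit, term_names: list[str]):
    """Joint Wald chi-square that the named fixed coefficients are all 0."""
    names = list(fit.coefficients.index)
    idx = [names.index(t) for t in term_names]
    b = fit.coefficients.iloc[idx].to_numpy(float)
    V = fit.cov_fixed[np.ix_(idx, idx)]
    stat = float(b @ np.linalg.solve(V, b))
    df = len(idx)
    return stat, df, float(stats.chi2.sf(stat, df))
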