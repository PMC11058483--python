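"""Inference sequence on top of the fitter.

Order of operations mirrors the analysis the package reproduces:

1. season-restrict the visits (heat models use warm-window visits only,
   cold models cold-window visits only);
2. scan every event definition at lag0 and keep the per-definition
   effect rows (beta, CI, p, AIC);
3. pick the best-fitting heat and cold definition by minimal AIC;
4. trace the lag curve for the selected definitions: eight single-day
   refits (lag0..lag7) and seven cumulative refits (lag0-1..lag0-7);
5. stratify at the lag of maximum effect and test effect heterogeneity
   two ways — a Wald chi-square on the pooled model's
   exposure-by-stratum interaction terms (primary) and a Cochran-Q over
   the per-stratum estimates (secondary).

Significance is two-tailed at 0.05 throughout; no multiplicity
correction is applied to the scan (a Bonferroni column is emitted for
transparency but never used for selection).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .events import EventCalendar, SeasonWindow
from .exposure import lag_exposures
from .gamm import ModelSpec, fit_pamm, wald_joint_test

logger = logging.getLogger(__name__)

SINGLE_LAGS = [f"lag{k}" for k in range(8)]
CUM_LAGS = [f"cum0{k}" for k in range(1, 8)]

AGE_GROUP_EDGES = [18, 30, 40, 50, np.inf]
AGE_GROUP_LABELS = ["18-29", "30-39", "40-49", "50-58"]
BMI_GROUP_LABELS = ["underweight", "normal", "overweight", "obese"]


def stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else \
        "*" if p < 0.05 else ""


@dataclass
class EffectRow:
    definition_id: str
    kind: str
    response: str
    lag: str
    beta: float
    se: float
    ci95: tuple
    p_value: float
    aic: float
    n_obs: int
    converged: bool

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ci_lo"], d["ci_hi"] = d.pop("ci95")
        d["stars"] = stars(self.p_value)
        return d


@dataclass
class StratumEffect:
    stratifier: str
    level: str
    beta: float
    se: float
    ci95: tuple
    p_value: float
    n_obs: int
    flagged: str = ""        # "", "small_stratum", "no_exposed", "failed"


@dataclass
class HeterogeneityResult:
    stratifier: str
    lag: str
    wald_chi2: float
    wald_df: int
    wald_p: float
    cochran_q: float
    q_df: int
    q_p: float
    excluded_levels: list = field(default_factory=list)


def seasonal_subset(visits: pd.DataFrame, window: SeasonWindow) -> pd.DataFrame:
    """Visits whose date falls inside the seasonal window (inclusive)."""
    dates = pd.to_datetime(visits["date"])
    mask = np.array([window.contains(d.date()) for d in dates])
    out = visits[mask].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError(f"no visits fall in the {window.kind} window")
    return out


def _merged_frame(data: pd.DataFrame, calendar: EventCalendar,
                  max_lag: int = 7) -> pd.DataFrame:
    subset = seasonal_subset(data, calendar.definition.window)
    expo = lag_exposures(calendar, subset, max_lag=max_lag)
    cols = [c for c in expo.columns if c.startswith("x_")]
    return subset.merge(expo[["subject_id", "date"] + cols],
                        on=["subject_id", "date"], how="inner")


def _fit_to_row(fit, definition_id, kind, response, lag) -> EffectRow:
    return EffectRow(definition_id=definition_id, kind=kind,
                     response=response, lag=lag, beta=fit.beta, se=fit.se,
                     ci95=fit.ci95, p_value=fit.p_value, aic=fit.aic,
                     n_obs=fit.n_obs, converged=fit.converged)


def definition_scan(data: pd.DataFrame, catalog, response: str,
                    spec: ModelSpec | None = None) -> list[EffectRow]:
    """One lag0 fit per event definition; failures are flagged rows."""
    base = spec or ModelSpec(response=response)
    rows = []
    warm_theta = {}
    for defn, cal in catalog:
        try:
            frame = _merged_frame(data, cal)
            s = dataclasses.replace(base, response=response,
                                    exposure="x_lag0")
            warm = warm_theta.get(defn.kind)
            fit = fit_pamm(s, frame, warm_start=warm, fast=warm is not None)
            warm_theta[defn.kind] = fit.theta
            rows.append(_fit_to_row(fit, defn.id, defn.kind, response,
                                    "lag0"))
        except ValueError as err:
            logger.warning("scan: %s failed: %s", defn.id, err)
            rows.append(EffectRow(defn.id, defn.kind, response, "lag0",
                                  np.nan, np.nan, (np.nan, np.nan), np.nan,
                                  np.nan, 0, False))
    return rows


def select_best(rows: list[EffectRow]) -> dict:
    """Minimal-AIC definition id per kind; ties break by catalog order."""
    best: dict[str, EffectRow] = {}
    for row in rows:
        if not row.converged or not np.isfinite(row.aic):
            continue
        cur = best.get(row.kind)
        if cur is None or row.aic < cur.aic:
            best[row.kind] = row
    if not best:
        raise ValueError("no converged definition fits to select from")
    return {kind: row.definition_id for kind, row in best.items()}


def lag_curve(data: pd.DataFrame, calendar: EventCalendar, response: str,
              max_lag: int = 7, include_cumulative: bool = True,
              spec: ModelSpec | None = None) -> list[EffectRow]:
    """15 independent refits: single-day lag0..lag7, cumulative 01..07."""
    base = spec or ModelSpec(response=response)
    defn = calendar.definition
    frame = _merged_frame(data, calendar, max_lag=max_lag)
    rows = []
    warm = None
    labels = [f"lag{k}" for k in range(max_lag + 1)]
    if include_cumulative:
        labels += [f"cum0{k}" for k in range(1, max_lag + 1)]
    for lag in labels:
        try:
            s = dataclasses.replace(base, response=response,
                                    exposure=f"x_{lag}")
            fit = fit_pamm(s, frame, warm_start=warm, fast=warm is not None)
            warm = fit.theta
            rows.append(_fit_to_row(fit, defn.id, defn.kind, response, lag))
        except ValueError as err:
            logger.warning("lag_curve: %s %s failed: %s", defn.id, lag, err)
            rows.append(EffectRow(defn.id, defn.kind, response, lag,
                                  np.nan, np.nan, (np.nan, np.nan), np.nan,
                                  np.nan, 0, False))
    return rows


def max_effect_lag(rows: list[EffectRow]) -> str:
    """Lag of maximum single-day |beta|, preferring significant lags."""
    single = [r for r in rows if r.lag in SINGLE_LAGS and r.converged
              and np.isfinite(r.beta)]
    if not single:
        raise ValueError("no converged single-day lag rows")
    sig = [r for r in single if r.p_value < 0.05]
    pool = sig or single
    return max(pool, key=lambda r: abs(r.beta)).lag


def _stratum_column(data: pd.DataFrame, stratifier: str):
    if stratifier == "sex":
        return data["sex"].astype(str), ["male", "female"]
    if stratifier == "age_group":
        col = pd.cut(data["age"], bins=AGE_GROUP_EDGES, right=False,
                     labels=AGE_GROUP_LABELS).astype(str)
        return col, AGE_GROUP_LABELS
    if stratifier == "bmi_group":
        return data["bmi_cat"].astype(str), BMI_GROUP_LABELS
    raise ValueError(f"unknown stratifier {stratifier!r}")


def cochran_q(betas, ses):
    """Cochran's heterogeneity Q over independent stratum estimates."""
    b = np.asarray(betas, float)
    s = np.asarray(ses, float)
    w = 1.0 / s ** 2
    bbar = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - bbar) ** 2))
    df = len(b) - 1
    if df <= 0:
        return q, 0, float("nan")
    return q, df, float(stats.chi2.sf(q, df))


def stratified_effects(data: pd.DataFrame, calendar: EventCalendar,
                       response: str, lag: str, stratifier: str,
                       spec: ModelSpec | None = None,
                       min_stratum_n: int = 30):
    """Per-stratum effects plus two heterogeneity tests.

    Primary: Wald chi-square on the joint exposure-by-stratum interaction
    coefficients of a pooled fit (df = usable levels - 1).  Secondary:
    Cochran-Q over the per-stratum estimates.  Strata with no exposed
    visits (or failed fits) are flagged and excluded, reducing the df.
    """
    base = spec or ModelSpec(response=response)
    col = f"x_{lag}"
    frame = _merged_frame(data, calendar)
    strat, levels = _stratum_column(frame, stratifier)
    frame = frame.assign(_stratum=strat)
    defn = calendar.definition

    # within a stratum the stratifier is constant: drop it there
    drop = {"sex": ("sex",), "bmi_group": ("bmi_cat",)}.get(stratifier, ())
    within = dataclasses.replace(
        base, linear_terms=tuple(t for t in base.linear_terms
                                 if t not in drop))

    effects, excluded = [], []
    for lev in levels:
        sub = frame[frame["_stratum"] == lev]
        flag = ""
        if len(sub) < min_stratum_n:
            flag = "small_stratum"
        if len(sub) and sub[col].nunique() < 2:
            flag = "no_exposed"
        fit = None
        if flag != "no_exposed" and len(sub) > 0:
            try:
                s = dataclasses.replace(within, response=response,
                                        exposure=col)
                fit = fit_pamm(s, sub)
            except ValueError as err:
                logger.warning("stratum %s=%s failed: %s", stratifier,
                               lev, err)
                flag = flag or "failed"
        if fit is not None and fit.converged:
            # a small stratum is flagged but still enters the tests;
            # only unfittable strata (no exposed / failed) are excluded
            effects.append(StratumEffect(stratifier, lev, fit.beta, fit.se,
                                         fit.ci95, fit.p_value, fit.n_obs,
                                         flag))
        else:
            effects.append(StratumEffect(stratifier, lev, np.nan, np.nan,
                                         (np.nan, np.nan), np.nan,
                                         len(sub), flag or "failed"))
            excluded.append(lev)

    usable = [e for e in effects if e.level not in excluded]
    # pooled interaction model over the usable strata only
    pool = frame[frame["_stratum"].isin([e.level for e in usable])].copy()
    ref = usable[0].level if usable else levels[0]
    inter_cols, extra = [], []
    for e in usable[1:]:
        name = f"{col}:{stratifier}[{e.level}]"
        pool[name] = pool[col] * (pool["_stratum"] == e.level)
        inter_cols.append(name)
    if stratifier == "age_group":
        # main effects of the grouping (age itself is already linear)
        for e in usable[1:]:
            mname = f"{stratifier}[{e.level}]"
            pool[mname] = (pool["_stratum"] == e.level).astype(float)
            extra.append(mname)
    wald_stat = wald_df = wald_p = np.nan
    if inter_cols:
        try:
            s = dataclasses.replace(base, response=response, exposure=col,
                                    extra_linear=tuple(extra + inter_cols))
            pooled_fit = fit_pamm(s, pool)
            wald_stat, wald_df, wald_p = wald_joint_test(pooled_fit,
                                                         inter_cols)
        except ValueError as err:
            logger.warning("pooled interaction fit failed: %s", err)

    if len(usable) >= 2:
        q, qdf, qp = cochran_q([e.beta for e in usable],
                               [e.se for e in usable])
    else:
        q, qdf, qp = np.nan, 0, np.nan
    het = HeterogeneityResult(stratifier=stratifier, lag=lag,
                              wald_chi2=wald_stat, wald_df=wald_df,
                              wald_p=wald_p, cochran_q=q, q_df=qdf, q_p=qp,
                              excluded_levels=excluded)
    return effects, het


@dataclass
class PipelineResults:
    scan: dict = field(default_factory=dict)        # response -> [EffectRow]
    best: dict = field(default_factory=dict)        # response -> {kind: id}
    lag_curves: dict = field(default_factory=dict)  # (response, id) -> rows
    strata: list = field(default_factory=list)      # StratumEffect
    heterogeneity: list = field(default_factory=list)


def analyze_study(data: pd.DataFrame, catalog, responses=("hb",),
                  stratifiers=("sex", "age_group", "bmi_group"),
                  spec: ModelSpec | None = None,
                  run_subgroups: bool = True) -> PipelineResults:
    """Full scan -> select -> lag curves -> subgroups for each response."""
    res = PipelineResults()
    cal_by_id = {d.id: cal for d, cal in catalog}
    for response in responses:
        rows = definition_scan(data, catalog, response, spec=spec)
        res.scan[response] = rows
        res.best[response] = select_best(rows)
        for kind, def_id in res.best[response].items():
            cal = cal_by_id[def_id]
            curve = lag_curve(data, cal, response, spec=spec)
            res.lag_curves[(response, def_id)] = curve
            if not run_subgroups:
                continue
            lag = max_effect_lag(curve)
            for stratifier in stratifiers:
                eff, het = stratified_effects(data, cal, response, lag,
                                              stratifier, spec=spec)
                res.strata.extend(eff)
                res.heterogeneity.append(het)
    return res


EFFECT_COLUMNS = ["definition_id", "kind", "response", "lag", "beta",
                  "se", "p_value", "aic", "n_obs", "converged",
                  "ci_lo", "ci_hi", "stars", "p_bonferroni"]


def effect_table(rows: list[EffectRow]) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame(columns=EFFECT_COLUMNS)
    df = pd.DataFrame([r.as_dict() for r in rows])
    m = df["p_value"].notna().sum()
    df["p_bonferroni"] = np.minimum(df["p_value"] * max(m, 1), 1.0)
    return df


def report(results: PipelineResults, outdir, make_plots: bool = False) -> dict:
    """Write CSV/JSON effect tables (and optional lag-curve plots)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    scan_rows = [r for rows in results.scan.values() for r in rows]
    scan_df = effect_table(scan_rows)
    scan_df.to_csv(outdir / "definition_scan.csv", index=False)
    written["definition_scan"] = str(outdir / "definition_scan.csv")

    curve_rows = [r for rows in results.lag_curves.values() for r in rows]
    curves_df = effect_table(curve_rows)
    curves_df.to_csv(outdir / "lag_curves.csv", index=False)
    written["lag_curves"] = str(outdir / "lag_curves.csv")

    strata_df = pd.DataFrame([{
        "stratifier": e.stratifier, "level": e.level, "beta": e.beta,
        "se": e.se, "ci_lo": e.ci95[0], "ci_hi": e.ci95[1],
        "p_value": e.p_value, "stars": stars(e.p_value),
        "n_obs": e.n_obs, "flagged": e.flagged,
    } for e in results.strata], columns=[
        "stratifier", "level", "beta", "se", "ci_lo", "ci_hi",
        "p_value", "stars", "n_obs", "flagged"])
    strata_df.to_csv(outdir / "stratum_effects.csv", index=False)
    written["stratum_effects"] = str(outdir / "stratum_effects.csv")

    het_df = pd.DataFrame([dataclasses.asdict(h)
                           for h in results.heterogeneity],
                          columns=[f.name for f in
                                   dataclasses.fields(HeterogeneityResult)])
    het_df.to_csv(outdir / "heterogeneity.csv", index=False)
    written["heterogeneity"] = str(outdir / "heterogeneity.csv")

    summary = {
        "best_definitions": results.best,
        "n_scan_rows": len(scan_rows),
        "n_lag_rows": len(curve_rows),
    }
    with open(outdir / "results.json", "w") as fh:
        json.dump({
            "summary": summary,
            "scan": scan_df.to_dict(orient="records"),
            "lag_curves": curves_df.to_dict(orient="records"),
            "strata": strata_df.to_dict(orient="records"),
            "heterogeneity": het_df.to_dict(orient="records"),
        }, fh, indent=2, default=str)
    written["results"] = str(outdir / "results.json")

    if make_plots and len(curves_df):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        for (resp, def_id), rows in results.lag_curves.items():
            df = effect_table(rows)
            single = df[df["lag"].isin(SINGLE_LAGS)]
            fig, ax = plt.subplots(figsize=(6, 3.5))
            x = np.arange(len(single))
            ax.errorbar(x, single["beta"],
                        yerr=[single["beta"] - single["ci_lo"],
                              single["ci_hi"] - single["beta"]],
                        fmt="o", capsize=3)
            ax.axhline(0.0, color="grey", lw=0.8)
            ax.set_xticks(x, single["lag"])
            ax.set_xlabel("lag (days)")
            ax.set_ylabel(f"effect on {resp}")
            ax.set_title(f"{def_id}: single-day lag effects")
            path = outdir / f"lag_curve_{resp}_{def_id}.png"
            fig.tight_layout()
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written[f"plot_{resp}_{def_id}"] = str(path)
    return written
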