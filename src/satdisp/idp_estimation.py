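"""Displaced-population inference from gridded car counts.

Two linkage models are fitted per city on the baseline year and used to
predict population in comparison months, bracketing the estimate:

* ratio method - per-cell population-to-car ratio r_z = y_z / x_z from the
  pooled baseline table, with the city-wide median ratio imputed for
  zero-car cells; period population is r_z times the period car count.
  Empty cells predict exactly zero people, so this estimator follows car
  losses fully (lower-bound flavor).
* regression method - a penalized cubic-spline Poisson regression of
  people on cars with log link, Y ~ Poisson(exp(b0 + f(x))).  Because the
  smooth assigns its conditional mean to every cell, including empty ones,
  its changes are milder (upper-bound flavor).

Comparisons only ever use matching months (calendar months present in
both the baseline and the comparison year) and matching cells (cells
covered in both periods); nothing is imputed for uncovered cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FitError

GAM_EXTRAPOLATION_TOL = 1e-9


def match_months(
    month_presence: pd.DataFrame, baseline_year: int, other_years: Sequence[int]
) -> dict:
    """Months shared between the baseline year and each other year, per city.

    `month_presence` needs columns aoi_id, year, month (one row per
    city-month with usable data).  Cities with no overlap in any year are
    returned with all-empty sets; the caller excludes them with a reason.
    """
    out: dict = {}
    for aoi_id, grp in month_presence.groupby("aoi_id"):
        months_of = {y: set(g["month"]) for y, g in grp.groupby("year")}
        base = months_of.get(baseline_year, set())
        out[aoi_id] = {
            int(y): sorted(base & months_of.get(y, set())) for y in other_years
        }
    return out


def pool_baseline(
    stats: pd.DataFrame, grid_cells: pd.DataFrame, baseline_year: int
) -> pd.DataFrame:
    """Pool baseline months into the per-cell mean-cars / people table.

    Only cells covered in at least one baseline month appear.  People come
    from the baseline gridded population attached to the analysis grid.
    """
    base = stats[stats["year"] == baseline_year]
    pooled = base.groupby("cell_id", as_index=False).agg(
        mean_cars=("mean_cars", "mean"), n_months=("month", "nunique"))
    people = grid_cells.set_index("cell_id")["baseline_people"]
    pooled["people"] = pooled["cell_id"].map(people)
    return pooled.dropna(subset=["people"]).reset_index(drop=True)


@dataclass
class RatioModel:
    ratios: pd.Series            # cell_id -> ratio (median-imputed where x=0)
    fallback_ratio: float
    n_imputed: int


def fit_ratio(baseline: pd.DataFrame) -> RatioModel:
    """Per-cell population-to-car ratios with global-median imputation.

    Cells with zero baseline cars cannot define a ratio; they borrow the
    median of the defined ratios of the same city.  Errors if every cell
    has zero cars.
    """
    x = baseline["mean_cars"].to_numpy(dtype=float)
    y = baseline["people"].to_numpy(dtype=float)
    defined = x > 0
    if not defined.any():
        raise FitError("all cells have zero baseline cars: ratio undefined city-wide")
    ratios = np.full(len(x), np.nan)
    ratios[defined] = y[defined] / x[defined]
    fallback = float(np.median(ratios[defined]))
    n_imputed = int((~defined).sum())
    ratios[~defined] = fallback
    return RatioModel(
        ratios=pd.Series(ratios, index=baseline["cell_id"].to_numpy()),
        fallback_ratio=fallback,
        n_imputed=n_imputed,
    )


def predict_ratio(model: RatioModel, period_cars: pd.Series) -> tuple[pd.Series, int]:
    """Predict people per cell as ratio x cars; zero cars give zero people.

    Cells absent from the baseline (no ratio) are excluded; their count is
    returned alongside the predictions.
    """
    has_ratio = period_cars.index.isin(model.ratios.index)
    n_excluded = int((~has_ratio).sum())
    cars = period_cars[has_ratio]
    pred = model.ratios.loc[cars.index] * cars
    return pred, n_excluded


@dataclass
class GamModel:
    """Fitted smooth Poisson people-on-cars regression for one city."""

    result: object
    smoother: object | None
    intercept: float
    alpha: float
    basis_dim: int
    x_min: float
    x_max: float
    deviance_explained: float
    r2: float
    dispersion: float
    n_cells: int
    degenerate: bool = False     # constant-x fallback to intercept-only
    low_confidence: bool = False


def fit_gam(
    baseline: pd.DataFrame,
    basis_dim: int = 10,
    min_cells: int = 10,
    alpha: float | None = None,
    r2_report_threshold: float = 0.6,
) -> GamModel:
    """Fit the penalized cubic-spline Poisson regression of people on cars.

    The smoothing penalty weight is chosen automatically (generalized
    cross-validation type criterion) unless given.  The pooled people
    response is a non-integer average; it is fitted through the Poisson
    log-likelihood treated as a quasi-likelihood, and the dispersion is
    reported.  Degenerate (constant-car) tables fall back to an
    intercept-only fit with a warning.  Spline knots span the observed
    car range; predictions outside it are evaluated at the boundary
    (constant extrapolation) and flagged, because an unpenalized basis
    tail outside the data support is not a trustworthy mean.
    """
    import statsmodels.api as sm
    from statsmodels.gam.api import BSplines, GLMGam
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    x = baseline["mean_cars"].to_numpy(dtype=float)
    y = baseline["people"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < min_cells:
        raise FitError(f"only {n} usable cells (< {min_cells}): refusing to fit")

    def _null_deviance() -> float:
        return sm.GLM(y, np.ones((n, 1)), family=sm.families.Poisson()).fit().deviance

    if float(x.max() - x.min()) <= 1e-12:
        warnings.warn("constant car counts: falling back to intercept-only model")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, np.ones((n, 1)), family=sm.families.Poisson()).fit()
        mu = np.asarray(res.fittedvalues)
        r2 = 0.0
        return GamModel(result=res, smoother=None, intercept=float(res.params[0]),
                        alpha=0.0, basis_dim=1, x_min=float(x.min()), x_max=float(x.max()),
                        deviance_explained=0.0, r2=r2,
                        dispersion=float(res.pearson_chi2 / max(res.df_resid, 1)),
                        n_cells=n, degenerate=True, low_confidence=True)

    df_eff = int(min(basis_dim, max(4, len(np.unique(x)) - 1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        smoother = BSplines(
            x, df=[df_eff], degree=[3],
            knot_kwds=[{"lower_bound": float(x.min()), "upper_bound": float(x.max())}])
        exog = np.ones((n, 1))
        gam = GLMGam(y, exog=exog, smoother=smoother, family=sm.families.Poisson())
        try:
            if alpha is None:
                try:
                    # Nelder-Mead keeps the selection deterministic
                    gam.fit()
                    alpha_arr = gam.select_penweight(method="nm", disp=False)[0]
                    alpha_val = float(np.atleast_1d(alpha_arr)[0])
                except FitError:
                    raise
                except Exception:
                    # e.g. perfect separation on noiseless data: any positive
                    # penalty regularizes the problem
                    alpha_val = 1.0
            else:
                alpha_val = float(alpha)
            try:
                res = GLMGam(y, exog=exog, smoother=smoother, alpha=alpha_val,
                             family=sm.families.Poisson()).fit()
            except PerfectSeparationError:
                # the smooth reproduces the data exactly (noiseless input):
                # the penalized iteration refuses, but the plain GLM on the
                # spline design is well defined
                design = np.column_stack([exog, smoother.basis])
                res = sm.GLM(y, design, family=sm.families.Poisson()).fit()
                alpha_val = 0.0
        except FitError:
            raise
        except Exception as exc:  # convergence / linalg failures carry diagnostics
            raise FitError(f"smooth Poisson fit failed: {type(exc).__name__}: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise FitError("smooth Poisson fit did not converge to finite coefficients")
    mu = np.asarray(res.fittedvalues)
    null_dev = _null_deviance()
    dev_expl = float(1.0 - res.deviance / null_dev) if null_dev > 0 else 0.0
    r2 = float(np.corrcoef(y, mu)[0, 1] ** 2) if np.std(mu) > 0 and np.std(y) > 0 else 0.0
    return GamModel(
        result=res, smoother=smoother, intercept=float(res.params[0]),
        alpha=alpha_val, basis_dim=df_eff, x_min=float(x.min()), x_max=float(x.max()),
        deviance_explained=dev_expl, r2=r2,
        dispersion=float(res.pearson_chi2 / max(res.df_resid, 1)),
        n_cells=n, degenerate=False, low_confidence=r2 < r2_report_threshold,
    )


def predict_gam(model: GamModel, period_cars: pd.Series, ci_level: float = 0.95
                ) -> pd.DataFrame:
    """Predict people per cell from the fitted smooth; flag extrapolation.

    Cars outside the training range are flagged `out_of_range` and
    evaluated at the nearest boundary (constant extrapolation) rather
    than trusted to the basis outside its support; in particular, a cell
    with zero cars still receives the smooth's strictly positive
    boundary mean rather than zero (the regression method's dampening
    behavior).  The interval is a normal interval on the link scale from
    the penalized coefficient covariance.
    """
    from scipy import stats as sps

    x = period_cars.to_numpy(dtype=float)
    out_of_range = (x > model.x_max + GAM_EXTRAPOLATION_TOL) | (
        x < model.x_min - GAM_EXTRAPOLATION_TOL)
    if model.degenerate or model.smoother is None:
        eta = np.full(len(x), model.intercept)
        se = np.full(len(x), float(np.sqrt(np.clip(model.result.cov_params()[0, 0], 0, None))))
    else:
        x_eval = np.clip(x, model.x_min, model.x_max)
        basis = model.smoother.transform(x_eval[:, None])
        design = np.column_stack([np.ones(len(x)), basis])
        params = np.asarray(model.result.params)
        cov = np.asarray(model.result.cov_params())
        eta = design @ params
        var = np.einsum("ij,jk,ik->i", design, cov, design)
        se = np.sqrt(np.clip(var, 0.0, None))
    z = sps.norm.ppf(0.5 + ci_level / 2.0)
    return pd.DataFrame({
        "cell_id": period_cars.index,
        "predicted_people": np.exp(eta),
        "pred_low": np.exp(eta - z * se),
        "pred_high": np.exp(eta + z * se),
        "out_of_range": out_of_range,
    }).set_index("cell_id")


def population_change(
    predictions: pd.Series,
    baseline_people: pd.Series,
    method: str,
    city: str,
    period: tuple[int, int],
    area_coverage_pct: float = np.nan,
) -> pd.DataFrame:
    """Cell- and city-level relative population change for one prediction.

    Predictions and baseline must be aligned on the identical matching
    cell set; the city level is the exact sum of its cells.
    """
    if len(predictions) == 0:
        raise FitError("empty matching cell set: change undefined")
    if not predictions.index.equals(baseline_people.index):
        raise ValueError("predictions and baseline must share the matching cell index")
    year, month = period
    pred = predictions.to_numpy(dtype=float)
    base = baseline_people.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cell_pct = np.where(base > 0, 100.0 * (pred - base) / base, np.nan)
    rows = pd.DataFrame({
        "city": city, "year": year, "month": month, "method": method,
        "level": "cell", "cell_id": predictions.index,
        "predicted_people": pred, "baseline_people": base,
        "pct_change": cell_pct, "area_coverage_pct": area_coverage_pct,
    })
    tot_pred, tot_base = float(pred.sum()), float(base.sum())
    city_row = pd.DataFrame({
        "city": [city], "year": [year], "month": [month], "method": [method],
        "level": ["city"], "cell_id": [""],
        "predicted_people": [tot_pred], "baseline_people": [tot_base],
        "pct_change": [100.0 * (tot_pred - tot_base) / tot_base if tot_base > 0 else np.nan],
        "area_coverage_pct": [area_coverage_pct],
    })
    return pd.concat([rows, city_row], ignore_index=True)


def estimate_city(
    stats: pd.DataFrame,
    grid_cells: pd.DataFrame,
    baseline_year: int,
    comparison_years: Sequence[int],
    methods: Sequence[str] = ("ratio", "gam"),
    gam_basis_dim: int = 10,
    gam_min_cells: int = 10,
    area_pct_of_month: Mapping[tuple[int, int], float] | None = None,
    city: str = "city",
) -> tuple[pd.DataFrame, dict]:
    """Run the full per-city inference; returns (changes, model summary).

    Excluded cities (no matching months) raise FitError with the reason.
    """
    matched = match_months(
        stats.assign(aoi_id=city)[["aoi_id", "year", "month"]].drop_duplicates(),
        baseline_year, comparison_years)[city]
    if all(len(m) == 0 for m in matched.values()):
        raise FitError("no matching months with the baseline year")
    baseline = pool_baseline(stats, grid_cells, baseline_year)
    summary: dict = {"city": city, "n_baseline_cells": len(baseline),
                     "matched_months": {y: list(m) for y, m in matched.items()}}
    models: dict = {}
    if "ratio" in methods:
        rm = fit_ratio(baseline)
        models["ratio"] = rm
        summary["ratio_fallback"] = rm.fallback_ratio
        summary["ratio_n_imputed"] = rm.n_imputed
    if "gam" in methods:
        gm = fit_gam(baseline, basis_dim=gam_basis_dim, min_cells=gam_min_cells)
        models["gam"] = gm
        summary.update({
            "gam_intercept": gm.intercept, "gam_alpha": gm.alpha,
            "gam_basis_dim": gm.basis_dim,
            "gam_deviance_explained": gm.deviance_explained,
            "gam_r2": gm.r2, "gam_dispersion": gm.dispersion,
            "gam_low_confidence": gm.low_confidence,
            "gam_degenerate": gm.degenerate,
        })
    base_people = baseline.set_index("cell_id")["people"]
    parts = []
    for year, months in matched.items():
        for month in months:
            sub = stats[(stats["year"] == year) & (stats["month"] == month)]
            cars = sub.set_index("cell_id")["mean_cars"]
            matching = cars.index.intersection(base_people.index)
            if len(matching) == 0:
                continue
            cars = cars.loc[matching].sort_index()
            base = base_people.loc[matching].sort_index()
            area_pct = np.nan
            if area_pct_of_month is not None:
                area_pct = area_pct_of_month.get((year, month), np.nan)
            if "ratio" in models:
                pred, _ = predict_ratio(models["ratio"], cars)
                parts.append(population_change(pred, base, "ratio", city,
                                               (year, month), area_pct))
            if "gam" in models:
                gp = predict_gam(models["gam"], cars)
                ch = population_change(gp["predicted_people"], base, "gam", city,
                                       (year, month), area_pct)
                oor = gp["out_of_range"].to_dict()
                ch["out_of_range"] = [bool(oor.get(c, False)) for c in ch["cell_id"]]
                ch.loc[ch["level"] == "city", "out_of_range"] = any(oor.values())
                parts.append(ch)
    if not parts:
        raise FitError("matching months found but no matching covered cells")
    changes = pd.concat(parts, ignore_index=True)
    return changes, summary
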