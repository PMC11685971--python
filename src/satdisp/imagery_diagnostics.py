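"""Imagery-feature model: how acquisition conditions shift car density.

Log car density (detections per imaged km^2) is modelled by ordinary
least squares on image resolution (categorical, 0.3 m reference), snow
presence (reference: absent), off-nadir angle, sun elevation, and cloud
fraction.  The output table carries the estimate on the log scale with a
95% confidence interval, t- and p-values, one row per parameter.
Zero-detection images have no defined log density and are excluded with a
reported count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FitError

PARAM_ORDER = [
    "Intercept",
    "resolution_0.4",
    "resolution_0.5",
    "snow_yes",
    "off_nadir",
    "sun_elevation",
    "cloud_coverage",
]


@dataclass
class FeatureGlmResult:
    table: pd.DataFrame          # parameter, estimate, ci_low, ci_high, t_value, p_value
    n_images: int
    n_excluded_zero: int
    result: object               # statsmodels OLS results


def _design(images: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    dens = images["n_detections"].to_numpy(dtype=float) / images["area_km2"].to_numpy(dtype=float)
    X = pd.DataFrame(index=images.index)
    gsd = images["gsd_m"].to_numpy(dtype=float)
    X["resolution_0.4"] = (np.abs(gsd - 0.4) < 1e-9).astype(float)
    X["resolution_0.5"] = (np.abs(gsd - 0.5) < 1e-9).astype(float)
    X["snow_yes"] = images["snow"].astype(bool).astype(float)
    X["off_nadir"] = images["off_nadir_deg"].astype(float)
    X["sun_elevation"] = images["sun_elev_deg"].astype(float)
    X["cloud_coverage"] = images["cloud_frac"].astype(float)
    return X, dens


def fit_feature_glm(images: pd.DataFrame, min_images: int = 30) -> FeatureGlmResult:
    """OLS of log car density on imagery features.

    Requires >= `min_images` images with positive density.  Zero-variance
    or collinear design columns abort with their names.  Categorical
    levels absent from the data are dropped from the output table.
    """
    import statsmodels.api as sm

    X_all, dens = _design(images)
    pos = dens > 0
    n_excluded = int((~pos).sum())
    X = X_all[pos].copy()
    y = np.log(dens[pos])
    if len(X) < min_images:
        raise FitError(f"only {len(X)} images with positive density (< {min_images})")
    # drop categorical levels that never occur (no observations at that level)
    for col in ("resolution_0.4", "resolution_0.5", "snow_yes"):
        if X[col].sum() == 0:
            X = X.drop(columns=[col])
    zero_var = [c for c in X.columns if float(np.std(X[c])) == 0.0]
    if zero_var:
        raise FitError(f"zero-variance (collinear) design columns: {', '.join(zero_var)}")
    design = sm.add_constant(X, prepend=True).rename(columns={"const": "Intercept"})
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # name the columns implicated via QR pivoting
        from scipy.linalg import qr

        _, r, piv = qr(design.to_numpy(), pivoting=True)
        bad = [design.columns[piv[i]] for i in range(rank, design.shape[1])]
        raise FitError(f"collinear design columns: {', '.join(bad)}")
    res = sm.OLS(y, design).fit()
    ci = res.conf_int(alpha=0.05)
    table = pd.DataFrame({
        "parameter": design.columns,
        "estimate": res.params.to_numpy(),
        "ci_low": ci[0].to_numpy(),
        "ci_high": ci[1].to_numpy(),
        "t_value": res.tvalues.to_numpy(),
        "p_value": res.pvalues.to_numpy(),
    })
    order = [p for p in PARAM_ORDER if p in set(table["parameter"])]
    table = table.set_index("parameter").loc[order].reset_index()
    return FeatureGlmResult(table=table, n_images=len(X),
                            n_excluded_zero=n_excluded, result=res)


def glm_diagnostics(fit: FeatureGlmResult, images: pd.DataFrame) -> dict:
    """Residual diagnostics: normality, homoscedasticity, independence.

    Returns Jarque-Bera and Shapiro normality p-values, the Breusch-Pagan
    heteroscedasticity p-value (flag below 5%), and the lag-1 residual
    autocorrelation in acquisition-time order with its approximate
    two-sided p-value.
    """
    from scipy import stats as sps
    from statsmodels.stats.diagnostic import het_breuschpagan

    res = fit.result
    resid = np.asarray(res.resid)
    fitted = np.asarray(res.fittedvalues)
    out: dict = {"n": len(resid)}
    out["jarque_bera_p"] = float(sps.jarque_bera(resid).pvalue)
    out["shapiro_p"] = float(sps.shapiro(resid).pvalue) if len(resid) <= 5000 else np.nan
    try:
        _, bp_p, _, _ = het_breuschpagan(resid, res.model.exog)
        out["breusch_pagan_p"] = float(bp_p)
    except Exception:
        out["breusch_pagan_p"] = np.nan
    out["heteroscedastic_flag"] = bool(out["breusch_pagan_p"] < 0.05) if np.isfinite(
        out["breusch_pagan_p"]) else False
    # residual-vs-fitted trend (slope of |resid| on fitted)
    if np.std(fitted) > 0:
        slope = float(np.polyfit(fitted, np.abs(resid), 1)[0])
    else:
        slope = 0.0
    out["abs_resid_vs_fitted_slope"] = slope
    # lag-1 autocorrelation by acquisition time
    X_all, dens = _design(images)
    pos = dens > 0
    order = np.argsort(pd.to_datetime(images.loc[pos, "acquired_at"]).to_numpy())
    r = resid[order]
    if len(r) > 2 and np.std(r) > 0:
        rho = float(np.corrcoef(r[:-1], r[1:])[0, 1])
        z = rho * np.sqrt(len(r) - 1)
        out["lag1_autocorr"] = rho
        out["lag1_autocorr_p"] = float(2.0 * (1.0 - sps.norm.cdf(abs(z))))
    else:
        out["lag1_autocorr"] = np.nan
        out["lag1_autocorr_p"] = np.nan
    return out
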