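"""Validation arithmetic: prediction errors, correlations, OLS correction fits.

Reproduces the statistics of an accelerometer-against-reference
validation design: per-sex mean and SD of the PAL and TEE prediction
errors for each prediction method (unadjusted device output, Nagayoshi
MET adjustment, and the fitted regression correction), Pearson
correlations between predicted and measured PAL, the OLS derivation of
the sex-specific correction equations, and paired/unpaired t tests.

Conventions: errors are predicted minus measured; sample SDs use the
n - 1 denominator; correction models are fitted per sex, never pooled.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .exceptions import EstimationError, InputError
from .params import CorrectionModel

__all__ = [
    "prediction_errors",
    "fit_correction",
    "correlation",
    "group_compare",
    "validation_report",
]


def _pair(pred, meas, min_n=2):
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if pred.shape != meas.shape or pred.ndim != 1:
        raise InputError("pred and meas must be 1-d series of equal length")
    if pred.size < min_n:
        raise EstimationError(f"need at least {min_n} observations, got {pred.size}")
    return pred, meas


def prediction_errors(pred, meas):
    """Mean and sample SD (n - 1) of the per-participant error pred - meas."""
    pred, meas = _pair(pred, meas)
    err = pred - meas
    return float(err.mean()), float(err.std(ddof=1))


def fit_correction(pal_pred, pal_meas, sex: str = "F") -> CorrectionModel:
    """OLS of measured PAL (Y) on predicted PAL (X) for one sex.

    Returns the fitted :class:`CorrectionModel`; ``resid_sd`` is the
    sample SD of the residuals, whose mean is exactly zero on the
    fitting sample (an OLS identity, matching the reported
    "mean +- SD = 0.00 +- sd" structure of such correction equations).
    """
    x, y = _pair(pal_pred, pal_meas, min_n=3)
    if np.ptp(x) == 0:
        raise EstimationError("predicted PAL has zero variance; slope is undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    if slope <= 0:
        raise EstimationError(
            "fitted correction slope is non-positive; the sample is too small "
            "or predicted and measured PAL are unrelated"
        )
    resid_sd = float(np.std(res.resid, ddof=1))
    return CorrectionModel(sex=sex, slope=float(slope), intercept=float(intercept), resid_sd=resid_sd)


def correlation(pred, meas) -> float:
    """Pearson product-moment correlation."""
    pred, meas = _pair(pred, meas, min_n=3)
    if np.ptp(pred) == 0 or np.ptp(meas) == 0:
        raise EstimationError("correlation undefined for a constant series")
    return float(stats.pearsonr(pred, meas).statistic)


def group_compare(a, b, paired: bool):
    """Two-tailed t test: paired for measured-vs-predicted, unpaired for sexes.

    Returns ``(t, p)``. Identical paired series give t = 0 by convention
    (scipy returns NaN for zero variance differences).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(a.size, b.size) < 2:
        raise EstimationError("need at least 2 observations per series")
    if paired:
        if a.size != b.size:
            raise InputError("paired series must have equal length")
        if np.ptp(a - b) == 0 and np.allclose(a, b):
            return 0.0, 1.0
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue)


def _method_block(pred, meas, paired=True):
    mean_err, sd_err = prediction_errors(pred, meas)
    t, p = group_compare(pred, meas, paired=paired)
    return {"mean_error": mean_err, "sd_error": sd_err, "t": t, "p": p}


def validation_report(results: pd.DataFrame) -> dict:
    """Per-sex validation of the three prediction methods.

    ``results`` needs one row per participant with columns: sex, pal_meas,
    tee_meas, bmr_meas, bmr_pred, pal_pred, tee_pred, pal_nagayoshi,
    tee_nagayoshi. The regression correction is fitted per sex on this
    table, applied to the fitting sample, and evaluated with both the
    predicted and the measured BMR for corrected TEE. Deterministic given
    the table.
    """
    required = {
        "sex", "pal_meas", "tee_meas", "bmr_meas", "bmr_pred",
        "pal_pred", "tee_pred", "pal_nagayoshi", "tee_nagayoshi",
    }
    missing = required - set(results.columns)
    if missing:
        raise InputError(f"results table missing columns: {sorted(missing)}")
    if results[sorted(required)].isna().any().any():
        raise InputError("results table has missing values in compared columns")

    report: dict = {"n_total": int(len(results)), "per_sex": {}}
    for sex, grp in results.groupby("sex", sort=True):
        model = fit_correction(grp["pal_pred"], grp["pal_meas"], sex=sex)
        pal_corr = model(grp["pal_pred"].to_numpy())
        tee_corr_pred = pal_corr * grp["bmr_pred"].to_numpy()
        tee_corr_meas = pal_corr * grp["bmr_meas"].to_numpy()
        block = {
            "n": int(len(grp)),
            "correction_model": {
                "slope": model.slope,
                "intercept": model.intercept,
                "resid_sd": model.resid_sd,
            },
            "correlation_r": correlation(grp["pal_pred"], grp["pal_meas"]),
            "bmr": _method_block(grp["bmr_pred"], grp["bmr_meas"]),
            "pal": {
                "unadjusted": _method_block(grp["pal_pred"], grp["pal_meas"]),
                "nagayoshi": _method_block(grp["pal_nagayoshi"], grp["pal_meas"]),
                "regression": _method_block(pal_corr, grp["pal_meas"]),
            },
            "tee": {
                "unadjusted": _method_block(grp["tee_pred"], grp["tee_meas"]),
                "nagayoshi": _method_block(grp["tee_nagayoshi"], grp["tee_meas"]),
                "regression_pred_bmr": _method_block(tee_corr_pred, grp["tee_meas"]),
                "regression_meas_bmr": _method_block(tee_corr_meas, grp["tee_meas"]),
            },
        }
        report["per_sex"][sex] = block
    if {"F", "M"} <= set(report["per_sex"]):
        f = results[results["sex"] == "F"]["pal_meas"]
        m = results[results["sex"] == "M"]["pal_meas"]
        t, p = group_compare(f, m, paired=False)
        report["sex_difference_pal_meas"] = {"t": t, "p": p}
    return report
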