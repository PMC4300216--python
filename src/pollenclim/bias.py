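"""Hindcasting: cross-era application of a transfer function and its bias.

A transfer function trained on one era's calibration set is applied to
another era's pollen, and the predictions are compared with that era's
observed climate. A systematic (e.g. warm) offset in the residuals —
predicted minus observed — measures the non-stationarity bias introduced by
training on the wrong era. The hindcast RMSE is contrasted with the
reference set's own cross-validation error (bootstrap RMSEP): their
percentage difference is the price paid for using the other era's set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import CalibrationSet, ClimateTable, PollenMatrix, ValidationError, harmonize_taxa
from .transfer import CVResult, WAPLS, bootstrap_rmsep, fit_wapls, loo_cross_validate, predict

logger = logging.getLogger(__name__)


@dataclass
class BiasReport:
    """Residual summary of a hindcast, optionally paired with CV references."""

    residuals: np.ndarray          # predicted − observed, °C
    predicted: np.ndarray
    observed: np.ndarray
    mean_bias: float
    residual_sd: float             # ddof=1
    rmse: float
    variable: str = ""
    loo: CVResult | None = None
    boot: CVResult | None = None
    improvement_percent: int | None = None


def hindcast(tf: WAPLS, target: CalibrationSet, variable: str | None = None) -> BiasReport:
    """Apply a transfer function to another calibration set's pollen.

    Residuals are predicted − observed (positive = warm bias), observed
    being the target set's own climate table.
    """
    variable = variable or getattr(tf, "variable_", None)
    if variable is None:
        raise ValidationError("variable must be given or recorded on the model")
    observed = target.climate.values_for(variable)
    predicted = predict(tf, target.pollen)
    residuals = predicted - observed
    return BiasReport(
        residuals=residuals,
        predicted=predicted,
        observed=observed,
        mean_bias=float(residuals.mean()),
        residual_sd=float(residuals.std(ddof=1)),
        rmse=float(np.sqrt(np.mean(residuals ** 2))),
        variable=variable,
    )


def improvement_percent(rmse_hindcast: float, rmsep_reference: float) -> int:
    """Percent excess of the hindcast RMSE over the reference RMSEP.

    100 × (RMSE_hindcast − RMSEP_ref) / RMSEP_ref, rounded to the nearest
    integer for reporting. Positive means the cross-era model is worse than
    the reference set's own cross-validated error.
    """
    if rmse_hindcast <= 0 or rmsep_reference <= 0:
        raise ValidationError("both error inputs must be positive")
    return int(round(100.0 * (rmse_hindcast - rmsep_reference) / rmsep_reference))


def _harmonized(cal_ref: CalibrationSet, cal_alt: CalibrationSet):
    pr, pa = harmonize_taxa(cal_ref.pollen, cal_alt.pollen)
    ref = CalibrationSet(pr, cal_ref.climate, label=cal_ref.label)
    alt = CalibrationSet(pa, cal_alt.climate, label=cal_alt.label)
    return ref, alt


def bias_experiment(cal_ref: CalibrationSet, cal_alt: CalibrationSet, variable: str,
                    n_components: int = 2, n_boot: int = 1000,
                    seed: int = 0) -> BiasReport:
    """Full cross-era design: hindcast plus the reference set's own CV.

    Fits the transfer function on ``cal_alt`` (e.g. the disturbed "modern"
    set), hindcasts onto ``cal_ref`` (e.g. the pre-settlement set), then runs
    leave-one-out and bootstrap cross-validation on ``cal_ref`` itself and
    reports the hindcast RMSE's percent excess over RMSEP_boot.
    """
    ref, alt = _harmonized(cal_ref, cal_alt)
    tf = fit_wapls(alt, variable, n_components=n_components)
    report = hindcast(tf, ref, variable)
    report.loo = loo_cross_validate(ref, variable, n_components=n_components)
    report.boot = bootstrap_rmsep(ref, variable, n_components=n_components,
                                  n_boot=n_boot, seed=seed)
    report.improvement_percent = improvement_percent(report.rmse,
                                                     report.boot.rmsep_boot)
    return report
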