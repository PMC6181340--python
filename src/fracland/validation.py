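"""Validation of predicted crop shares against observed unit shares.

Three instruments, applied in-sample at Level 1 and out-of-sample at
Level 2 (district/county units never used in estimation):

* RMSE over units: sqrt(mean_j (predicted_j - observed_j)^2);
* a calibration regression — OLS of observed on predicted shares, ideal
  fit having intercept 0 and slope 1 (points on the 45-degree line with
  predicted on the horizontal axis), with t-tests against those values;
* the squared Pearson correlation of the two series, reported as R^2.

Level-2 validation aggregates the Level-1-calibrated pixel fractions to
whatever subset of Level-2 units has observed data, then applies the same
metrics; partial coverage simply reduces n_units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import DataError, PredictionError
from .grid import AggregateShares
from .downscale import PredictionGrid


def rmse(predicted: pd.Series | np.ndarray, observed: pd.Series | np.ndarray) -> float:
    """Root mean squared error over aligned units (order-invariant when both
    inputs are Series keyed by unit)."""
    if isinstance(predicted, pd.Series) and isinstance(observed, pd.Series):
        diff = set(predicted.index.astype(str)) ^ set(observed.index.astype(str))
        if diff:
            raise DataError(f"mismatched unit sets: {sorted(diff)[:10]}")
        observed = observed.reindex(predicted.index)
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise DataError(f"shape mismatch: {p.shape} vs {o.shape}")
    return float(np.sqrt(np.mean((p - o) ** 2)))


@dataclass
class CalibrationResult:
    """OLS calibration of observed on predicted shares."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    t_intercept_vs0: float
    t_slope_vs1: float
    p_intercept_vs0: float
    p_slope_vs1: float
    r_squared: float
    n_units: int


def calibration(
    predicted: pd.Series | np.ndarray,
    observed: pd.Series | np.ndarray,
    direction: str = "observed_on_predicted",
) -> CalibrationResult:
    """Calibration regression with tests of intercept=0 and slope=1.

    ``direction`` selects which series is the regressand; the default
    regresses observed on predicted, so slope 1 / intercept 0 corresponds to
    points on the 45-degree line. R^2 is the squared Pearson correlation
    (identical in either direction).
    """
    if isinstance(predicted, pd.Series) and isinstance(observed, pd.Series):
        observed = observed.reindex(predicted.index)
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.size < 3:
        raise DataError(f"need at least 3 units for calibration, got {p.size}")
    if direction == "observed_on_predicted":
        yv, xv = o, p
    elif direction == "predicted_on_observed":
        yv, xv = p, o
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if np.ptp(xv) == 0:
        raise DataError("zero-variance regressor in calibration regression")
    X = sm.add_constant(xv, has_constant="add")
    fit = sm.OLS(yv, X).fit()
    b0, b1 = fit.params
    se0, se1 = fit.bse
    r2 = float(np.corrcoef(p, o)[0, 1] ** 2)
    t0 = b0 / se0 if se0 > 0 else np.inf * np.sign(b0)
    t1 = (b1 - 1.0) / se1 if se1 > 0 else np.inf * np.sign(b1 - 1.0)
    from scipy import stats

    dof = p.size - 2
    return CalibrationResult(
        intercept=float(b0),
        slope=float(b1),
        se_intercept=float(se0),
        se_slope=float(se1),
        t_intercept_vs0=float(t0),
        t_slope_vs1=float(t1),
        p_intercept_vs0=float(2 * stats.t.sf(abs(t0), dof)),
        p_slope_vs1=float(2 * stats.t.sf(abs(t1), dof)),
        r_squared=r2,
        n_units=int(p.size),
    )


@dataclass
class ValidationReport:
    """Per-crop validation metrics at one administrative level."""

    level: int
    metrics: pd.DataFrame  # index: crop; columns: rmse, intercept, slope, ses, r2, n_units
    scatter: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        return {"level": self.level, "metrics": self.metrics.to_dict(orient="index")}


def _report(
    predicted: pd.DataFrame, observed: pd.DataFrame, level: int, crops: list[str]
) -> ValidationReport:
    rows = {}
    scatter = []
    for k in crops:
        p = predicted[k]
        o = observed[k].reindex(p.index)
        cal = calibration(p, o)
        rows[k] = {
            "rmse": rmse(p, o),
            "calib_intercept": cal.intercept,
            "calib_slope": cal.slope,
            "se_intercept": cal.se_intercept,
            "se_slope": cal.se_slope,
            "r_squared": cal.r_squared,
            "n_units": cal.n_units,
        }
        scatter.append(
            pd.DataFrame({"unit": p.index, "crop": k, "predicted": p.values, "observed": o.values})
        )
    return ValidationReport(
        level=level,
        metrics=pd.DataFrame(rows).T,
        scatter=pd.concat(scatter, ignore_index=True),
    )


def level1_report(
    grid: PredictionGrid, observed: AggregateShares, kind: str = "raw"
) -> ValidationReport:
    """In-sample validation: aggregate pixel fractions to Level 1 and compare
    with the observed unit shares (raw fractions by default — the scaled
    ones match by construction)."""
    agg = grid.aggregate(level=1, kind=kind)
    common = [u for u in agg.index if u in set(observed.units)]
    if not common:
        raise PredictionError("no overlap between predicted and observed Level-1 units")
    crops = [c for c in grid.crops[1:] if c in observed.crops]
    return _report(agg.loc[common], observed.frame.loc[common], 1, crops)


def level2_report(grid: PredictionGrid, level2_observed: AggregateShares) -> ValidationReport:
    """Out-of-sample validation at Level 2 from the Level-1-calibrated grid.

    Aggregates scaled pixel fractions to the Level-2 units present in the
    observed set (coverage may be partial; n_units records what was used).
    """
    if grid.scaled is None:
        raise PredictionError("scale the grid to Level-1 totals before Level-2 validation")
    agg = grid.aggregate(level=2, kind="scaled")
    common = [u for u in agg.index if u in set(level2_observed.units)]
    if not common:
        raise PredictionError("no overlapping Level-2 units between grid and observed shares")
    crops = [c for c in grid.crops[1:] if c in level2_observed.crops]
    return _report(agg.loc[common], level2_observed.frame.loc[common], 2, crops)
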