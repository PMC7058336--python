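"""Quantitation-side computations upstream of precision profiles.

Clinical LC-MS/MS assays quantify through a weighted linear calibration
of the instrument response ratio (analyte / internal standard peak area)
on nominal concentration, with 1/x^2 weights so low calibrators are not
swamped by high ones.  Concentrations below the calibrated range are
evaluated by single-point proportionality through the lowest calibrator,
which is legitimate only when the calibration intercept is statistically
indistinguishable from zero — hence the one-sample location test on the
intercepts observed across experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, UsageError

__all__ = [
    "CalibrationModel",
    "fit_calibration",
    "back_accuracy",
    "quantify_single_point",
    "intercept_zero_test",
]


@dataclass(frozen=True)
class CalibrationModel:
    """1/x^2-weighted linear calibration: response_ratio = a*C + b."""

    slope: float
    intercept: float
    r_squared: float
    levels: tuple[tuple[float, float], ...]  # (nominal, response_ratio)
    weighting: str = "inv_x2"

    def concentration(self, response_ratio: float) -> float:
        """Back-calculate a concentration from a response ratio."""
        return (response_ratio - self.intercept) / self.slope


def fit_calibration(
    levels: Sequence[tuple[float, float]]
) -> CalibrationModel:
    """Fit the 1/x^2-weighted calibration line.

    ``levels`` are (nominal concentration, response ratio) pairs;
    calibrators exclude the blank, so every nominal must be positive.
    The reported determination coefficient is the weighted R^2.
    """
    if len(levels) < 2:
        raise DegenerateDesignError("calibration needs >= 2 levels")
    x = np.array([lv[0] for lv in levels], dtype=float)
    y = np.array([lv[1] for lv in levels], dtype=float)
    if np.any(x <= 0):
        raise DegenerateDesignError("calibrator nominals must be > 0")
    if np.unique(x).size < 2:
        raise DegenerateDesignError("calibrators must span >= 2 distinct levels")
    w = 1.0 / x ** 2
    X = np.column_stack([np.ones_like(x), x])
    XtW = X.T * w
    beta = np.linalg.solve(XtW @ X, XtW @ y)
    intercept, slope = float(beta[0]), float(beta[1])
    resid = y - (intercept + slope * x)
    ybar = np.sum(w * y) / np.sum(w)
    ss_res = float(np.sum(w * resid ** 2))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationModel(
        slope=slope, intercept=intercept, r_squared=r2,
        levels=tuple((float(a), float(b)) for a, b in levels),
    )


def back_accuracy(model: CalibrationModel) -> list[float]:
    """Back-calculated accuracy (%) of each calibrator against its nominal."""
    if model.slope <= 0:
        raise DegenerateDesignError(
            f"unusable calibration: slope {model.slope} <= 0"
        )
    return [
        100.0 * model.concentration(ratio) / nominal
        for nominal, ratio in model.levels
    ]


def quantify_single_point(
    sample_ratio: float, cal_ratio: float, cal_conc: float
) -> float:
    """Below-range quantitation through the lowest calibrator.

    Proportionality with a forced zero intercept:
    C = cal_conc * sample_ratio / cal_ratio.  Appropriate when the fitted
    calibration intercepts are indistinguishable from zero (see
    :func:`intercept_zero_test`).
    """
    if cal_ratio <= 0:
        raise UsageError(f"calibrator response ratio must be > 0, got {cal_ratio}")
    return cal_conc * sample_ratio / cal_ratio


def intercept_zero_test(intercepts: Sequence[float]) -> tuple[float, float]:
    """One-sample location test of mean(intercepts) = 0.

    Returns (t, two-sided p) with t = mean / (sd / sqrt(n)) on n - 1
    degrees of freedom.  Degenerate zero-variance inputs return p = 1
    when the mean is also zero and p = 0 otherwise.
    """
    vals = np.asarray(intercepts, dtype=float)
    if vals.size < 2:
        raise UsageError("need at least 2 intercepts")
    if np.std(vals, ddof=1) == 0:
        if np.mean(vals) == 0:
            return 0.0, 1.0
        return float("inf") * np.sign(np.mean(vals)), 0.0
    t, p = stats.ttest_1samp(vals, 0.0)
    return float(t), float(p)
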