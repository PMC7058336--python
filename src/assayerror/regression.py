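"""The six assay-error-equation regression algorithms.

An assay error equation (AEE) is a polynomial SD(C) = c0 + c1*C + c2*C^2
+ c3*C^3 fitted to a precision profile; 1/SD(C)^2 is then the weight a
pharmacokinetic model assigns to an assay result at concentration C.  Six
algorithms are provided, conventionally labelled (a)-(f):

(a) unweighted linear least squares          ``LeastSquaresAEE(degree=1)``
(b) unweighted 2nd-order least squares       ``LeastSquaresAEE(degree=2)``
(c) unweighted 3rd-order least squares       ``LeastSquaresAEE(degree=3)``
(d) 1/x^2-weighted linear least squares      ``WeightedLeastSquaresAEE()``
(e) Theil's original median regression       ``TheilAEE()``
(f) Theil's regression, Siegel repeated
    median estimator                         ``SiegelAEE()``

The estimators follow the scikit-learn protocol (``fit(X, y)`` with X the
concentrations as a single-column array and y the per-level SDs,
``predict``, ``get_params``/``set_params``) so they compose with sklearn
pipelines and model selection.  Fitted coefficients are never clamped:
negative intercepts are physically impossible SDs, and the evaluation
stage screens for them, so the raw value must survive fitting.

The module-level ``fit_*`` functions are thin wrappers taking a
:class:`~assayerror.profiles.PrecisionProfile` and returning a
:class:`FitResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import _batch
from .datamodel import AssayErrorEquation
from .errors import DegenerateDesignError
from .profiles import PrecisionProfile

__all__ = [
    "LeastSquaresAEE",
    "WeightedLeastSquaresAEE",
    "TheilAEE",
    "SiegelAEE",
    "FitResult",
    "make_estimator",
    "fit_ols_linear",
    "fit_ols_poly",
    "fit_wls_inv_x2",
    "fit_theil",
    "fit_theil_siegel",
    "fit_algorithm",
    "predict_sd",
]


@dataclass
class FitResult:
    """Outcome of fitting one algorithm to one profile."""

    aee: AssayErrorEquation
    profile_ref: str = ""
    converged: bool = True
    notes: list[str] = field(default_factory=list)


class _BaseAEE(RegressorMixin, BaseEstimator):
    """Shared fit/predict plumbing for the AEE estimators."""

    #: algorithm tag recorded on the fitted equation; set by subclasses
    algorithm: str = ""

    # minimum number of profile points; subclasses may override
    _min_points = 3

    def _solve(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _check_design(self, x: np.ndarray) -> None:
        if len(x) < self._min_points:
            raise DegenerateDesignError(
                f"{self.algorithm} needs at least {self._min_points} "
                f"profile points, got {len(x)}"
            )
        if np.unique(x).size < 2:
            raise DegenerateDesignError(
                f"{self.algorithm}: all concentrations identical"
            )

    def fit(self, X, y):
        """Fit SD(C) to (concentration, SD) pairs.

        Parameters
        ----------
        X : array-like of shape (M, 1) or (M,)
            Profile concentrations.
        y : array-like of shape (M,)
            Per-level standard deviations.
        """
        X, y = check_X_y(np.reshape(np.asarray(X, dtype=float), (-1, 1)), y)
        x = X[:, 0]
        self._check_design(x)
        coef = self._solve(x, np.asarray(y, dtype=float))
        self.intercept_ = float(coef[0])
        self.coef_ = np.asarray(coef[1:], dtype=float)
        self.n_features_in_ = 1
        self.equation_ = AssayErrorEquation(
            self.algorithm, float(coef[0]), float(coef[1]),
            float(coef[2]), float(coef[3]),
        )
        self.notes_ = []
        if self.intercept_ < 0:
            self.notes_.append(
                f"negative intercept {self.intercept_:.6g} (SD at blank < 0)"
            )
        return self

    def predict(self, X):
        """Predicted SD at each concentration (raw, unclamped)."""
        check_is_fitted(self, "equation_")
        X = check_array(np.reshape(np.asarray(X, dtype=float), (-1, 1)))
        c = X[:, 0]
        c0, c1, c2, c3 = self.equation_.coefficients
        return c0 + c * (c1 + c * (c2 + c * c3))


class LeastSquaresAEE(_BaseAEE):
    """Unweighted least-squares polynomial AEE — algorithms (a), (b), (c).

    Parameters
    ----------
    degree : int, default 1
        Polynomial degree, 1-3.  A degree-d fit needs at least d + 2
        profile points (one more than the exact-interpolation minimum, so
        a residual degree of freedom always exists).
    """

    def __init__(self, degree: int = 1):
        self.degree = degree

    @property
    def algorithm(self) -> str:
        return {1: "ols_linear", 2: "ols_poly2", 3: "ols_poly3"}[self.degree]

    @property
    def _min_points(self) -> int:
        return self.degree + 2

    def _check_design(self, x):
        if self.degree not in (1, 2, 3):
            raise DegenerateDesignError(f"degree must be 1-3, got {self.degree}")
        super()._check_design(x)
        if np.unique(x).size < self.degree + 1:
            raise DegenerateDesignError(
                f"degree-{self.degree} fit needs {self.degree + 1} distinct "
                f"concentrations"
            )

    def _solve(self, x, y):
        return _batch.batch_ols_poly(x, y[None, :], self.degree)[0]


class WeightedLeastSquaresAEE(_BaseAEE):
    """1/x^2-weighted linear least squares — algorithm (d).

    The weight of the blank point (x = 0), where 1/x^2 is undefined, is
    set by ``blank_policy``: ``"cap"`` (default) gives it the weight of
    the lowest nonzero level so the blank still constrains the intercept;
    ``"drop"`` excludes it.
    """

    algorithm = "wls_inv_x2"

    def __init__(self, blank_policy: str = "cap"):
        self.blank_policy = blank_policy

    def _check_design(self, x):
        super()._check_design(x)
        if np.unique(x[x > 0]).size < 2:
            raise DegenerateDesignError(
                "1/x^2 weighting needs at least 2 distinct nonzero "
                "concentrations"
            )

    def _solve(self, x, y):
        return _batch.batch_wls_inv_x2(x, y[None, :], self.blank_policy)[0]


class TheilAEE(_BaseAEE):
    """Theil's original median regression — algorithm (e).

    The slope is the median of the slopes of the lines connecting every
    pair of profile points (pairs with equal concentration are skipped);
    the intercept is the median over points of sd_i - slope * x_i.
    Nonparametric and resistant to outlying SDs up to a breakdown point of
    about 29%.
    """

    algorithm = "theil"

    def _solve(self, x, y):
        return _batch.batch_theil(x, y[None, :])[0]


class SiegelAEE(_BaseAEE):
    """Theil's regression with Siegel's repeated-median estimator — (f).

    Per point i, the median over j != i of the pairwise slopes and of the
    pairwise intercept terms (x_j*sd_i - x_i*sd_j)/(x_j - x_i) is taken;
    the estimates are the medians of those per-point medians.  Maximally
    robust: breakdown point ~50%.
    """

    algorithm = "theil_siegel"

    def _solve(self, x, y):
        return _batch.batch_siegel(x, y[None, :])[0]


_FACTORIES = {
    "ols_linear": lambda: LeastSquaresAEE(1),
    "ols_poly2": lambda: LeastSquaresAEE(2),
    "ols_poly3": lambda: LeastSquaresAEE(3),
    "wls_inv_x2": WeightedLeastSquaresAEE,
    "theil": TheilAEE,
    "theil_siegel": SiegelAEE,
}


def make_estimator(algorithm: str, **kwargs) -> _BaseAEE:
    """Instantiate the estimator for an algorithm tag."""
    try:
        factory = _FACTORIES[algorithm]
    except KeyError:
        raise DegenerateDesignError(
            f"unknown algorithm {algorithm!r}; expected one of "
            f"{sorted(_FACTORIES)}"
        ) from None
    est = factory()
    if kwargs:
        est.set_params(**kwargs)
    return est


def _fit(est: _BaseAEE, profile: PrecisionProfile) -> FitResult:
    est.fit(profile.x.reshape(-1, 1), profile.sd)
    return FitResult(aee=est.equation_, notes=list(est.notes_))


def fit_ols_linear(profile: PrecisionProfile) -> FitResult:
    """Algorithm (a): unweighted linear least squares."""
    return _fit(LeastSquaresAEE(1), profile)


def fit_ols_poly(profile: PrecisionProfile, degree: int) -> FitResult:
    """Algorithms (b)/(c): unweighted polynomial least squares."""
    if degree not in (2, 3):
        raise DegenerateDesignError(f"degree must be 2 or 3, got {degree}")
    return _fit(LeastSquaresAEE(degree), profile)


def fit_wls_inv_x2(
    profile: PrecisionProfile, blank_policy: str = "cap"
) -> FitResult:
    """Algorithm (d): 1/x^2-weighted linear least squares."""
    return _fit(WeightedLeastSquaresAEE(blank_policy), profile)


def fit_theil(profile: PrecisionProfile) -> FitResult:
    """Algorithm (e): Theil's original median regression."""
    return _fit(TheilAEE(), profile)


def fit_theil_siegel(profile: PrecisionProfile) -> FitResult:
    """Algorithm (f): Theil with the Siegel repeated-median estimator."""
    return _fit(SiegelAEE(), profile)


def fit_algorithm(profile: PrecisionProfile, algorithm: str, **kwargs) -> FitResult:
    """Fit any algorithm by tag."""
    return _fit(make_estimator(algorithm, **kwargs), profile)


def predict_sd(aee: AssayErrorEquation, conc):
    """Evaluate SD(C) = c0 + c1*C + c2*C^2 + c3*C^3, unclamped.

    Negative return values are physically impossible SDs; they are left
    raw so the evaluation stage can flag the equation rather than mask it.
    Accepts a scalar or an array of concentrations.
    """
    c = np.asarray(conc, dtype=float)
    out = aee.c0 + c * (aee.c1 + c * (aee.c2 + c * aee.c3))
    return float(out) if np.isscalar(conc) else out
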