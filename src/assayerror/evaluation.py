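"""Goodness of fit (NSSR), combinatorial subset stability, and ranking.

Two complementary criteria judge an assay error equation:

* **NSSR** — the sum of squared residuals normalized to the predicted
  SDs, ``sum((SD_obs_i - SD_pred_i)^2 / SD_pred_i^2)``.  Unlike a
  correlation coefficient it weights relative misfit equally across the
  concentration range, which matters because SDs span orders of
  magnitude.
* **NNI%** — across all C(N, R) subsets of R of the N specimens, the
  percentage of fitted equations whose intercept is non-negative.  A
  negative intercept is a negative blank SD, which is physically
  impossible, so NNI% is the primary admissibility screen.

The subset analysis also reports the spread of the fitted slope (median,
range, high/low ratio) as a stability measure, and the expected fractional
error of an SD estimated from R replicates, 1/sqrt(2(R-1)) (the large-n
normal approximation), as design guidance for choosing R.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _batch
from .datamodel import ALGORITHMS, AssayErrorEquation, Dataset
from .errors import DegenerateDesignError, IntegrityError, UsageError
from .profiles import PrecisionProfile, profile_from_dataset
from .regression import fit_algorithm, predict_sd

__all__ = [
    "FitEvaluation",
    "CombinationSummary",
    "AlgorithmReport",
    "RankingReport",
    "nssr",
    "evaluate_fit",
    "binomial_combinations",
    "fractional_sd_error",
    "combinatorial_analysis",
    "rank_algorithms",
]


def nssr(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Sum of squared residuals normalized to the predicted SDs.

    Returns ``inf`` when any predicted SD is <= 0: such an equation
    cannot provide 1/SD^2 weights and must not look artificially good by
    having the offending points dropped.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 1:
        raise UsageError(
            f"observed and predicted must be equal-length 1-d sequences, "
            f"got shapes {obs.shape} and {pred.shape}"
        )
    if np.any(pred <= 0):
        return float("inf")
    return float(np.sum((obs - pred) ** 2 / pred ** 2))


@dataclass
class FitEvaluation:
    """NSSR, residuals and sign diagnostics of one AEE on one profile."""

    nssr: float
    predicted: np.ndarray
    residuals: np.ndarray
    negative_prediction_flag: bool
    negative_intercept_flag: bool

    @property
    def valid(self) -> bool:
        return not (self.negative_prediction_flag or self.negative_intercept_flag)


def evaluate_fit(profile: PrecisionProfile, aee: AssayErrorEquation) -> FitEvaluation:
    """Score an equation against a profile (prediction at each profile x)."""
    pred = predict_sd(aee, profile.x)
    return FitEvaluation(
        nssr=nssr(profile.sd, pred),
        predicted=pred,
        residuals=profile.sd - pred,
        negative_prediction_flag=bool(np.any(pred < 0)),
        negative_intercept_flag=aee.c0 < 0,
    )


def binomial_combinations(n: int, r: int) -> int:
    """Exact C(n, r) — the number of size-r specimen subsets."""
    if r < 0 or n < 0 or r > n:
        raise UsageError(f"need 0 <= r <= n, got n={n}, r={r}")
    return math.comb(n, r)


def fractional_sd_error(r: int) -> float:
    """Expected fractional error of an SD estimated from r replicates.

    The large-sample approximation sigma_S/sigma ~= 1/sqrt(2(r-1)):
    about 32% at r = 6 and 16% at r = 20, which quantifies why profiles
    from small replicate sets scatter so much.
    """
    if r < 2:
        raise UsageError(f"need r >= 2, got {r}")
    return 1.0 / math.sqrt(2.0 * (r - 1))


@dataclass
class CombinationSummary:
    """Distribution of AEE coefficients over size-R specimen subsets."""

    algorithm: str
    N: int
    R: int
    n_combinations: int          # C(N, R)
    n_evaluated: int             # subsets actually fitted
    exhaustive: bool
    slope_median: float
    slope_min: float
    slope_max: float
    high_low_ratio: float        # NaN when slope_min <= 0 (ND in reports)
    intercept_median: float
    intercept_min: float
    intercept_max: float
    nni_pct: float
    expected_sd_fraction_error: float
    slopes: np.ndarray = field(repr=False, default=None)
    intercepts: np.ndarray = field(repr=False, default=None)

    def to_row(self) -> dict:
        """One report row mirroring the median (range) / high-low / NNI layout."""
        hl = "ND" if math.isnan(self.high_low_ratio) else f"{self.high_low_ratio:.3g}"
        return {
            "algorithm": self.algorithm,
            "N": self.N,
            "R": self.R,
            "n_combinations": self.n_combinations,
            "n_evaluated": self.n_evaluated,
            "slope_median_range": (
                f"{self.slope_median:.4g} "
                f"({self.slope_min:.4g}–{self.slope_max:.4g})"
            ),
            "high_low": hl,
            "intercept_median_range": (
                f"{self.intercept_median:.4g} "
                f"({self.intercept_min:.4g}–{self.intercept_max:.4g})"
            ),
            "nni_pct": round(self.nni_pct, 2),
            "expected_sd_fraction_error": round(
                self.expected_sd_fraction_error, 4
            ),
        }


def _level_matrix(dataset: Dataset, x_convention: str):
    """Pivot to (levels x specimens) value matrix; x value per level row."""
    df = dataset.to_frame()
    wide = df.pivot_table(
        index=["experiment_id", "level_id"], columns="specimen_id",
        values="measured_conc", aggfunc="first",
    )
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any(axis=0)].tolist()
        raise IntegrityError(
            f"specimen(s) {missing} are absent from some level; the "
            f"combinatorial analysis needs every specimen at every level"
        )
    if x_convention == "nominal":
        xmap = df.groupby(["experiment_id", "level_id"])["nominal_conc"].first()
    else:
        xmap = df.groupby(["experiment_id", "level_id"])["measured_conc"].mean()
    x = xmap.loc[wide.index].to_numpy(dtype=float)
    return wide.to_numpy(dtype=float), x, list(wide.columns)


_BATCH_SOLVERS = {
    "ols_linear": lambda x, Y: _batch.batch_ols_poly(x, Y, 1),
    "ols_poly2": lambda x, Y: _batch.batch_ols_poly(x, Y, 2),
    "ols_poly3": lambda x, Y: _batch.batch_ols_poly(x, Y, 3),
    "wls_inv_x2": lambda x, Y: _batch.batch_wls_inv_x2(x, Y),
    "theil": _batch.batch_theil,
    "theil_siegel": _batch.batch_siegel,
}

_MIN_POINTS = {"ols_linear": 3, "ols_poly2": 4, "ols_poly3": 5,
               "wls_inv_x2": 3, "theil": 3, "theil_siegel": 3}


def combinatorial_analysis(
    dataset: Dataset,
    r: int,
    algorithm: str = "theil_siegel",
    max_enumerate: int | None = None,
    seed: int | None = None,
    x_convention: str = "nominal",
) -> CombinationSummary:
    """Refit one algorithm on every (or a sample of) size-r specimen subsets.

    All C(N, r) subsets are enumerated when their count does not exceed
    ``max_enumerate`` (or ``max_enumerate`` is None); otherwise a seeded
    uniform sample of ``max_enumerate`` subsets is drawn and the summary
    records that it is not exhaustive.  Within each subset the per-level
    SDs form a resampled precision profile which is fitted by the chosen
    algorithm; the distribution of the resulting coefficients measures
    how stable the equation is to the choice of specimens.
    """
    if algorithm not in ALGORITHMS:
        raise UsageError(f"unknown algorithm {algorithm!r}")
    values, x, specimens = _level_matrix(dataset, x_convention)
    n = len(specimens)
    if not 3 <= r < n:
        raise UsageError(f"need 3 <= r < N={n}, got r={r}")

    # merge level cells that share an x value (pooled variance), and sort
    order = np.argsort(x, kind="stable")
    values, x = values[order], x[order]
    ux, inverse = np.unique(x, return_inverse=True)
    m = len(ux)
    if m < _MIN_POINTS[algorithm]:
        raise DegenerateDesignError(
            f"{algorithm} needs {_MIN_POINTS[algorithm]} profile points, "
            f"profile has {m}"
        )

    total = math.comb(n, r)
    if max_enumerate is None or total <= max_enumerate:
        subsets = np.fromiter(
            (i for comb in combinations(range(n), r) for i in comb),
            dtype=np.intp, count=total * r,
        ).reshape(total, r)
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        subsets = np.empty((max_enumerate, r), dtype=np.intp)
        for k in range(max_enumerate):
            subsets[k] = rng.choice(n, size=r, replace=False)
        exhaustive = False
    n_eval = subsets.shape[0]

    # per-profile-point SD for every subset: (n_eval, m)
    var = np.empty((len(x), n_eval))
    for li in range(len(x)):
        var[li] = np.var(values[li][subsets], axis=1, ddof=1)
    if m < len(x):  # pool equal-x cells: df-weighted mean variance (equal n)
        pooled = np.zeros((m, n_eval))
        counts = np.zeros(m)
        for li, ui in enumerate(inverse):
            pooled[ui] += var[li]
            counts[ui] += 1
        var = pooled / counts[:, None]
    Y = np.sqrt(var).T

    coef = _BATCH_SOLVERS[algorithm](ux, Y)
    intercepts, slopes = coef[:, 0], coef[:, 1]

    smin, smax = float(slopes.min()), float(slopes.max())
    return CombinationSummary(
        algorithm=algorithm,
        N=n,
        R=r,
        n_combinations=total,
        n_evaluated=int(n_eval),
        exhaustive=exhaustive,
        slope_median=float(np.median(slopes)),
        slope_min=smin,
        slope_max=smax,
        high_low_ratio=(smax / smin) if smin > 0 else float("nan"),
        intercept_median=float(np.median(intercepts)),
        intercept_min=float(intercepts.min()),
        intercept_max=float(intercepts.max()),
        nni_pct=100.0 * float(np.mean(intercepts >= 0)),
        expected_sd_fraction_error=fractional_sd_error(r),
        slopes=slopes,
        intercepts=intercepts,
    )


@dataclass
class AlgorithmReport:
    """Full-profile fit plus subset-stability screen for one algorithm."""

    algorithm: str
    aee: AssayErrorEquation | None
    nssr: float
    nni_by_r: dict[int, float]
    admissible: bool
    notes: list[str] = field(default_factory=list)


@dataclass
class RankingReport:
    """Ordered algorithm comparison; ``recommended`` heads the ranking."""

    reports: list[AlgorithmReport]
    nni_threshold: float

    @property
    def recommended(self) -> str | None:
        for rep in self.reports:
            if rep.admissible:
                return rep.algorithm
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "algorithm": r.algorithm,
                "equation": r.aee.as_string() if r.aee else "",
                "nssr": r.nssr,
                **{f"nni_pct_r{k}": v for k, v in r.nni_by_r.items()},
                "admissible": r.admissible,
                "notes": "; ".join(r.notes),
            }
            for r in self.reports
        ])


def rank_algorithms(
    dataset: Dataset,
    algorithms: Iterable[str] = ALGORITHMS,
    r_values: Iterable[int] = (6, 20),
    nni_threshold: float = 99.5,
    max_enumerate: int | None = None,
    seed: int | None = None,
    x_convention: str = "nominal",
) -> RankingReport:
    """Rank algorithms by the two-step admissibility rule.

    Step 1 screens on the subset-stability NNI%: an algorithm is
    admissible only if, at every requested subset size, at least
    ``nni_threshold`` percent of subsets give a non-negative intercept
    (an SD cannot be negative, and the blank SD is the intercept).
    Step 2 orders admissible algorithms by ascending full-profile NSSR.
    Inadmissible algorithms follow, ordered by their worst NNI%.
    """
    profile = profile_from_dataset(dataset, x_convention)
    reports: list[AlgorithmReport] = []
    for alg in algorithms:
        notes: list[str] = []
        try:
            fit = fit_algorithm(profile, alg)
        except DegenerateDesignError as exc:
            reports.append(AlgorithmReport(alg, None, float("inf"), {},
                                           False, [str(exc)]))
            continue
        notes.extend(fit.notes)
        evaluation = evaluate_fit(profile, fit.aee)
        nni_by_r: dict[int, float] = {}
        for r in r_values:
            summary = combinatorial_analysis(
                dataset, r, alg, max_enumerate=max_enumerate, seed=seed,
                x_convention=x_convention,
            )
            nni_by_r[r] = summary.nni_pct
        admissible = (
            bool(nni_by_r)
            and min(nni_by_r.values()) >= nni_threshold
            and not evaluation.negative_intercept_flag
        )
        reports.append(AlgorithmReport(alg, fit.aee, evaluation.nssr,
                                       nni_by_r, admissible, notes))
    reports.sort(key=lambda rep: (
        not rep.admissible,
        rep.nssr if rep.admissible else -min(rep.nni_by_r.values(), default=0.0),
    ))
    return RankingReport(reports, nni_threshold)
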