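"""Per-level summaries and precision profiles.

A precision profile is the ordered series of (concentration, SD, n)
points obtained from replicate measurements at each spiking level, from
the blank up to the top of the assayed range.  It is the input to every
assay-error-equation regression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import Dataset
from .errors import IntegrityError, UsageError

__all__ = [
    "LevelSummary",
    "PrecisionProfile",
    "summarize_levels",
    "build_profile",
    "subset_profile",
    "profile_from_dataset",
]


@dataclass(frozen=True)
class LevelSummary:
    """Accuracy and precision of one (experiment, spiking level) cell.

    ``cv_pct`` is 100*sd/mean_measured (undefined, stored as NaN, when the
    mean is 0) and ``accuracy_pct`` is 100*mean_measured/nominal (undefined
    at the blank).  The sample SD uses the n-1 denominator.
    """

    experiment_id: str
    level_id: str
    nominal_conc: float
    n: int
    mean_measured: float
    sd: float

    @property
    def cv_pct(self) -> float:
        if self.mean_measured == 0:
            return float("nan")
        return 100.0 * self.sd / self.mean_measured

    @property
    def accuracy_pct(self) -> float:
        if self.nominal_conc == 0:
            return float("nan")
        return 100.0 * self.mean_measured / self.nominal_conc


@dataclass(frozen=True)
class PrecisionProfile:
    """Ordered (concentration, SD, n) points; the regression input.

    ``x_convention`` records whether the concentration axis holds the
    nominal (spiked) or the mean measured concentration.
    """

    concentrations: tuple[float, ...]
    sds: tuple[float, ...]
    ns: tuple[int, ...]
    x_convention: str = "nominal"

    def __post_init__(self) -> None:
        if not (len(self.concentrations) == len(self.sds) == len(self.ns)):
            raise UsageError("profile arrays must have equal length")
        x = np.asarray(self.concentrations)
        if len(x) >= 2 and not np.all(np.diff(x) > 0):
            raise UsageError("profile concentrations must be strictly increasing")
        if any(s < 0 for s in self.sds):
            raise UsageError("profile SDs must be >= 0")

    @property
    def M(self) -> int:
        """Number of profile points."""
        return len(self.concentrations)

    @property
    def x(self) -> np.ndarray:
        return np.asarray(self.concentrations, dtype=float)

    @property
    def sd(self) -> np.ndarray:
        return np.asarray(self.sds, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "concentration": self.concentrations,
            "sd": self.sds,
            "n": self.ns,
        })


def summarize_levels(
    dataset: Dataset,
    specimen_subset: set[str] | Iterable[str] | None = None,
) -> list[LevelSummary]:
    """Per (experiment, level) n, mean, sample SD (n-1), CV% and accuracy%.

    ``specimen_subset`` restricts the computation to the named specimens,
    which is how the combinatorial subset analysis resamples profiles.

    Raises
    ------
    IntegrityError
        If subsetting leaves any level with fewer than two specimens.
    """
    df = dataset.to_frame()
    if specimen_subset is not None:
        subset = set(specimen_subset)
        missing = subset - set(df["specimen_id"])
        if missing:
            raise IntegrityError(f"unknown specimen id(s): {sorted(missing)}")
        df = df[df["specimen_id"].isin(subset)]
    out: list[LevelSummary] = []
    for (exp, lev), grp in df.groupby(["experiment_id", "level_id"], sort=True):
        vals = grp["measured_conc"].to_numpy(dtype=float)
        if len(vals) < 2:
            raise IntegrityError(
                f"level {lev!r} in experiment {exp!r} has {len(vals)} "
                f"specimen(s) after subsetting; need >= 2"
            )
        out.append(LevelSummary(
            experiment_id=exp,
            level_id=lev,
            nominal_conc=float(grp["nominal_conc"].iloc[0]),
            n=int(len(vals)),
            mean_measured=float(np.mean(vals)),
            sd=float(np.std(vals, ddof=1)),
        ))
    out.sort(key=lambda s: (s.nominal_conc, s.experiment_id, s.level_id))
    return out


def summaries_to_frame(summaries: Sequence[LevelSummary]) -> pd.DataFrame:
    """Tabulate summaries with the conventional validation-report columns."""
    return pd.DataFrame({
        "experiment_id": [s.experiment_id for s in summaries],
        "level_id": [s.level_id for s in summaries],
        "nominal_conc": [s.nominal_conc for s in summaries],
        "n": [s.n for s in summaries],
        "mean_measured": [s.mean_measured for s in summaries],
        "sd": [s.sd for s in summaries],
        "accuracy_pct": [s.accuracy_pct for s in summaries],
        "cv_pct": [s.cv_pct for s in summaries],
    })


def build_profile(
    summaries: Sequence[LevelSummary],
    x_convention: str = "nominal",
) -> PrecisionProfile:
    """Assemble level summaries into a precision profile.

    Levels from different experiments stay distinct profile points unless
    their concentration coincides exactly, in which case they are pooled:
    the pooled variance is the df-weighted mean of the variances
    (sum((n_i-1) sd_i^2) / sum(n_i-1)) and the ns add.  The blank (0) is an
    ordinary point, so the fitted intercept estimates the blank SD.
    """
    if x_convention not in ("nominal", "mean_measured"):
        raise UsageError(f"unknown x_convention {x_convention!r}")
    if len(summaries) < 3:
        raise UsageError("a profile needs at least 3 level summaries")
    keyed: dict[float, list[LevelSummary]] = {}
    for s in summaries:
        xval = s.nominal_conc if x_convention == "nominal" else s.mean_measured
        keyed.setdefault(float(xval), []).append(s)
    xs, sds, ns = [], [], []
    for xval in sorted(keyed):
        group = keyed[xval]
        if len(group) == 1:
            s = group[0]
            xs.append(xval); sds.append(s.sd); ns.append(s.n)
        else:
            warnings.warn(
                f"{len(group)} levels share x = {xval}; pooling their variances",
                stacklevel=2,
            )
            dfs = np.array([s.n - 1 for s in group], dtype=float)
            var = np.array([s.sd ** 2 for s in group])
            xs.append(xval)
            sds.append(float(math.sqrt(np.sum(dfs * var) / np.sum(dfs))))
            ns.append(int(sum(s.n for s in group)))
    return PrecisionProfile(tuple(xs), tuple(sds), tuple(ns), x_convention)


def subset_profile(
    dataset: Dataset,
    specimen_ids: set[str] | Iterable[str],
    x_convention: str = "nominal",
) -> PrecisionProfile:
    """Profile computed from only the named specimens (at every level).

    This is the elementary operation of the combinatorial stability
    analysis: each size-R subset of the N specimens yields one profile and
    hence one fitted equation.
    """
    ids = set(specimen_ids)
    df = dataset.to_frame()
    per_level = df.groupby(["experiment_id", "level_id"])["specimen_id"].agg(set)
    for (exp, lev), present in per_level.items():
        absent = ids - present
        if absent:
            raise IntegrityError(
                f"specimen(s) {sorted(absent)} absent from level {lev!r} "
                f"in experiment {exp!r}"
            )
    return build_profile(summarize_levels(dataset, ids), x_convention)


def profile_from_dataset(
    dataset: Dataset, x_convention: str = "nominal"
) -> PrecisionProfile:
    """Shorthand: summarize all specimens and build the profile."""
    return build_profile(summarize_levels(dataset), x_convention)
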