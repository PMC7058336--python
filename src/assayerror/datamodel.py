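"""Domain types and delimited-text I/O for assay validation measurements.

A validation campaign is a table of single measurements: an independent
serum *specimen*, spiked to a *nominal* concentration at a given *spiking
level* within an *experiment*, is assayed once and yields a *measured*
concentration.  Specimens additionally carry an interference class
(normal / hemolytic / icteric / lipemic serum).

The on-disk representation is plain delimited text (comma or tab), one row
per measurement, so the package can consume spreadsheets exported from any
LIMS or instrument software once concentrations have been back-calculated.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, IntegrityError

__all__ = [
    "INTERFERENCE_CLASSES",
    "ALGORITHMS",
    "Measurement",
    "Dataset",
    "AssayErrorEquation",
    "IntegrityWarning",
    "read_measurements",
    "write_measurements",
    "write_aee",
    "read_aee",
]

#: Recognised serum interference classes (LIH-index categories plus normal).
INTERFERENCE_CLASSES = ("normal", "hemolytic", "icteric", "lipemic")

#: The six regression algorithm tags, in the conventional (a)-(f) order.
ALGORITHMS = (
    "ols_linear",
    "ols_poly2",
    "ols_poly3",
    "wls_inv_x2",
    "theil",
    "theil_siegel",
)

#: Default column names of the measurement table.
DEFAULT_COLUMNS = (
    "specimen_id",
    "experiment_id",
    "level_id",
    "nominal_conc",
    "measured_conc",
    "interference",
)


class IntegrityWarning(UserWarning):
    """A dataset is usable but violates a soft invariant (e.g. n < 2)."""


@dataclass(frozen=True)
class Measurement:
    """One assay result: a specimen assayed at one spiking level."""

    specimen_id: str
    experiment_id: str
    level_id: str
    nominal_conc: float
    measured_conc: float
    interference: str = "normal"

    def __post_init__(self) -> None:
        if self.nominal_conc < 0:
            raise IntegrityError(
                f"nominal_conc must be >= 0, got {self.nominal_conc!r}"
            )
        if self.interference not in INTERFERENCE_CLASSES:
            raise IntegrityError(
                f"unknown interference class {self.interference!r}; "
                f"expected one of {INTERFERENCE_CLASSES}"
            )


@dataclass
class Dataset:
    """A validated collection of measurements for one analyte.

    Parameters
    ----------
    measurements:
        The individual assay results.
    analyte:
        Free-text analyte label (e.g. ``"carbamazepine"``).
    units:
        Concentration units; everything downstream is unit-agnostic but the
        label is carried through reports.

    Invariants enforced at construction: the (specimen, experiment, level)
    triple is unique; within an experiment each level maps to exactly one
    nominal concentration; each (experiment, level) cell should contain at
    least two specimens (an SD needs n >= 2) — violations raise an
    :class:`IntegrityWarning` or, with ``strict=True``, an error.
    """

    measurements: list[Measurement]
    analyte: str = "analyte"
    units: str = "µg/mL"
    strict: bool = False

    def __post_init__(self) -> None:
        self.measurements = [
            m if isinstance(m, Measurement) else Measurement(**m)
            for m in self.measurements
        ]
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants; idempotent."""
        seen: set[tuple[str, str, str]] = set()
        level_conc: dict[tuple[str, str], float] = {}
        counts: dict[tuple[str, str], int] = {}
        negatives = 0
        for m in self.measurements:
            key = (m.specimen_id, m.experiment_id, m.level_id)
            if key in seen:
                raise IntegrityError(
                    f"duplicate measurement for specimen={m.specimen_id!r} "
                    f"experiment={m.experiment_id!r} level={m.level_id!r}"
                )
            seen.add(key)
            lk = (m.experiment_id, m.level_id)
            if lk in level_conc and level_conc[lk] != m.nominal_conc:
                raise IntegrityError(
                    f"level {m.level_id!r} in experiment {m.experiment_id!r} "
                    f"maps to conflicting nominal concentrations "
                    f"{level_conc[lk]} and {m.nominal_conc}"
                )
            level_conc[lk] = m.nominal_conc
            counts[lk] = counts.get(lk, 0) + 1
            if m.measured_conc < 0:
                negatives += 1
        for (exp, lev), n in sorted(counts.items()):
            if n < 2:
                msg = (
                    f"level {lev!r} in experiment {exp!r} has only {n} "
                    f"specimen(s); an SD needs n >= 2"
                )
                if self.strict:
                    raise IntegrityError(msg)
                warnings.warn(msg, IntegrityWarning, stacklevel=2)
        self.n_negative_measured = negatives

    # -- convenience views ---------------------------------------------
    def __len__(self) -> int:
        return len(self.measurements)

    def to_frame(self) -> pd.DataFrame:
        """Return the measurements as a tidy DataFrame (one row each)."""
        return pd.DataFrame([dataclasses.asdict(m) for m in self.measurements])

    @property
    def specimen_ids(self) -> list[str]:
        return sorted({m.specimen_id for m in self.measurements})

    @property
    def experiment_ids(self) -> list[str]:
        return sorted({m.experiment_id for m in self.measurements})

    def equals(self, other: "Dataset", rel_tol: float = 1e-9) -> bool:
        """Field-wise equality with a relative tolerance on concentrations."""
        if len(self) != len(other):
            return False
        key = lambda m: (m.experiment_id, m.level_id, m.specimen_id)
        for a, b in zip(sorted(self.measurements, key=key),
                        sorted(other.measurements, key=key)):
            if (a.specimen_id, a.experiment_id, a.level_id, a.interference) != (
                b.specimen_id, b.experiment_id, b.level_id, b.interference
            ):
                return False
            for x, y in ((a.nominal_conc, b.nominal_conc),
                         (a.measured_conc, b.measured_conc)):
                if not math.isclose(x, y, rel_tol=rel_tol, abs_tol=1e-12):
                    return False
        return True


@dataclass(frozen=True)
class AssayErrorEquation:
    """SD(C) = c0 + c1*C + c2*C**2 + c3*C**3.

    ``c0`` is the SD at zero concentration (the blank SD); ``c1`` is the
    dimensionless slope of the linear error pattern.  Linear algorithms set
    ``c2 = c3 = 0``; the quadratic sets ``c3 = 0``.  The inverse square of
    the predicted SD is the weight a pharmacokinetic fit assigns to an
    observation at concentration C.
    """

    algorithm: str
    c0: float
    c1: float
    c2: float = 0.0
    c3: float = 0.0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )
        if self.algorithm in ("ols_linear", "wls_inv_x2", "theil", "theil_siegel"):
            if self.c2 != 0.0 or self.c3 != 0.0:
                raise ConfigurationError(
                    f"{self.algorithm} is linear: c2 and c3 must be 0"
                )
        elif self.algorithm == "ols_poly2" and self.c3 != 0.0:
            raise ConfigurationError("ols_poly2 is quadratic: c3 must be 0")

    @property
    def coefficients(self) -> tuple[float, float, float, float]:
        return (self.c0, self.c1, self.c2, self.c3)

    def __call__(self, conc: float) -> float:
        """Evaluate SD at a concentration (Horner form, unclamped)."""
        c = conc
        return self.c0 + c * (self.c1 + c * (self.c2 + c * self.c3))

    def as_string(self) -> str:
        """Human-readable ``y = c0 + c1x [+ c2x^2 + c3x^3]`` rendering."""
        parts = [f"{self.c0:g}"]
        for coef, power in ((self.c1, "x"), (self.c2, "x^2"), (self.c3, "x^3")):
            if coef != 0.0 or power == "x":
                sign = "-" if coef < 0 else "+"
                parts.append(f"{sign} {abs(coef):g}{power}")
        return "y = " + " ".join(parts)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_measurements(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    analyte: str = "analyte",
    units: str = "µg/mL",
    strict: bool = False,
) -> Dataset:
    """Read a delimited measurement table into a validated :class:`Dataset`.

    Parameters
    ----------
    path:
        CSV or TSV file; the delimiter is auto-detected from the header.
    dialect:
        Optional mapping from canonical column names
        (``specimen_id`` ... ``interference``) to the file's column names.
        A missing ``interference`` column defaults every row to ``normal``.
    strict:
        Escalate integrity warnings (n < 2 at a level) to errors.

    Raises
    ------
    ConfigurationError
        If a mapped column is absent from the file.
    IntegrityError
        On duplicate (specimen, experiment, level) rows or conflicting
        nominal concentrations; rows whose concentrations fail to parse are
        rejected with their row numbers reported.
    """
    path = Path(path)
    mapping = {c: c for c in DEFAULT_COLUMNS}
    if dialect:
        mapping.update(dialect)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str,
                     skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]

    required = [mapping[c] for c in DEFAULT_COLUMNS if c != "interference"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path.name}: missing required column(s) {missing}; "
            f"present: {list(df.columns)}"
        )

    bad_rows: list[int] = []
    records = []
    has_interf = mapping["interference"] in df.columns
    for idx, row in df.iterrows():
        try:
            nominal = float(row[mapping["nominal_conc"]])
            measured = float(row[mapping["measured_conc"]])
        except (TypeError, ValueError):
            bad_rows.append(int(idx) + 2)  # 1-based, counting the header
            continue
        records.append(
            Measurement(
                specimen_id=str(row[mapping["specimen_id"]]).strip(),
                experiment_id=str(row[mapping["experiment_id"]]).strip(),
                level_id=str(row[mapping["level_id"]]).strip(),
                nominal_conc=nominal,
                measured_conc=measured,
                interference=(
                    str(row[mapping["interference"]]).strip()
                    if has_interf else "normal"
                ),
            )
        )
    if bad_rows:
        raise IntegrityError(
            f"{path.name}: non-numeric concentration in file row(s) {bad_rows}"
        )
    return Dataset(records, analyte=analyte, units=units, strict=strict)


def write_measurements(dataset: Dataset, path: str | Path, sep: str = ",") -> Path:
    """Write a dataset as delimited text re-readable by :func:`read_measurements`.

    Concentrations are rendered with ``repr`` round-trip precision (up to
    17 significant digits), so write-then-read restores values exactly.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(DEFAULT_COLUMNS) + "\n")
        for m in dataset.measurements:
            fh.write(sep.join([
                m.specimen_id, m.experiment_id, m.level_id,
                repr(m.nominal_conc), repr(m.measured_conc),
                m.interference,
            ]) + "\n")
    return path


def write_aee(
    aee: AssayErrorEquation,
    path: str | Path,
    format: str = "json",
) -> Path:
    """Serialize an assay error equation.

    ``format="json"`` stores the algorithm tag and all four coefficients.
    ``format="error_poly_line"`` emits one whitespace-separated line
    ``C0 C1 C2 C3`` — the error-polynomial convention pharmacometric
    software (e.g. Pmetrics-style tools) reads for 1/SD² weighting —
    with zeros written explicitly.
    """
    path = Path(path)
    if format == "json":
        payload = {"algorithm": aee.algorithm,
                   "c0": aee.c0, "c1": aee.c1, "c2": aee.c2, "c3": aee.c3}
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    elif format == "error_poly_line":
        path.write_text(
            " ".join(f"{c:g}" for c in aee.coefficients) + "\n",
            encoding="utf-8",
        )
    else:
        raise ConfigurationError(
            f"unknown AEE format {format!r}; expected 'json' or 'error_poly_line'"
        )
    return path


def read_aee(path: str | Path) -> AssayErrorEquation:
    """Read back an equation written by :func:`write_aee` in JSON format."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return AssayErrorEquation(**payload)
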