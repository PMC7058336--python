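"""Synthetic validation campaigns with a linear error pattern.

LC-MS/MS drug assays in serum typically show a standard deviation that
grows linearly with concentration, ``SD(C) = c0 + c1*C`` — the blank is
measured with a small constant SD ``c0`` and the relative error approaches
the constant ``c1`` at high levels.  The generator draws one measurement
per specimen per spiking level,

    measured = C * accuracy_bias + eps,
    eps ~ Normal(0, (c0 + c1*C) * m_s * o_C),

where ``m_s`` is an SD multiplier attached to the specimen's serum
interference class (constant across levels, emulating lipemic / icteric /
hemolytic matrix effects) and ``o_C`` inflates a chosen fraction of levels
to emulate outlier SDs in a precision profile.  Measured values are not
truncated at zero: blank-level back-calculated concentrations scatter
around zero and the blank SD must be estimable from them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .datamodel import Dataset, Measurement, INTERFERENCE_CLASSES
from .errors import ConfigurationError

__all__ = ["SyntheticConfig", "generate_campaign", "default_levels"]

#: Spiking ladders mirroring a real three-experiment carbamazepine-type
#: campaign: 4, 6 and 10 levels spanning ~4 orders of magnitude, merged
#: (plus one blank) into the final 20-level profile.
LADDER_4 = (3.02, 15.1, 60.3, 181.0)
LADDER_6 = (0.209, 0.419, 2.09, 8.38, 16.8, 33.5)
LADDER_10 = (0.0122, 0.0243, 0.0486, 0.0972, 0.243, 0.810, 2.43, 4.21, 12.2, 24.3)


def default_levels(m: int = 20, include_blank: bool = True) -> list[float]:
    """A realistic spiking ladder with ``m`` positive levels.

    ``m = 20`` returns the merged three-experiment ladder; ``m = 4``, ``6``
    and ``10`` return the single-experiment ladders.  Other values return a
    log-spaced ladder across the same range.
    """
    if m == 20:
        levels = sorted(LADDER_4 + LADDER_6 + LADDER_10)
    elif m == 4:
        levels = list(LADDER_4)
    elif m == 6:
        levels = list(LADDER_6)
    elif m == 10:
        levels = list(LADDER_10)
    else:
        levels = list(np.geomspace(0.0122, 181.0, m))
    return ([0.0] if include_blank else []) + list(levels)


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic validation campaign.

    Defaults reproduce the structure of a final merged campaign: 20
    spiking levels plus blank, 24 independent specimens per level, and a
    linear error law SD(C) = 0.002 + 0.05*C (blank SD of 0.002 µg/mL and a
    5% proportional error, typical of a well-behaved serum LC-MS/MS assay).
    """

    true_c0: float = 0.002
    true_c1: float = 0.05
    levels: Sequence[float] = field(default_factory=default_levels)
    replicates_per_level: int = 24
    accuracy_bias: float | Sequence[float] = 1.0
    interference_mix: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"normal": (1.0, 1.0)}
    )
    outlier_fraction: float = 0.0
    outlier_multiplier: float = 10.0
    seed: int = 0
    analyte: str = "synthetic"
    experiment_id: str = "E1"

    def __post_init__(self) -> None:
        if self.true_c0 < 0 or self.true_c1 < 0:
            raise ConfigurationError("true_c0 and true_c1 must be >= 0")
        if self.true_c0 == 0 and self.true_c1 == 0:
            raise ConfigurationError("true_c0 and true_c1 cannot both be 0")
        if len(self.levels) == 0:
            raise ConfigurationError("levels must be non-empty")
        if any(c < 0 for c in self.levels):
            raise ConfigurationError("levels must be >= 0")
        if len(set(self.levels)) != len(self.levels):
            raise ConfigurationError("levels must be distinct")
        if self.replicates_per_level < 2:
            raise ConfigurationError("replicates_per_level must be >= 2")
        for cls, (frac, mult) in self.interference_mix.items():
            if cls not in INTERFERENCE_CLASSES:
                raise ConfigurationError(f"unknown interference class {cls!r}")
            if frac < 0 or mult < 1.0:
                raise ConfigurationError(
                    "interference fractions must be >= 0 and multipliers >= 1"
                )
        total = sum(f for f, _ in self.interference_mix.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ConfigurationError(
                f"interference fractions must sum to 1, got {total}"
            )
        if not 0.0 <= self.outlier_fraction < 0.5:
            raise ConfigurationError("outlier_fraction must be in [0, 0.5)")
        if self.outlier_multiplier < 1.0:
            raise ConfigurationError("outlier_multiplier must be >= 1")
        bias = self.accuracy_bias
        if not np.isscalar(bias) and len(bias) != len(self.levels):
            raise ConfigurationError(
                "per-level accuracy_bias must match the number of levels"
            )

    def sd_at(self, conc: float) -> float:
        """The generating error law SD(C) = c0 + c1*C."""
        return self.true_c0 + self.true_c1 * conc

    # -- JSON round trip ------------------------------------------------
    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "true_c0": self.true_c0,
            "true_c1": self.true_c1,
            "levels": list(self.levels),
            "replicates_per_level": self.replicates_per_level,
            "accuracy_bias": (
                self.accuracy_bias if np.isscalar(self.accuracy_bias)
                else list(self.accuracy_bias)
            ),
            "interference_mix": {
                k: list(v) for k, v in self.interference_mix.items()
            },
            "outlier_fraction": self.outlier_fraction,
            "outlier_multiplier": self.outlier_multiplier,
            "seed": self.seed,
            "analyte": self.analyte,
            "experiment_id": self.experiment_id,
        }
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticConfig":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        payload["interference_mix"] = {
            k: tuple(v) for k, v in payload.get(
                "interference_mix", {"normal": [1.0, 1.0]}
            ).items()
        }
        return cls(**payload)


def _assign_classes(mix: Mapping[str, tuple[float, float]], n: int) -> list[str]:
    """Deterministic largest-remainder allocation of specimens to classes."""
    classes = sorted(mix, key=INTERFERENCE_CLASSES.index)
    exact = {c: mix[c][0] * n for c in classes}
    counts = {c: int(math.floor(exact[c])) for c in classes}
    short = n - sum(counts.values())
    for c in sorted(classes, key=lambda c: exact[c] - counts[c], reverse=True):
        if short == 0:
            break
        counts[c] += 1
        short -= 1
    labels: list[str] = []
    for c in classes:
        labels.extend([c] * counts[c])
    return labels


def generate_campaign(config: SyntheticConfig) -> Dataset:
    """Draw one synthetic campaign; deterministic for a given config+seed."""
    rng = np.random.default_rng(config.seed)
    n = config.replicates_per_level
    levels = list(config.levels)
    m = len(levels)
    bias = (
        np.full(m, float(config.accuracy_bias))
        if np.isscalar(config.accuracy_bias)
        else np.asarray(config.accuracy_bias, dtype=float)
    )

    labels = _assign_classes(config.interference_mix, n)
    multipliers = np.array([config.interference_mix[c][1] for c in labels])

    n_outliers = int(math.floor(config.outlier_fraction * m))
    outlier_levels = set(
        rng.choice(m, size=n_outliers, replace=False).tolist()
    ) if n_outliers else set()

    width = len(str(n))
    lwidth = len(str(m))
    records: list[Measurement] = []
    for li, conc in enumerate(levels):
        sigma = config.sd_at(conc)
        o = config.outlier_multiplier if li in outlier_levels else 1.0
        eps = rng.normal(0.0, 1.0, size=n) * sigma * multipliers * o
        measured = conc * bias[li] + eps
        for si in range(n):
            records.append(Measurement(
                specimen_id=f"S{si + 1:0{width}d}",
                experiment_id=config.experiment_id,
                level_id=f"L{li:0{lwidth}d}",
                nominal_conc=conc,
                measured_conc=float(measured[si]),
                interference=labels[si],
            ))
    return Dataset(records, analyte=config.analyte)
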