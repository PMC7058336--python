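"""End-to-end workflow: measurements -> profile -> fits -> ranking -> export.

The pipeline mirrors how an assay error equation is established in
practice: summarize every (experiment, level) cell, merge the levels of
all experiments into one final precision profile, fit the requested
algorithms, score each fit by NSSR, probe coefficient stability over
specimen subsets, apply the NNI% screen, and export the winning equation
as an error-polynomial line for pharmacokinetic software.  Every output
is listed in a JSON manifest together with the configuration and seed, so
a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .datamodel import (
    ALGORITHMS,
    Dataset,
    read_measurements,
    write_aee,
)
from .errors import AssayErrorError, ConfigurationError, DegenerateDesignError
from .evaluation import combinatorial_analysis, evaluate_fit, rank_algorithms
from .profiles import (
    build_profile,
    summaries_to_frame,
    summarize_levels,
)
from .regression import fit_algorithm

log = logging.getLogger("assayerror")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input_path: str
    output_dir: str
    analyte: str = "analyte"
    x_convention: str = "nominal"
    algorithms: Sequence[str] = ALGORITHMS
    r_values: Sequence[int] = (6, 20)
    max_enumerate: int | None = 20000
    nni_threshold: float = 99.5
    seed: int = 0
    dialect: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.nni_threshold <= 100:
            raise ConfigurationError("nni_threshold must be in [0, 100]")
        if any(r < 3 for r in self.r_values):
            raise ConfigurationError("every r value must be >= 3")
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ConfigurationError(f"unknown algorithm(s): {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["algorithms"] = list(self.algorithms)
        d["r_values"] = list(self.r_values)
        return d


def run_pipeline(config: RunConfig, dataset: Dataset | None = None) -> dict:
    """Execute the workflow and return the manifest (also written to disk).

    ``dataset`` may be passed directly (e.g. a synthetic campaign); by
    default it is read from ``config.input_path``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "outputs": {}, "stages": []}

    def _record(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, **info})
        log.info("%s: %s", stage, info)

    try:
        if dataset is None:
            dataset = read_measurements(
                config.input_path, dialect=config.dialect,
                analyte=config.analyte,
            )
        _record("read", n_measurements=len(dataset),
                n_specimens=len(dataset.specimen_ids))

        summaries = summarize_levels(dataset)
        sfile = out / "level_summaries.csv"
        summaries_to_frame(summaries).to_csv(sfile, index=False)
        manifest["outputs"]["level_summaries"] = sfile.name
        _record("summarize", n_levels=len(summaries))

        profile = build_profile(summaries, config.x_convention)
        pfile = out / "precision_profile.csv"
        profile.to_frame().to_csv(pfile, index=False)
        manifest["outputs"]["precision_profile"] = pfile.name
        _record("profile", M=profile.M)

        fits: dict[str, dict] = {}
        for alg in config.algorithms:
            try:
                fit = fit_algorithm(profile, alg)
            except DegenerateDesignError as exc:
                fits[alg] = {"error": str(exc)}
                continue
            ev = evaluate_fit(profile, fit.aee)
            fits[alg] = {
                "equation": fit.aee.as_string(),
                "coefficients": list(fit.aee.coefficients),
                "nssr": ev.nssr,
                "negative_intercept": ev.negative_intercept_flag,
                "negative_prediction": ev.negative_prediction_flag,
                "notes": fit.notes,
            }
        ffile = out / "fits.json"
        ffile.write_text(json.dumps(fits, indent=2, default=str) + "\n")
        manifest["outputs"]["fits"] = ffile.name
        _record("fit", n_fitted=sum("error" not in f for f in fits.values()))

        n = len(dataset.specimen_ids)
        combo_rows = []
        for alg in config.algorithms:
            for r in config.r_values:
                if r >= n:
                    continue
                try:
                    summary = combinatorial_analysis(
                        dataset, r, alg,
                        max_enumerate=config.max_enumerate,
                        seed=config.seed,
                        x_convention=config.x_convention,
                    )
                except DegenerateDesignError:
                    continue
                combo_rows.append(summary.to_row())
        cfile = out / "combination_summaries.csv"
        if combo_rows:
            import pandas as pd
            pd.DataFrame(combo_rows).to_csv(cfile, index=False)
            manifest["outputs"]["combination_summaries"] = cfile.name
        _record("combinations", n_summaries=len(combo_rows))

        ranking = rank_algorithms(
            dataset, config.algorithms, [r for r in config.r_values if r < n],
            nni_threshold=config.nni_threshold,
            max_enumerate=config.max_enumerate,
            seed=config.seed,
            x_convention=config.x_convention,
        )
        rfile = out / "ranking.csv"
        ranking.to_frame().to_csv(rfile, index=False)
        manifest["outputs"]["ranking"] = rfile.name
        manifest["recommended_algorithm"] = ranking.recommended
        _record("rank", recommended=ranking.recommended)

        if ranking.recommended is not None:
            win = fit_algorithm(profile, ranking.recommended).aee
            efile = out / "assay_error_equation.txt"
            write_aee(win, efile, format="error_poly_line")
            write_aee(win, out / "assay_error_equation.json", format="json")
            manifest["outputs"]["error_polynomial"] = efile.name
            manifest["outputs"]["aee_json"] = "assay_error_equation.json"
        manifest["status"] = "ok"
    except AssayErrorError as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str) + "\n"
        )
        raise
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n"
    )
    return manifest
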