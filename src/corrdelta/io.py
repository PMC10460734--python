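"""CSV/JSON interchange: parameter tables, correlation matrices, samples,
trajectories and result reports.

Conventions: comma-separated, '.' decimal, UTF-8, header row required.
Unknown correlation entries are written as the literal token ``NA``.
Sample matrices round-trip at full double precision.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .deb import BodyTrajectory
from .delta import DeltaEstimate
from .distributions import (
    CorrelationTemplate,
    InputSampleMatrix,
    ParameterSpec,
)
from .two_stage import TwoStageReport
from .uncertainty import UncertaintySummary

__all__ = [
    "read_parameter_table",
    "write_parameter_table",
    "read_correlation_template",
    "write_correlation_template",
    "write_correlation_matrix",
    "read_samples",
    "write_samples",
    "read_trajectory",
    "write_delta_results",
    "write_report",
]

log = logging.getLogger("corrdelta")

NA_TOKEN = "NA"


def read_parameter_table(path) -> list[ParameterSpec]:
    """Read a parameter CSV: columns name, value, cv_percent[, family, units]."""
    df = pd.read_csv(path)
    required = {"name", "value", "cv_percent"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parameter table {path} lacks columns {sorted(missing)}")
    specs = []
    for row in df.itertuples(index=False):
        specs.append(
            ParameterSpec(
                name=str(row.name),
                typical_value=float(row.value),
                cv=float(row.cv_percent) / 100.0,
                family=str(getattr(row, "family", "lognormal")),
                units=str(getattr(row, "units", "")),
            )
        )
    return specs


def write_parameter_table(specs: list[ParameterSpec], path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "name": [s.name for s in specs],
            "value": [s.typical_value for s in specs],
            "cv_percent": [100.0 * s.cv for s in specs],
            "family": [s.family for s in specs],
            "units": [s.units for s in specs],
        }
    )
    df.to_csv(path, index=False)
    return path


def read_correlation_template(path) -> CorrelationTemplate:
    """Read a square correlation CSV (names in header and first column).

    Numeric cells are known correlations; the token ``NA`` (or an empty
    cell) marks an unknown entry to be estimated by completion.
    """
    df = pd.read_csv(path, index_col=0, na_values=[NA_TOKEN])
    names = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != names:
        raise ValueError("correlation CSV row and column names differ")
    return CorrelationTemplate(names=names, values=df.to_numpy(dtype=float))


def write_correlation_template(template: CorrelationTemplate, path) -> Path:
    return write_correlation_matrix(template.names, template.values, path)


def write_correlation_matrix(names, matrix, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(np.asarray(matrix, float), index=list(names),
                      columns=list(names))
    df.to_csv(path, na_rep=NA_TOKEN)
    return path


def read_samples(path) -> pd.DataFrame:
    # round_trip parsing: the default fast parser can be one ulp off
    df = pd.read_csv(path, float_precision="round_trip")
    if df.isna().any().any():
        raise ValueError(f"sample matrix {path} contains missing values")
    return df


def write_samples(samples, path) -> Path:
    path = Path(path)
    df = samples.data if isinstance(samples, InputSampleMatrix) else samples
    # repr-based float formatting keeps the round-trip lossless
    df.to_csv(path, index=False, float_format=None)
    return path


def read_trajectory(path) -> BodyTrajectory:
    """Read a trajectory CSV with columns time, degradation_rate."""
    df = pd.read_csv(path)
    missing = {"time", "degradation_rate"} - set(df.columns)
    if missing:
        raise ValueError(f"trajectory {path} lacks columns {sorted(missing)}")
    return BodyTrajectory(
        times=df["time"].to_numpy(float),
        degradation_rate=df["degradation_rate"].to_numpy(float),
    )


def _delta_frame(
    estimates: dict[str, DeltaEstimate] | list[DeltaEstimate],
    threshold: float,
) -> pd.DataFrame:
    if isinstance(estimates, dict):
        estimates = list(estimates.values())
    return pd.DataFrame(
        {
            "name": [e.name for e in estimates],
            "point": [e.point for e in estimates],
            "bootstrap_median": [e.bootstrap_median for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
            "significant": [e.significant for e in estimates],
            "zeroed_value": [e.zeroed_value for e in estimates],
            "threshold": threshold,
        }
    )


def write_delta_results(estimates, threshold: float, path) -> Path:
    path = Path(path)
    _delta_frame(estimates, threshold).to_csv(path, index=False)
    return path


def _step_metadata(step) -> dict:
    return {
        "threshold": step.threshold,
        "sample_seed": step.sample_seed,
        "noise_seed": step.noise_seed,
        "bootstrap_seed": step.bootstrap_seed,
        "dropped_rows": step.dropped_rows,
        "clipped_estimates": step.clipped,
        "noise": {
            "point": step.noise.point,
            "bootstrap_median": step.noise.bootstrap_median,
            "ci_low": step.noise.ci_low,
            "ci_high": step.noise.ci_high,
        },
    }


def write_report(report, directory) -> list[Path]:
    """Write a two-stage or uncertainty report with deterministic names.

    Two-stage reports produce ``delta_step1.csv``, ``delta_step2.csv``,
    ``report.json`` and ``run.log``; uncertainty summaries produce
    ``uncertainty.json``.  The JSON carries all seeds, thresholds, dropped
    row counts and warnings needed to audit or repeat the run.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    if isinstance(report, TwoStageReport):
        for label, step in (("step1", report.step1), ("step2", report.step2)):
            p = directory / f"delta_{label}.csv"
            write_delta_results(step.estimates, step.threshold, p)
            paths.append(p)
        meta = {
            "n": report.n,
            "partitions": report.partitions,
            "bootstrap": report.B,
            "seed": report.seed,
            "effect_classes": {
                k: v.value for k, v in report.effect_classes.items()
            },
            "step1": _step_metadata(report.step1),
            "step2": _step_metadata(report.step2),
            "warnings": report.warnings,
        }
        p = directory / "report.json"
        p.write_text(json.dumps(meta, indent=2, sort_keys=True))
        paths.append(p)
        logp = directory / "run.log"
        lines = [
            f"seed={report.seed} n={report.n} partitions={report.partitions} "
            f"B={report.B}",
            f"step1: sample_seed={report.step1.sample_seed} "
            f"noise_seed={report.step1.noise_seed} "
            f"bootstrap_seed={report.step1.bootstrap_seed} "
            f"threshold={report.step1.threshold!r}",
            f"step2: sample_seed={report.step2.sample_seed} "
            f"noise_seed={report.step2.noise_seed} "
            f"bootstrap_seed={report.step2.bootstrap_seed} "
            f"threshold={report.step2.threshold!r}",
            *(f"warning: {w}" for w in report.warnings),
        ]
        logp.write_text("\n".join(lines) + "\n")
        paths.append(logp)
    elif isinstance(report, UncertaintySummary):
        p = directory / "uncertainty.json"
        payload = {
            "output": report.output,
            "n_effective": report.n_effective,
            "mean": report.mean,
            "median": report.median,
            "ci_low": report.ci_low,
            "ci_high": report.ci_high,
            "level": report.level,
            "dropped_count": report.dropped_count,
            "seed": report.seed,
            "independent": report.independent,
        }
        p.write_text(json.dumps(payload, indent=2, sort_keys=True))
        paths.append(p)
    else:
        raise TypeError(f"cannot write report of type {type(report).__name__}")
    for p in paths:
        log.info("wrote %s", p)
    return paths
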