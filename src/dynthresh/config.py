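"""Configuration files, run manifests, and output persistence.

Configuration is a flat YAML mapping mirroring ``ModelParameters`` field
names, plus optional run options (seed, burnin, n, replicates).  CLI
flags override file values.  Every run writes a manifest sufficient to
reproduce it bit-exactly (resolved parameters, seeds, package version).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .domain import ModelParameters, ParameterError
from .simulator import SimulationOutput

__all__ = ["RunOptions", "RunManifest", "load_config", "write_outputs", "ConfigError"]

logger = logging.getLogger("dynthresh")

_RUN_OPTION_KEYS = {"seed", "burnin", "n", "replicates"}


class ConfigError(ValueError):
    """A configuration file could not be parsed."""


@dataclass(frozen=True)
class RunOptions:
    seed: int = 0
    burnin: int = 2000
    n: int = 3000
    replicates: int = 1

    def merged(self, **overrides) -> "RunOptions":
        clean = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **clean)


@dataclass
class RunManifest:
    """Reproducibility record written next to every output set."""

    parameters: dict
    seeds: Tuple[int, ...]
    options: dict
    outputs: Tuple[str, ...]
    version: str = ""
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=False)


def load_config(path) -> Tuple[ModelParameters, RunOptions]:
    """Parse a YAML config into (ModelParameters, RunOptions).

    Absent keys take the base-case defaults; unknown keys, malformed
    numbers, and out-of-range values raise with the offending key named.
    An empty file yields the full default parameter set.
    """
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a flat key/value mapping")

    run_kwargs = {}
    for key in _RUN_OPTION_KEYS & set(data):
        value = data.pop(key)
        if not isinstance(value, int) or isinstance(value, bool) or value < 0:
            raise ConfigError(f"{path}: {key} must be a nonnegative integer, got {value!r}")
        run_kwargs[key] = value

    for key, value in data.items():
        if isinstance(value, str):
            raise ConfigError(f"{path}: malformed numeric value for {key!r}: {value!r}")
    try:
        params = ModelParameters.from_dict(data)
    except ParameterError:
        raise
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return params, RunOptions().merged(**run_kwargs)


def trajectory_frame(output: SimulationOutput) -> pd.DataFrame:
    """Per-visit trajectory table for one run."""
    outcome_labels = np.array(["TP", "FP", "TN", "FN"])
    return pd.DataFrame(
        {
            "visit": np.arange(len(output.threshold_trajectory)),
            "threshold": output.threshold_trajectory,
            "threshold_probability": output.threshold_probability_trajectory,
            "outcome": outcome_labels[output.outcomes],
            "rolling_sensitivity": output.rolling_sensitivity,
            "rolling_specificity": output.rolling_specificity,
            "fp_regret": output.fp_regret_trajectory,
            "fn_regret": output.fn_regret_trajectory,
        }
    )


def summary_dict(output: SimulationOutput) -> dict:
    return {
        "parameters": output.parameters.to_dict(),
        "seed": output.seed,
        "n_burnin": output.n_burnin,
        "n_measure": output.n_measure,
        "counts": {
            "TP": output.n_tp,
            "FP": output.n_fp,
            "TN": output.n_tn,
            "FN": output.n_fn,
        },
        "sensitivity": output.sensitivity,
        "specificity": output.specificity,
        "referral_rate": output.referral_rate,
    }


def write_outputs(output: SimulationOutput, out_dir, stem: str = "run") -> RunManifest:
    """Write trajectory CSV, summary JSON, and manifest JSON to ``out_dir``.

    The directory is created if missing.  Full float precision (17
    significant digits) is written, so re-reading the CSV with an
    exactly-rounding parser (pandas ``float_precision="round_trip"``)
    reproduces the trajectory bit-for-bit.
    """
    out_dir = Path(out_dir)
    if not out_dir.exists():
        out_dir.mkdir(parents=True)
        logger.info("created output directory %s", out_dir)
    csv_path = out_dir / f"{stem}_trajectory.csv"
    json_path = out_dir / f"{stem}_summary.json"
    manifest_path = out_dir / f"{stem}_manifest.json"

    trajectory_frame(output).to_csv(
        csv_path, index=False, float_format="%.17g"
    )
    json_path.write_text(json.dumps(summary_dict(output), indent=2))

    try:
        from importlib.metadata import version
        pkg_version = version("dynthresh")
    except Exception:  # pragma: no cover - not installed
        pkg_version = "unknown"
    manifest = RunManifest(
        parameters=output.parameters.to_dict(),
        seeds=(output.seed,),
        options={"n_burnin": output.n_burnin, "n_measure": output.n_measure},
        outputs=(str(csv_path), str(json_path)),
        version=pkg_version,
    )
    manifest_path.write_text(manifest.to_json())
    logger.info("wrote %s, %s, %s", csv_path, json_path, manifest_path)
    return manifest
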