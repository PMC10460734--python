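"""Run configuration: YAML round-trip with aggregated validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]

_DEFAULTS = dict(
    n=100_000,
    partitions=30,
    bootstrap=1000,
    level=0.95,
    seed=0,
)

_MODELS = ("ct", "tvdt", "linear-example", "plugin")


class ConfigError(ValueError):
    """Invalid run configuration; ``problems`` lists every issue found."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration: " + "; ".join(problems))


@dataclass
class RunConfig:
    params_path: str
    model: str
    scenario: str = ""
    corr_path: str | None = None
    n: int = _DEFAULTS["n"]
    partitions: int = _DEFAULTS["partitions"]
    bootstrap: int = _DEFAULTS["bootstrap"]
    level: float = _DEFAULTS["level"]
    seed: int = _DEFAULTS["seed"]
    out_dir: str = "."


def _validate(raw: dict) -> RunConfig:
    problems = []
    for key in ("params_path", "model"):
        if not raw.get(key):
            problems.append(f"missing required field {key!r}")
    model = raw.get("model")
    if model and model not in _MODELS:
        problems.append(f"model must be one of {_MODELS}, got {model!r}")
    merged = {**_DEFAULTS, **{k: v for k, v in raw.items() if v is not None}}
    for key in ("n", "partitions", "bootstrap"):
        try:
            merged[key] = int(merged[key])
            if merged[key] <= 0:
                problems.append(f"{key} must be positive")
        except (TypeError, ValueError):
            problems.append(f"{key} must be an integer")
    try:
        merged["level"] = float(merged["level"])
        if not 0 < merged["level"] < 1:
            problems.append("level must be in (0, 1)")
    except (TypeError, ValueError):
        problems.append("level must be a number")
    try:
        merged["seed"] = int(merged["seed"])
    except (TypeError, ValueError):
        problems.append("seed must be an integer")
    if problems:
        raise ConfigError(problems)
    known = {f for f in RunConfig.__dataclass_fields__}
    return RunConfig(**{k: v for k, v in merged.items() if k in known})


def load_config(path) -> RunConfig:
    """Load a YAML config, apply defaults, report all validation errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["config file must contain a mapping"])
    return _validate(raw)


def save_config(config: RunConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(asdict(config), sort_keys=True))
    return path
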