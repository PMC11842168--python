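"""Run configuration: parsing, validation with aggregated errors, defaults.

A run config (YAML or JSON) drives the CLI and the reproduction profiles.
Validation never stops at the first problem; every offending key is
reported with the violated constraint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "validate_config", "load_config", "ConfigError"]

_DESIGNS = ("hypothetical", "real_lakes")
_CAPTURE_MODES = ("vertex", "segment")
_CAPTURE_SIZINGS = ("circumference", "arc")


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every violation."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class RunConfig:
    """Validated configuration of one simulation run."""

    seed: int
    design: str = "hypothetical"
    out_dir: str = "results"
    n_per_cell: int = 200
    swim_speed: float = 0.17
    collision_coeff: float = 0.1
    collision_exponent: float = 2.0
    capture_mode: str = "vertex"
    capture_sizing: str = "circumference"
    ci_level: float = 0.95
    equal_area: bool = False
    basin_files: list[str] = field(default_factory=list)  # fixture overrides

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def validate_config(raw: dict) -> RunConfig:
    """Validate a raw mapping into a RunConfig; all errors are aggregated.

    Unknown keys are rejected (they are silent typos otherwise); missing
    optional keys take package defaults, echoed back in the result.
    """
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])
    known = {f.name for f in fields(RunConfig)}
    for key in raw:
        if key not in known:
            errors.append(f"unknown key '{key}'")

    def get(key, default=None):
        return raw.get(key, default)

    if "seed" not in raw:
        errors.append("missing required key 'seed'")
    elif not isinstance(raw["seed"], int) or isinstance(raw["seed"], bool):
        errors.append("'seed' must be an integer")

    if get("design", "hypothetical") not in _DESIGNS:
        errors.append(f"'design' must be one of {_DESIGNS}")
    n = get("n_per_cell", 200)
    if not isinstance(n, int) or n < 1:
        errors.append("'n_per_cell' must be an integer >= 1")
    v = get("swim_speed", 0.17)
    if not isinstance(v, (int, float)) or isinstance(v, bool) or v <= 0:
        errors.append("'swim_speed' must be a positive number")
    for key in ("collision_coeff", "collision_exponent"):
        v = get(key, 0.1)
        if not isinstance(v, (int, float)) or isinstance(v, bool) or v < 0:
            errors.append(f"'{key}' must be a non-negative number")
    if get("capture_mode", "vertex") not in _CAPTURE_MODES:
        errors.append(f"'capture_mode' must be one of {_CAPTURE_MODES}")
    if get("capture_sizing", "circumference") not in _CAPTURE_SIZINGS:
        errors.append(f"'capture_sizing' must be one of {_CAPTURE_SIZINGS}")
    ci = get("ci_level", 0.95)
    if not isinstance(ci, (int, float)) or not (0.5 < ci < 1.0):
        errors.append("'ci_level' must be a number in (0.5, 1)")
    if not isinstance(get("equal_area", False), bool):
        errors.append("'equal_area' must be a boolean")
    basin_files = get("basin_files", [])
    if not isinstance(basin_files, list) or not all(
        isinstance(b, str) for b in basin_files
    ):
        errors.append("'basin_files' must be a list of paths")
    else:
        for b in basin_files:
            if not Path(b).exists():
                errors.append(f"'basin_files' entry not found: {b}")

    if errors:
        raise ConfigError(errors)
    clean = {k: v for k, v in raw.items() if k in known}
    return RunConfig(**clean)


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML or JSON config file."""
    text = Path(path).read_text()
    raw = (
        json.loads(text)
        if str(path).endswith(".json")
        else yaml.safe_load(text)
    )
    return validate_config(raw)
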