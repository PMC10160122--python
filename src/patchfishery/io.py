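"""Serialization: trajectory/spectrum CSV, parameter config files, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import ModelParameters, Trajectory
from .stochastic import SpectrumResult

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_spectrum_csv",
    "read_params_config",
    "write_json_report",
    "SUMMARY_SCHEMA",
    "validate_summary",
]

TRAJECTORY_HEADER = ["t", "x", "y", "z", "w"]
SPECTRUM_HEADER = ["omega", "S_u1", "S_u2", "S_u3", "S_u4"]

#: Minimal schema for JSON run summaries (jsonschema-style subset).
SUMMARY_SCHEMA = {
    "type": "object",
    "required": ["command", "preset_or_config", "seed", "results"],
    "properties": {
        "command": {"type": "string"},
        "preset_or_config": {"type": "string"},
        "seed": {"type": ["integer", "null"]},
        "results": {"type": "object"},
    },
}

_JSON_TYPES = {
    "string": str, "integer": int, "number": (int, float),
    "object": dict, "array": list, "boolean": bool, "null": type(None),
}


def validate_summary(summary: dict, schema: dict = SUMMARY_SCHEMA) -> None:
    """Check required keys and types against the shipped summary schema."""
    if not isinstance(summary, dict):
        raise TypeError("summary must be a JSON object")
    for key in schema.get("required", []):
        if key not in summary:
            raise ValueError(f"summary missing required key {key!r}")
    for key, spec in schema.get("properties", {}).items():
        if key not in summary:
            continue
        expected = spec["type"]
        names = [expected] if isinstance(expected, str) else expected
        allowed = tuple(_JSON_TYPES[n] for n in names)
        if not isinstance(summary[key], allowed):
            raise TypeError(
                f"summary key {key!r} has type {type(summary[key]).__name__}, "
                f"expected {names}"
            )


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """Write `t,x,y,z,w` rows with IEEE-754 round-trip precision."""
    df = pd.DataFrame(
        np.column_stack([traj.times, traj.states]), columns=TRAJECTORY_HEADER
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_trajectory_csv(path) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != TRAJECTORY_HEADER:
        raise ValueError(
            f"unexpected trajectory header {list(df.columns)}; "
            f"want {TRAJECTORY_HEADER}"
        )
    return Trajectory(df["t"].to_numpy(), df[["x", "y", "z", "w"]].to_numpy())


def write_spectrum_csv(spec: SpectrumResult, path) -> None:
    df = pd.DataFrame(
        np.column_stack([spec.omegas, spec.S]), columns=SPECTRUM_HEADER
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_params_config(path) -> ModelParameters:
    """Load the 16 model parameters from a YAML or JSON mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        mapping = json.loads(text)
    else:
        mapping = yaml.safe_load(text)
    if not isinstance(mapping, dict):
        raise ValueError(f"config {path} must contain a mapping of parameters")
    return ModelParameters.from_dict(mapping)


def write_json_report(report: dict, path) -> None:
    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, complex):
            return {"re": obj.real, "im": obj.imag}
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default) + "\n")
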