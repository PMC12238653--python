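"""Simulation-table I/O: CSV with a JSON config sidecar, schema-checked.

The trajectory table is written as plain CSV (human-inspectable and
diffable) with the full column schema in the header; the resolved run
configuration travels in a ``<name>.config.json`` sidecar.  Reading
validates the schema and reproduces the table bit-for-bit at double
precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .mpc import RESULT_COLUMNS, SimulationResult

__all__ = ["SchemaError", "write_simulation_csv", "read_simulation_csv", "sidecar_path"]


class SchemaError(ValueError):
    """A required column is missing or malformed."""


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".config.json")


def write_simulation_csv(result: SimulationResult, path: str | Path) -> Path:
    """Write the trajectory CSV and its config sidecar; returns the CSV path."""
    path = Path(path)
    missing = [c for c in RESULT_COLUMNS if c not in result.frame.columns]
    if missing:
        raise SchemaError(f"result frame missing column(s): {', '.join(missing)}")
    result.frame.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "config": result.config_echo,
        "failed": result.failed,
        "failure_time": result.failure_time,
        "failure_frequency": result.failure_frequency,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_simulation_csv(path: str | Path) -> SimulationResult:
    """Read a trajectory CSV (and sidecar if present) back into a result."""
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path.name} missing column(s): {', '.join(missing)}")
    meta: dict = {}
    sc = sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return SimulationResult(
        frame=frame,
        config_echo=meta.get("config", {}),
        failed=bool(meta.get("failed", False)),
        failure_time=meta.get("failure_time"),
        failure_frequency=meta.get("failure_frequency"),
    )
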