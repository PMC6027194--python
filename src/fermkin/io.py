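"""CSV/JSON writers and readers for trajectories and experiment reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .experiments import ExperimentReport
from .kinetics import Trajectory

__all__ = ["write_trajectory", "read_trajectory", "write_report"]


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as CSV, one row per grid point, full double
    precision (shortest round-trip float representation)."""
    trajectory.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(Trajectory.COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file missing column(s): {sorted(missing)}")
    return Trajectory(**{c: df[c].to_numpy(dtype=float) for c in Trajectory.COLUMNS})


def write_report(report: ExperimentReport, path: str | Path) -> None:
    """Write a report table as CSV plus a JSON snapshot alongside.

    The JSON (same stem, ``.json`` suffix) carries the label, derived
    comparisons, ordering checks and the full configuration snapshot, so
    the run can be reproduced bit-identically.
    """
    path = Path(path)
    report.table.to_csv(path, index=False)
    meta = {
        "label": report.label,
        "comparisons": report.comparisons,
        "checks": report.checks,
        "config": report.config,
        "wall_time_s": report.wall_time_s,
    }
    path.with_suffix(".json").write_text(
        json.dumps(_jsonable(meta), indent=2, sort_keys=True)
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj
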