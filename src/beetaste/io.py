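"""Plain-text I/O: trace CSVs with YAML sidecars, visit logs, rate tables."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .spikes import FiringRecord, Trace
from .synth import VISIT_COLUMNS, SimulatedTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_visit_log",
    "read_visit_log",
    "firing_records_frame",
    "write_firing_records",
    "read_manifest",
    "report_to_json",
]


def write_trace(sim: SimulatedTrace, prefix: str | Path) -> tuple[Path, Path]:
    """Write a trace as ``<prefix>.csv`` (time_s, voltage_mv) plus a
    ``<prefix>.yaml`` sidecar holding metadata and simulation ground truth."""
    prefix = Path(prefix)
    trace = sim.trace
    csv_path = prefix.with_suffix(".csv")
    yaml_path = prefix.with_suffix(".yaml")
    pd.DataFrame({"time_s": trace.times, "voltage_mv": trace.samples}).to_csv(
        csv_path, index=False, float_format="%.6f"
    )
    meta = {
        "sample_rate": float(trace.sample_rate),
        "bee_id": trace.bee_id,
        "sensillum_id": trace.sensillum_id,
        "location": trace.location,
        "stimulus": trace.stimulus,
        "truth": {
            "spike_times": [float(t) for t in sim.spike_times],
            "artifacts": sim.artifacts.to_dict("records"),
        },
    }
    yaml_path.write_text(yaml.safe_dump(meta, sort_keys=False))
    return csv_path, yaml_path


def read_trace(csv_path: str | Path, yaml_path: str | Path | None = None) -> Trace:
    """Read a two-column trace CSV; metadata comes from the YAML sidecar if
    present, else defaults."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    if not {"time_s", "voltage_mv"} <= set(df.columns):
        raise ValueError(f"{csv_path} lacks time_s/voltage_mv columns")
    meta: dict = {}
    if yaml_path is None:
        candidate = csv_path.with_suffix(".yaml")
        yaml_path = candidate if candidate.exists() else None
    if yaml_path is not None:
        meta = yaml.safe_load(Path(yaml_path).read_text())
    times = df["time_s"].to_numpy()
    if len(times) > 1:
        sample_rate = float(round(1.0 / np.median(np.diff(times))))
    else:
        sample_rate = float(meta.get("sample_rate", 30000.0))
    return Trace(
        samples=df["voltage_mv"].to_numpy(),
        sample_rate=float(meta.get("sample_rate", sample_rate)),
        bee_id=str(meta.get("bee_id", "bee")),
        sensillum_id=str(meta.get("sensillum_id", "s1")),
        location=str(meta.get("location", "tip")),
        stimulus=str(meta.get("stimulus", "water")),
    )


def write_visit_log(log: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    log[VISIT_COLUMNS].to_csv(path, index=False)
    return path


def read_visit_log(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(VISIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"visit log {path} missing columns {sorted(missing)}")
    return df


def firing_records_frame(records: Sequence[FiringRecord]) -> pd.DataFrame:
    """Flatten FiringRecords to one row per sensillum x stimulus."""
    rows = []
    for r in records:
        row = {
            "bee_id": r.bee_id,
            "sensillum_id": r.sensillum_id,
            "location": r.location,
            "stimulus": r.stimulus,
            "rate_1s": r.rate_1s,
        }
        for i, c in enumerate(r.binned, start=1):
            row[f"bin_{i:02d}"] = int(c)
        row["n_rejected_amplitude"] = r.n_rejected_amplitude
        row["n_rejected_width"] = r.n_rejected_width
        rows.append(row)
    return pd.DataFrame(rows)


def write_firing_records(records: Sequence[FiringRecord], path: str | Path) -> Path:
    path = Path(path)
    firing_records_frame(records).to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest CSV listing traces: bee_id, sensillum_id, location, stimulus, path."""
    df = pd.read_csv(path)
    required = {"bee_id", "sensillum_id", "location", "stimulus", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    return df


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict("records")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def report_to_json(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(report), indent=2))
    return path
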