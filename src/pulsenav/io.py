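"""Readers/writers for the delimited-text formats and run manifests.

All tables are comma-separated UTF-8 with a mandatory header row.  Standard
columns:

- traces:       worm_id, neuron, time_s, value
- pulse tables: worm_id, peak_time_s, amplitude, tau_s, rmse, interval_s
- profiles:     time_s, conc_uM [, d1, d2]
- schedules:    time_s, stim_fraction
- trajectories: time_s, x_mm, y_mm (target coordinate in a JSON sidecar)

Time is always seconds and concentration µM; the simulator's dimensionless
step-length units never pass through these readers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .adaptation import Trajectory
from .errors import DataError
from .pulses import CalciumTrace
from .stimulus import StimulusProfile

__all__ = [
    "read_traces",
    "write_traces",
    "read_pulse_table",
    "write_pulse_table",
    "read_profile",
    "write_profile",
    "read_trajectory",
    "write_trajectory",
    "RunManifest",
    "write_manifest",
]

TRACE_COLUMNS = ["worm_id", "neuron", "time_s", "value"]


def _read_table(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path} is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path} is missing required column(s): {missing}")
    return df


def read_traces(path) -> list[CalciumTrace]:
    """Read a trace table into per-(worm, neuron) CalciumTrace objects.

    Rows are grouped by (worm_id, neuron) and time-sorted; non-numeric or NaN
    rows raise a DataError naming the offending row numbers.
    """
    df = _read_table(path, TRACE_COLUMNS)
    for col in ("time_s", "value"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()].tolist()
        if bad:
            raise DataError(
                f"{path}: non-numeric or missing {col!r} at data row(s) {bad[:10]}"
            )
        df[col] = numeric
    traces = []
    for (wid, neuron), g in df.groupby(["worm_id", "neuron"], sort=True):
        g = g.sort_values("time_s", kind="stable")
        traces.append(
            CalciumTrace(str(wid), str(neuron), g["time_s"].to_numpy(), g["value"].to_numpy())
        )
    return traces


def write_traces(traces: list[CalciumTrace], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "worm_id": t.worm_id,
                "neuron": t.neuron,
                "time_s": t.times,
                "value": t.values,
            }
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_pulse_table(path) -> pd.DataFrame:
    return _read_table(path, ["worm_id", "peak_time_s", "amplitude", "tau_s"])


def write_pulse_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_profile(path) -> StimulusProfile:
    df = _read_table(path, ["time_s", "conc_uM"])
    d1 = df["d1"].to_numpy() if "d1" in df.columns else None
    d2 = df["d2"].to_numpy() if "d2" in df.columns else None
    return StimulusProfile(df["time_s"].to_numpy(), df["conc_uM"].to_numpy(), d1, d2)


def write_profile(profile: StimulusProfile, path) -> None:
    data = {"time_s": profile.times, "conc_uM": profile.conc}
    if profile.d1 is not None:
        data["d1"] = profile.d1
    if profile.d2 is not None:
        data["d2"] = profile.d2
    pd.DataFrame(data).to_csv(path, index=False)


def write_schedule(times: np.ndarray, fractions: np.ndarray, path) -> None:
    pd.DataFrame({"time_s": times, "stim_fraction": fractions}).to_csv(path, index=False)


def read_trajectory(path, target: tuple[float, float] | None = None) -> Trajectory:
    """Read a trajectory table; the target comes from ``<path>.json`` unless given."""
    df = _read_table(path, ["time_s", "x_mm", "y_mm"])
    if target is None:
        sidecar = Path(str(path) + ".json")
        if not sidecar.exists():
            raise DataError(f"no target given and no sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        target = tuple(meta["target"])
    return Trajectory(
        df["time_s"].to_numpy(), df["x_mm"].to_numpy(), df["y_mm"].to_numpy(), target
    )


def write_trajectory(traj: Trajectory, path) -> None:
    pd.DataFrame({"time_s": traj.times, "x_mm": traj.x, "y_mm": traj.y}).to_csv(
        path, index=False
    )
    Path(str(path) + ".json").write_text(json.dumps({"target": list(traj.target)}))


@dataclass
class RunManifest:
    """Provenance record written once per CLI run."""

    tool: str
    version: str
    config_hash: str
    seed: int | None
    inputs: list[str]
    outputs: list[str]
    timestamp: str


def write_manifest(
    out_dir,
    tool: str,
    config: dict,
    seed: int | None,
    inputs: list[str],
    outputs: list[str],
) -> Path:
    from . import __version__

    payload = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = RunManifest(
        tool=tool,
        version=__version__,
        config_hash=hashlib.sha256(payload).hexdigest()[:16],
        seed=seed,
        inputs=[str(p) for p in inputs],
        outputs=[str(p) for p in outputs],
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{tool}_manifest.json"
    path.write_text(json.dumps(asdict(manifest), indent=2))
    return path
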