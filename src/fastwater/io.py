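"""Readers and writers for the plain-text formats used around the analyses.

Covers GROMACS-style XVG series (``@``/``#`` headers skipped), CSV
collective-variable series and crash-record tables, NPZ trajectory
bundles, and JSON/YAML artifact output.  All numeric outputs embed the
unit in the field name so downstream tooling cannot silently mix units.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .crash_kinetics import CrashRecord
from .errors import InvalidArgumentError
from .sampling_efficiency import CVSeries
from .trajectory_kinetics import WrappedTrajectory

__all__ = [
    "read_xvg",
    "read_series",
    "write_series_csv",
    "read_crash_records",
    "write_crash_records",
    "read_trajectory_npz",
    "write_trajectory_npz",
    "read_trajectory_mdanalysis",
    "write_json",
    "write_model_card",
]


def read_xvg(path: str | Path) -> np.ndarray:
    """Read a GROMACS XVG table, skipping ``@`` and ``#`` header lines."""
    rows = []
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped[0] in "@#&":
                continue
            rows.append([float(tok) for tok in stripped.split()])
    if not rows:
        raise InvalidArgumentError(f"no data rows in {path}")
    return np.array(rows)


def read_series(path: str | Path, frame_dt: float | None = None,
                circular: bool = False,
                replica_id: int | str | None = None) -> CVSeries:
    """Read a collective-variable series from XVG or CSV.

    Two-column files are interpreted as (time ps, value); ``frame_dt`` is
    then inferred from the time column.  One-column files require
    ``frame_dt`` explicitly.
    """
    path = Path(path)
    if path.suffix.lower() == ".xvg":
        data = read_xvg(path)
    else:
        data = pd.read_csv(path, comment="#").to_numpy(dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    if data.shape[1] >= 2:
        times, values = data[:, 0], data[:, 1]
        inferred = float(np.median(np.diff(times)))
        frame_dt = frame_dt if frame_dt is not None else inferred
    else:
        values = data[:, 0]
        if frame_dt is None:
            raise InvalidArgumentError(
                "one-column series needs an explicit frame_dt")
    return CVSeries(values=values, frame_dt=frame_dt, circular=circular,
                    replica_id=replica_id)


def write_series_csv(path: str | Path, series: CVSeries,
                     value_name: str = "value") -> None:
    times = np.arange(series.n) * series.frame_dt
    pd.DataFrame({"time_ps": times, value_name: series.values}).to_csv(
        path, index=False, float_format="%.10g")


def read_crash_records(path: str | Path) -> list[CrashRecord]:
    """Read crash records from CSV with columns replica_id, time_ns, crashed."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"time_ns", "crashed"} - set(df.columns)
    if missing:
        raise InvalidArgumentError(
            f"{path}: missing column(s) {sorted(missing)}")
    crashed = df["crashed"]
    if crashed.dtype == object:
        crashed = crashed.astype(str).str.strip().str.lower().isin(
            ("true", "1", "yes"))
    return [CrashRecord(float(t), bool(c))
            for t, c in zip(df["time_ns"], crashed)]


def write_crash_records(path: str | Path, records: list[CrashRecord]) -> None:
    pd.DataFrame({
        "replica_id": np.arange(len(records)),
        "time_ns": [r.t for r in records],
        "crashed": [r.crashed for r in records],
    }).to_csv(path, index=False, float_format="%.17g")


def read_trajectory_npz(path: str | Path) -> WrappedTrajectory:
    """Load a trajectory bundle: arrays ``positions``, ``box``, ``frame_dt``."""
    with np.load(path) as data:
        try:
            return WrappedTrajectory(positions=data["positions"],
                                     box=data["box"],
                                     frame_dt=float(data["frame_dt"]))
        except KeyError as exc:
            raise InvalidArgumentError(
                f"{path}: missing array {exc}") from exc


def write_trajectory_npz(path: str | Path, traj: WrappedTrajectory) -> None:
    np.savez_compressed(path, positions=traj.positions, box=traj.box,
                        frame_dt=traj.frame_dt)


def read_trajectory_mdanalysis(topology: str | Path,
                               trajectory: str | Path | None = None,
                               selection: str = "all",
                               frame_dt: float | None = None,
                               ) -> WrappedTrajectory:
    """Load GRO/XTC/TRR (or any MDAnalysis-readable pair) as a trajectory.

    Requires the optional ``MDAnalysis`` dependency.  Orthorhombic boxes
    only; coordinates are wrapped into [0, box).  ``frame_dt`` (ps)
    overrides the file's time metadata.
    """
    import MDAnalysis as mda  # optional dependency

    universe = (mda.Universe(str(topology)) if trajectory is None
                else mda.Universe(str(topology), str(trajectory)))
    atoms = universe.select_atoms(selection)
    positions, boxes = [], []
    for ts in universe.trajectory:
        dims = ts.dimensions
        if dims is None or not np.allclose(dims[3:], 90.0):
            raise InvalidArgumentError("orthorhombic boxes required")
        boxes.append(dims[:3] / 10.0)        # Angstrom -> nm
        positions.append(atoms.positions / 10.0)
    box = np.array(boxes)
    pos = np.mod(np.array(positions), box[:, None, :])
    if frame_dt is None:
        frame_dt = float(universe.trajectory.dt) if len(boxes) > 1 else 1.0
    return WrappedTrajectory(positions=pos, box=box, frame_dt=frame_dt)


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_model_card(path: str | Path, card: dict) -> None:
    """Write a water-model card as JSON or YAML depending on the suffix."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(card, sort_keys=True))
    else:
        write_json(path, card)
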