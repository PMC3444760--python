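"""Configuration files, trajectory serialization, and VTK export.

Run output layout (one directory per run)::

    run_dir/
      config.echo         # effective config incl. defaults, YAML
      manifest.json       # schema version, config hash, package version
      snapshots/000000.csv
      snapshots/000123.csv
      adhesion_events.csv

Snapshot CSVs carry one row per point (id, tag, x, y, marker, adhesion
count) with full round-trip float precision; all files are written
atomically (temp file + rename), so an interrupted run never leaves a
truncated file that parses as valid.  Units in files are CGS (cm, s,
dyn); config files may use micron convenience keys with a ``_um`` suffix.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import SimulationConfig
from .errors import ConfigurationError
from .simulate import Snapshot, Trajectory

__all__ = [
    "load_config",
    "save_config",
    "config_hash",
    "write_trajectory",
    "read_trajectory",
    "write_vtk_boundaries",
    "write_vtk_velocity",
]

SCHEMA_VERSION = 1
FLOAT_FMT = "%.17g"


def _atomic_write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML config; missing keys take defaults.

    An empty file yields the full baseline scenario.  Unknown keys are
    rejected with the offending key named.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError("config file must contain a YAML mapping")
    return SimulationConfig.from_dict(data)


def save_config(config: SimulationConfig, path) -> None:
    """Write the effective config (all fields, CGS units) as YAML."""
    _atomic_write(Path(path), yaml.safe_dump(config.to_dict(), sort_keys=True))


def config_hash(config: SimulationConfig) -> str:
    """SHA-256 of the canonicalized config; changes iff the config does."""
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def _snapshot_frame(traj: Trajectory, snap: Snapshot) -> pd.DataFrame:
    pts = traj.points
    n = len(pts)
    counts = np.zeros(n, dtype=int)
    if snap.n_links:
        np.add.at(counts, snap.links[0], 1)
    return pd.DataFrame({
        "point_id": np.arange(n),
        "tag": pts.tag,
        "x": snap.xy[:, 0],
        "y": snap.xy[:, 1],
        "marker": pts.marker.astype(int),
        "adhesion_count": counts,
    })


def write_trajectory(traj: Trajectory, out_dir) -> Path:
    """Write snapshots, adhesion events, config echo, and manifest."""
    out = Path(out_dir)
    snap_dir = out / "snapshots"
    snap_dir.mkdir(parents=True, exist_ok=True)
    for k, snap in enumerate(traj.snapshots):
        df = _snapshot_frame(traj, snap)
        header = (f"# ctcflow snapshot schema v{SCHEMA_VERSION}; units cm; "
                  f"time_s={snap.time!r}\n")
        _atomic_write(snap_dir / f"{k:06d}.csv",
                      header + df.to_csv(index=False, float_format=FLOAT_FMT))
    ev = pd.DataFrame(traj.events or [],
                      columns=["time_s", "event", "cell_id", "wall_id", "length_cm"])
    _atomic_write(out / "adhesion_events.csv",
                  ev.to_csv(index=False, float_format=FLOAT_FMT))
    save_config(traj.config, out / "config.echo")
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config_sha256": config_hash(traj.config),
        "n_snapshots": len(traj.snapshots),
        "times_s": [s.time for s in traj.snapshots],
        "package": "ctcflow",
    }
    _atomic_write(out / "manifest.json", json.dumps(manifest, indent=1))
    return out


def read_trajectory(run_dir) -> tuple[SimulationConfig, list[pd.DataFrame], pd.DataFrame]:
    """Read back a written run: (config, snapshot frames, event frame).

    Coordinates round-trip bit-exactly thanks to the 17-significant-digit
    CSV format.  Each snapshot frame carries its time in ``frame.attrs``.
    """
    run = Path(run_dir)
    config = load_config(run / "config.echo")
    frames = []
    for f in sorted((run / "snapshots").glob("*.csv")):
        with open(f) as fh:
            header = fh.readline()
        t = float(header.rsplit("time_s=", 1)[1])
        df = pd.read_csv(f, skiprows=1, float_precision="round_trip")
        df.attrs["time_s"] = t
        frames.append(df)
    events = pd.read_csv(run / "adhesion_events.csv", float_precision="round_trip")
    return config, frames, events


# --------------------------------------------------------------------------
# legacy-VTK (ASCII) export for visualization
# --------------------------------------------------------------------------

def write_vtk_boundaries(traj: Trajectory, snap_index: int, path) -> None:
    """Write one snapshot's boundary contours as VTK polylines."""
    snap = traj.snapshots[snap_index]
    pts = traj.points
    lines = []
    for name, idx in pts.groups.items():
        closed = name not in ("wall_bottom", "wall_top")
        seq = list(idx) + ([idx[0]] if closed else [])
        lines.append(seq)
    out = ["# vtk DataFile Version 3.0",
           f"ctcflow boundaries t={snap.time:g}s", "ASCII",
           "DATASET POLYDATA", f"POINTS {len(pts)} double"]
    for x, y in snap.xy:
        out.append(f"{x:.9e} {y:.9e} 0.0")
    total = sum(len(s) + 1 for s in lines)
    out.append(f"LINES {len(lines)} {total}")
    for seq in lines:
        out.append(" ".join([str(len(seq))] + [str(int(i)) for i in seq]))
    _atomic_write(Path(path), "\n".join(out) + "\n")


def write_vtk_velocity(state, path) -> None:
    """Write a velocity field as a VTK structured-points dataset."""
    g = state.grid
    out = ["# vtk DataFile Version 3.0", "ctcflow velocity", "ASCII",
           "DATASET STRUCTURED_POINTS",
           f"DIMENSIONS {g.nx} {g.ny} 1",
           "ORIGIN 0 0 0",
           f"SPACING {g.hx:.9e} {g.hy:.9e} 1",
           f"POINT_DATA {g.nx * g.ny}",
           "VECTORS velocity double"]
    ux, uy = state.u[0], state.u[1]
    for j in range(g.ny):
        for i in range(g.nx):
            out.append(f"{ux[j, i]:.9e} {uy[j, i]:.9e} 0.0")
    _atomic_write(Path(path), "\n".join(out) + "\n")
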