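"""Plain-text trajectory and metrics formats, with optional HDF5.

One trajectory is a CSV with header ``time_s,point_index,x_nm,y_nm,z_nm``
(one row per particle per frame) plus a JSON sidecar capturing the
protocol, thermal model, resolution, replicate and seed, so externally
produced filament centerlines (e.g. segmented tomograms) can be fed to the
metrics stage by writing the same format. ``read_trajectory(write(x))``
round-trips bit-exactly via full-precision floats.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import CompressionProtocol, Trajectory
from .frames import FilamentFrame

TRAJECTORY_COLUMNS = ["time_s", "point_index", "x_nm", "y_nm", "z_nm"]

METRICS_COLUMNS = ["resolution", "velocity_um_s", "replicate", "time_s",
                   "normalized_time", "end_to_end_nm", "compression_ratio",
                   "peak_asymmetry", "non_coplanarity", "supertwist_deg"]


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write a trajectory CSV and its ``<stem>.config.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for t, frame in zip(traj.times, traj.frames):
        n = frame.n_points
        rows.append(np.column_stack([
            np.full(n, t), np.arange(n),
            frame.points[:, 0], frame.points[:, 1], frame.points[:, 2]]))
    data = np.concatenate(rows)
    with open(path, "w") as fh:
        fh.write(",".join(TRAJECTORY_COLUMNS) + "\n")
        np.savetxt(fh, data, delimiter=",",
                   fmt=["%.17g", "%d", "%.17g", "%.17g", "%.17g"])
    sidecar = {
        "resolution": traj.resolution_label,
        "replicate": traj.replicate,
        "seed": traj.seed,
        "protocol": dataclasses.asdict(traj.protocol)
        if traj.protocol is not None else None,
        "metadata": _jsonable(traj.metadata),
    }
    sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".config.json")


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory CSV (+ sidecar if present)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    meta: dict = {}
    protocol = None
    resolution = "external"
    replicate = 0
    seed = 0
    sc = sidecar_path(path)
    if sc.exists():
        info = json.loads(sc.read_text())
        resolution = info.get("resolution", "external")
        replicate = int(info.get("replicate", 0))
        seed = int(info.get("seed", 0))
        meta = info.get("metadata") or {}
        if info.get("protocol"):
            protocol = CompressionProtocol(**info["protocol"])
    frames = []
    times = []
    for t, grp in df.groupby("time_s", sort=True):
        grp = grp.sort_values("point_index")
        frames.append(FilamentFrame(
            grp[["x_nm", "y_nm", "z_nm"]].to_numpy(), time=float(t)))
        times.append(float(t))
    return Trajectory(frames=frames, times=np.asarray(times),
                      protocol=protocol, resolution_label=resolution,
                      replicate=replicate, seed=seed, metadata=meta)


def write_trajectory_hdf5(traj: Trajectory, path: str | Path) -> Path:
    """Same schema in an HDF5 container (optional binary output)."""
    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("times_s", data=traj.times)
        h5.create_dataset(
            "points_nm", data=np.stack([f.points for f in traj.frames]))
        h5.attrs["resolution"] = traj.resolution_label
        h5.attrs["replicate"] = traj.replicate
        h5.attrs["seed"] = traj.seed
        if traj.protocol is not None:
            h5.attrs["protocol_json"] = json.dumps(
                dataclasses.asdict(traj.protocol))
    return path


def read_trajectory_hdf5(path: str | Path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as h5:
        times = h5["times_s"][:]
        points = h5["points_nm"][:]
        protocol = None
        if "protocol_json" in h5.attrs:
            protocol = CompressionProtocol(
                **json.loads(h5.attrs["protocol_json"]))
        frames = [FilamentFrame(points[i], time=float(times[i]))
                  for i in range(points.shape[0])]
        return Trajectory(frames=frames, times=times, protocol=protocol,
                          resolution_label=str(h5.attrs["resolution"]),
                          replicate=int(h5.attrs["replicate"]),
                          seed=int(h5.attrs["seed"]))


def metrics_to_csv(df: pd.DataFrame, path: str | Path) -> Path:
    """Write the per-frame metric table in the documented column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.rename(columns={"time": "time_s", "end_to_end": "end_to_end_nm",
                             "supertwist_angle": "supertwist_deg"})
    out = out[[c for c in METRICS_COLUMNS if c in out.columns]]
    out.to_csv(path, index=False, float_format="%.17g")
    return path


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()
                if _jsonable(v) is not None or v is None}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return None  # drop non-serialisable entries (e.g. dataclass handles)
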