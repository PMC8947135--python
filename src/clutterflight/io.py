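"""File-format plumbing: CSV/JSON schemas with provenance headers.

Dialect is fixed for cross-language reuse: UTF-8, comma separator, '.'
decimal, mandatory header row.  Every table written here is prefixed
with ``#``-comment provenance lines (package version, seed, config
hash) that ``read_table`` skips transparently.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__

DETECTIONS_COLUMNS = ["flight_id", "camera_id", "frame", "u", "v", "area"]
TRAJECTORY_COLUMNS = ["flight_id", "frame", "t", "x", "y", "z",
                      "reproj_err", "flag"]
METRICS_COLUMNS = ["bee_id", "flight_number", "wind", "direction",
                   "wind_class", "field_height", "altitude_floor",
                   "altitude_range", "altitude_obstacle", "route",
                   "ground_speed", "lateral_excursion", "speed_change",
                   "min_clearance", "collision", "kept"]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def provenance_lines(seed=None, config=None) -> list[str]:
    lines = [f"# clutterflight version: {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    return lines


def write_table(df: pd.DataFrame, path, seed=None, config=None,
                required_columns=None) -> None:
    """Write a CSV with provenance header comments."""
    if required_columns is not None:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise ValueError(f"table missing required column(s): {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in provenance_lines(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def read_table(path, required_columns=None) -> pd.DataFrame:
    """Read a provenance-headed CSV, validating required columns."""
    df = pd.read_csv(path, comment="#")
    if required_columns is not None:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise ValueError(
                f"{path}: missing required column(s): {missing}")
    return df


def write_json(obj, path, seed=None, config=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"provenance": {"version": __version__, "seed": seed,
                              "config_hash": config_hash(config) if config else None},
               **obj}
    path.write_text(json.dumps(payload, indent=2, default=str))


def detections_to_frame(observations: dict, flight_id: str) -> pd.DataFrame:
    """Flatten per-camera detection dicts into the detections CSV schema."""
    rows = []
    for cam_id, frames in observations.items():
        for f, dets in sorted(frames.items()):
            for d in dets:
                rows.append({"flight_id": flight_id, "camera_id": cam_id,
                             "frame": f, "u": d.centroid[0], "v": d.centroid[1],
                             "area": d.area})
    return pd.DataFrame(rows, columns=DETECTIONS_COLUMNS)


def frame_to_detections(df: pd.DataFrame) -> dict:
    """Inverse of :func:`detections_to_frame` for one flight's rows."""
    from .tracking import Detection2D
    out: dict[str, dict[int, list]] = {}
    for row in df.itertuples():
        out.setdefault(row.camera_id, {}).setdefault(int(row.frame), []).append(
            Detection2D(camera_id=row.camera_id, frame_index=int(row.frame),
                        centroid=(float(row.u), float(row.v)),
                        area=float(row.area)))
    return out


def trajectory_to_frame(traj, smooth=None) -> pd.DataFrame:
    """Trajectory CSV rows; smoothed output adds vx, vy, vz columns."""
    df = pd.DataFrame({
        "flight_id": traj.flight_id, "frame": traj.frames, "t": traj.times,
        "x": traj.positions[:, 0], "y": traj.positions[:, 1],
        "z": traj.positions[:, 2],
        "reproj_err": traj.reprojection_error, "flag": traj.flags,
    })
    if smooth is not None:
        vel = smooth.velocity(traj.times)
        df["vx"], df["vy"], df["vz"] = vel[:, 0], vel[:, 1], vel[:, 2]
    return df
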