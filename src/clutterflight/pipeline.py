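"""End-to-end measurement chain: detections -> tracks -> 3D -> metrics.

Ties the per-camera tracking, stereo reconstruction, transit clipping,
excluded-zone screening, quintic smoothing and metric computation into
one call per flight, and over a whole (synthetic or imported)
experiment into a tidy per-flight metrics table plus a rejects table
listing every discarded flight with its reason — the transparent
counterpart of the discard step in the protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import trajectory as tj
from .camera import CameraParams
from .kinematics import FlightMetrics, TrialCondition, compute_metrics
from .scene import SceneSpec
from .tracking import (KalmanConfig, NoTrackError, reject_displacement_outliers,
                       track_single_target)


@dataclass
class FlightRecord:
    """One processed flight: condition, trajectory products and metrics."""

    cond: TrialCondition
    metrics: FlightMetrics | None
    kept: bool
    reject_reason: str = ""
    trajectory: tj.Trajectory3D | None = None
    smooth: object | None = None


def process_flight(detections_by_camera: dict,
                   cam_a: CameraParams, cam_b: CameraParams,
                   scene: SceneSpec, cond: TrialCondition,
                   kalman: KalmanConfig = KalmanConfig(),
                   smoothing="auto",
                   altitude_source: str = "smoothed") -> FlightRecord:
    """Run the full chain for one flight.

    ``altitude_source`` selects whether altitude statistics come from the
    smoothed spline ("smoothed", default) or the raw reconstructed
    positions ("raw"); speeds always come from the spline derivative.
    Returns a :class:`FlightRecord`; screening failures produce a
    not-kept record rather than an exception.
    """
    flight_id = f"{cond.bee_id}_f{cond.flight_number}"
    try:
        track_a = reject_displacement_outliers(track_single_target(
            detections_by_camera[cam_a.camera_id], kalman))
        track_b = reject_displacement_outliers(track_single_target(
            detections_by_camera[cam_b.camera_id], kalman))
        traj = tj.reconstruct(track_a, track_b, cam_a, cam_b, flight_id)
        traj = tj.clip_to_field(traj, scene)
    except (NoTrackError, tj.NoTransitError, tj.ShortOverlapError) as exc:
        return FlightRecord(cond=cond, metrics=None, kept=False,
                            reject_reason=f"{type(exc).__name__}: {exc}")
    if not tj.excluded_zone_filter(traj, scene):
        return FlightRecord(cond=cond, metrics=None, kept=False,
                            reject_reason="excluded_zone", trajectory=traj)
    if len(traj) < 12:
        return FlightRecord(cond=cond, metrics=None, kept=False,
                            reject_reason="too_few_samples", trajectory=traj)
    smooth = tj.smooth(traj, smoothing)
    metrics = compute_metrics(smooth, scene, cond)
    if altitude_source == "raw":
        z = traj.positions[:, 2]
        from dataclasses import replace
        metrics = replace(metrics,
                          altitude_floor=float(np.median(z)),
                          altitude_range=float(z.max() - z.min()),
                          altitude_obstacle=float(np.median(z) - scene.field_height))
    return FlightRecord(cond=cond, metrics=metrics, kept=True,
                        trajectory=traj, smooth=smooth)


def records_to_tables(records: list[FlightRecord]):
    """Split processed flights into (metrics_df, rejects_df)."""
    rows, rejects = [], []
    for rec in records:
        c = rec.cond
        base = {"bee_id": c.bee_id, "flight_number": c.flight_number,
                "wind": c.wind, "direction": c.direction,
                "wind_class": c.wind_class, "field_height": c.field_height}
        if rec.kept:
            m = rec.metrics
            rows.append({**base,
                         "altitude_floor": m.altitude_floor,
                         "altitude_range": m.altitude_range,
                         "altitude_obstacle": m.altitude_obstacle,
                         "route": m.route,
                         "ground_speed": m.ground_speed,
                         "lateral_excursion": m.lateral_excursion,
                         "speed_change": m.speed_change_entry_exit,
                         "min_clearance": m.min_obstacle_clearance,
                         "collision": m.collision,
                         "kept": True})
        else:
            rejects.append({**base, "reason": rec.reject_reason})
    return pd.DataFrame(rows), pd.DataFrame(rejects)


def process_experiment(experiment, rig=None,
                       kalman: KalmanConfig = KalmanConfig(),
                       smoothing="auto") -> tuple[pd.DataFrame, pd.DataFrame,
                                                  list[FlightRecord]]:
    """Run the pipeline over a :class:`SyntheticExperiment` with observations.

    Returns ``(metrics_df, rejects_df, records)``.
    """
    if experiment.observations is None:
        raise ValueError("experiment carries no observations to process")
    if rig is None:
        from .camera import default_rig
        rig = default_rig()
    cam_a, cam_b = rig
    records = []
    for fl, obs in zip(experiment.flights, experiment.observations):
        scene = experiment.scenes[fl.cond.field_height]
        records.append(process_flight(obs, cam_a, cam_b, scene, fl.cond,
                                      kalman=kalman, smoothing=smoothing))
    metrics_df, rejects_df = records_to_tables(records)
    return metrics_df, rejects_df, records
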