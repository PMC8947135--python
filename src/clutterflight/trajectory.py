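"""3D trajectory assembly: stereo fusion, transit clipping, screening, smoothing.

A flight is analyzed from when the bee enters to when it exits the
obstacle field.  The two per-camera tracks are fused frame-by-frame by
triangulation, clipped to the field's longitudinal extent (closed
interval — boundary samples belong to the transit), screened against
the ceiling excluded zone, and smoothed with quintic splines
(:mod:`clutterflight.smoothing`), whose analytic derivative supplies
velocities.

The excluded-zone rule is applied to the raw clipped positions, before
smoothing, since the discard decision is about where the bee actually
flew, not about the fitted curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .camera import FRAME_RATE, CameraParams, triangulate_many
from .smoothing import SmoothTrajectory, smooth_path
from .tracking import MEASURED, Track2D


class NoTransitError(RuntimeError):
    """The trajectory never crosses the obstacle field."""


class ShortOverlapError(RuntimeError):
    """The two camera tracks overlap on too few frames."""


FLAG_OK = "ok"
FLAG_ONE_COASTED = "one_coasted"


@dataclass
class Trajectory3D:
    """Reconstructed flight path sampled uniformly at the frame rate."""

    flight_id: str
    frames: np.ndarray = field(repr=False)
    positions: np.ndarray = field(repr=False)  # (n, 3) mm, tunnel frame
    reprojection_error: np.ndarray = field(repr=False)  # px
    flags: np.ndarray = field(repr=False)  # per-sample quality flag
    frame_rate: float = FRAME_RATE
    calibration_mismatch: bool = False

    @property
    def times(self) -> np.ndarray:
        return self.frames / self.frame_rate

    def __len__(self) -> int:
        return len(self.frames)


def reconstruct(track_a: Track2D, track_b: Track2D,
                cam_a: CameraParams, cam_b: CameraParams,
                flight_id: str = "flight",
                min_overlap: int = 12,
                mismatch_median_px: float = 5.0) -> Trajectory3D:
    """Fuse two per-camera tracks into a 3D trajectory.

    Only the overlapping frame range is used; frames coasted in both
    cameras are dropped, frames coasted in exactly one are triangulated
    (the coasted side contributes its predicted position) and flagged.
    A median reprojection error above ``mismatch_median_px`` sets the
    ``calibration_mismatch`` warning flag on the result.
    """
    lo = max(track_a.start_frame, track_b.start_frame)
    hi = min(track_a.end_frame, track_b.end_frame)
    if hi - lo + 1 < min_overlap:
        raise ShortOverlapError(
            f"tracks overlap on {max(hi - lo + 1, 0)} frames (< {min_overlap})")

    ia = lo - track_a.start_frame
    ib = lo - track_b.start_frame
    n = hi - lo + 1
    uv_a = track_a.states[ia:ia + n, :2]
    uv_b = track_b.states[ib:ib + n, :2]
    fa = np.array(track_a.flags[ia:ia + n]) == MEASURED
    fb = np.array(track_b.flags[ib:ib + n]) == MEASURED
    keep = fa | fb
    if keep.sum() < min_overlap:
        raise ShortOverlapError("too few frames with a measurement")

    pts, err = triangulate_many(cam_a, cam_b, uv_a[keep], uv_b[keep])
    flags = np.where(fa[keep] & fb[keep], FLAG_OK, FLAG_ONE_COASTED)
    return Trajectory3D(
        flight_id=flight_id,
        frames=np.arange(lo, hi + 1)[keep],
        positions=pts,
        reprojection_error=err,
        flags=flags,
        calibration_mismatch=bool(np.median(err) > mismatch_median_px),
    )


def clip_to_field(traj: Trajectory3D, scene) -> Trajectory3D:
    """Restrict to the obstacle-field transit, x in [x_start, x_end] closed."""
    x0, x1 = scene.field_x_extent
    keep = (traj.positions[:, 0] >= x0) & (traj.positions[:, 0] <= x1)
    if not keep.any():
        raise NoTransitError(
            f"{traj.flight_id}: no samples inside field x-extent [{x0}, {x1}]")
    return replace(traj,
                   frames=traj.frames[keep],
                   positions=traj.positions[keep],
                   reprojection_error=traj.reprojection_error[keep],
                   flags=traj.flags[keep])


def excluded_zone_filter(traj: Trajectory3D, scene) -> bool:
    """True if the flight is kept; False if it entered the excluded zone.

    Discard iff any altitude strictly exceeds ceiling minus the
    excluded-zone depth (default threshold 176 mm); a sample exactly on
    the boundary is kept.
    """
    return not bool(np.any(traj.positions[:, 2] > scene.excluded_zone_floor))


def smooth(traj: Trajectory3D, smoothing="auto",
           max_interior_knots: int = 120) -> SmoothTrajectory:
    """Quintic-spline smooth a trajectory; velocities come with it."""
    return smooth_path(traj.times, traj.positions, smoothing,
                       max_interior_knots)
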