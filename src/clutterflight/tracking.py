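"""Per-camera 2D measurement: blob detection and Kalman/Munkres tracking.

The bee appears in each camera as a small dark-or-bright blob moving
over a static speckled background.  Detection subtracts a per-pixel
median background, thresholds the absolute difference and extracts
8-connected components with intensity-weighted centroids.  A single
constant-velocity Kalman filter, with detection-to-prediction
association by the Munkres (Hungarian) algorithm and gating, links the
per-frame detections into one track; frames with no acceptable
detection are coasted (predict-only) for up to ``max_coast`` frames.

One target per camera per trial is assumed (single bees are flown), but
the assignment step is kept general so spurious detections (reflections,
distractors) are handled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage import measure


@dataclass(frozen=True)
class Detection2D:
    camera_id: str
    frame_index: int
    centroid: tuple[float, float]  # (u, v) px
    area: float  # px^2
    is_distractor: bool = False  # ground-truth bookkeeping in synthetic runs


@dataclass(frozen=True)
class KalmanConfig:
    """Tuning of the constant-velocity tracker (all units pixels/frames)."""

    process_noise_accel: float = 1.0  # white-accel std, px / frame^2
    measurement_noise: float = 0.7  # px
    gate_radius: float = 25.0  # px
    max_coast: int = 10  # frames
    min_track_length: int = 12  # frames

    def __post_init__(self):
        for name in ("process_noise_accel", "measurement_noise",
                     "gate_radius", "max_coast", "min_track_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


MEASURED, COASTED = "measured", "coasted"


@dataclass
class Track2D:
    """Gap-free per-frame states (u, v, du, dv) with measured/coasted flags."""

    camera_id: str
    start_frame: int
    states: np.ndarray = field(repr=False)  # (n, 4)
    flags: list[str] = field(repr=False)

    @property
    def end_frame(self) -> int:
        return self.start_frame + len(self.states) - 1

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.start_frame, self.end_frame + 1)

    def __len__(self) -> int:
        return len(self.states)


class NoTrackError(RuntimeError):
    """No track reached the configured minimum length."""


def estimate_background(frames) -> np.ndarray:
    """Per-pixel median over an image stack (>= 3 frames)."""
    stack = np.asarray(frames, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 3:
        raise ValueError("need an image stack of at least 3 frames")
    return np.median(stack, axis=0)


def detect_blobs(frame: np.ndarray, background: np.ndarray, threshold: float,
                 min_blob_area: float = 4.0, camera_id: str = "cam",
                 frame_index: int = 0) -> list[Detection2D]:
    """Threshold |frame - background| and report blob centroids.

    Connected components (8-connectivity) with area >= ``min_blob_area``
    are returned sorted by area, largest first, with intensity-weighted
    centroids for sub-pixel accuracy.
    """
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError(f"frame {frame.shape} vs background {background.shape}")
    diff = np.abs(frame - background)
    labels = measure.label(diff > threshold, connectivity=2)
    out = []
    for region in measure.regionprops(labels, intensity_image=diff):
        if region.area < min_blob_area:
            continue
        v, u = region.centroid_weighted
        out.append(Detection2D(camera_id=camera_id, frame_index=frame_index,
                               centroid=(float(u), float(v)),
                               area=float(region.area)))
    out.sort(key=lambda d: -d.area)
    return out


def munkres_assign(cost: np.ndarray) -> dict[int, int]:
    """Minimum-cost assignment (row -> column), rectangular allowed.

    Backed by the Jonker-Volgenant solver in scipy; returns a possibly
    partial mapping covering min(n_rows, n_cols) pairs.
    """
    cost = np.atleast_2d(np.asarray(cost, dtype=float))
    if cost.size == 0:
        return {}
    if not np.all(np.isfinite(cost)):
        raise ValueError("costs must be finite")
    rows, cols = linear_sum_assignment(cost)
    return dict(zip(rows.tolist(), cols.tolist()))


def brute_force_assign(cost: np.ndarray) -> float:
    """Exhaustive minimum total assignment cost (test oracle, tiny matrices)."""
    cost = np.atleast_2d(np.asarray(cost, dtype=float))
    n, m = cost.shape
    if n <= m:
        return min(sum(cost[i, p[i]] for i in range(n))
                   for p in itertools.permutations(range(m), n))
    return brute_force_assign(cost.T)


def _kalman_matrices(config: KalmanConfig):
    F = np.array([[1.0, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0], [0, 0, 0, 1]])
    q = config.process_noise_accel ** 2
    # discrete white-noise acceleration, dt = 1 frame
    G = np.array([[0.5, 0], [0, 0.5], [1, 0], [0, 1]])
    Q = q * (G @ G.T)
    H = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])
    R = config.measurement_noise ** 2 * np.eye(2)
    return F, Q, H, R


def kalman_step(state: np.ndarray, P: np.ndarray, measurement,
                config: KalmanConfig):
    """One predict(+update) cycle; ``measurement=None`` coasts.

    Returns (state, P, predicted_position).  Exposed so a hand-computed
    single cycle can be checked against it.
    """
    F, Q, H, R = _kalman_matrices(config)
    state = F @ state
    P = F @ P @ F.T + Q
    pred = state[:2].copy()
    if measurement is not None:
        y = np.asarray(measurement, dtype=float) - H @ state
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.inv(S)
        state = state + K @ y
        P = (np.eye(4) - K @ H) @ P
    return state, P, pred


def track_single_target(detections_by_frame: dict[int, list[Detection2D]],
                        config: KalmanConfig = KalmanConfig(),
                        camera_id: str | None = None) -> Track2D:
    """Link per-frame detections into the longest single-target track.

    Gating is Euclidean: only detections within ``gate_radius`` of the
    predicted position are candidates; among gated candidates the
    Munkres assignment on Euclidean distance picks the match (with one
    live track this is the nearest gated detection).  A frame with no
    gated detection is coasted; ``max_coast`` consecutive coasts end the
    track, and tracking restarts from the next detection.  The longest
    track of at least ``min_track_length`` frames is returned, trailing
    coasted states trimmed.
    """
    frames = sorted(detections_by_frame)
    if not frames:
        raise NoTrackError("no detections at all")
    if camera_id is None:
        for f in frames:
            if detections_by_frame[f]:
                camera_id = detections_by_frame[f][0].camera_id
                break
        else:
            raise NoTrackError("no detections at all")

    tracks: list[Track2D] = []
    state = P = None
    start = None
    states: list[np.ndarray] = []
    flags: list[str] = []
    n_coast = 0

    def flush():
        nonlocal state, P, start, states, flags, n_coast
        if states:
            while flags and flags[-1] == COASTED:  # trim trailing coasts
                flags.pop()
                states.pop()
            if len(states) >= config.min_track_length:
                tracks.append(Track2D(camera_id=camera_id, start_frame=start,
                                      states=np.array(states), flags=list(flags)))
        state = P = None
        start = None
        states, flags, n_coast = [], [], 0

    all_frames = range(frames[0], frames[-1] + 1)
    for f in all_frames:
        dets = detections_by_frame.get(f, [])
        if state is None:
            if dets:
                d = max(dets, key=lambda d: d.area)
                state = np.array([d.centroid[0], d.centroid[1], 0.0, 0.0])
                P = np.diag([config.measurement_noise ** 2] * 2 +
                            [config.gate_radius ** 2] * 2)
                start = f
                states = [state.copy()]
                flags = [MEASURED]
            continue
        # predict, gate, assign
        F, Q, H, R = _kalman_matrices(config)
        pred = (F @ state)[:2]
        cand = [d for d in dets
                if np.hypot(d.centroid[0] - pred[0], d.centroid[1] - pred[1])
                <= config.gate_radius]
        meas = None
        if cand:
            cost = np.array([[np.hypot(d.centroid[0] - pred[0],
                                       d.centroid[1] - pred[1])] for d in cand]).T
            j = munkres_assign(cost)[0]
            meas = cand[j].centroid
        state, P, _ = kalman_step(state, P, meas, config)
        if meas is None:
            n_coast += 1
            flags.append(COASTED)
        else:
            n_coast = 0
            flags.append(MEASURED)
        states.append(state.copy())
        if n_coast > config.max_coast:
            flush()
    flush()

    if not tracks:
        raise NoTrackError(
            f"no track reached min_track_length={config.min_track_length}")
    return max(tracks, key=len)


def reject_displacement_outliers(track: Track2D, n_mad: float = 5.0) -> Track2D:
    """Median-absolute-deviation pass over per-frame displacements.

    A measured state whose displacement from its predecessor exceeds
    ``n_mad`` MADs of the track's displacement distribution is relabeled
    coasted and replaced by the linear interpolation of its neighbours —
    the automated stand-in for a manual track-checking step.
    """
    if len(track) < 5:
        return track
    disp = np.linalg.norm(np.diff(track.states[:, :2], axis=0), axis=1)
    med = np.median(disp)
    mad = np.median(np.abs(disp - med)) + 1e-12
    bad = np.where(disp - med > n_mad * 1.4826 * mad)[0] + 1
    if len(bad) == 0:
        return track
    states = track.states.copy()
    flags = list(track.flags)
    for i in bad:
        if 0 < i < len(states) - 1:
            states[i, :2] = 0.5 * (states[i - 1, :2] + states[i + 1, :2])
            flags[i] = COASTED
    return Track2D(camera_id=track.camera_id, start_frame=track.start_frame,
                   states=states, flags=flags)
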