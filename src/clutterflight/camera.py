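"""Pinhole stereo cameras: projection, undistortion and two-view triangulation.

The reconstruction geometry mirrors a calibrated high-speed stereo rig:
each camera is a pinhole with two radial distortion coefficients,
``x_cam = R x_world + t``, perspective division, then
``x_d = x_n (1 + k1 r^2 + k2 r^4)`` on normalized coordinates before the
focal/principal-point mapping to pixels.  Calibration estimation is out
of scope — parameters are inputs (ground truth in synthetic runs),
loaded from JSON.

Triangulation back-projects the two undistorted rays and returns the
midpoint of their common perpendicular, plus the mean reprojection
error over both views.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

FRAME_RATE = 500.0  # frames per second, global sampling rate


class BehindCameraError(ValueError):
    """World point has non-positive depth in the camera frame."""


class DegenerateGeometryError(ValueError):
    """Rays are (near-)parallel; the 3D point is unconstrained."""


@dataclass(frozen=True)
class CameraParams:
    """Calibrated camera: intrinsics, radial distortion and pose (world→camera)."""

    focal: tuple[float, float]
    principal_point: tuple[float, float]
    radial_distortion: tuple[float, float]
    rotation: tuple  # 3x3 nested tuples, world -> camera
    translation: tuple[float, float, float]  # mm
    image_size: tuple[int, int]  # (width, height) px
    camera_id: str = "cam"

    def __post_init__(self):
        R = self.R
        if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-9 or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with det +1")
        if self.focal[0] <= 0 or self.focal[1] <= 0:
            raise ValueError("focal lengths must be positive")
        if self.image_size[0] <= 0 or self.image_size[1] <= 0:
            raise ValueError("image_size must be positive")

    @property
    def R(self) -> np.ndarray:
        return np.asarray(self.rotation, dtype=float)

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.translation, dtype=float)

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates, ``-R.T @ t``."""
        return -self.R.T @ self.t

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CameraParams":
        d = json.loads(text)
        return cls(focal=tuple(d["focal"]),
                   principal_point=tuple(d["principal_point"]),
                   radial_distortion=tuple(d["radial_distortion"]),
                   rotation=tuple(tuple(r) for r in d["rotation"]),
                   translation=tuple(d["translation"]),
                   image_size=tuple(d["image_size"]),
                   camera_id=d.get("camera_id", "cam"))


@dataclass(frozen=True)
class PixelPoint:
    """A pixel-plane measurement at a given frame."""

    u: float
    v: float
    frame_index: int = 0

    @property
    def time(self) -> float:
        return self.frame_index / FRAME_RATE

    def in_frame(self, camera: CameraParams) -> bool:
        w, h = camera.image_size
        return 0 <= self.u < w and 0 <= self.v < h


def distort(xn: np.ndarray, k1: float, k2: float) -> np.ndarray:
    """Apply the radial polynomial to normalized coordinates (..., 2)."""
    r2 = np.sum(xn ** 2, axis=-1, keepdims=True)
    return xn * (1.0 + k1 * r2 + k2 * r2 ** 2)


def undistort(xd: np.ndarray, k1: float, k2: float,
              max_iter: int = 20, tol: float = 1e-12) -> np.ndarray:
    """Invert :func:`distort` by fixed-point iteration.

    Converges to < 1e-9 normalized units for the mild distortions used
    here (|k1| <= 0.2, |k2| <= 0.05).
    """
    xd = np.asarray(xd, dtype=float)
    xn = xd.copy()
    for _ in range(max_iter):
        r2 = np.sum(xn ** 2, axis=-1, keepdims=True)
        xn_new = xd / (1.0 + k1 * r2 + k2 * r2 ** 2)
        if np.max(np.abs(xn_new - xn)) < tol:
            xn = xn_new
            break
        xn = xn_new
    return xn


def project(camera: CameraParams, point_world) -> PixelPoint:
    """Project one world point (mm) to a pixel position."""
    uv = project_many(camera, np.asarray(point_world, dtype=float)[None, :])
    return PixelPoint(u=float(uv[0, 0]), v=float(uv[0, 1]))


def project_many(camera: CameraParams, points_world: np.ndarray) -> np.ndarray:
    """Vectorized projection of (n, 3) world points to (n, 2) pixels.

    Raises :class:`BehindCameraError` if any point has non-positive
    depth in the camera frame.
    """
    P = np.asarray(points_world, dtype=float)
    xc = P @ camera.R.T + camera.t
    if np.any(xc[:, 2] <= 0):
        raise BehindCameraError("point(s) behind camera")
    xn = xc[:, :2] / xc[:, 2:3]
    k1, k2 = camera.radial_distortion
    xd = distort(xn, k1, k2)
    fx, fy = camera.focal
    cx, cy = camera.principal_point
    return np.column_stack((cx + fx * xd[:, 0], cy + fy * xd[:, 1]))


def _rays(camera: CameraParams, uv: np.ndarray):
    """World-frame origins and unit directions of back-projected pixels."""
    fx, fy = camera.focal
    cx, cy = camera.principal_point
    k1, k2 = camera.radial_distortion
    xd = np.column_stack(((uv[:, 0] - cx) / fx, (uv[:, 1] - cy) / fy))
    xn = undistort(xd, k1, k2)
    d_cam = np.column_stack((xn[:, 0], xn[:, 1], np.ones(len(xn))))
    d_world = d_cam @ camera.R  # R.T @ d for each row
    d_world /= np.linalg.norm(d_world, axis=1, keepdims=True)
    return camera.center, d_world


def triangulate_many(cam_a: CameraParams, cam_b: CameraParams,
                     uv_a: np.ndarray, uv_b: np.ndarray,
                     parallel_tol: float = 1e-6):
    """Midpoint triangulation of paired pixel observations.

    Parameters are (n, 2) pixel arrays from the same frames.  Returns
    ``(points (n, 3) mm, reproj_err (n,) px)`` where the error is the
    mean over both views of the reprojection distance.  Rows whose rays
    are near-parallel (``1 - |d_a . d_b| < parallel_tol``) raise
    :class:`DegenerateGeometryError`.
    """
    uv_a = np.atleast_2d(np.asarray(uv_a, dtype=float))
    uv_b = np.atleast_2d(np.asarray(uv_b, dtype=float))
    oa, da = _rays(cam_a, uv_a)
    ob, db = _rays(cam_b, uv_b)
    # closest points on the two rays: solve for s, t in
    #   (oa + s da - ob - t db) . da = 0 ;  ... . db = 0
    w = oa - ob
    b = np.einsum("ij,ij->i", da, db)
    denom = 1.0 - b ** 2
    if np.any(denom < parallel_tol):
        raise DegenerateGeometryError("near-parallel viewing rays")
    d_w_a = da @ w
    d_w_b = db @ w
    s = (b * d_w_b - d_w_a) / denom
    t = (d_w_b - b * d_w_a) / denom
    pts = 0.5 * ((oa + s[:, None] * da) + (ob + t[:, None] * db))
    err = 0.5 * (
        np.linalg.norm(project_many(cam_a, pts) - uv_a, axis=1)
        + np.linalg.norm(project_many(cam_b, pts) - uv_b, axis=1))
    return pts, err


def triangulate(cam_a: CameraParams, cam_b: CameraParams,
                obs_a: PixelPoint, obs_b: PixelPoint):
    """Triangulate one matched pair of pixel observations.

    Returns ``(point_mm (3,), reprojection_error px)``.  The two
    observations must come from the same frame.
    """
    if obs_a.frame_index != obs_b.frame_index:
        raise ValueError(
            f"frame mismatch: {obs_a.frame_index} vs {obs_b.frame_index}")
    pts, err = triangulate_many(cam_a, cam_b,
                                np.array([[obs_a.u, obs_a.v]]),
                                np.array([[obs_b.u, obs_b.v]]))
    return pts[0], float(err[0])


def _look_at_rotation(position: np.ndarray, target: np.ndarray) -> np.ndarray:
    """World->camera rotation with +z toward ``target`` and x roughly lateral."""
    z = target - position
    z = z / np.linalg.norm(z)
    up = np.array([0.0, 0.0, 1.0])
    x = np.cross(z, up)
    if np.linalg.norm(x) < 1e-9:
        up = np.array([1.0, 0.0, 0.0])
        x = np.cross(z, up)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return np.vstack((x, y, z))


def default_rig(field_center=(575.0, 0.0, 95.0)) -> tuple[CameraParams, CameraParams]:
    """The package's synthetic stereo rig.

    Two 1280x800 cameras mounted above and beyond the up-tunnel end of
    the working section, on opposing sides laterally, both aimed at the
    obstacle-field center so they view down the length of the tunnel.
    Poses and intrinsics are fixture constants chosen to cover the
    working section with sub-millimetre triangulation noise at 0.5 px
    pixel noise; mild barrel distortion is included so the undistortion
    path is always exercised.
    """
    target = np.asarray(field_center, dtype=float)
    cams = []
    for cam_id, y_off in (("cam_a", -520.0), ("cam_b", 520.0)):
        pos = np.array([1500.0, y_off, 1000.0])
        R = _look_at_rotation(pos, target)
        t = -R @ pos
        cams.append(CameraParams(
            focal=(1500.0, 1500.0),
            principal_point=(640.0, 400.0),
            radial_distortion=(-0.08, 0.01),
            rotation=tuple(tuple(float(v) for v in row) for row in R),
            translation=tuple(float(v) for v in t),
            image_size=(1280, 800),
            camera_id=cam_id,
        ))
    return cams[0], cams[1]
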