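"""Quintic smoothing splines with GCV-selected penalty.

Trajectory coordinates are smoothed per axis with a penalized quintic
B-spline: minimize

    sum_i (y_i - f(t_i))^2 + lam * Int f'''(t)^2 dt

over quintic splines f.  The curvature-of-acceleration penalty is the
natural one for a quintic smoothing spline and leaves every polynomial
of degree <= 5 unpenalized, so lam -> 0 reproduces quintic polynomials
exactly and the analytic derivative of the fit gives velocities.

The penalty Gram matrix is computed exactly (third derivatives of
quintic B-splines are piecewise quadratic; 3-point Gauss-Legendre per
knot interval integrates their products without error).  "auto"
smoothing picks lam by generalized cross-validation,

    GCV(lam) = n * RSS(lam) / (n - tr H(lam))^2,

minimized over a log-spaced grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

DEGREE = 5

# 3-point Gauss-Legendre nodes/weights on [-1, 1]
_GL_X = np.array([-np.sqrt(3.0 / 5.0), 0.0, np.sqrt(3.0 / 5.0)])
_GL_W = np.array([5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0])


def _knot_vector(t: np.ndarray, max_interior: int) -> np.ndarray:
    """Clamped quintic knot vector with interior knots at (a subset of)
    the sample times, capped at ``max_interior`` for large series."""
    interior = t[1:-1]
    if len(interior) > max_interior:
        idx = np.unique(np.linspace(0, len(interior) - 1, max_interior).round().astype(int))
        interior = interior[idx]
    return np.concatenate((np.repeat(t[0], DEGREE + 1), interior,
                           np.repeat(t[-1], DEGREE + 1)))


def _penalty_matrix(knots: np.ndarray) -> np.ndarray:
    """Exact Gram matrix of third derivatives of the B-spline basis."""
    nb = len(knots) - DEGREE - 1
    breaks = np.unique(knots)
    P = np.zeros((nb, nb))
    c = np.eye(nb)
    basis = BSpline(knots, c.T, DEGREE, extrapolate=False)
    d3 = basis.derivative(3)
    for a, b in zip(breaks[:-1], breaks[1:]):
        half = 0.5 * (b - a)
        xs = 0.5 * (a + b) + half * _GL_X
        V = d3(xs)  # (3, nb)
        P += half * (V.T * _GL_W) @ V
    return P


@dataclass
class SmoothAxis:
    spline: BSpline
    lam: float
    residual_rms: float

    def __call__(self, t):
        return self.spline(t)

    def velocity(self, t):
        return self.spline.derivative(1)(t)


class SmoothTrajectory:
    """Per-axis quintic smoothing-spline representation of a 3D path.

    Evaluators ``position(t)`` and ``velocity(t)`` return (n, 3) arrays;
    velocity is the analytic first derivative of the fitted splines.
    """

    def __init__(self, axes: dict[str, SmoothAxis], t: np.ndarray):
        self.axes = axes
        self.t = np.asarray(t, dtype=float)

    @property
    def smoothing(self) -> dict[str, float]:
        return {k: ax.lam for k, ax in self.axes.items()}

    @property
    def residual_rms(self) -> dict[str, float]:
        return {k: ax.residual_rms for k, ax in self.axes.items()}

    def position(self, t=None) -> np.ndarray:
        t = self.t if t is None else np.asarray(t, dtype=float)
        return np.column_stack([self.axes[k](t) for k in ("x", "y", "z")])

    def velocity(self, t=None) -> np.ndarray:
        t = self.t if t is None else np.asarray(t, dtype=float)
        return np.column_stack([self.axes[k].velocity(t) for k in ("x", "y", "z")])


def fit_axis(t: np.ndarray, y: np.ndarray, smoothing="auto",
             max_interior_knots: int = 120,
             lam_grid: np.ndarray | None = None) -> SmoothAxis:
    """Fit one coordinate with a penalized quintic spline.

    ``smoothing`` is the penalty weight lam (0 gives an unpenalized
    least-squares quintic spline) or "auto" for GCV selection.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 12:
        raise ValueError(f"need >= 12 samples to smooth, got {len(t)}")
    knots = _knot_vector(t, max_interior_knots)
    B = BSpline.design_matrix(t, knots, DEGREE).toarray()
    BtB = B.T @ B
    Bty = B.T @ y
    P = _penalty_matrix(knots)
    n, nb = B.shape
    ridge = 1e-10 * np.trace(BtB) / nb * np.eye(nb)

    def solve(lam):
        M = BtB + lam * P + ridge
        cf = cho_factor(M, lower=True)
        coef = cho_solve(cf, Bty)
        # tr H = tr(B M^-1 B^T) = sum(B * (M^-1 B^T)^T)
        MiBt = cho_solve(cf, B.T)
        trH = float(np.sum(B * MiBt.T))
        return coef, trH

    def gcv_at(lam):
        coef, trH = solve(lam)
        rss = float(np.sum((B @ coef - y) ** 2))
        denom = max(n - trH, 1e-6)
        return n * rss / denom ** 2, coef

    if smoothing == "auto":
        if lam_grid is None:
            # tr(P) dwarfs tr(BtB) at high sampling rates, so the
            # effective lam range sits many decades above their ratio
            scale = np.trace(BtB) / max(np.trace(P), 1e-300)
            lam_grid = scale * np.logspace(-2, 14, 17)
        lam_grid = np.asarray(lam_grid, dtype=float)
        scores = []
        for lam in lam_grid:
            gcv, coef = gcv_at(lam)
            scores.append((gcv, lam, coef))
        best = min(scores, key=lambda s: s[0])
        # one refinement pass around the coarse minimum
        for lam in best[1] * np.logspace(-1, 1, 5)[[0, 1, 3, 4]]:
            gcv, coef = gcv_at(lam)
            if gcv < best[0]:
                best = (gcv, lam, coef)
        _, lam, coef = best
    else:
        lam = float(smoothing)
        coef, _ = solve(lam)

    resid = B @ coef - y
    return SmoothAxis(spline=BSpline(knots, coef, DEGREE),
                      lam=float(lam),
                      residual_rms=float(np.sqrt(np.mean(resid ** 2))))


def smooth_path(t: np.ndarray, positions: np.ndarray, smoothing="auto",
                max_interior_knots: int = 120) -> SmoothTrajectory:
    """Smooth an (n, 3) position series; one spline per axis."""
    positions = np.asarray(positions, dtype=float)
    axes = {k: fit_axis(t, positions[:, i], smoothing, max_interior_knots)
            for i, k in enumerate(("x", "y", "z"))}
    return SmoothTrajectory(axes, t)
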