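"""Synthetic flights, stereo observations and rendered frames.

Ground-truth generator emulating the tunnel experiment: wild-caught
bees (default 58) each assigned one obstacle-field height at random,
flying 5-13 transits (mean ~9) alternately up- and down-tunnel, half in
still air and half in a 0.54 m/s wind, filmed at 500 frames/s through
the calibrated synthetic stereo rig with pixel noise and detection
dropout.

The behavioural structure is injected so the recovery targets are
well-defined:

* route (above vs within the obstacle field) is Bernoulli with a
  per-height probability, zero for the 11-mm control field;
* ground speed is constant over a transit at a per-flight draw from a
  lognormal whose median is the condition median — still-air above-route
  0.32 m/s, times 1.23 in tailwinds, divided by 1.40 within the field —
  so ratios of group medians equal the configured ratios;
* lateral casting is a two-frequency sinusoid rescaled so the in-field
  IQR of lateral position equals a per-flight lognormal draw around the
  configured median (route and wind multipliers apply);
* altitude is a mean-reverting (coarse-grid AR(1), spline-interpolated)
  wander around the route-appropriate level, rescaled so the in-field
  altitudinal range equals a lognormal draw with median 20.9 mm.

The forward speed is decomposed as ``vx = sqrt(s^2 - vy^2)`` so the
horizontal-plane ground speed is exactly the drawn value at every
sample.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .camera import FRAME_RATE, CameraParams, project_many
from .kinematics import (DIR_DOWN, DIR_UP, ROUTE_ABOVE, ROUTE_WITHIN,
                         WIND_ON, WIND_STILL, TrialCondition, iqr)
from .scene import SceneSpec, build_scene
from .tracking import Detection2D


@dataclass(frozen=True)
class BehaviorConfig:
    """Study-condition parameters of the generator (units noted per field)."""

    n_bees: int = 58
    flights_min: int = 5
    flights_max: int = 13
    still_air_ground_speed_median: float = 0.32  # m/s, above-route still air
    route_speed_ratio: float = 1.40  # above / within
    route_excursion_ratio: float = 1.36  # above / within
    wind_excursion_ratio: float = 1.19  # wind / still
    tailwind_speed_ratio: float = 1.23  # tailwind / still (down-tunnel)
    headwind_speed_ratio: float = 1.00  # headwind matches still air
    within_still_excursion_median: float = 12.0  # mm, IQR of lateral position
    altitude_preference: float = 100.0  # mm, above-route level at low fields
    altitude_shift_by_height: tuple = ((98.0, 22.2), (127.0, 26.6))  # mm
    min_above_clearance: float = 22.0  # mm, above-route margin over field top
    altitudinal_range_median: float = 20.9  # mm, median of max-min altitude
    altitudinal_range_log_sd: float = 0.25  # lognormal spread of range draws
    p_within: tuple = ((11.0, 0.0), (40.0, 0.05), (69.0, 0.10),
                       (98.0, 0.25), (127.0, 0.55))
    casting_frequencies: tuple[float, float] = (1.8, 0.45)  # Hz
    speed_log_sd_flight: float = 0.10  # lognormal sd of per-flight speed draw
    speed_log_sd_bee: float = 0.08  # lognormal sd of per-bee speed intercept
    excursion_log_sd_flight: float = 0.12
    altitude_sd_bee: float = 6.0  # mm, per-bee altitude intercept
    wind_speed: float = 0.54  # m/s
    transit_margin: float = 60.0  # mm of path generated beyond the field
    seed: int = 0

    def __post_init__(self):
        for name in ("route_speed_ratio", "route_excursion_ratio",
                     "wind_excursion_ratio", "tailwind_speed_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        p = dict(self.p_within)
        if any(not 0 <= v <= 1 for v in p.values()):
            raise ValueError("p_within values must be probabilities")
        if p.get(11.0, 0.0) != 0.0:
            raise ValueError("the 11-mm control field admits no within-route flights")

    def p_within_for(self, h: float) -> float:
        return dict(self.p_within).get(float(h), 0.0)

    def altitude_shift_for(self, h: float) -> float:
        return dict(self.altitude_shift_by_height).get(float(h), 0.0)


@dataclass
class GroundTruthFlight:
    """True kinematics of one simulated transit."""

    cond: TrialCondition
    route: str
    times: np.ndarray = field(repr=False)
    positions: np.ndarray = field(repr=False)  # (n, 3) mm
    velocities: np.ndarray = field(repr=False)  # (n, 3) mm/s
    in_field: np.ndarray = field(repr=False)  # bool mask over samples
    true_metrics: dict = field(default_factory=dict)


def _calibrated_above_still_speed(config: BehaviorConfig) -> float:
    """Above-route still-air median speed (mm/s) such that the *pooled*
    still-air median over both routes equals the configured value.

    The configured ``still_air_ground_speed_median`` is the median over
    all still-air flights, a mixture of above-route flights and slower
    (by ``route_speed_ratio``) within-route flights; the mixture weight
    is the mean within-route probability over the five field heights
    (heights are assigned uniformly).  Solved from the lognormal mixture
    CDF.
    """
    from scipy.optimize import brentq
    from scipy.stats import norm

    target = config.still_air_ground_speed_median * 1000.0
    w = float(np.mean([p for _, p in config.p_within]))
    if w <= 0:
        return target
    sigma = float(np.hypot(config.speed_log_sd_flight, config.speed_log_sd_bee))
    log_ratio = np.log(config.route_speed_ratio)

    def mixture_cdf_at_target(log_m_above):
        za = (np.log(target) - log_m_above) / sigma
        zw = (np.log(target) - (log_m_above - log_ratio)) / sigma
        return (1 - w) * norm.cdf(za) + w * norm.cdf(zw) - 0.5

    log_m = brentq(mixture_cdf_at_target, np.log(target) - 1.0,
                   np.log(target) + 1.0)
    return float(np.exp(log_m))


def _condition_speed_median(cond: TrialCondition, route: str,
                            config: BehaviorConfig) -> float:
    """Median ground speed (mm/s) of the condition/route cell."""
    s = _calibrated_above_still_speed(config)
    wc = cond.wind_class
    if wc == "tailwind":
        s *= config.tailwind_speed_ratio
    elif wc == "headwind":
        s *= config.headwind_speed_ratio
    if route == ROUTE_WITHIN:
        s /= config.route_speed_ratio
    return s


def _condition_excursion_median(cond: TrialCondition, route: str,
                                config: BehaviorConfig) -> float:
    iq = config.within_still_excursion_median
    if route == ROUTE_ABOVE:
        iq *= config.route_excursion_ratio
    if cond.wind == WIND_ON:
        iq *= config.wind_excursion_ratio
    return iq


def _ar1_wander(n_frames: int, rng, corner_hz: float = 2.5,
                coarse_hz: float = 25.0) -> np.ndarray:
    """Smooth mean-reverting path: AR(1) on a coarse grid, cubic-splined
    to the frame rate.  Returned with zero mean, unit-free scale."""
    dt = 1.0 / coarse_hz
    n_coarse = max(int(np.ceil(n_frames / FRAME_RATE * coarse_hz)) + 4, 8)
    phi = np.exp(-2.0 * np.pi * corner_hz * dt / (2.0 * np.pi))
    x = np.empty(n_coarse)
    x[0] = rng.normal()
    eps = rng.normal(size=n_coarse - 1) * np.sqrt(1 - phi ** 2)
    for i in range(1, n_coarse):
        x[i] = phi * x[i - 1] + eps[i - 1]
    t_coarse = np.arange(n_coarse) * dt
    t_fine = np.arange(n_frames) / FRAME_RATE
    return CubicSpline(t_coarse, x)(t_fine)


def simulate_flight(cond: TrialCondition, config: BehaviorConfig,
                    scene: SceneSpec, rng,
                    bee_speed_mult: float = 1.0,
                    bee_altitude_offset: float = 0.0) -> GroundTruthFlight:
    """Draw one ground-truth transit of the obstacle field."""
    h = scene.field_height
    route = (ROUTE_WITHIN if rng.random() < config.p_within_for(h)
             else ROUTE_ABOVE)

    # --- per-flight targets ------------------------------------------
    s_target = (_condition_speed_median(cond, route, config)
                * bee_speed_mult
                * np.exp(rng.normal(0.0, config.speed_log_sd_flight)))
    iqr_target = (_condition_excursion_median(cond, route, config)
                  * np.exp(rng.normal(0.0, config.excursion_log_sd_flight)))
    range_target = (config.altitudinal_range_median
                    * np.exp(rng.normal(0.0, config.altitudinal_range_log_sd)))

    x0, x1 = scene.field_x_extent
    span = (x1 - x0) + 2.0 * config.transit_margin
    duration = span / (0.92 * s_target)  # ample: vx <= s_target
    n = int(np.ceil(duration * FRAME_RATE)) + 2
    t = np.arange(n) / FRAME_RATE

    # --- lateral casting ---------------------------------------------
    f1, f2 = config.casting_frequencies
    ph = rng.uniform(0, 2 * np.pi, size=2)
    a2 = rng.uniform(0.3, 0.7)
    y_shape = np.sin(2 * np.pi * f1 * t + ph[0]) + a2 * np.sin(2 * np.pi * f2 * t + ph[1])
    vy_shape = (2 * np.pi * f1 * np.cos(2 * np.pi * f1 * t + ph[0])
                + a2 * 2 * np.pi * f2 * np.cos(2 * np.pi * f2 * t + ph[1]))
    if route == ROUTE_WITHIN:
        corridor = rng.choice(scene.corridor_y_centers)
        y_center = corridor + rng.normal(0.0, 2.0)
    else:
        y_center = float(np.clip(rng.normal(0.0, 15.0), -45.0, 45.0))

    sign = 1.0 if cond.direction == DIR_UP else -1.0
    x_entry = (x0 - config.transit_margin if sign > 0
               else x1 + config.transit_margin)

    # iterate the casting scale: the in-field window depends on vx,
    # which depends on the scaled vy (second-order coupling)
    k = iqr_target / max(iqr(y_shape), 1e-9)
    in_field = np.ones(n, dtype=bool)
    for _ in range(3):
        vy = k * vy_shape
        vy = np.clip(vy, -0.85 * s_target, 0.85 * s_target)
        vx = sign * np.sqrt(s_target ** 2 - vy ** 2)
        x = x_entry + np.concatenate(([0.0], np.cumsum(
            0.5 * (vx[1:] + vx[:-1]) / FRAME_RATE)))
        in_field = (x >= x0) & (x <= x1)
        realized = iqr(y_shape[in_field]) if in_field.sum() >= 12 else iqr(y_shape)
        k = iqr_target / max(realized, 1e-9)
    vy = np.clip(k * vy_shape, -0.85 * s_target, 0.85 * s_target)
    vx = sign * np.sqrt(s_target ** 2 - vy ** 2)
    x = x_entry + np.concatenate(([0.0], np.cumsum(
        0.5 * (vx[1:] + vx[:-1]) / FRAME_RATE)))
    in_field = (x >= x0) & (x <= x1)
    y = y_center + k * (y_shape - np.median(y_shape[in_field]))

    # --- altitude ------------------------------------------------------
    if route == ROUTE_ABOVE:
        z_level = max(config.altitude_preference + config.altitude_shift_for(h),
                      h + config.min_above_clearance)
        z_lo, z_hi = h + 2.0, scene.excluded_zone_floor - 4.0
    else:
        z_level = min(config.altitude_preference, 0.7 * h)
        z_lo, z_hi = 5.0, h - 2.0
    z_level = float(np.clip(z_level + bee_altitude_offset,
                            z_lo + range_target, z_hi - range_target / 2.0))
    wander = _ar1_wander(n, rng)
    w_in = wander[in_field]
    z_scale = range_target / max(np.ptp(w_in), 1e-9)
    z_spline = CubicSpline(t, z_level + z_scale * (wander - np.median(w_in)))
    z = z_spline(t)
    # keep the flight legal for its route (shift, preserving the range)
    z_field = z[in_field]
    if z_field.min() < z_lo:
        z = z + (z_lo - z_field.min())
    elif z_field.max() > z_hi:
        z = z - (z_field.max() - z_hi)
    vz = z_spline(t, 1)

    positions = np.column_stack((x, y, z))
    velocities = np.column_stack((vx, vy, vz))
    m_in = in_field
    true_metrics = {
        "route": route,
        "ground_speed": float(s_target),
        "lateral_excursion": float(iqr(y[m_in])),
        "altitude_floor": float(np.median(z[m_in])),
        "altitude_range": float(np.ptp(z[m_in])),
        "altitude_obstacle": float(np.median(z[m_in]) - h),
    }
    return GroundTruthFlight(cond=cond, route=route, times=t,
                             positions=positions, velocities=velocities,
                             in_field=m_in, true_metrics=true_metrics)


def observe_flight(flight: GroundTruthFlight,
                   rig: tuple[CameraParams, CameraParams],
                   noise: float = 0.5, dropout: float = 0.02,
                   distractor_rate: float = 0.0,
                   rng=None) -> dict[str, dict[int, list[Detection2D]]]:
    """Project a flight through the rig into per-camera detection lists.

    Isotropic pixel noise is added to every projection, each detection
    is independently deleted with probability ``dropout``, out-of-frame
    projections are dropped, and distractor detections are injected at
    ``distractor_rate`` per frame per camera (flagged for scoring).
    """
    rng = np.random.default_rng() if rng is None else rng
    out = {}
    n = len(flight.times)
    for cam in rig:
        uv = project_many(cam, flight.positions)
        uv = uv + rng.normal(0.0, noise, uv.shape) if noise > 0 else uv
        keep = rng.random(n) >= dropout
        w, hpx = cam.image_size
        keep &= (uv[:, 0] >= 0) & (uv[:, 0] < w) & (uv[:, 1] >= 0) & (uv[:, 1] < hpx)
        frames: dict[int, list[Detection2D]] = {}
        for i in np.flatnonzero(keep):
            frames.setdefault(int(i), []).append(Detection2D(
                camera_id=cam.camera_id, frame_index=int(i),
                centroid=(float(uv[i, 0]), float(uv[i, 1])), area=25.0))
        if distractor_rate > 0:
            n_extra = rng.poisson(distractor_rate, n)
            for i in np.flatnonzero(n_extra):
                for _ in range(n_extra[i]):
                    frames.setdefault(int(i), []).append(Detection2D(
                        camera_id=cam.camera_id, frame_index=int(i),
                        centroid=(float(rng.uniform(0, w)),
                                  float(rng.uniform(0, hpx))),
                        area=9.0, is_distractor=True))
        out[cam.camera_id] = frames
    return out


def render_frames(flight: GroundTruthFlight, cam: CameraParams,
                  texture_seed: int = 0, frame_indices=None,
                  image_size: tuple[int, int] = (160, 120),
                  blob_sigma: float = 2.0, blob_amplitude: float = 120.0):
    """Render a small image stack: static speckled background plus a
    moving Gaussian blob at the projected bee position.

    The full-resolution projection is mapped into a reduced
    ``image_size`` raster to keep fixtures small; returns
    ``(frames (k, h, w), background (h, w), centroids_px (k, 2))`` where
    centroids are in the reduced raster (NaN when the bee is absent).
    """
    rng = np.random.default_rng(texture_seed)
    w_full, h_full = cam.image_size
    w, h = image_size
    background = 60.0 + 40.0 * (rng.random((h, w)) > 0.5)
    if frame_indices is None:
        frame_indices = range(0, len(flight.times), max(1, len(flight.times) // 20))
    uv_full = project_many(cam, flight.positions)
    sx, sy = w / w_full, h / h_full
    frames, centroids = [], []
    yy, xx = np.mgrid[0:h, 0:w]
    for i in frame_indices:
        img = background.copy()
        if 0 <= i < len(uv_full):
            u, v = uv_full[i, 0] * sx, uv_full[i, 1] * sy
            img += blob_amplitude * np.exp(
                -((xx - u) ** 2 + (yy - v) ** 2) / (2 * blob_sigma ** 2))
            centroids.append((u, v))
        else:
            centroids.append((np.nan, np.nan))
        frames.append(img)
    return np.array(frames), background, np.array(centroids)


@dataclass
class SyntheticExperiment:
    """Everything one seeded run of the tunnel experiment produces."""

    config: BehaviorConfig
    scenes: dict[float, SceneSpec]
    flights: list[GroundTruthFlight]
    observations: list[dict] | None  # aligned with flights; None if not observed

    def truth_table(self):
        import pandas as pd
        rows = []
        for fl in self.flights:
            c = fl.cond
            rows.append({"bee_id": c.bee_id, "flight_number": c.flight_number,
                         "wind": c.wind, "direction": c.direction,
                         "wind_class": c.wind_class,
                         "field_height": c.field_height, **fl.true_metrics})
        return pd.DataFrame(rows)


def simulate_experiment(config: BehaviorConfig | None = None,
                        rig: tuple[CameraParams, CameraParams] | None = None,
                        noise: float = 0.5, dropout: float = 0.02,
                        observe: bool = True) -> SyntheticExperiment:
    """Run the full seeded experiment design.

    Each bee receives one randomly drawn obstacle-field height and a
    number of flights uniform on [flights_min, flights_max]; wind is
    blocked (first half of a bee's flights in one condition, second half
    in the other, starting condition randomized) and flight direction
    alternates, so a bee with wind experiences both head- and tailwinds.
    """
    config = BehaviorConfig() if config is None else config
    rng = np.random.default_rng(config.seed)
    if rig is None and observe:
        from .camera import default_rig
        rig = default_rig()
    heights = sorted(dict(config.p_within))
    scenes = {h: build_scene(h) for h in heights}

    flights: list[GroundTruthFlight] = []
    observations = [] if observe else None
    for b in range(config.n_bees):
        bee_id = f"bee{b:03d}"
        h = float(rng.choice(heights))
        n_fl = int(rng.integers(config.flights_min, config.flights_max + 1))
        first_wind = rng.random() < 0.5
        first_dir = rng.random() < 0.5
        speed_mult = float(np.exp(rng.normal(0.0, config.speed_log_sd_bee)))
        alt_off = float(rng.normal(0.0, config.altitude_sd_bee))
        for j in range(n_fl):
            in_first_block = j < n_fl // 2
            wind = WIND_ON if (in_first_block == first_wind) else WIND_STILL
            direction = DIR_UP if ((j % 2 == 0) == first_dir) else DIR_DOWN
            cond = TrialCondition(bee_id=bee_id, flight_number=j + 1,
                                  wind=wind, direction=direction,
                                  field_height=h)
            fl = simulate_flight(cond, config, scenes[h], rng,
                                 bee_speed_mult=speed_mult,
                                 bee_altitude_offset=alt_off)
            flights.append(fl)
            if observe:
                observations.append(observe_flight(fl, rig, noise=noise,
                                                   dropout=dropout, rng=rng))
    return SyntheticExperiment(config=config, scenes=scenes, flights=flights,
                               observations=observations)
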