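"""Flight-performance metrics and route classification for one transit.

Per flight: median altitude above the floor, altitudinal range
(max - min), altitude relative to the obstacle tops
(``altitude_obstacle = altitude_floor - field_height``), the categorical
route — "above" iff altitude_obstacle > 0, "within" iff <= 0 (boundary
assigned to within) — median horizontal-plane ground speed, lateral
excursion as the interquartile range of lateral position (type-7 linear
quantile interpolation, the numpy default; IQR values depend on the
convention so it is fixed here), entry-to-exit speed change over 10%
end-windows, and minimum obstacle clearance with a body-radius collision
flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scene import SceneSpec, distance_to_nearest_column
from .smoothing import SmoothTrajectory

ROUTE_ABOVE, ROUTE_WITHIN = "above", "within"
WIND_STILL, WIND_ON = "still", "wind"
DIR_UP, DIR_DOWN = "up_tunnel", "down_tunnel"

#: Approximate honeybee body half-width used only by the collision flag, mm.
DEFAULT_BODY_RADIUS = 6.0


@dataclass(frozen=True)
class TrialCondition:
    """One flight's experimental condition."""

    bee_id: str
    flight_number: int
    wind: str  # still | wind
    direction: str  # up_tunnel | down_tunnel
    field_height: float

    def __post_init__(self):
        if self.wind not in (WIND_STILL, WIND_ON):
            raise ValueError(f"wind must be still|wind, got {self.wind}")
        if self.direction not in (DIR_UP, DIR_DOWN):
            raise ValueError(f"bad direction {self.direction}")

    @property
    def wind_class(self) -> str:
        """still_up / still_down / headwind / tailwind.

        With the fans on, an up-tunnel flight faces a headwind and a
        down-tunnel flight rides a tailwind.
        """
        if self.wind == WIND_STILL:
            return "still_up" if self.direction == DIR_UP else "still_down"
        return "headwind" if self.direction == DIR_UP else "tailwind"


@dataclass(frozen=True)
class FlightMetrics:
    altitude_floor: float  # mm, median z
    altitude_range: float  # mm, max z - min z
    altitude_obstacle: float  # mm, altitude_floor - field_height
    route: str  # above | within
    ground_speed: float  # mm/s, median horizontal speed
    lateral_excursion: float  # mm, IQR of y
    speed_change_entry_exit: float  # mm/s
    min_obstacle_clearance: float  # mm (inf if always above the field)
    collision: bool


def iqr(values) -> float:
    """Interquartile range, type-7 (linear) quantile interpolation."""
    q1, q3 = np.percentile(np.asarray(values, dtype=float), [25, 75])
    return float(q3 - q1)


def compute_metrics(traj: SmoothTrajectory, scene: SceneSpec,
                    cond: TrialCondition,
                    body_radius: float = DEFAULT_BODY_RADIUS) -> FlightMetrics:
    """Evaluate the performance metrics of one clipped, kept transit."""
    if len(traj.t) < 12:
        raise ValueError("need >= 12 samples")
    pos = traj.position()
    vel = traj.velocity()
    z = pos[:, 2]
    y = pos[:, 1]
    horiz = np.hypot(vel[:, 0], vel[:, 1])

    altitude_floor = float(np.median(z))
    altitude_obstacle = altitude_floor - scene.field_height
    route = ROUTE_ABOVE if altitude_obstacle > 0 else ROUTE_WITHIN

    k = max(1, int(round(0.10 * len(horiz))))
    speed_change = float(np.mean(horiz[-k:]) - np.mean(horiz[:k]))

    clearances = np.array([distance_to_nearest_column(scene, p) for p in pos])
    min_clear = float(np.min(clearances))

    return FlightMetrics(
        altitude_floor=altitude_floor,
        altitude_range=float(z.max() - z.min()),
        altitude_obstacle=altitude_obstacle,
        route=route,
        ground_speed=float(np.median(horiz)),
        lateral_excursion=iqr(y),
        speed_change_entry_exit=speed_change,
        min_obstacle_clearance=min_clear,
        collision=bool(min_clear <= body_radius),
    )


def required_airspeed(ground_speed: float, wind_speed_signed: float) -> float:
    """Air-relative speed needed to hold a ground speed in a given wind.

    ``wind_speed_signed`` is positive for a tailwind, negative for a
    headwind, zero in still air; a negative result means the bee must
    fly backwards relative to the air (e.g. holding the preferred
    0.32 m/s ground speed in a 0.54 m/s tailwind requires -0.22 m/s).
    """
    return ground_speed - wind_speed_signed
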