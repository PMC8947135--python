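"""Flight-tunnel and obstacle-field geometry.

World coordinate frame (fixed for the whole package): x runs along the
tunnel axis (down-tunnel positive), y is lateral with the tunnel
centerline at 0, z is altitude above the floor.  All lengths in mm,
right-handed axes.

The working section is a 200 x 191 x 1150 mm tunnel whose middle holds a
field of vertical columns (7 mm diameter) arranged in three longitudinal
rows of five, leaving two unobstructed 57-mm corridors between the rows.
Fields of five heights (11, 40, 69, 98, 127 mm) are used; a 15-mm band
below the ceiling is the "excluded zone" — flights entering it are
discarded by the trajectory pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

#: The five obstacle-field heights used in the experiment, mm.
FIELD_HEIGHTS = (11.0, 40.0, 69.0, 98.0, 127.0)

#: Sentinel returned by :func:`distance_to_nearest_column` when the query
#: point is above every column top.
ABOVE_FIELD = float("inf")


@dataclass(frozen=True)
class SceneSpec:
    """Tunnel plus obstacle-field geometry shared by every stage.

    ``column_positions`` holds the (x, y) axis location of each column;
    the middle row sits on the centerline (y = 0) and the outer rows are
    offset so the edge-to-edge gap between adjacent rows equals
    ``corridor_width``.
    """

    field_height: float
    tunnel_width: float = 200.0
    tunnel_height: float = 191.0
    tunnel_length: float = 1150.0
    excluded_zone_depth: float = 15.0
    column_diameter: float = 7.0
    n_rows: int = 3
    n_cols_per_row: int = 5
    corridor_width: float = 57.0
    field_x_extent: tuple[float, float] = field(default=None)  # type: ignore[assignment]
    column_positions: tuple[tuple[float, float], ...] = field(default=None)  # type: ignore[assignment]

    @property
    def column_radius(self) -> float:
        return self.column_diameter / 2.0

    @property
    def excluded_zone_floor(self) -> float:
        """Altitude above which a flight is discarded (default 176 mm)."""
        return self.tunnel_height - self.excluded_zone_depth

    @property
    def is_control(self) -> bool:
        """True for the shortest field, too short for bees to fly within."""
        return self.field_height <= 11.0

    @property
    def row_y_positions(self) -> tuple[float, ...]:
        """Row axis y-coordinates: centerline row plus symmetric outer rows."""
        pitch = self.corridor_width + self.column_diameter
        half = (self.n_rows - 1) // 2
        return tuple(pitch * k for k in range(-half, self.n_rows - half))

    @property
    def corridor_y_centers(self) -> tuple[float, ...]:
        """Centerlines of the unobstructed corridors between adjacent rows."""
        rows = self.row_y_positions
        return tuple((a + b) / 2.0 for a, b in zip(rows[:-1], rows[1:]))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SceneSpec":
        d = json.loads(text)
        d["field_x_extent"] = tuple(d["field_x_extent"])
        d["column_positions"] = tuple(tuple(p) for p in d["column_positions"])
        return cls(**d)


def build_scene(field_height: float, **overrides) -> SceneSpec:
    """Construct a :class:`SceneSpec` for one obstacle-field height.

    The default layout centers the field longitudinally over the middle
    40% of the tunnel with columns evenly spaced, and places the middle
    row on the centerline.  Any ``SceneSpec`` field may be overridden by
    keyword.

    Raises
    ------
    ValueError
        If ``field_height`` is not positive, or reaches into the
        excluded zone below the ceiling, or any dimension is
        non-positive.
    """
    proto = SceneSpec(field_height=field_height, **{
        k: v for k, v in overrides.items()
        if k not in ("field_x_extent", "column_positions")
    })
    for name in ("tunnel_width", "tunnel_height", "tunnel_length",
                 "column_diameter", "corridor_width"):
        if getattr(proto, name) <= 0:
            raise ValueError(f"{name} must be positive")
    if field_height <= 0:
        raise ValueError("field_height must be positive")
    if field_height >= proto.tunnel_height - proto.excluded_zone_depth:
        raise ValueError(
            f"field_height {field_height} mm reaches the excluded zone "
            f"(ceiling {proto.tunnel_height} mm minus "
            f"{proto.excluded_zone_depth} mm)")

    extent = overrides.get("field_x_extent")
    if extent is None:
        center = proto.tunnel_length / 2.0
        span = 0.40 * proto.tunnel_length
        extent = (center - span / 2.0, center + span / 2.0)
    extent = (float(extent[0]), float(extent[1]))

    positions = overrides.get("column_positions")
    if positions is None:
        xs = np.linspace(extent[0], extent[1], proto.n_cols_per_row)
        positions = tuple(
            (float(x), float(y))
            for y in SceneSpec(field_height=field_height,
                               corridor_width=proto.corridor_width,
                               column_diameter=proto.column_diameter,
                               n_rows=proto.n_rows).row_y_positions
            for x in xs
        )

    scene = SceneSpec(field_height=field_height,
                      **{**{k: v for k, v in overrides.items()
                            if k not in ("field_x_extent", "column_positions")},
                         "field_x_extent": extent,
                         "column_positions": tuple(positions)})
    half_w = scene.tunnel_width / 2.0
    for x, y in scene.column_positions:
        if not (0 <= x <= scene.tunnel_length and abs(y) <= half_w):
            raise ValueError(f"column at ({x}, {y}) outside tunnel footprint")
    return scene


def ceiling_clearance(scene: SceneSpec) -> float:
    """Free height between the obstacle tops and the ceiling (mm)."""
    return scene.tunnel_height - scene.field_height


def distance_to_nearest_column(scene: SceneSpec, point) -> float:
    """Horizontal clearance from ``point`` to the nearest column surface.

    Only columns that reach the point's altitude count; a point above the
    field top has no obstacle at its level and gets the ``ABOVE_FIELD``
    sentinel (+inf).  A point inside a column yields a negative value
    down to ``-column_radius`` on the axis.
    """
    x, y, z = (float(c) for c in point)
    if z > scene.field_height:
        return ABOVE_FIELD
    cols = np.asarray(scene.column_positions)
    d = np.hypot(cols[:, 0] - x, cols[:, 1] - y)
    return float(d.min() - scene.column_radius)
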