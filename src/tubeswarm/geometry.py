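"""Trapezoidal tube geometry and middle/edge region partition.

A tube is a trapezoidal channel cut between two straight walls.  Fish enter
through the wide (entrance) opening and leave through the narrow (exit)
opening; the tube x-axis points along the exit direction.  The interior is
partitioned into a *middle region* -- the rectangle obtained by sweeping the
narrow exit opening back along the tube axis -- and two residual triangles,
the *left-edge* and *right-edge* regions.

Angle convention
----------------
``theta_l`` and ``theta_r`` are the signed angles measured from each wall to
the tube x-axis, in degrees.  For a symmetric converging tube with included
(opening) angle ``phi`` this gives ``theta_l = +phi/2`` on the left wall and
``theta_r = -phi/2`` on the right wall, so the included angle is always
``|theta_r - theta_l|``.  With this convention the inward unit normal of the
left wall is ``(-sin(theta_l), -cos(theta_l))`` in tube-local coordinates and
that of the right wall is ``(sin(theta_r), cos(theta_r))``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import shapely
import yaml
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "GeometryError",
    "RegionLabel",
    "TubeGeometry",
    "included_angle",
    "cosine_of_included_angle",
    "build_region_polygons",
    "classify_point",
    "classify_points",
    "load_geometry",
    "save_geometry",
]


class GeometryError(ValueError):
    """Raised for degenerate or self-intersecting tube configurations."""


class RegionLabel(str, Enum):
    MIDDLE = "middle"
    LEFT_EDGE = "left_edge"
    RIGHT_EDGE = "right_edge"
    OUTSIDE = "outside"


def _as_segment(seg) -> np.ndarray:
    a = np.asarray(seg, dtype=float)
    if a.shape != (2, 2):
        raise GeometryError(f"segment must be a pair of 2-D points, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise GeometryError("segment contains non-finite coordinates")
    if np.allclose(a[0], a[1]):
        raise GeometryError("degenerate segment: endpoints coincide")
    return a


def _signed_angle_deg(v: np.ndarray, ref: np.ndarray) -> float:
    """Signed angle (degrees) of vector ``v`` measured from ``ref``."""
    cross = ref[0] * v[1] - ref[1] * v[0]
    dot = float(np.dot(ref, v))
    return math.degrees(math.atan2(cross, dot))


@dataclass(frozen=True)
class TubeGeometry:
    """A trapezoidal tube in (pixel) plane coordinates.

    Walls are stored as 2x2 arrays of endpoints ordered entrance-end first.
    ``entrance_line`` joins the entrance ends of the walls, ``exit_line`` the
    exit ends, so the four segments close a simple trapezoid.
    """

    tube_id: str
    wall_left: np.ndarray
    wall_right: np.ndarray
    entrance_line: np.ndarray = field(init=False)
    exit_line: np.ndarray = field(init=False)

    def __post_init__(self):
        wl = _as_segment(self.wall_left)
        wr = _as_segment(self.wall_right)
        object.__setattr__(self, "wall_left", wl)
        object.__setattr__(self, "wall_right", wr)
        object.__setattr__(self, "entrance_line", np.array([wl[0], wr[0]]))
        object.__setattr__(self, "exit_line", np.array([wl[1], wr[1]]))
        self._validate()

    # -- derived frame ----------------------------------------------------
    @property
    def entrance_mid(self) -> np.ndarray:
        return self.entrance_line.mean(axis=0)

    @property
    def exit_mid(self) -> np.ndarray:
        return self.exit_line.mean(axis=0)

    @property
    def x_axis_direction(self) -> np.ndarray:
        """Unit vector of the exit direction (tube x-axis)."""
        d = self.exit_mid - self.entrance_mid
        n = np.linalg.norm(d)
        if n == 0:
            raise GeometryError("entrance and exit midpoints coincide")
        return d / n

    @property
    def y_axis_direction(self) -> np.ndarray:
        x = self.x_axis_direction
        return np.array([-x[1], x[0]])  # right-hand rule

    @property
    def theta_l(self) -> float:
        """Angle from the left wall to the tube x-axis, degrees (signed)."""
        d = self.wall_left[1] - self.wall_left[0]
        return -_signed_angle_deg(d, self.x_axis_direction)

    @property
    def theta_r(self) -> float:
        d = self.wall_right[1] - self.wall_right[0]
        return -_signed_angle_deg(d, self.x_axis_direction)

    # -- local coordinates -------------------------------------------------
    def to_local(self, points) -> np.ndarray:
        """Map ambient points to tube-local (x along axis, y left) coords."""
        p = np.atleast_2d(np.asarray(points, dtype=float)) - self.entrance_mid
        R = np.column_stack([self.x_axis_direction, self.y_axis_direction])
        return p @ R

    def from_local(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        R = np.column_stack([self.x_axis_direction, self.y_axis_direction])
        return p @ R.T + self.entrance_mid

    @property
    def length(self) -> float:
        """Tube height: axial distance from entrance to exit, px."""
        return float(np.linalg.norm(self.exit_mid - self.entrance_mid))

    @property
    def exit_width(self) -> float:
        return float(np.linalg.norm(self.exit_line[1] - self.exit_line[0]))

    @property
    def entrance_width(self) -> float:
        return float(np.linalg.norm(self.entrance_line[1] - self.entrance_line[0]))

    # -- polygons ----------------------------------------------------------
    @property
    def trapezoid(self) -> Polygon:
        poly = Polygon([self.wall_left[0], self.wall_left[1],
                        self.wall_right[1], self.wall_right[0]])
        return poly

    def _validate(self):
        poly = self.trapezoid
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError("tube walls do not form a simple trapezoid")
        x = self.x_axis_direction  # raises if degenerate
        for name, wall in (("left", self.wall_left), ("right", self.wall_right)):
            d = wall[1] - wall[0]
            if abs(float(np.dot(d / np.linalg.norm(d), x))) < 1e-12:
                raise GeometryError(f"{name} wall is parallel to the entrance line")
        inc = abs(self.theta_r - self.theta_l)
        if not (0.0 <= inc < 90.0):
            raise GeometryError(
                f"included angle {inc:.2f} deg outside [0, 90)")
        if self.exit_width <= 0:
            raise GeometryError("zero-width exit opening")

    # -- walls as shapely lines -------------------------------------------
    def wall_line(self, side: str) -> LineString:
        wall = self.wall_left if side == "l" else self.wall_right
        return LineString(wall)

    def inward_wall_normal(self, side: str) -> np.ndarray:
        """Unit normal of wall ``side`` pointing into the tube interior."""
        wall = self.wall_left if side == "l" else self.wall_right
        d = wall[1] - wall[0]
        d = d / np.linalg.norm(d)
        n = np.array([-d[1], d[0]])
        mid = wall.mean(axis=0)
        centroid = np.asarray(self.trapezoid.centroid.coords[0])
        if np.dot(n, centroid - mid) < 0:
            n = -n
        return n

    def wall_distance(self, point) -> tuple[float, str]:
        """Perpendicular distance to the nearer wall and its side label."""
        p = Point(np.asarray(point, dtype=float))
        dl = self.wall_line("l").distance(p)
        dr = self.wall_line("r").distance(p)
        return (dl, "l") if dl <= dr else (dr, "r")


def included_angle(geometry: TubeGeometry) -> float:
    """Opening angle of the tube, ``|theta_r - theta_l|`` in degrees."""
    return abs(geometry.theta_r - geometry.theta_l)


def cosine_of_included_angle(geometry: TubeGeometry, ndigits: int | None = None) -> float:
    """Cosine of the included angle; ``ndigits`` applies report rounding."""
    c = math.cos(math.radians(included_angle(geometry)))
    return round(c, ndigits) if ndigits is not None else c


def build_region_polygons(geometry: TubeGeometry) -> dict[str, Polygon]:
    """Partition the trapezoid into middle rectangle and two edge triangles.

    The middle region is the exit opening swept along the tube axis down to
    the entrance line; the left/right edge regions are the residual pieces
    between that rectangle and each wall.  The three polygons tile the
    trapezoid exactly.
    """
    half = geometry.exit_width / 2.0
    L = geometry.length
    local_trap = Polygon(geometry.to_local(np.array(geometry.trapezoid.exterior.coords)[:-1]))
    big = max(geometry.entrance_width, geometry.exit_width) * 2 + L
    mid_band = Polygon([(-big, -half), (big, -half), (big, half), (-big, half)])
    middle = local_trap.intersection(mid_band)
    left = local_trap.difference(mid_band).intersection(
        Polygon([(-big, half), (big, half), (big, big), (-big, big)]))
    right = local_trap.difference(mid_band).intersection(
        Polygon([(-big, -big), (big, -big), (big, -half), (-big, -half)]))

    def back(poly: Polygon) -> Polygon:
        if poly.is_empty:
            return Polygon()
        return Polygon(geometry.from_local(np.array(poly.exterior.coords)[:-1]))

    return {"middle": back(middle), "left_edge": back(left), "right_edge": back(right)}


def classify_point(p, geometry: TubeGeometry,
                   polygons: dict[str, Polygon] | None = None) -> RegionLabel:
    """Label a single point; boundary ties go to the middle region."""
    return classify_points(np.asarray(p, dtype=float)[None, :], geometry, polygons)[0]


def classify_points(points, geometry: TubeGeometry,
                    polygons: dict[str, Polygon] | None = None) -> list[RegionLabel]:
    """Vectorised region labels for an (n, 2) array of points.

    Points on a region boundary are assigned middle first, then left edge,
    then right edge, so every point receives exactly one label.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if polygons is None:
        polygons = build_region_polygons(geometry)
    labels: list[RegionLabel] = [RegionLabel.OUTSIDE] * len(pts)
    x, y = pts[:, 0], pts[:, 1]
    order = [(RegionLabel.MIDDLE, polygons["middle"]),
             (RegionLabel.LEFT_EDGE, polygons["left_edge"]),
             (RegionLabel.RIGHT_EDGE, polygons["right_edge"])]
    unassigned = np.ones(len(pts), dtype=bool)
    for label, poly in order:
        if poly.is_empty:
            continue
        shapely.prepare(poly)
        hit = shapely.intersects_xy(poly, x, y) & unassigned
        for idx in np.nonzero(hit)[0]:
            labels[idx] = label
        unassigned &= ~hit
    return labels


# ---------------------------------------------------------------------------
# configuration I/O

def load_geometry(path) -> TubeGeometry:
    """Load a tube geometry from a JSON or YAML config.

    The config carries ``tube_id`` and the two wall segments as
    ``[[x_entrance, y_entrance], [x_exit, y_exit]]`` pairs.
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    try:
        geom = TubeGeometry(
            tube_id=str(cfg["tube_id"]),
            wall_left=np.asarray(cfg["wall_left"], dtype=float),
            wall_right=np.asarray(cfg["wall_right"], dtype=float),
        )
    except KeyError as exc:
        raise GeometryError(f"geometry config missing key {exc}") from exc
    return geom


def save_geometry(geometry: TubeGeometry, path) -> None:
    path = Path(path)
    cfg = {
        "tube_id": geometry.tube_id,
        "wall_left": geometry.wall_left.tolist(),
        "wall_right": geometry.wall_right.tolist(),
        "included_angle_deg": round(included_angle(geometry), 6),
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
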