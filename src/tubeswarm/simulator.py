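"""Discrete-time agent-based model of a fish swarm crossing a trapezoidal tube.

Each fish updates its velocity synchronously every frame as the sum of four
terms::

    v_i(t+1) = v0 + v_s,i(t) + v_n,i(t) + v_w,i(t)

* ``v0`` -- constant forward drive along the tube axis (the shared tendency
  to swim out of the tube);
* ``v_s,i`` -- following: half the attraction gain times the offset to the
  centroid of the fish ahead of i inside its field of view;
* ``v_n,i`` -- nearest-neighbour zones: repulsion closer than ``d1``,
  nothing in the parallel band [d1, d2], attraction beyond ``d2``;
* ``v_w,i`` -- wall avoidance: when the perpendicular distance to the nearer
  wall is at most ``d3``, a push of magnitude ``b * d_w`` along that wall's
  inward normal.

The field of view is a circular sector of half-angle ``fov_half_angle``
(default 90 deg, i.e. a 180-degree field) and radius ``fov_range`` centred
on the fish's heading.  Positions advance by ``p += v * dt`` with dt of one
frame; fish crossing the exit line are marked passed and frozen (their last
position is still emitted, mirroring how the tracker parks lost fish, but
they no longer influence the dynamics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point

from .fitting import predict_number_ratio, predict_speed_ratio
from .geometry import TubeGeometry, build_region_polygons, included_angle
from .trajectory import FrameTable

__all__ = [
    "ModelParams",
    "FishState",
    "SwarmState",
    "NeighborSet",
    "neighbors_in_fov",
    "swarm_following_velocity",
    "nearest_neighbor_velocity",
    "wall_avoidance_velocity",
    "step_swarm",
    "simulate",
    "initialize_swarm",
    "sample_in_polygon",
]


@dataclass(frozen=True)
class ModelParams:
    """Tunable parameters of the movement model (pixel/frame units)."""

    v0: float = 3.0            # forward drive, px/frame
    k: float = 0.1             # attraction gain, 1/frame
    b: float = 0.8             # wall gain, 1/frame
    d1: float = 12.0           # repulsion threshold, px
    d2: float = 36.0           # attraction threshold, px
    d3: float = 18.0           # wall-avoidance threshold, px
    fov_half_angle: float = 90.0   # deg; 90 -> 180-degree field of view
    fov_range: float = 200.0       # px
    dt: float = 1.0                # frames
    n_fish: int = 30
    heading_noise_deg: float = 15.0  # initial heading spread
    init_wall_margin: float = 5.0    # px; ~a body width of clearance at start
    seed: int | None = None

    def __post_init__(self):
        positives = {"v0": self.v0, "k": self.k, "b": self.b, "d1": self.d1,
                     "d2": self.d2, "d3": self.d3, "fov_range": self.fov_range,
                     "dt": self.dt}
        for name, val in positives.items():
            if not val > 0:
                raise ValueError(f"{name} must be positive, got {val}")
        if not self.d1 < self.d2:
            raise ValueError("zone thresholds must satisfy d1 < d2")
        if not 0 < self.fov_half_angle <= 180:
            raise ValueError("fov_half_angle must be in (0, 180] degrees")
        if self.n_fish < 1:
            raise ValueError("need at least one fish")


@dataclass(frozen=True)
class FishState:
    id: int
    position: np.ndarray
    velocity: np.ndarray

    @property
    def heading(self) -> np.ndarray:
        n = float(np.linalg.norm(self.velocity))
        if n > 0:
            return self.velocity / n
        return np.array([1.0, 0.0])


@dataclass
class SwarmState:
    """Positions/velocities of all fish plus who has already passed."""

    positions: np.ndarray          # (n, 2) px
    velocities: np.ndarray         # (n, 2) px/frame
    active: np.ndarray             # (n,) bool; False once passed the exit
    ids: np.ndarray = field(default=None)
    time: int = 0

    def __post_init__(self):
        n = len(self.positions)
        if self.ids is None:
            self.ids = np.arange(1, n + 1)
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.active = np.asarray(self.active, dtype=bool)

    @property
    def n_fish(self) -> int:
        return len(self.positions)

    @property
    def n_passed(self) -> int:
        return int((~self.active).sum())

    def fish(self, i: int) -> FishState:
        return FishState(id=int(self.ids[i]), position=self.positions[i].copy(),
                         velocity=self.velocities[i].copy())

    def heading(self, i: int, default: np.ndarray) -> np.ndarray:
        v = self.velocities[i]
        n = float(np.linalg.norm(v))
        return v / n if n > 0 else default


@dataclass(frozen=True)
class NeighborSet:
    """Everything fish i perceives: FOV members, front centroid, nearest fish
    and the nearer wall."""

    ids: np.ndarray                # indices (0-based) of fish in the FOV
    m: int                         # |N_i|
    n_front: int                   # fish ahead of i along the tube axis
    front_centroid: np.ndarray | None   # p_c, px
    nearest_index: int | None
    d_n: float                     # distance to nearest FOV fish, px (inf if none)
    d_w: float                     # distance to nearer wall, px
    wall_side: str                 # 'l' or 'r'


def neighbors_in_fov(i: int, swarm: SwarmState, params: ModelParams,
                     geometry: TubeGeometry) -> NeighborSet:
    """Perceived neighbourhood of fish i.

    Membership: active fish j != i within ``fov_range`` whose bearing from
    i's heading is at most ``fov_half_angle``; a fish with zero velocity
    looks along the tube axis.  Front members are those whose tube-local x
    is >= that of fish i; ties in the nearest-fish distance break to the
    lowest id.
    """
    axis = geometry.x_axis_direction
    p_i = swarm.positions[i]
    heading = swarm.heading(i, default=axis)
    offsets = swarm.positions - p_i
    dist = np.linalg.norm(offsets, axis=1)
    candidate = swarm.active.copy()
    candidate[i] = False
    candidate &= dist <= params.fov_range
    cos_lim = math.cos(math.radians(params.fov_half_angle))
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_bearing = np.where(dist > 0, offsets @ heading / dist, 1.0)
    candidate &= cos_bearing >= cos_lim - 1e-12
    members = np.nonzero(candidate)[0]

    d_w, wall_side = geometry.wall_distance(p_i)
    if members.size == 0:
        return NeighborSet(ids=members, m=0, n_front=0, front_centroid=None,
                           nearest_index=None, d_n=math.inf,
                           d_w=d_w, wall_side=wall_side)

    local_x = geometry.to_local(swarm.positions)[:, 0]
    front = members[local_x[members] >= local_x[i]]
    centroid = swarm.positions[front].mean(axis=0) if front.size else None
    d_members = dist[members]
    nearest = members[np.lexsort((members, d_members))[0]]  # ties -> lowest id
    return NeighborSet(ids=members, m=int(members.size), n_front=int(front.size),
                       front_centroid=centroid, nearest_index=int(nearest),
                       d_n=float(dist[nearest]), d_w=d_w, wall_side=wall_side)


def swarm_following_velocity(i: int, swarm: SwarmState, neighbors: NeighborSet,
                             params: ModelParams) -> np.ndarray:
    """Pull toward the centroid of the fish ahead: ``0.5 k (p_c - p_i)``."""
    if neighbors.n_front == 0:
        return np.zeros(2)
    return 0.5 * params.k * (neighbors.front_centroid - swarm.positions[i])


def nearest_neighbor_velocity(i: int, swarm: SwarmState, neighbors: NeighborSet,
                              params: ModelParams) -> np.ndarray:
    """Zonal response to the nearest perceived fish.

    Repulsion (``-k (p_n - p_i)``) inside ``d1``, attraction
    (``+k (p_n - p_i)``) beyond ``d2``, zero in the parallel band and when
    no fish is perceived.
    """
    if neighbors.nearest_index is None:
        return np.zeros(2)
    offset = swarm.positions[neighbors.nearest_index] - swarm.positions[i]
    if neighbors.d_n < params.d1:
        return -params.k * offset
    if neighbors.d_n > params.d2:
        return params.k * offset
    return np.zeros(2)


def wall_avoidance_velocity(i: int, swarm: SwarmState, params: ModelParams,
                            geometry: TubeGeometry,
                            check_inside: bool = True) -> np.ndarray:
    """Inward push of magnitude ``b * d_w`` when within ``d3`` of a wall.

    The push is directed along the nearer wall's inward unit normal (for the
    left wall ``(-sin theta_l, -cos theta_l)`` in tube-local coordinates).
    """
    p_i = swarm.positions[i]
    if check_inside and not geometry.trapezoid.covers(Point(p_i)):
        raise ValueError(f"fish {i} at {p_i} is outside the tube")
    d_w, side = geometry.wall_distance(p_i)
    if d_w > params.d3:
        return np.zeros(2)
    return params.b * d_w * geometry.inward_wall_normal(side)


def step_swarm(swarm: SwarmState, params: ModelParams,
               geometry: TubeGeometry) -> SwarmState:
    """One synchronous update of every active fish.

    All four velocity components are evaluated on the state at time t, then
    positions advance together; fish whose new tube-local x reaches the exit
    are marked passed and frozen.
    """
    axis = geometry.x_axis_direction
    v0_vec = params.v0 * axis
    new_v = swarm.velocities.copy()
    for i in range(swarm.n_fish):
        if not swarm.active[i]:
            new_v[i] = 0.0
            continue
        nb = neighbors_in_fov(i, swarm, params, geometry)
        v_s = swarm_following_velocity(i, swarm, nb, params)
        v_n = nearest_neighbor_velocity(i, swarm, nb, params)
        if nb.d_w <= params.d3:
            v_w = params.b * nb.d_w * geometry.inward_wall_normal(nb.wall_side)
        else:
            v_w = np.zeros(2)
        new_v[i] = v0_vec + v_s + v_n + v_w
    new_p = swarm.positions.copy()
    new_p[swarm.active] += new_v[swarm.active] * params.dt
    new_active = swarm.active.copy()
    exited = geometry.to_local(new_p)[:, 0] >= geometry.length
    newly_passed = swarm.active & exited
    # freeze passed fish at the exit-crossing position with zero velocity
    new_v[newly_passed] = 0.0
    new_active[newly_passed] = False
    return SwarmState(positions=new_p, velocities=new_v, active=new_active,
                      ids=swarm.ids.copy(), time=swarm.time + 1)


# ---------------------------------------------------------------------------
# initialization and the full run

def sample_in_polygon(polygon, n: int, rng: np.random.Generator,
                      max_tries: int = 10_000, exclude=None) -> np.ndarray:
    """Uniform points inside a shapely polygon by rejection sampling.

    ``exclude`` optionally names a region (e.g. a wall buffer) whose points
    are rejected as well.
    """
    if n == 0:
        return np.empty((0, 2))
    if polygon.is_empty or polygon.area <= 0:
        raise ValueError("cannot place fish in an empty region")
    if exclude is not None and polygon.difference(exclude).area <= 0:
        raise ValueError("exclusion zone covers the whole region")
    minx, miny, maxx, maxy = polygon.bounds
    out = []
    tries = 0
    while len(out) < n:
        m = max(4 * (n - len(out)), 16)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(polygon, xs, ys)
        if exclude is not None:
            keep &= ~shapely.intersects_xy(exclude, xs, ys)
        out.extend(np.column_stack([xs[keep], ys[keep]]))
        tries += 1
        if tries > max_tries:
            raise RuntimeError("rejection sampling failed to converge")
    return np.asarray(out[:n])


def initialize_swarm(params: ModelParams, geometry: TubeGeometry,
                     rng: np.random.Generator) -> SwarmState:
    """Random initial swarm reproducing the measured region structure.

    Fish counts are split between middle and edge regions according to the
    count-ratio law at this tube's opening angle, and initial speeds are
    scaled region-wise by the speed-ratio law (edge fish start at ``v0``,
    middle fish faster by the predicted ratio).  Positions are uniform in
    the assigned region polygon, keeping ``init_wall_margin`` (about a fish
    body width) of clearance from the walls; headings point down-tube with
    Gaussian spread.
    """
    theta = included_angle(geometry)
    polys = build_region_polygons(geometry)
    n = params.n_fish
    r_n = predict_number_ratio(theta)
    r_s = predict_speed_ratio(theta)
    edge_usable = (not polys["left_edge"].is_empty and polys["left_edge"].area > 1e-9)
    n_middle = int(round(n * r_n / (1.0 + r_n))) if edge_usable else n
    n_middle = min(max(n_middle, 0), n)
    n_edge = n - n_middle
    n_left = (n_edge + 1) // 2
    n_right = n_edge - n_left

    wall_buffer = None
    if params.init_wall_margin > 0:
        wall_buffer = shapely.unary_union(
            [geometry.wall_line("l"), geometry.wall_line("r")]
        ).buffer(params.init_wall_margin)
    pos = [sample_in_polygon(polys["middle"], n_middle, rng, exclude=wall_buffer)]
    if n_left:
        pos.append(sample_in_polygon(polys["left_edge"], n_left, rng, exclude=wall_buffer))
    if n_right:
        pos.append(sample_in_polygon(polys["right_edge"], n_right, rng, exclude=wall_buffer))
    positions = np.vstack(pos)

    speeds = np.concatenate([
        np.full(n_middle, params.v0 * r_s),
        np.full(n_edge, params.v0),
    ])
    angles = np.deg2rad(rng.normal(0.0, params.heading_noise_deg, n))
    axis, yax = geometry.x_axis_direction, geometry.y_axis_direction
    headings = (np.cos(angles)[:, None] * axis + np.sin(angles)[:, None] * yax)
    velocities = speeds[:, None] * headings
    return SwarmState(positions=positions, velocities=velocities,
                      active=np.ones(n, dtype=bool))


def _state_to_frame(state: SwarmState, frame: int) -> FrameTable:
    v = state.velocities
    df = pd.DataFrame({
        "number": state.ids,
        "x": state.positions[:, 0],
        "y": state.positions[:, 1],
        "speed_x": np.abs(v[:, 0]),
        "speed_y": v[:, 1],
        "speed": np.hypot(v[:, 0], v[:, 1]),
    })
    return FrameTable(frame=frame, data=df)


def simulate(params: ModelParams, geometry: TubeGeometry, n_steps: int,
             seed: int | None = None,
             return_states: bool = False):
    """Run the movement model and emit one frame table per step.

    Passed fish stay in the output frozen at their exit position (speed 0),
    so every frame carries ``n_fish`` rows.  With ``return_states`` the raw
    ``SwarmState`` sequence is returned alongside the frame tables.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    state = initialize_swarm(params, geometry, rng)
    frames = [_state_to_frame(state, 0)]
    states = [state]
    for t in range(1, n_steps + 1):
        state = step_swarm(state, params, geometry)
        frames.append(_state_to_frame(state, t))
        if return_states:
            states.append(state)
    if return_states:
        return frames, states
    return frames
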