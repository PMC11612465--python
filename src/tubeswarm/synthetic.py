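"""Synthetic trajectory and summary generators with known ground truth.

The generators emulate the statistical structure of the measured tables --
prescribed middle/edge occupancy, region-wise speed levels and the two
angle-ratio laws -- so every pipeline stage can be tested end to end without
the original video data.  Counts are exact (the requested split is realized
every frame); speeds carry optional truncated-normal noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm
from shapely.geometry import Point

from .geometry import TubeGeometry, build_region_polygons
from .simulator import sample_in_polygon
from .trajectory import FrameTable

__all__ = [
    "SyntheticSpec",
    "make_tube_fixture",
    "tube_fixture",
    "generate_frames",
    "generate_summary_dataset",
]

#: Default canvas: exit opening and tube height, px (order of the real setup).
DEFAULT_OPENING_WIDTH = 120.0
DEFAULT_LENGTH = 600.0


def make_tube_fixture(included_angle_deg: float,
                      opening_width: float = DEFAULT_OPENING_WIDTH,
                      length: float = DEFAULT_LENGTH,
                      tube_id: str | None = None) -> TubeGeometry:
    """Symmetric trapezoidal tube with the requested opening angle.

    The tube is axis-aligned with the entrance at x=0, the exit opening of
    ``opening_width`` at x=``length``, and walls tilted by half the included
    angle each side, so ``included_angle`` returns the requested value.
    """
    phi = float(included_angle_deg)
    if not (0.0 <= phi < 90.0):
        raise ValueError(f"included angle {phi} deg outside [0, 90)")
    if opening_width <= 0 or length <= 0:
        raise ValueError("opening_width and length must be positive")
    half_exit = opening_width / 2.0
    half_entrance = half_exit + length * math.tan(math.radians(phi / 2.0))
    wall_left = [[0.0, half_entrance], [length, half_exit]]
    wall_right = [[0.0, -half_entrance], [length, -half_exit]]
    return TubeGeometry(tube_id=tube_id or f"synthetic-{phi:g}deg",
                        wall_left=wall_left, wall_right=wall_right)


def tube_fixture(tube_id: str, **kwargs) -> TubeGeometry:
    """Named fixture for one of the eight experimental tubes (A..H)."""
    from .datasets import TUBE_ANGLES_DEG
    if tube_id not in TUBE_ANGLES_DEG:
        raise KeyError(f"unknown tube {tube_id!r}; choose from {sorted(TUBE_ANGLES_DEG)}")
    return make_tube_fixture(TUBE_ANGLES_DEG[tube_id], tube_id=tube_id, **kwargs)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for frame tables with prescribed region structure."""

    geometry: TubeGeometry
    n_fish: int = 16
    n_frames: int = 1
    target_ratio_n: float = 3.0    # middle/edge fish count ratio
    target_ratio_s: float = 1.12   # middle/edge mean-speed ratio
    edge_speed: float = 7.42       # mean edge-region speed, px/frame
    speed_noise: float = 0.0       # truncated-normal sigma, px/frame
    placement_jitter: float = 0.0  # px of position jitter (resampled in-region)
    seed: int | None = None

    def __post_init__(self):
        if self.target_ratio_n <= 0 or self.target_ratio_s <= 0:
            raise ValueError("target ratios must be positive")
        if self.n_fish < 2 or self.n_frames < 1:
            raise ValueError("need at least two fish and one frame")
        if self.edge_speed <= 0:
            raise ValueError("edge_speed must be positive")

    @property
    def n_middle(self) -> int:
        return int(round(self.n_fish * self.target_ratio_n / (1 + self.target_ratio_n)))

    @property
    def n_edge(self) -> int:
        return self.n_fish - self.n_middle

    @property
    def middle_speed(self) -> float:
        return self.edge_speed * self.target_ratio_s


def _draw_speeds(mean: float, sigma: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return np.full(n, mean)
    a = (0.0 - mean) / sigma  # truncate at zero: speeds are magnitudes
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sigma, size=n, random_state=rng)


def generate_frames(spec: SyntheticSpec) -> list[FrameTable]:
    """Frame tables realizing the spec's occupancy and speed structure.

    Every frame places exactly ``n_middle`` fish uniformly in the middle
    region and ``n_edge`` in the edge triangles (split as evenly as the
    integer count allows), with per-region speeds whose expectation matches
    the target speed ratio.  Velocity components point down-tube so each row
    is self-consistent (``speed = hypot(speed_x, speed_y)``).
    """
    polys = build_region_polygons(spec.geometry)
    n_edge = spec.n_edge
    if n_edge > 0 and (polys["left_edge"].is_empty or polys["left_edge"].area <= 0):
        raise ValueError("edge quota infeasible: edge regions have zero area")
    n_left = (n_edge + 1) // 2
    n_right = n_edge - n_left
    rng = np.random.default_rng(spec.seed)
    axis, yax = spec.geometry.x_axis_direction, spec.geometry.y_axis_direction

    tables = []
    for frame in range(1, spec.n_frames + 1):
        chunks = [sample_in_polygon(polys["middle"], spec.n_middle, rng)]
        if n_left:
            chunks.append(sample_in_polygon(polys["left_edge"], n_left, rng))
        if n_right:
            chunks.append(sample_in_polygon(polys["right_edge"], n_right, rng))
        positions = np.vstack(chunks)
        if spec.placement_jitter > 0:
            regions = ([polys["middle"]] * spec.n_middle
                       + [polys["left_edge"]] * n_left
                       + [polys["right_edge"]] * n_right)
            for idx, region in enumerate(regions):
                for _ in range(100):
                    cand = positions[idx] + rng.normal(0, spec.placement_jitter, 2)
                    if region.covers(Point(cand)):
                        positions[idx] = cand
                        break
        speeds = np.concatenate([
            _draw_speeds(spec.middle_speed, spec.speed_noise, spec.n_middle, rng),
            _draw_speeds(spec.edge_speed, spec.speed_noise, n_edge, rng),
        ])
        bearing = np.deg2rad(rng.uniform(-45, 45, spec.n_fish))
        vel = speeds[:, None] * (np.cos(bearing)[:, None] * axis
                                 + np.sin(bearing)[:, None] * yax)
        df = pd.DataFrame({
            "number": np.arange(1, spec.n_fish + 1),
            "x": positions[:, 0],
            "y": positions[:, 1],
            "speed_x": np.abs(vel[:, 0]),
            "speed_y": vel[:, 1],
            "speed": speeds,
        })
        tables.append(FrameTable(frame=frame, data=df))
    return tables


def generate_summary_dataset(angles_deg, alpha: float, beta: float,
                             slope: float, intercept: float,
                             noise: float = 0.0,
                             seed: int | None = None) -> pd.DataFrame:
    """Tube summaries drawn from the two angle-ratio laws plus noise.

    ``ratio_s`` gets additive Gaussian noise; ``ratio_n`` gets multiplicative
    log-normal noise (Gaussian on the log scale), matching how each law is
    fitted.  Returns a summary-schema DataFrame for fit-recovery tests.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size < 2:
        raise ValueError("need at least two angles")
    if np.any((angles < 0) | (angles >= 90)):
        raise ValueError("angles must lie in [0, 90) degrees")
    rng = np.random.default_rng(seed)
    cos = np.cos(np.deg2rad(angles))
    ratio_s = slope * cos + intercept + rng.normal(0, noise, angles.size)
    ratio_n = np.exp(alpha * cos - beta + rng.normal(0, noise, angles.size))
    return pd.DataFrame({
        "tube_id": [f"S{i}" for i in range(angles.size)],
        "ratio_s": ratio_s,
        "ratio_n": ratio_n,
        "angle_deg": angles,
        "cosine": cos,
    })
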