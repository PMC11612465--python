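"""Middle/edge region statistics and occupancy density curves.

For each frame the fish inside the tube are split into the middle region and
the (pooled left+right) edge region; the mean combined speed and the head
count of each region give the frame's speed ratio ``ratio_s = V_middle /
V_edge`` and count ratio ``ratio_n = N_middle / N_edge``.  When a region is
empty or its mean speed is zero the corresponding ratio is defined as 0 --
the convention used in the measured tables.  Per-tube summaries average the
per-frame ratios over a selected frame window (mean of ratios, not ratio of
means; the measured six-tube summary pins this choice down).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .geometry import (RegionLabel, TubeGeometry, build_region_polygons,
                       classify_points, cosine_of_included_angle, included_angle)
from .trajectory import FrameTable, drop_flagged

__all__ = [
    "RegionFrameStats",
    "TubeSummary",
    "DensityCurve",
    "frame_region_stats",
    "summarize_tube",
    "kde_1d",
    "occupancy_fraction",
    "stats_to_dataframe",
]


@dataclass(frozen=True)
class RegionFrameStats:
    """Region speed/count statistics of a single frame."""

    frame: int
    V_middle: float
    V_edge: float
    ratio_s: float
    N_middle: int
    N_edge: int
    ratio_n: float


@dataclass(frozen=True)
class TubeSummary:
    """Window-averaged ratios of one tube plus its opening angle."""

    tube_id: str
    mean_ratio_s: float
    mean_ratio_n: float
    angle_deg: float
    cosine: float


@dataclass(frozen=True)
class DensityCurve:
    """1-D kernel density of fish positions along one axis."""

    axis: str
    grid: np.ndarray
    density: np.ndarray

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def peak_position(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])


def _zero_safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def frame_region_stats(table: FrameTable, geometry: TubeGeometry,
                       polygons=None, exclude_anomalies: bool = True) -> RegionFrameStats:
    """Compute one frame's middle/edge speeds, counts and their ratios.

    Fish classified outside the tube (e.g. parked tracker defaults) and rows
    failing the speed-consistency check are excluded before averaging.
    """
    if table.n_fish == 0:
        raise ValueError("empty frame table")
    clean = drop_flagged(table) if exclude_anomalies else table
    labels = np.array([lab.value for lab in
                       classify_points(clean.positions(), geometry, polygons)])
    speeds = clean.speeds()
    in_middle = labels == RegionLabel.MIDDLE.value
    in_edge = ((labels == RegionLabel.LEFT_EDGE.value)
               | (labels == RegionLabel.RIGHT_EDGE.value))
    n_mid, n_edge = int(in_middle.sum()), int(in_edge.sum())
    v_mid = float(speeds[in_middle].mean()) if n_mid else 0.0
    v_edge = float(speeds[in_edge].mean()) if n_edge else 0.0
    return RegionFrameStats(
        frame=table.frame,
        V_middle=v_mid,
        V_edge=v_edge,
        ratio_s=_zero_safe_ratio(v_mid, v_edge),
        N_middle=n_mid,
        N_edge=n_edge,
        ratio_n=_zero_safe_ratio(float(n_mid), float(n_edge)),
    )


def summarize_tube(stats: list[RegionFrameStats] | pd.DataFrame,
                   frames, geometry: TubeGeometry | None = None,
                   angle_deg: float | None = None,
                   tube_id: str = "") -> TubeSummary:
    """Average per-frame ratios over a frame window.

    ``frames`` selects the window; the summary is the arithmetic mean of the
    per-frame ``ratio_s`` and ``ratio_n`` over it.  The tube angle comes from
    ``geometry`` or, when only tabulated statistics are available, from
    ``angle_deg``.
    """
    df = stats_to_dataframe(stats) if not isinstance(stats, pd.DataFrame) else stats
    window = df[df["frame"].isin(list(frames))]
    missing = set(frames) - set(window["frame"])
    if missing:
        raise ValueError(f"frames {sorted(missing)} not present in statistics")
    if window.empty:
        raise ValueError("empty frame window")
    if geometry is not None:
        angle = included_angle(geometry)
        cos = cosine_of_included_angle(geometry)
        tube_id = tube_id or geometry.tube_id
    elif angle_deg is not None:
        angle = float(angle_deg)
        cos = float(np.cos(np.deg2rad(angle)))
    else:
        raise ValueError("need geometry or angle_deg")
    return TubeSummary(
        tube_id=tube_id,
        mean_ratio_s=float(window["ratio_s"].mean()),
        mean_ratio_n=float(window["ratio_n"].mean()),
        angle_deg=angle,
        cosine=cos,
    )


def stats_to_dataframe(stats: list[RegionFrameStats]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in stats],
                        columns=["frame", "V_middle", "V_edge", "ratio_s",
                                 "N_middle", "N_edge", "ratio_n"])


# ---------------------------------------------------------------------------
# density curves

_MIN_BANDWIDTH = 1.0  # px; fallback for degenerate (constant) samples


def kde_1d(positions, axis: str = "x", bandwidth="auto",
           grid_size: int = 512) -> DensityCurve:
    """Gaussian kernel density of 1-D positions on a regular grid.

    ``bandwidth`` is either ``"auto"`` (Silverman's rule) or a fixed kernel
    width in pixels.  The grid spans the data plus six bandwidths on each
    side so the truncated curve still integrates to one to ~1e-6.
    """
    x = np.asarray(positions, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least two positions")
    std = float(np.std(x, ddof=1))
    if bandwidth == "auto":
        if std == 0:
            h = _MIN_BANDWIDTH
        else:
            iqr = float(np.subtract(*np.percentile(x, [75, 25])))
            spread = min(std, iqr / 1.34) if iqr > 0 else std
            h = 0.9 * spread * x.size ** (-1 / 5)  # Silverman
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    grid = np.linspace(x.min() - 6 * h, x.max() + 6 * h, grid_size)
    if std > 0:
        kde = gaussian_kde(x, bw_method=h / std)
        density = kde(grid)
    else:
        # all points identical: a single Gaussian bump of width h
        density = np.exp(-0.5 * ((grid - x[0]) / h) ** 2) / (h * np.sqrt(2 * np.pi))
    return DensityCurve(axis=axis, grid=grid, density=density)


def occupancy_fraction(tables: list[FrameTable], geometry: TubeGeometry,
                       exclude_anomalies: bool = True) -> float:
    """Fraction of in-tube fish-frames spent in the middle region."""
    if not tables:
        raise ValueError("no frame tables")
    polygons = build_region_polygons(geometry)
    n_mid = n_in = 0
    for t in tables:
        clean = drop_flagged(t) if exclude_anomalies else t
        labels = classify_points(clean.positions(), geometry, polygons)
        for lab in labels:
            if lab == RegionLabel.OUTSIDE:
                continue
            n_in += 1
            if lab == RegionLabel.MIDDLE:
                n_mid += 1
    if n_in == 0:
        raise ValueError("no observations inside the tube")
    return n_mid / n_in
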