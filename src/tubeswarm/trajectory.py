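"""Per-frame fish observation tables and their CSV round trip.

A *frame table* holds one video frame's worth of tracked fish: position in
pixels plus the tracker's per-axis speeds in pixels/frame.  ``speed_x`` is
stored as a magnitude (the tracking pipeline reports the absolute value of
the x-velocity) while ``speed_y`` keeps its sign; ``speed`` is the combined
magnitude of both components.  Tracker glitches occasionally produce rows
whose speed column contradicts its components, so the module also provides a
row-level consistency check used to exclude such rows from region averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FRAME_TABLE_COLUMNS",
    "FrameTableError",
    "FrameTable",
    "combined_speed",
    "finite_difference_velocity",
    "flag_anomalies",
    "read_frame_tables",
    "write_frame_tables",
    "frames_to_dataframe",
]

#: CSV schema for frame tables (one row per fish per frame).
FRAME_TABLE_COLUMNS = ["number", "x", "y", "speed_x", "speed_y", "speed", "frame"]

#: Components larger than this (px/frame) are treated as tracking glitches.
DEFAULT_MAX_SPEED = 100.0

#: Allowed |hypot(speed_x, speed_y) - speed| after 2-dp rounding.
SPEED_CONSISTENCY_TOL = 0.01


class FrameTableError(ValueError):
    """Raised for malformed frame-table files or inconsistent tables."""


@dataclass
class FrameTable:
    """Observations of all tracked fish at a single frame."""

    frame: int
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        missing = [c for c in FRAME_TABLE_COLUMNS[:-1] if c not in self.data.columns]
        if missing:
            raise FrameTableError(f"frame table missing columns {missing}")
        ids = self.data["number"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            dupes = sorted(set(int(i) for i in ids[pd.Series(ids).duplicated()]))
            raise FrameTableError(f"duplicate fish ids in frame {self.frame}: {dupes}")
        self.data = self.data.reset_index(drop=True)

    @property
    def n_fish(self) -> int:
        return len(self.data)

    def positions(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(dtype=float)

    def speeds(self) -> np.ndarray:
        return self.data["speed"].to_numpy(dtype=float)


def combined_speed(speed_x, speed_y):
    """Magnitude of the two speed components, ``hypot(speed_x, speed_y)``.

    Accepts scalars or arrays; raises for non-finite input.
    """
    sx = np.asarray(speed_x, dtype=float)
    sy = np.asarray(speed_y, dtype=float)
    if not (np.all(np.isfinite(sx)) and np.all(np.isfinite(sy))):
        raise ValueError("non-finite speed component")
    out = np.hypot(sx, sy)
    return float(out) if out.ndim == 0 else out


def finite_difference_velocity(positions, frame_gap: float = 1.0) -> np.ndarray:
    """Per-step velocities of an ordered track, px/frame.

    ``positions`` is an (n, 2) array sampled every ``frame_gap`` frames.
    Velocity at step i>=1 is the displacement from i-1 divided by the gap;
    the first sample's velocity is backfilled from the second so the output
    stays aligned with the input.
    """
    p = np.asarray(positions, dtype=float)
    if p.ndim != 2 or p.shape[0] < 2:
        raise ValueError("need at least two position samples")
    if frame_gap <= 0:
        raise ValueError("frame_gap must be positive")
    v = np.empty_like(p)
    v[1:] = np.diff(p, axis=0) / frame_gap
    v[0] = v[1]
    return v


def flag_anomalies(table: FrameTable,
                   max_speed: float = DEFAULT_MAX_SPEED,
                   tol: float = SPEED_CONSISTENCY_TOL) -> list[tuple[int, str]]:
    """Return (fish_id, reason) pairs for rows failing the speed checks.

    A row is anomalous when its printed combined speed disagrees with
    ``hypot(speed_x, speed_y)`` by more than ``tol`` after 2-dp rounding, or
    when either component exceeds ``max_speed``.
    """
    flagged: list[tuple[int, str]] = []
    df = table.data
    for _, row in df.iterrows():
        fish = int(row["number"])
        sx, sy, s = float(row["speed_x"]), float(row["speed_y"]), float(row["speed"])
        recomputed = round(float(np.hypot(sx, sy)), 2)
        if abs(recomputed - round(s, 2)) > tol:
            flagged.append((fish, f"speed {s:.2f} inconsistent with components ({recomputed:.2f})"))
        elif max(abs(sx), abs(sy)) > max_speed:
            flagged.append((fish, f"component speed exceeds {max_speed:g} px/frame"))
    return flagged


def drop_flagged(table: FrameTable, **kwargs) -> FrameTable:
    """Copy of ``table`` with anomalous rows removed."""
    bad = {fish for fish, _ in flag_anomalies(table, **kwargs)}
    keep = ~table.data["number"].isin(bad)
    return FrameTable(frame=table.frame, data=table.data[keep].copy())


# ---------------------------------------------------------------------------
# CSV I/O

def frames_to_dataframe(tables: list[FrameTable]) -> pd.DataFrame:
    rows = []
    for t in tables:
        df = t.data.copy()
        df["frame"] = t.frame
        rows.append(df[FRAME_TABLE_COLUMNS])
    return pd.concat(rows, ignore_index=True)


def dataframe_to_frames(df: pd.DataFrame) -> list[FrameTable]:
    tables = []
    for frame, grp in df.groupby("frame", sort=True):
        tables.append(FrameTable(frame=int(frame), data=grp.drop(columns=["frame"])))
    counts = {t.n_fish for t in tables}
    if len(counts) > 1:
        raise FrameTableError(f"fish count varies across frames: {sorted(counts)}")
    return tables


def read_frame_tables(path) -> list[FrameTable]:
    """Read a frame-table CSV into per-frame tables, sorted by frame."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FrameTableError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in FRAME_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FrameTableError(f"{path}: missing columns {missing}")
    if df.empty:
        raise FrameTableError(f"{path}: no observations")
    bad = df[FRAME_TABLE_COLUMNS].isna().any(axis=1)
    if bad.any():
        raise FrameTableError(f"{path}: unparseable values in rows {list(df.index[bad])}")
    return dataframe_to_frames(df)


def write_frame_tables(tables: list[FrameTable], path, ndigits: int = 2) -> None:
    """Write tables as CSV, rounding coordinates/speeds to ``ndigits`` dp."""
    df = frames_to_dataframe(tables).copy()
    for col in ["x", "y", "speed_x", "speed_y", "speed"]:
        df[col] = df[col].round(ndigits)
    df["number"] = df["number"].astype(int)
    df["frame"] = df["frame"].astype(int)
    df.to_csv(path, index=False, float_format=f"%.{ndigits}f")
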