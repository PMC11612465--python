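"""Bundled observation tables from the trapezoidal-tube experiments.

Three small tables from the published tube study ship with the package so
every pipeline stage can be exercised against measured values without any
download: one 16-fish frame table from Tube A, the full per-frame region
statistics of Tube A, and the six-tube summary (middle/edge speed and count
ratios with each tube's opening angle).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .trajectory import FrameTable, read_frame_tables

__all__ = [
    "TUBE_ANGLES_DEG",
    "FRAMES_PER_TUBE",
    "TUBE_A_FRAME_WINDOW",
    "load_tube_a_frame37",
    "load_tube_a_region_stats",
    "load_tube_summaries",
]

#: Opening angle (degrees) of each of the eight experimental tubes.
TUBE_ANGLES_DEG = {
    "A": 29.05, "B": 5.52, "C": 34.12, "D": 22.03,
    "E": 23.84, "F": 51.00, "G": 36.32, "H": 19.48,
}

#: Number of frame tables extracted per tube in the study (total 79).
FRAMES_PER_TUBE = {
    "A": 18, "B": 10, "C": 10, "D": 7, "E": 10, "F": 7, "G": 10, "H": 7,
}

#: Frames of Tube A in which all 16 fish met the swarm-passage requirement.
TUBE_A_FRAME_WINDOW = (28, 37, 46)


def _data_path(name: str):
    return resources.files("tubeswarm.data").joinpath(name)


def load_tube_a_frame37() -> FrameTable:
    """The 16-fish frame table recorded at frame 37 of Tube A.

    Row 9 is a known tracker glitch (huge components, zero combined speed)
    kept on purpose as an anomaly-handling test case.
    """
    with resources.as_file(_data_path("tube_a_frame37.csv")) as p:
        return read_frame_tables(p)[0]


def load_tube_a_region_stats() -> pd.DataFrame:
    """Per-frame middle/edge speed and count statistics for Tube A."""
    with resources.as_file(_data_path("tube_a_region_stats.csv")) as p:
        return pd.read_csv(p)


def load_tube_summaries() -> pd.DataFrame:
    """Six-tube summary: mean ratios, opening angle and its cosine."""
    with resources.as_file(_data_path("tube_summaries.csv")) as p:
        return pd.read_csv(p)
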