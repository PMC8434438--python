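"""Depth-frame containers and the depth-CSV on-disk format.

A recording is a folder of CSV files, one frame per file, one CSV row per
image row, values in metres with 3-decimal precision.  Missing depth
(camera holes) is encoded as 0, a non-physical distance.  Negative or
non-numeric cells are mapped to the hole marker with a warning rather
than rejected, since vendor exports contain such sentinels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

HOLE = 0.0  # depth value marking missing data

DEFAULT_SHAPE = (180, 320)  # rows x cols of the recording system


@dataclass
class DepthFrame:
    """One depth image: an H x W grid of distances in metres (0 = hole)."""

    grid: np.ndarray
    index: int = 0
    frame_rate: float = 1.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("depth grid must be 2-D")
        if np.any(self.grid < 0):
            raise ValueError("depth values must be non-negative (0 = hole)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def holes(self) -> np.ndarray:
        """Boolean mask of missing-depth pixels."""
        return self.grid == HOLE

    @property
    def valid(self) -> np.ndarray:
        return self.grid > HOLE

    def copy(self) -> "DepthFrame":
        return DepthFrame(self.grid.copy(), self.index, self.frame_rate)


def read_depth_csv(path, index: int = 0, frame_rate: float = 1.0) -> DepthFrame:
    """Read one depth frame from a CSV file.

    Non-numeric or negative cells become holes (logged).  Ragged rows and
    empty files are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[list[float]] = []
    n_bad = 0
    with open(path) as fh:
        for r, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            vals = []
            for cell in line.split(","):
                try:
                    v = float(cell)
                except ValueError:
                    v, n_bad = HOLE, n_bad + 1
                else:
                    if v < 0 or not np.isfinite(v):
                        v, n_bad = HOLE, n_bad + 1
                vals.append(v)
            if rows and len(vals) != len(rows[0]):
                raise ValueError(
                    f"{path}: ragged row {r}: {len(vals)} fields, "
                    f"expected {len(rows[0])}"
                )
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: empty depth CSV")
    if n_bad:
        logger.warning("%s: %d invalid cells mapped to hole marker", path, n_bad)
    return DepthFrame(np.array(rows, dtype=float), index=index,
                      frame_rate=frame_rate)


def write_depth_csv(frame: DepthFrame, path, precision: int = 3) -> None:
    """Write a frame in the depth-CSV dialect (metres, fixed precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = f"%.{precision}f"
    np.savetxt(path, frame.grid, fmt=fmt, delimiter=",")


def load_sequence(directory, frame_rate: float = 1.0) -> list[DepthFrame]:
    """Load a folder of depth-CSV frames, ordered by file name.

    All frames must share one resolution; a mismatch names both files.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() == ".csv")
    if not files:
        logger.warning("%s: no CSV frames found", directory)
        return []
    frames: list[DepthFrame] = []
    for i, p in enumerate(files):
        f = read_depth_csv(p, index=i, frame_rate=frame_rate)
        if frames and f.shape != frames[0].shape:
            raise ValueError(
                f"mixed frame dimensions: {files[0].name} is "
                f"{frames[0].shape}, {p.name} is {f.shape}"
            )
        frames.append(f)
    return frames


def save_sequence(frames: Iterable[DepthFrame], directory,
                  precision: int = 3) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, f in enumerate(frames):
        write_depth_csv(f, directory / f"frame_{i:06d}.csv", precision)
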