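"""Frame enhancement and background modelling.

Raw depth frames contain holes (0-valued pixels where the camera lost
depth) and per-pixel range noise.  Holes are filled row-wise from the
left, noise is reduced with an edge-preserving bilateral filter, and a
static background is modelled as the mean of the first 30 person-free
frames with distant (unstable) pixels masked out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.restoration import denoise_bilateral

from .io import DepthFrame, HOLE

logger = logging.getLogger(__name__)


def fill_holes_from_left(frame: DepthFrame) -> DepthFrame:
    """Replace each hole with the nearest valid value to its left.

    Leading holes in a row (nothing valid to their left) are backfilled
    from the first valid pixel of that row.  Rows with no valid pixel at
    all are left untouched; an all-hole frame is returned unchanged with
    a warning.  Idempotent; valid pixels are never altered.
    """
    g = frame.grid
    if not (g > HOLE).any():
        logger.warning("frame %d: all pixels are holes; nothing to fill",
                       frame.index)
        return frame.copy()
    valid = g > HOLE
    # forward-fill along each row: index of the most recent valid column
    idx = np.where(valid, np.arange(g.shape[1]), 0)
    idx = np.maximum.accumulate(idx, axis=1)
    out = g[np.arange(g.shape[0])[:, None], idx]
    # leading holes: positions before the first valid pixel picked column 0,
    # which may itself be a hole -> backfill from the first valid pixel
    rows_any = valid.any(axis=1)
    first_valid = np.argmax(valid, axis=1)
    lead = out == HOLE
    if lead.any():
        fill_vals = np.where(rows_any, g[np.arange(g.shape[0]), first_valid],
                             HOLE)
        out = np.where(lead, fill_vals[:, None], out)
    return DepthFrame(out, index=frame.index, frame_rate=frame.frame_rate)


def smooth_bilateral(frame: DepthFrame, diameter: int = 5,
                     sigma_value: float = 0.1,
                     sigma_space: float = 3.0) -> DepthFrame:
    """Edge-preserving smoothing of a hole-free depth frame.

    ``sigma_value`` is the range kernel width in metres: depth steps much
    larger than it (object boundaries) are preserved, smaller variations
    (range noise) are averaged out.
    """
    if diameter <= 0 or sigma_value <= 0 or sigma_space <= 0:
        raise ValueError("bilateral parameters must be positive")
    g = frame.grid
    zmax = float(g.max())
    if zmax == 0:
        return frame.copy()
    # denoise_bilateral works on [0, 1]-scaled images
    out = denoise_bilateral(g / zmax, win_size=diameter,
                            sigma_color=sigma_value / zmax,
                            sigma_spatial=sigma_space) * zmax
    return DepthFrame(out, index=frame.index, frame_rate=frame.frame_rate)


def preprocess_frame(frame: DepthFrame, diameter: int = 5,
                     sigma_value: float = 0.1,
                     sigma_space: float = 3.0) -> DepthFrame:
    """Hole filling followed by bilateral smoothing."""
    return smooth_bilateral(fill_holes_from_left(frame), diameter,
                            sigma_value, sigma_space)


@dataclass
class BackgroundModel:
    """Static-room model used for foreground extraction.

    ``average`` is the pixel-wise mean of the person-free lead-in frames;
    ``far_mask`` flags pixels whose mean depth exceeds the far threshold
    (distant, unstable range readings) — they are excluded from all later
    subtraction and region analysis.
    """
    average: DepthFrame
    far_mask: np.ndarray
    far_threshold: float


def build_background(frames: Sequence[DepthFrame],
                     far_threshold: float = 6.0,
                     n_frames: int = 30) -> BackgroundModel:
    """Average the first ``n_frames`` person-free frames into a background.

    The frame count defaults to 30 (the standard lead-in of the
    recording protocol) and a different count is rejected unless
    ``n_frames`` is changed accordingly.
    """
    if len(frames) != n_frames:
        raise ValueError(
            f"background model needs exactly {n_frames} frames, "
            f"got {len(frames)}")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError("background frames must share one resolution")
    avg = np.mean([f.grid for f in frames], axis=0)
    far = avg > far_threshold
    return BackgroundModel(average=DepthFrame(avg), far_mask=far,
                           far_threshold=far_threshold)
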