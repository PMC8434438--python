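"""Background subtraction, mask cleanup, person detection and tracking.

A pixel is foreground when the background is deeper than the current
frame by at least 0.2 standard deviations of the current frame's depths
(one-sided: only objects nearer than the background count).  Cleaned
blobs are tracked across frames by a three-gate association rule
(centroid distance < 30 px, area difference < 5000 px, mean-depth
difference < 0.5 m); a tracked blob is confirmed as a person once motion
is observed in more than six of the last ten frames (ten seconds at
1 fps).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .io import DepthFrame, HOLE
from .preprocessing import BackgroundModel

logger = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=int)


@dataclass
class ForegroundMask:
    grid: np.ndarray          # H x W boolean
    threshold_used: float     # metres


@dataclass
class TrackedObject:
    """One foreground blob carried across frames."""
    id: int
    centroid: tuple[float, float]      # (row, col)
    area: int
    mean_depth: float
    bbox: tuple[int, int, int, int]    # (r0, r1, c0, c1), half-open
    mask: Optional[np.ndarray] = None
    motion_flags: list[bool] = field(default_factory=list)
    is_person: bool = False
    age: int = 0
    missed: int = 0

    def __post_init__(self):
        if self.area <= 0:
            raise ValueError("blob area must be positive")


def subtract_background(frame: DepthFrame, bg: BackgroundModel,
                        factor: float = 0.2,
                        sigma_floor: float = 0.05) -> ForegroundMask:
    """One-sided depth background subtraction.

    F(i,j) = 1 iff B(i,j) - I(i,j) >= factor * sigma(I), where sigma(I)
    is the standard deviation of the current frame's valid depths.  Far
    (masked) background pixels never become foreground.  A degenerate
    sigma of 0 falls back to a fixed threshold floor.
    """
    if frame.shape != bg.average.shape:
        raise ValueError("frame and background must share one shape")
    g = frame.grid
    valid = g > HOLE
    sigma = float(g[valid].std()) if valid.any() else 0.0
    th = factor * sigma
    if th == 0.0:
        logger.info("degenerate frame sigma; using threshold floor %.3f m",
                    sigma_floor)
        th = sigma_floor
    mask = (bg.average.grid - g >= th) & valid & ~bg.far_mask
    return ForegroundMask(grid=mask, threshold_used=th)


def clean_mask(mask: ForegroundMask,
               curtain_mask: Optional[np.ndarray] = None,
               min_area: int = 100) -> ForegroundMask:
    """Morphological opening + closing, curtain removal, small-blob drop."""
    g = mask.grid
    if curtain_mask is not None:
        if curtain_mask.shape != g.shape:
            raise ValueError("curtain mask shape mismatch")
        g = g & ~curtain_mask
    g = ndimage.binary_opening(g, structure=_STRUCT8)
    g = ndimage.binary_closing(g, structure=_STRUCT8)
    lab, n = ndimage.label(g, structure=_STRUCT8)
    if n:
        areas = ndimage.sum_labels(np.ones_like(lab), lab,
                                   index=np.arange(1, n + 1))
        keep = np.flatnonzero(areas >= min_area) + 1
        g = np.isin(lab, keep)
    return ForegroundMask(grid=g, threshold_used=mask.threshold_used)


def extract_blobs(mask: ForegroundMask, frame: DepthFrame,
                  next_id) -> list[TrackedObject]:
    """Connected components of a cleaned mask as candidate objects."""
    lab, n = ndimage.label(mask.grid, structure=_STRUCT8)
    blobs = []
    for k in range(1, n + 1):
        m = lab == k
        rows, cols = np.nonzero(m)
        depths = frame.grid[m]
        depths = depths[depths > HOLE]
        blobs.append(TrackedObject(
            id=next(next_id),
            centroid=(float(rows.mean()), float(cols.mean())),
            area=int(m.sum()),
            mean_depth=float(depths.mean()) if depths.size else 0.0,
            bbox=(int(rows.min()), int(rows.max()) + 1,
                  int(cols.min()), int(cols.max()) + 1),
            mask=m))
    return blobs


def frame_motion(frame_t: DepthFrame, frame_prev: DepthFrame,
                 bbox: tuple[int, int, int, int]) -> float:
    """Sum of absolute per-pixel depth changes inside a bounding box."""
    r0, r1, c0, c1 = bbox
    H, W = frame_t.shape
    if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
        raise ValueError(f"bbox {bbox} outside frame bounds {frame_t.shape}")
    dt = frame_t.grid[r0:r1, c0:c1] - frame_prev.grid[r0:r1, c0:c1]
    return float(np.abs(dt).sum())


def classify_person(motion_flags: Sequence[bool], window: int = 10,
                    min_true: int = 6) -> bool:
    """Person iff motion in strictly more than ``min_true`` of the last
    ``window`` observations; undecided (False) with fewer observations."""
    flags = list(motion_flags)[-window:]
    if len(flags) < window:
        return False
    return sum(flags) > min_true


def associate(prev: Sequence[TrackedObject], curr: Sequence[TrackedObject],
              th_dist: float = 30.0, th_area: float = 5000.0,
              th_depth: float = 0.5) -> list[tuple[int, int]]:
    """Greedy matching of previous to current blobs.

    A pair is admissible iff centroid distance, area difference and
    mean-depth difference are all below their gates; admissible pairs
    are resolved greedily by nearest centroid.  Returns (prev_index,
    curr_index) pairs.
    """
    cand = []
    for i, p in enumerate(prev):
        for j, c in enumerate(curr):
            dist = float(np.hypot(p.centroid[0] - c.centroid[0],
                                  p.centroid[1] - c.centroid[1]))
            if (dist < th_dist and abs(p.area - c.area) < th_area
                    and abs(p.mean_depth - c.mean_depth) < th_depth):
                cand.append((dist, i, j))
    cand.sort()
    used_p, used_c, out = set(), set(), []
    for _, i, j in cand:
        if i in used_p or j in used_c:
            continue
        used_p.add(i)
        used_c.add(j)
        out.append((i, j))
    return out


class Tracker:
    """Frame-to-frame blob tracker with the 10-frame person rule.

    Confirmed person status is sticky for the lifetime of a track; a
    track that misses more than ``grace`` consecutive frames is dropped.
    """

    def __init__(self, th_dist: float = 30.0, th_area: float = 5000.0,
                 th_depth: float = 0.5, th_motion: float = 80.0,
                 person_window: int = 10, person_min_true: int = 6,
                 grace: int = 5):
        self.th_dist = th_dist
        self.th_area = th_area
        self.th_depth = th_depth
        self.th_motion = th_motion
        self.person_window = person_window
        self.person_min_true = person_min_true
        self.grace = grace
        self.tracks: list[TrackedObject] = []
        self._ids = itertools.count(1)
        self._prev_frame: Optional[DepthFrame] = None

    def step(self, mask: ForegroundMask,
             frame: DepthFrame) -> list[TrackedObject]:
        """Advance one frame; returns the live tracks."""
        blobs = extract_blobs(mask, frame, self._ids)
        pairs = associate(self.tracks, blobs, self.th_dist, self.th_area,
                          self.th_depth)
        matched_prev = {i for i, _ in pairs}
        matched_curr = {j for _, j in pairs}
        new_tracks: list[TrackedObject] = []
        for i, j in pairs:
            t, b = self.tracks[i], blobs[j]
            b.id = t.id
            b.motion_flags = t.motion_flags
            b.is_person = t.is_person
            b.age = t.age + 1
            new_tracks.append(b)
        for i, t in enumerate(self.tracks):
            if i not in matched_prev:
                t.missed += 1
                if t.missed <= self.grace:
                    new_tracks.append(t)
        for j, b in enumerate(blobs):
            if j not in matched_curr:
                b.age = 1
                new_tracks.append(b)
        # motion + person decision for tracks observed this frame
        if self._prev_frame is not None:
            for t in new_tracks:
                if t.missed == 0 and t.mask is not None:
                    motion = frame_motion(frame, self._prev_frame, t.bbox)
                    t.motion_flags = (t.motion_flags
                                      + [motion > self.th_motion])[-self.person_window:]
                    if classify_person(t.motion_flags, self.person_window,
                                       self.person_min_true):
                        t.is_person = True
        self._prev_frame = frame
        self.tracks = new_tracks
        return self.tracks

    def persons(self) -> list[TrackedObject]:
        return [t for t in self.tracks if t.is_person and t.missed == 0]
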