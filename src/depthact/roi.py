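"""Region-of-interest extraction from UV-disparity maps.

Depth is converted to a quantised disparity image (disparity is
inversely proportional to depth: d_px = f * baseline / Z).  Row-wise and
column-wise disparity histograms — the V- and U-disparity maps — turn
flat surfaces into straight lines: the floor projects into V-disparity
as the slanted "ground correlation line" (detected with a Hough
transform), the bed into the largest connected component of the
remaining V-disparity mass, and a hanging curtain into a line in the
U-disparity map of the foreground.  Pixels are then labelled
floor / bed / ignored, and person blobs are localised by how much they
overlap each region (>70% on bed -> on the bed, else >30% on floor ->
on the floor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy import ndimage
from skimage.transform import hough_line, hough_line_peaks

from .config import CameraIntrinsics
from .io import DepthFrame, HOLE
from .synthetic import FLOOR, BED, IGNORED  # shared region codes

logger = logging.getLogger(__name__)

INVALID = -1  # disparity bin for holes / masked pixels


class FloorLine(NamedTuple):
    """Ground correlation line d = slope * row + intercept (bins)."""
    slope: float
    intercept: float

    def __call__(self, row):
        return self.slope * np.asarray(row, dtype=float) + self.intercept


class BedExtremes(NamedTuple):
    min_height: int     # image rows
    max_height: int
    min_disparity: int  # bins
    max_disparity: int


@dataclass
class DisparityMap:
    """Quantised disparity image: integer bins, INVALID where unknown."""
    bins: np.ndarray
    n_levels: int

    def __post_init__(self):
        self.bins = np.asarray(self.bins)
        if self.bins.max(initial=0) >= self.n_levels:
            raise ValueError("disparity bins exceed n_levels")

    @property
    def valid(self) -> np.ndarray:
        return self.bins != INVALID


@dataclass
class UVDisparity:
    v_map: np.ndarray  # (H, n_levels) per-row disparity histogram
    u_map: np.ndarray  # (n_levels, W) per-column disparity histogram


@dataclass
class RegionMap:
    """Per-pixel {floor, bed, ignored} labels plus the fitted structures."""
    labels: np.ndarray
    floor_line: Optional[FloorLine] = None
    bed_extremes: Optional[BedExtremes] = None


def disparity_pixels(depth, intrinsics: CameraIntrinsics):
    """Stereo disparity in pixels: f * baseline / depth."""
    depth = np.asarray(depth, dtype=float)
    if np.any(depth <= 0):
        raise ValueError("depth must be positive")
    return intrinsics.fb / depth


def depth_to_disparity(frame: DepthFrame, intrinsics: CameraIntrinsics,
                       n_levels: int = 128, min_depth: float = 1.0,
                       exclude: Optional[np.ndarray] = None) -> DisparityMap:
    """Quantise inverse depth into ``n_levels`` disparity bins.

    The continuous pixel disparity f*b/Z is mapped linearly onto
    [0, n_levels-1] with bin n_levels-1 at ``min_depth`` (the nearest
    depth the pipeline resolves), i.e. bin = round((n_levels-1) *
    min_depth / Z), clipped.  Holes and ``exclude`` pixels get INVALID
    and never enter the histograms.
    """
    g = frame.grid
    valid = g > HOLE
    if exclude is not None:
        valid &= ~exclude
    bins = np.full(g.shape, INVALID, dtype=np.int32)
    with np.errstate(divide="ignore"):
        d = np.rint((n_levels - 1) * min_depth / np.where(valid, g, np.inf))
    bins[valid] = np.clip(d[valid], 0, n_levels - 1).astype(np.int32)
    return DisparityMap(bins=bins, n_levels=n_levels)


def build_uv_disparity(dmap: DisparityMap) -> UVDisparity:
    """Row-wise (V) and column-wise (U) disparity histograms."""
    H, W = dmap.bins.shape
    L = dmap.n_levels
    rows, cols = np.nonzero(dmap.valid)
    d = dmap.bins[rows, cols]
    v_map = np.zeros((H, L), dtype=np.int64)
    u_map = np.zeros((L, W), dtype=np.int64)
    np.add.at(v_map, (rows, d), 1)
    np.add.at(u_map, (d, cols), 1)
    return UVDisparity(v_map=v_map, u_map=u_map)


def extract_floor(uv: UVDisparity, dmap: DisparityMap,
                  line_tolerance: int = 1, bin_threshold: int = 5,
                  angle_min: float = 20.0, angle_max: float = 80.0,
                  min_votes: int = 20):
    """Detect the ground correlation line and label floor pixels.

    The binarised V-disparity map is searched for the strongest Hough
    line whose slant lies in [angle_min, angle_max] degrees from the
    disparity axis (the floor line rises toward the bottom of the image;
    vertical walls, at 90 degrees, are excluded).  A pixel is floor iff
    its disparity bin is within ``line_tolerance`` of the line evaluated
    at its row.
    """
    binary = uv.v_map >= bin_threshold
    # line angle alpha from the horizontal (disparity) axis -> Hough
    # normal angle theta = alpha - 90 degrees
    thetas = np.deg2rad(np.arange(angle_min - 90.0, angle_max - 90.0 + 0.25,
                                  0.25))
    acc, theta, dist = hough_line(binary, theta=thetas)
    _, peak_theta, peak_dist = hough_line_peaks(
        acc, theta, dist, num_peaks=1, threshold=min_votes)
    empty = np.zeros(dmap.bins.shape, dtype=bool)
    if len(peak_theta) == 0:
        logger.warning("no ground correlation line found in V-disparity")
        return empty, None
    th, rho = float(peak_theta[0]), float(peak_dist[0])
    # rho = d*cos(th) + row*sin(th)  with x = disparity bin, y = image row
    slope = -np.sin(th) / np.cos(th)
    intercept = rho / np.cos(th)
    line = FloorLine(slope=slope, intercept=intercept)
    rows = np.arange(dmap.bins.shape[0])
    d_line = line(rows)[:, None]
    mask = dmap.valid & (np.abs(dmap.bins - d_line) <= line_tolerance) \
        & (d_line >= 0)
    return mask, line


def extract_bed(dmap_without_floor: DisparityMap, bin_threshold: int = 5):
    """Largest V-disparity connected component of the floor-free map.

    The component with the largest represented pixel count is assumed to
    be the bed; its four extreme points (min/max image row, min/max
    disparity) delimit the bed pixels: every remaining pixel between the
    row extremes whose disparity falls inside the disparity extremes.
    """
    uv = build_uv_disparity(dmap_without_floor)
    binary = uv.v_map >= bin_threshold
    empty = np.zeros(dmap_without_floor.bins.shape, dtype=bool)
    if not binary.any():
        logger.warning("empty V-disparity map: no bed component")
        return empty, None
    lab, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    # weight each component by the number of image pixels it represents
    weights = ndimage.sum_labels(uv.v_map, lab, index=np.arange(1, n + 1))
    best = int(np.argmax(weights)) + 1
    rows, dbins = np.nonzero(lab == best)
    ext = BedExtremes(min_height=int(rows.min()), max_height=int(rows.max()),
                      min_disparity=int(dbins.min()),
                      max_disparity=int(dbins.max()))
    rr = np.arange(dmap_without_floor.bins.shape[0])[:, None]
    mask = (dmap_without_floor.valid
            & (rr >= ext.min_height) & (rr <= ext.max_height)
            & (dmap_without_floor.bins >= ext.min_disparity)
            & (dmap_without_floor.bins <= ext.max_disparity))
    return mask, ext


def remove_floor(dmap: DisparityMap, floor_mask: np.ndarray) -> DisparityMap:
    """Zero out floor pixels (mark INVALID) before bed extraction."""
    bins = dmap.bins.copy()
    bins[floor_mask] = INVALID
    return DisparityMap(bins=bins, n_levels=dmap.n_levels)


def build_region_map(floor_mask: np.ndarray, bed_mask: np.ndarray,
                     floor_line: Optional[FloorLine] = None,
                     bed_extremes: Optional[BedExtremes] = None) -> RegionMap:
    """Combine masks into an exhaustive label grid, floor > bed > ignored."""
    if floor_mask.shape != bed_mask.shape:
        raise ValueError("region masks must share one shape")
    overlap = int(np.count_nonzero(floor_mask & bed_mask))
    if overlap:
        logger.info("%d overlapping floor/bed pixels resolved as floor",
                    overlap)
    labels = np.full(floor_mask.shape, IGNORED, dtype=np.int8)
    labels[bed_mask] = BED
    labels[floor_mask] = FLOOR
    return RegionMap(labels=labels, floor_line=floor_line,
                     bed_extremes=bed_extremes)


def extract_regions(background: DepthFrame, intrinsics: CameraIntrinsics,
                    far_mask: Optional[np.ndarray] = None,
                    n_levels: int = 128, min_depth: float = 1.0,
                    line_tolerance: int = 1, bin_threshold: int = 5,
                    angle_min: float = 20.0, angle_max: float = 80.0,
                    min_votes: int = 20) -> RegionMap:
    """Full ROI pass on a background frame: floor, then bed, then rest."""
    dmap = depth_to_disparity(background, intrinsics, n_levels, min_depth,
                              exclude=far_mask)
    uv = build_uv_disparity(dmap)
    floor_mask, line = extract_floor(uv, dmap, line_tolerance, bin_threshold,
                                     angle_min, angle_max, min_votes)
    bed_mask, ext = extract_bed(remove_floor(dmap, floor_mask), bin_threshold)
    return build_region_map(floor_mask, bed_mask, line, ext)


def localize_blob(blob_mask: np.ndarray, regions: RegionMap,
                  bed_fraction: float = 0.70,
                  floor_fraction: float = 0.30) -> str:
    """Locate a person blob: 'bed', 'floor' or 'other'.

    The bed test (>70% of blob pixels on the bed region) has precedence;
    the floor test (>30%) is the fallback branch.
    """
    n = int(np.count_nonzero(blob_mask))
    if n == 0:
        raise ValueError("empty blob")
    lab = regions.labels[blob_mask]
    if np.count_nonzero(lab == BED) / n > bed_fraction:
        return "bed"
    if np.count_nonzero(lab == FLOOR) / n > floor_fraction:
        return "floor"
    return "other"


def detect_curtain(dmap: DisparityMap, foreground: np.ndarray,
                   line_tolerance: int = 8, bin_threshold: int = 2,
                   min_cols: int = 120) -> np.ndarray:
    """Detect curtain pixels in the U-disparity map of the foreground.

    A hanging curtain is a flat vertical surface: its disparity traces a
    straight line across columns of the U-disparity map.  The strongest
    non-vertical Hough line spanning at least ``min_cols`` distinct
    columns is taken as the curtain; foreground pixels whose disparity
    is within ``line_tolerance`` of the line at their column are
    removed.  Compact person blobs never span enough columns.

    The default tolerance is wider than the floor line's: a hanging
    curtain seen by a tilted camera spreads over roughly half a pixel of
    disparity per column (several quantisation bins).
    """
    empty = np.zeros(foreground.shape, dtype=bool)
    fg_valid = foreground & dmap.valid
    if not fg_valid.any():
        return empty
    rows, cols = np.nonzero(fg_valid)
    d = dmap.bins[rows, cols]
    u_map = np.zeros((dmap.n_levels, foreground.shape[1]), dtype=np.int64)
    np.add.at(u_map, (d, cols), 1)
    binary = u_map >= bin_threshold
    # exclude near-vertical u-map lines (one column, many disparities):
    # keep line slants within +-60 deg of the column axis
    thetas = np.deg2rad(np.r_[np.arange(-90.0, -29.75, 0.25),
                              np.arange(30.0, 90.0, 0.25)])
    acc, theta, dist = hough_line(binary, theta=thetas)
    _, peak_theta, peak_dist = hough_line_peaks(
        acc, theta, dist, num_peaks=1, threshold=max(10, min_cols // 3))
    if len(peak_theta) == 0:
        return empty
    th, rho = float(peak_theta[0]), float(peak_dist[0])
    # rho = col*cos(th) + dbin*sin(th); solve for dbin at each column
    cc = np.arange(foreground.shape[1], dtype=float)
    d_line = (rho - cc * np.cos(th)) / np.sin(th)
    # only columns where the histogram actually supports the line count
    # as curtain; the line is not extrapolated past the curtain's span
    dd = np.arange(dmap.n_levels, dtype=float)[:, None]
    support = (binary & (np.abs(dd - d_line[None, :])
                         <= line_tolerance)).any(axis=0)
    if int(support.sum()) < min_cols:
        return empty
    on_line = fg_valid & support[None, :] & \
        (np.abs(dmap.bins - d_line[None, :]) <= line_tolerance)
    return on_line
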