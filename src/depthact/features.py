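"""Action-representation maps and descriptors.

Two temporal templates are accumulated over a recognition window from
the person's normalised depth silhouette:

* DMA (depth motion appearance) — the pixel-wise running *minimum* of
  depth, the nearest-surface envelope swept by the body;
* DMH (depth motion history) — a decaying timestamp map, set to ``tau``
  wherever the depth changed by more than ``delta`` between consecutive
  frames and decremented toward 0 elsewhere.

Each map is described by a HOG descriptor (16x16-px cells, 9 unsigned
orientation bins, per-cell L2 normalisation, 16 x 11 cell grid ->
1584 values); the two descriptors are concatenated into the 3168-dim
fused feature.  Independently, the person's height above the floor is
measured as the signed distance from the back-projected 3-D centroid to
the least-squares floor plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.transform import resize

from .config import CameraIntrinsics
from .io import DepthFrame

CANVAS = (176, 256)      # rows x cols: 11 x 16 cells of 16 px
HOG_CELL = 16
HOG_BINS = 9
HOG_LEN = (CANVAS[0] // HOG_CELL) * (CANVAS[1] // HOG_CELL) * HOG_BINS  # 1584
_EPS = 1e-6


# ---------------------------------------------------------------------------
# silhouette normalisation
# ---------------------------------------------------------------------------

def normalize_silhouette(frame: DepthFrame, blob_mask: np.ndarray,
                         canvas: tuple[int, int] = CANVAS) -> np.ndarray:
    """Crop the blob and centre it on a fixed zero-padded canvas.

    The blob's bounding box is cut from the depth image (non-blob pixels
    zeroed), isotropically downscaled if it exceeds the canvas, and
    pasted so that the blob centroid sits at the canvas centre (clamped
    so the whole box stays inside).  Translation of the blob within the
    source frame therefore does not change the patch.
    """
    if not blob_mask.any():
        raise ValueError("empty blob")
    rows, cols = np.nonzero(blob_mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    patch = np.where(blob_mask, frame.grid, 0.0)[r0:r1, c0:c1]
    ch, cw = canvas
    scale = min(1.0, ch / patch.shape[0], cw / patch.shape[1])
    if scale < 1.0:
        new_shape = (max(1, int(patch.shape[0] * scale)),
                     max(1, int(patch.shape[1] * scale)))
        patch = resize(patch, new_shape, order=0, preserve_range=True,
                       anti_aliasing=False)
    mask = patch > 0
    if not mask.any():
        raise ValueError("blob vanished during rescaling")
    pr, pc = np.nonzero(mask)
    cen_r, cen_c = pr.mean(), pc.mean()
    off_r = int(round(ch / 2 - cen_r))
    off_c = int(round(cw / 2 - cen_c))
    off_r = min(max(off_r, 0), ch - patch.shape[0])
    off_c = min(max(off_c, 0), cw - patch.shape[1])
    out = np.zeros(canvas, dtype=float)
    out[off_r:off_r + patch.shape[0], off_c:off_c + patch.shape[1]] = patch
    return out


# ---------------------------------------------------------------------------
# DMA / DMH
# ---------------------------------------------------------------------------

@dataclass
class ActionMaps:
    """DMA/DMH pair accumulated over a growing recognition window."""
    tau: int = 30
    delta: float = 0.01
    shape: tuple[int, int] = CANVAS
    dma: np.ndarray = None
    dmh: np.ndarray = None
    t: int = 0

    def __post_init__(self):
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.dma is None:
            self.dma = np.zeros(self.shape, dtype=float)
        if self.dmh is None:
            self.dmh = np.zeros(self.shape, dtype=float)


def update_dma(maps: ActionMaps, patch: np.ndarray) -> ActionMaps:
    """Running-minimum update of the appearance map.

    Pixels where the incoming silhouette is 0 (zero padding, no person)
    leave the map unchanged: padding is absence of data, not a nearer
    surface.
    """
    if patch.shape != maps.dma.shape:
        raise ValueError("patch shape mismatch")
    person = patch > 0
    first = (maps.dma == 0) & person
    maps.dma = np.where(first, patch,
                        np.where(person, np.minimum(maps.dma, patch),
                                 maps.dma))
    return maps


def update_dmh(maps: ActionMaps, patch_t: np.ndarray,
               patch_prev: np.ndarray) -> ActionMaps:
    """History update: tau where |D_t - D_{t-1}| > delta, else decay."""
    if patch_t.shape != maps.dmh.shape or patch_prev.shape != maps.dmh.shape:
        raise ValueError("patch shape mismatch")
    moved = np.abs(patch_t - patch_prev) > maps.delta
    maps.dmh = np.where(moved, float(maps.tau),
                        np.maximum(maps.dmh - 1.0, 0.0))
    return maps


def update_maps(maps: ActionMaps, patch_t: np.ndarray,
                patch_prev: Optional[np.ndarray]) -> ActionMaps:
    """One frame of incremental DMA + DMH accumulation."""
    update_dma(maps, patch_t)
    if patch_prev is None:
        patch_prev = np.zeros_like(patch_t)
    update_dmh(maps, patch_t, patch_prev)
    maps.t += 1
    return maps


# ---------------------------------------------------------------------------
# HOG
# ---------------------------------------------------------------------------

def hog_descriptor(grid: np.ndarray, cell: int = HOG_CELL,
                   bins: int = HOG_BINS) -> np.ndarray:
    """HOG over a fixed-size map: per-cell orientation histograms.

    Gradients are centred differences (one-sided at borders), orientations
    are unsigned over [0, 180), binned hard into ``bins`` equal sectors
    and weighted by gradient magnitude; each cell's 9-vector is its own
    L2-normalised block.  Cell grid raster order (rows, then columns).
    """
    g = np.asarray(grid, dtype=float)
    if g.shape[0] % cell or g.shape[1] % cell:
        raise ValueError(f"grid shape {g.shape} not a multiple of {cell}")
    gy, gx = np.gradient(g)
    mag = np.hypot(gx, gy)
    ang = np.degrees(np.arctan2(gy, gx)) % 180.0
    b = np.minimum((ang / (180.0 / bins)).astype(int), bins - 1)
    nr, nc = g.shape[0] // cell, g.shape[1] // cell
    hist = np.zeros((nr, nc, bins), dtype=float)
    for k in range(bins):
        mk = np.where(b == k, mag, 0.0)
        hist[:, :, k] = mk.reshape(nr, cell, nc, cell).sum(axis=(1, 3))
    norm = np.sqrt((hist ** 2).sum(axis=2, keepdims=True) + _EPS ** 2)
    return (hist / norm).ravel()


def fuse_features(hog_dma: np.ndarray, hog_dmh: np.ndarray) -> np.ndarray:
    """Concatenate the two map descriptors, DMA half first."""
    if hog_dma.shape != (HOG_LEN,) or hog_dmh.shape != (HOG_LEN,):
        raise ValueError(f"descriptors must have length {HOG_LEN}")
    return np.concatenate([hog_dma, hog_dmh])


def maps_to_feature(maps: ActionMaps) -> np.ndarray:
    return fuse_features(hog_descriptor(maps.dma), hog_descriptor(maps.dmh))


# ---------------------------------------------------------------------------
# floor plane and height feature
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FloorPlane:
    """Unit-normalised plane aX + bY + cZ + d = 0 in camera coordinates."""
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        n = np.sqrt(self.a ** 2 + self.b ** 2 + self.c ** 2)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("plane normal must be unit length")

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d])


def pixel_to_camera(x, y, Z, intrinsics: CameraIntrinsics):
    """Back-project pixel (x, y) at depth Z: X = Z(x-c_x)/f, Y = Z(y-c_y)/f."""
    Z = np.asarray(Z, dtype=float)
    if np.any(Z <= 0):
        raise ValueError("depth must be positive")
    cx, cy = intrinsics.principal_point
    f = intrinsics.focal_length
    X = Z * (np.asarray(x, dtype=float) - cx) / f
    Y = Z * (np.asarray(y, dtype=float) - cy) / f
    return X, Y, Z


def fit_floor_plane(points: np.ndarray) -> FloorPlane:
    """Total-least-squares plane through 3-D floor points.

    ``points`` is (n, 3) in camera coordinates.  The normal is the
    smallest-eigenvalue direction of the centred covariance; coefficients
    are unit-normalised with c >= 0.  Requires >= 3 non-collinear points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    centroid = pts.mean(axis=0)
    q = pts - centroid
    cov = q.T @ q
    w, v = np.linalg.eigh(cov)
    if w[1] < 1e-12 * max(w[2], 1.0):
        raise ValueError("points are collinear; plane is underdetermined")
    normal = v[:, 0]
    if normal[2] < 0:
        normal = -normal
    d = -float(normal @ centroid)
    return FloorPlane(*normal, d)


def centroid_floor_distance(point, plane: FloorPlane) -> float:
    """Signed point-plane distance, positive above the floor.

    The camera sits above the floor at the coordinate origin, so the
    plane's sign is oriented to make the origin side positive (for a
    plane through the origin the raw signed value is returned).
    """
    X, Y, Z = point
    v = plane.a * X + plane.b * Y + plane.c * Z + plane.d
    return float(-v if plane.d < 0 else v)


def blob_floor_distance(blob, plane: FloorPlane,
                        intrinsics: CameraIntrinsics) -> float:
    """Height of a tracked blob's centroid above the floor."""
    row, col = blob.centroid
    X, Y, Z = pixel_to_camera(col, row, blob.mean_depth, intrinsics)
    return centroid_floor_distance((float(X), float(Y), float(Z)), plane)


def floor_points_from_frame(frame: DepthFrame, floor_mask: np.ndarray,
                            intrinsics: CameraIntrinsics,
                            max_points: int = 2000,
                            seed: int = 0) -> np.ndarray:
    """Back-project (sub-sampled) floor pixels to 3-D for plane fitting."""
    rows, cols = np.nonzero(floor_mask & (frame.grid > 0))
    if rows.size == 0:
        raise ValueError("no valid floor pixels")
    if rows.size > max_points:
        sel = np.random.default_rng(seed).choice(rows.size, max_points,
                                                 replace=False)
        rows, cols = rows[sel], cols[sel]
    Z = frame.grid[rows, cols]
    X, Y, Z = pixel_to_camera(cols, rows, Z, intrinsics)
    return np.column_stack([X, Y, Z])
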