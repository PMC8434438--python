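"""Parametric depth-scene simulator for a monitored care-center bedroom.

Renders sequences of depth frames (metres, 0 = hole) from a pinhole
camera mounted ~2.1 m above the floor looking down into a room that
contains a floor plane, a bed cuboid, a wheelchair-sized static box, an
optional curtain plane and a person modelled as a composite of three
ellipsoids whose arrangement encodes posture (standing, seated, lying).
Each rendered sequence comes with full ground truth: per-frame action
labels, per-frame person masks, a floor/bed/ignored region map and the
floor-plane coefficients in camera coordinates — so every stage of the
recognition pipeline has an independent oracle to be tested against.

Depth is the distance along the optical axis (Z-depth), matching the
back-projection X = Z(x-c_x)/f, Y = Z(y-c_y)/f used downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .config import CameraIntrinsics
from .io import DepthFrame, HOLE

# region labels shared with roi_extraction
FLOOR, BED, IGNORED = 0, 1, 2


# ---------------------------------------------------------------------------
# geometry primitives (world frame: X right, Y up, Z forward; floor at Y=0)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Box:
    """Axis-aligned cuboid given by (min, max) per axis, metres."""
    x: tuple[float, float]
    y: tuple[float, float]
    z: tuple[float, float]

    def __post_init__(self):
        for lo, hi in (self.x, self.y, self.z):
            if hi <= lo:
                raise ValueError("box extents must satisfy min < max")


@dataclass(frozen=True)
class Quad:
    """Planar rectangle: origin + two edge vectors (used for curtains)."""
    origin: tuple[float, float, float]
    edge_u: tuple[float, float, float]
    edge_v: tuple[float, float, float]


@dataclass(frozen=True)
class SceneSpec:
    """Static room geometry plus acquisition noise parameters."""
    camera_height: float = 2.1          # metres above the floor
    camera_tilt: float = 25.0           # degrees below horizontal
    intrinsics: CameraIntrinsics = field(default_factory=CameraIntrinsics)
    shape: tuple[int, int] = (180, 320)  # rows, cols
    bed_box: Optional[Box] = None
    static_objects: tuple[Box, ...] = ()
    curtain: Optional[Quad] = None
    back_wall_z: Optional[float] = None
    sensor_range: float = 6.5           # metres; depth saturates here
    noise_sigma: float = 0.0            # metres
    hole_rate: float = 0.0              # fraction of pixels dropped

    def __post_init__(self):
        if self.camera_height <= 0:
            raise ValueError("camera_height must be positive")
        if not (0 <= self.hole_rate < 1):
            raise ValueError("hole_rate must be in [0, 1)")
        if self.bed_box is not None and self.bed_box.y[0] < 0:
            raise ValueError("bed_box must lie above the floor plane")


def _camera_axes(tilt_deg: float):
    t = math.radians(tilt_deg)
    x_c = np.array([1.0, 0.0, 0.0])
    y_c = np.array([0.0, -math.cos(t), -math.sin(t)])   # image down
    z_c = np.array([0.0, -math.sin(t), math.cos(t)])    # optical axis
    return x_c, y_c, z_c


def _ray_dirs(spec: SceneSpec) -> np.ndarray:
    """World-frame ray directions, normalised to unit optical-axis component.

    With this normalisation the ray parameter s at a hit equals the
    Z-depth of the hit point.
    """
    H, W = spec.shape
    f = spec.intrinsics.focal_length
    cx, cy = spec.intrinsics.principal_point
    xs = (np.arange(W) - cx) / f
    ys = (np.arange(H) - cy) / f
    vx, vy = np.meshgrid(xs, ys)
    x_c, y_c, z_c = _camera_axes(spec.camera_tilt)
    d = (vx[..., None] * x_c + vy[..., None] * y_c + z_c)
    return d


def _hit_floor(origin, d):
    dy = d[..., 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = -origin[1] / dy
    s = np.where((dy < 0) & (s > 0), s, np.inf)
    return s


def _hit_plane_z(origin, d, z0):
    dz = d[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (z0 - origin[2]) / dz
    return np.where((dz > 0) & (s > 0), s, np.inf)


def _hit_box(origin, d, box: Box):
    bounds = np.array([box.x, box.y, box.z])  # (3, 2)
    tmin = np.full(d.shape[:2], -np.inf)
    tmax = np.full(d.shape[:2], np.inf)
    for ax in range(3):
        da = d[..., ax]
        oa = origin[ax]
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (bounds[ax, 0] - oa) / da
            t2 = (bounds[ax, 1] - oa) / da
        lo = np.fmin(t1, t2)
        hi = np.fmax(t1, t2)
        # rays parallel to the slab: inside iff origin within bounds
        par = da == 0
        inside = (oa >= bounds[ax, 0]) & (oa <= bounds[ax, 1])
        lo = np.where(par, np.where(inside, -np.inf, np.inf), lo)
        hi = np.where(par, np.where(inside, np.inf, -np.inf), hi)
        tmin = np.fmax(tmin, lo)
        tmax = np.fmin(tmax, hi)
    s = np.where(tmin > 0, tmin, tmax)
    return np.where((tmax >= tmin) & (s > 0), s, np.inf)


def _hit_ellipsoid(origin, d, center, semi):
    o = (np.asarray(origin) - np.asarray(center)) / np.asarray(semi)
    dd = d / np.asarray(semi)
    a = np.sum(dd * dd, axis=-1)
    b = 2.0 * np.sum(dd * o, axis=-1)
    c = float(np.sum(o * o)) - 1.0
    disc = b * b - 4 * a * c
    with np.errstate(invalid="ignore"):
        sq = np.sqrt(np.where(disc >= 0, disc, np.nan))
        s1 = (-b - sq) / (2 * a)
        s2 = (-b + sq) / (2 * a)
    s = np.where(s1 > 0, s1, s2)
    return np.where((disc >= 0) & (s > 0), s, np.inf)


def _hit_quad(origin, d, quad: Quad):
    q0 = np.asarray(quad.origin, dtype=float)
    e1 = np.asarray(quad.edge_u, dtype=float)
    e2 = np.asarray(quad.edge_v, dtype=float)
    n = np.cross(e1, e2)
    dn = d @ n
    with np.errstate(divide="ignore", invalid="ignore"):
        s = ((q0 - origin) @ n) / dn
    p = origin + s[..., None] * d
    rel = p - q0
    u = (rel @ e1) / (e1 @ e1)
    v = (rel @ e2) / (e2 @ e2)
    ok = (np.abs(dn) > 1e-12) & (s > 0) & (u >= 0) & (u <= 1) & (v >= 0) & (v <= 1)
    return np.where(ok, s, np.inf)


# ---------------------------------------------------------------------------
# person model
# ---------------------------------------------------------------------------

#: posture -> list of (centre offset from (x, base, z), semi-axes), for a
#: 1.6 m reference body.  Four parts (shins, thighs, torso, head) so
#: postures can be blended part-by-part.  Offsets are relative to the
#: supporting surface (``base``); seated shins reach below it to the
#: floor.
_POSTURES: dict[str, list[tuple[tuple[float, float, float],
                                tuple[float, float, float]]]] = {
    # upright stack
    "standing": [
        ((0.0, 0.25, 0.0), (0.13, 0.27, 0.11)),
        ((0.0, 0.64, 0.0), (0.15, 0.26, 0.12)),
        ((0.0, 1.10, 0.0), (0.20, 0.30, 0.14)),
        ((0.0, 1.50, 0.0), (0.10, 0.12, 0.10)),
    ],
    # seated: shins drop to the floor, thighs forward (-z, toward camera)
    "seated": [
        ((0.0, -0.24, -0.34), (0.10, 0.22, 0.10)),
        ((0.0, 0.06, -0.22), (0.16, 0.10, 0.26)),
        ((0.0, 0.40, 0.02), (0.19, 0.27, 0.14)),
        ((0.0, 0.74, 0.02), (0.10, 0.11, 0.10)),
    ],
    # lying: long axis along z (the bed's long axis), low profile
    "lying": [
        ((0.0, 0.10, 0.85), (0.12, 0.09, 0.15)),
        ((0.0, 0.12, 0.35), (0.18, 0.12, 0.45)),
        ((0.0, 0.16, -0.25), (0.22, 0.16, 0.35)),
        ((0.0, 0.13, -0.70), (0.10, 0.10, 0.11)),
    ],
}


@dataclass(frozen=True)
class PersonPose:
    """Position + posture of the person blob.

    ``base`` is the height of the supporting surface (0 on the floor,
    the bed-top height when on the bed); ``height`` scales the body.
    """
    x: float
    z: float
    base: float = 0.0
    posture: str = "standing"
    height: float = 1.55  # elderly resident; the nurse blob is taller

    def parts(self):
        scale = self.height / 1.6
        out = []
        for off, semi in _POSTURES[self.posture]:
            c = (self.x + off[0] * scale,
                 self.base + off[1] * scale,
                 self.z + off[2] * scale)
            out.append((c, tuple(s * scale for s in semi)))
        return out


def _blend_parts(pa, pb, w: float):
    """Linear interpolation of two 3-part bodies (posture morphing)."""
    out = []
    for (ca, sa), (cb, sb) in zip(pa, pb):
        c = tuple((1 - w) * a + w * b for a, b in zip(ca, cb))
        s = tuple((1 - w) * a + w * b for a, b in zip(sa, sb))
        out.append((c, s))
    return out


# ---------------------------------------------------------------------------
# action scripts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScriptStep:
    """``duration`` frames with one ground-truth label.

    If both poses are given the person morphs/moves linearly from
    ``start`` to ``end`` over the step; a lone ``start`` is held static.
    ``sway`` adds a small sinusoidal z-oscillation (metres) so that a
    nominally static person still shows physiological micro-motion.
    """
    label: int
    duration: int
    start: Optional[PersonPose] = None
    end: Optional[PersonPose] = None
    sway: float = 0.0

    def __post_init__(self):
        if self.duration < 1:
            raise ValueError("step duration must be >= 1")
        if not (0 <= self.label <= 7):
            raise ValueError("labels must be in 0..7")


@dataclass(frozen=True)
class ActionScript:
    steps: tuple[ScriptStep, ...]

    def __post_init__(self):
        if not self.steps:
            raise ValueError("script must contain at least one step")

    @property
    def n_frames(self) -> int:
        return sum(s.duration for s in self.steps)

    def expand(self):
        """Per-frame (label, body parts or None)."""
        frames = []
        for step in self.steps:
            for k in range(step.duration):
                if step.start is None:
                    frames.append((step.label, None))
                    continue
                w = k / max(step.duration - 1, 1)
                a = step.start
                if step.end is None:
                    pose = a
                    pb = None
                else:
                    b = step.end
                    pose = PersonPose(
                        x=(1 - w) * a.x + w * b.x,
                        z=(1 - w) * a.z + w * b.z,
                        base=(1 - w) * a.base + w * b.base,
                        posture=a.posture, height=a.height)
                    pb = PersonPose(
                        x=pose.x, z=pose.z, base=pose.base,
                        posture=b.posture, height=b.height)
                sway = step.sway * math.sin(2 * math.pi * k / 7.0)
                pose = replace(pose, z=pose.z + sway)
                parts = pose.parts()
                if pb is not None and pb.posture != pose.posture:
                    parts = _blend_parts(parts,
                                         replace(pb, z=pose.z).parts(), w)
                elif pb is not None and pb.height != a.height:
                    parts = _blend_parts(parts, pb.parts(), w)
                frames.append((step.label, parts))
        return frames


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""
    labels: np.ndarray            # (T,) int action label per frame
    person_masks: np.ndarray      # (T, H, W) bool
    region_labels: np.ndarray     # (H, W) int in {FLOOR, BED, IGNORED}
    floor_plane: np.ndarray       # (a, b, c, d) in camera coordinates
    background_depth: np.ndarray  # (H, W) clean static-scene depth


def floor_plane_camera(spec: SceneSpec) -> np.ndarray:
    """Analytic floor plane aX+bY+cZ+d=0 in camera coordinates (c >= 0)."""
    t = math.radians(spec.camera_tilt)
    return np.array([0.0, math.cos(t), math.sin(t), -spec.camera_height])


def render_background(spec: SceneSpec):
    """Render the empty room once: (depth grid, region label grid).

    Depth saturates at ``sensor_range`` (the camera cannot range beyond
    it); region labels only describe surfaces the sensor actually
    resolved — saturated pixels are part of the ignored region.
    """
    origin = np.array([0.0, spec.camera_height, 0.0])
    d = _ray_dirs(spec)
    layers = [(_hit_floor(origin, d), FLOOR)]
    if spec.bed_box is not None:
        layers.append((_hit_box(origin, d, spec.bed_box), BED))
    for box in spec.static_objects:
        layers.append((_hit_box(origin, d, box), IGNORED))
    if spec.curtain is not None:
        layers.append((_hit_quad(origin, d, spec.curtain), IGNORED))
    if spec.back_wall_z is not None:
        layers.append((_hit_plane_z(origin, d, spec.back_wall_z), IGNORED))
    depths = np.stack([s for s, _ in layers])
    idx = np.argmin(depths, axis=0)
    depth = np.take_along_axis(depths, idx[None], axis=0)[0]
    labels = np.array([lab for _, lab in layers])[idx]
    saturated = ~np.isfinite(depth) | (depth >= spec.sensor_range)
    labels = np.where(saturated, IGNORED, labels)
    depth = np.where(saturated, spec.sensor_range, depth)
    return depth, labels


def render_person(spec: SceneSpec, parts) -> np.ndarray:
    """Depth of the person body alone (inf where the body is missed)."""
    origin = np.array([0.0, spec.camera_height, 0.0])
    d = _ray_dirs(spec)
    s = np.full(spec.shape, np.inf)
    for center, semi in parts:
        s = np.minimum(s, _hit_ellipsoid(origin, d, center, semi))
    return s


def corrupt(frames: Sequence[DepthFrame], noise_sigma: float,
            hole_rate: float, seed: int) -> list[DepthFrame]:
    """Add Gaussian depth noise and random holes, reproducibly.

    Input frames must be hole-free.  Noise is applied first (clipped to
    stay positive), then a Bernoulli(hole_rate) mask drops pixels to the
    hole marker.
    """
    if not (0 <= hole_rate < 1):
        raise ValueError("hole_rate must be in [0, 1)")
    for f in frames:
        if np.any(f.grid == HOLE):
            raise ValueError("corrupt() expects hole-free input frames")
    rng = np.random.default_rng(seed)
    out = []
    for f in frames:
        g = f.grid.copy()
        if noise_sigma > 0:
            g = np.maximum(g + rng.normal(0, noise_sigma, g.shape), 0.01)
        if hole_rate > 0:
            g[rng.random(g.shape) < hole_rate] = HOLE
        out.append(DepthFrame(g, index=f.index, frame_rate=f.frame_rate))
    return out


def render_sequence(spec: SceneSpec, script: ActionScript, seed: int = 0):
    """Render a full scripted sequence.

    Returns ``(frames, ground_truth)``; frames carry the spec's noise
    and holes, the ground truth is computed from the clean geometry.
    Rejects a script step whose label implies a person in the room but
    whose pose projects entirely outside the camera frustum.
    """
    bg_depth, regions = render_background(spec)
    per_frame = script.expand()
    T = len(per_frame)
    H, W = spec.shape
    labels = np.zeros(T, dtype=int)
    masks = np.zeros((T, H, W), dtype=bool)
    frames = []
    for t, (lab, parts) in enumerate(per_frame):
        depth = bg_depth
        if parts is not None:
            s = render_person(spec, parts)
            mask = s < bg_depth
            if lab != 0 and not mask.any():
                raise ValueError(
                    f"frame {t}: label {lab} requires a visible person, "
                    "but the pose projects outside the camera frustum")
            depth = np.where(mask, s, bg_depth)
            masks[t] = mask
        labels[t] = lab
        frames.append(DepthFrame(depth.copy(), index=t))
    if spec.noise_sigma > 0 or spec.hole_rate > 0:
        frames = corrupt(frames, spec.noise_sigma, spec.hole_rate, seed)
    gt = GroundTruth(labels=labels, person_masks=masks,
                     region_labels=regions,
                     floor_plane=floor_plane_camera(spec),
                     background_depth=bg_depth)
    return frames, gt


# ---------------------------------------------------------------------------
# canned scenes and scripts (the study conditions)
# ---------------------------------------------------------------------------

BED_TOP = 0.45       # bed height, metres
WHEELCHAIR_POS = (-1.0, 2.3)   # (x, z) where the wheelchair stands
BED_SIT = (1.0, 2.7)           # sitting spot on the bed edge
BED_LIE = (1.3, 3.3)           # lying position on the bed


def default_room(noise_sigma: float = 0.02, hole_rate: float = 0.05,
                 camera_tilt: float = 25.0, curtain: bool = False,
                 intrinsics: Optional[CameraIntrinsics] = None) -> SceneSpec:
    """The reference bedroom: floor, bed, wheelchair, distant back wall."""
    quad = None
    if curtain:
        # partially drawn curtain screening the bed side of the room
        quad = Quad(origin=(-0.4, 0.3, 1.7), edge_u=(2.6, 0.0, 1.2),
                    edge_v=(0.0, 1.7, 0.0))
    return SceneSpec(
        camera_height=2.1, camera_tilt=camera_tilt,
        intrinsics=intrinsics or CameraIntrinsics(),
        bed_box=Box(x=(0.55, 2.15), y=(0.0, BED_TOP), z=(2.4, 4.5)),
        static_objects=(Box(x=(-1.35, -0.65), y=(0.0, 0.55), z=(2.0, 2.7)),),
        curtain=quad, sensor_range=6.5,
        noise_sigma=noise_sigma, hole_rate=hole_rate)


def benchmark_script() -> ActionScript:
    """A scripted 600-frame day sequence.

    enter (in wheelchair) -> seated in wheelchair -> stand -> walk ->
    sit on the bed -> lie on the bed, with short transitions between.
    """
    wx, wz = WHEELCHAIR_POS
    sx, sz = BED_SIT
    lx, lz = BED_LIE
    seated_wc = PersonPose(wx, wz, base=0.50, posture="seated")
    stand_a = PersonPose(wx + 0.25, wz + 0.15, posture="standing")
    stand_b = PersonPose(sx - 0.15, sz - 0.10, posture="standing")
    sit_bed = PersonPose(sx, sz, base=BED_TOP, posture="seated")
    lie_bed = PersonPose(lx, lz, base=BED_TOP, posture="lying")
    enter = PersonPose(-2.1, wz + 0.1, base=0.50, posture="seated")
    return ActionScript(steps=(
        ScriptStep(0, 60),                                        # empty room
        ScriptStep(2, 12, enter, seated_wc),                      # rolls in
        ScriptStep(2, 100, seated_wc, sway=0.015),                # seated
        ScriptStep(1, 8, seated_wc, stand_a),                     # stands up
        ScriptStep(3, 80, stand_a, stand_b),                      # stands/walks
        ScriptStep(1, 8, stand_b, sit_bed),                       # sits down
        ScriptStep(4, 140, sit_bed, sway=0.015),                  # sits on bed
        ScriptStep(1, 8, sit_bed, lie_bed),                       # lies down
        ScriptStep(5, 184, lie_bed, sway=0.015),                  # lying
    ))


def training_scripts(seed: int, per_label: int = 16):
    """Short labelled scripts for the five trainable actions (1..5).

    Durations are drawn from the 5-30 frame range used for training
    sequences; positions and body height are jittered per sequence.
    Standing alternates between still (with physiological sway) and
    slow-walking variants so both modes of the class are covered.
    """
    rng = np.random.default_rng(seed)
    wx, wz = WHEELCHAIR_POS
    sx, sz = BED_SIT
    lx, lz = BED_LIE
    out = []

    def jit(p: PersonPose, dx=0.15, dz=0.15):
        return replace(p, x=p.x + rng.uniform(-dx, dx),
                       z=p.z + rng.uniform(-dz, dz),
                       height=p.height * rng.uniform(0.93, 1.05))

    seated_wc = PersonPose(wx, wz, base=0.50, posture="seated")
    stand = PersonPose(0.0, 2.6, posture="standing")
    sit_bed = PersonPose(sx, sz, base=BED_TOP, posture="seated")
    lie_bed = PersonPose(lx, lz, base=BED_TOP, posture="lying")

    for k in range(per_label):
        dur = int(rng.integers(5, 31))
        out.append((2, ActionScript((ScriptStep(2, dur, jit(seated_wc),
                                                sway=0.015),))))
        a = jit(stand, dx=0.6, dz=0.3)
        if k % 2 == 0:
            out.append((3, ActionScript((ScriptStep(3, dur, a,
                                                    sway=0.015),))))
        else:
            b = replace(a, x=a.x + rng.uniform(-0.5, 0.5),
                        z=a.z + rng.uniform(-0.2, 0.2))
            out.append((3, ActionScript((ScriptStep(3, dur, a, b),))))
        out.append((4, ActionScript((ScriptStep(4, dur, jit(sit_bed),
                                                sway=0.015),))))
        out.append((5, ActionScript((ScriptStep(5, dur, jit(lie_bed, dx=0.1),
                                                sway=0.015),))))
        # transitions: random pair among the posture changes of the routine
        tdur = int(rng.integers(5, 13))
        pairs = [(jit(seated_wc), jit(stand, dx=0.3)),
                 (jit(stand, dx=0.3), jit(sit_bed)),
                 (jit(sit_bed), jit(lie_bed, dx=0.1)),
                 (jit(lie_bed, dx=0.1), jit(sit_bed)),
                 (jit(stand, dx=0.3), jit(seated_wc))]
        a, b = pairs[int(rng.integers(len(pairs)))]
        out.append((1, ActionScript((ScriptStep(1, tdur, a, b),))))
    return out
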