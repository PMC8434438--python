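"""End-to-end orchestration: frames in, per-frame action labels out.

A sequence is processed in the order of the acquisition protocol:
pre-processing (hole filling + bilateral smoothing), background model
from the first 30 person-free frames, ROI extraction from the
background's UV-disparity maps, floor-plane fitting, then per frame:
background subtraction, curtain removal, mask cleanup, tracking with
the 10-frame person rule, silhouette normalisation and finally the
automatic-rounding recogniser.

Also provides the synthetic training loop: labelled short scripts are
rendered, pushed through the same foreground-extraction path, and their
accumulated DMA/DMH HOG features train the SVM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import synthetic
from .config import PipelineConfig
from .features import (ActionMaps, blob_floor_distance, fit_floor_plane,
                       floor_points_from_frame, maps_to_feature,
                       normalize_silhouette, update_maps)
from .io import DepthFrame
from .preprocessing import BackgroundModel, build_background, preprocess_frame
from .recognition import (ActionClassifier, FrameState, RecognitionRound,
                          rounding_recognize, train_classifier)
from .roi import RegionMap, depth_to_disparity, detect_curtain, extract_regions
from .tracking import Tracker, clean_mask, subtract_background

logger = logging.getLogger(__name__)


@dataclass
class SequenceResult:
    """Everything computed while processing one long sequence."""
    states: list[FrameState]
    rounds: list[RecognitionRound] = field(default_factory=list)
    labels: Optional[np.ndarray] = None           # per-frame codes
    region_map: Optional[RegionMap] = None
    background: Optional[BackgroundModel] = None
    floor_plane: Optional[object] = None
    track_log: list[dict] = field(default_factory=list)


def _setup_scene(frames: Sequence[DepthFrame], cfg: PipelineConfig):
    """Background model, region map and floor plane from the lead-in."""
    lead = [preprocess_frame(f, cfg.bilateral_diameter,
                             cfg.bilateral_sigma_value,
                             cfg.bilateral_sigma_space)
            for f in frames[:cfg.background_frames]]
    bg = build_background(lead, cfg.far_threshold, cfg.background_frames)
    regions = extract_regions(
        bg.average, cfg.intrinsics, far_mask=bg.far_mask,
        n_levels=cfg.n_disparity_levels, min_depth=cfg.min_depth,
        line_tolerance=cfg.line_tolerance,
        bin_threshold=cfg.vmap_bin_threshold,
        angle_min=cfg.hough_angle_min, angle_max=cfg.hough_angle_max,
        min_votes=cfg.hough_min_votes)
    floor_mask = regions.labels == synthetic.FLOOR
    plane = None
    if floor_mask.any():
        pts = floor_points_from_frame(bg.average, floor_mask, cfg.intrinsics,
                                      seed=cfg.seed)
        plane = fit_floor_plane(pts)
    else:
        logger.warning("no floor pixels found; height features disabled")
    return bg, regions, plane


def extract_states(frames: Sequence[DepthFrame], cfg: PipelineConfig,
                   bg: BackgroundModel, regions: RegionMap, plane,
                   require_person: bool = True) -> SequenceResult:
    """Per-frame foreground extraction, tracking and silhouette states.

    With ``require_person`` the 10-frame motion rule gates silhouettes
    (long-sequence mode); without it the largest blob is used from the
    first frame (training mode on annotated short sequences).
    """
    from .roi import localize_blob
    tracker = Tracker(th_dist=cfg.th_dist, th_area=cfg.th_area,
                      th_depth=cfg.th_depth, th_motion=cfg.th_motion,
                      person_window=cfg.person_window,
                      person_min_true=cfg.person_min_true,
                      grace=cfg.track_grace)
    states: list[FrameState] = []
    log: list[dict] = []
    for f in frames:
        pf = preprocess_frame(f, cfg.bilateral_diameter,
                              cfg.bilateral_sigma_value,
                              cfg.bilateral_sigma_space)
        fg = subtract_background(pf, bg, cfg.bg_sub_factor, cfg.bg_sub_floor)
        dmap = depth_to_disparity(pf, cfg.intrinsics,
                                  cfg.n_disparity_levels, cfg.min_depth,
                                  exclude=bg.far_mask)
        curtain = detect_curtain(dmap, fg.grid,
                                 min_cols=cfg.curtain_min_cols)
        fg = clean_mask(fg, curtain, cfg.min_blob_area)
        tracks = tracker.step(fg, pf)
        candidates = tracker.persons() if require_person else \
            [t for t in tracks if t.missed == 0 and t.mask is not None]
        if candidates:
            heights = [blob_floor_distance(t, plane, cfg.intrinsics)
                       if plane is not None else 0.0 for t in candidates]
            if len(candidates) > 1:
                logger.info("frame %d: %d blobs; tracking the tallest",
                            f.index, len(candidates))
            k = int(np.argmax(heights))
            blob = candidates[k]
            states.append(FrameState(
                patch=normalize_silhouette(pf, blob.mask,
                                           (cfg.canvas_height,
                                            cfg.canvas_width)),
                location=localize_blob(blob.mask, regions,
                                       cfg.bed_fraction, cfg.floor_fraction),
                floor_distance=heights[k]))
            log.append({"frame": f.index, "id": blob.id,
                        "centroid": blob.centroid, "area": blob.area,
                        "mean_depth": blob.mean_depth,
                        "person": blob.is_person})
        else:
            states.append(FrameState(patch=None))
    res = SequenceResult(states=states, region_map=regions, background=bg,
                         floor_plane=plane, track_log=log)
    return res


def process_sequence(frames: Sequence[DepthFrame], cfg: PipelineConfig,
                     model: Optional[ActionClassifier] = None
                     ) -> SequenceResult:
    """Full pass over a long sequence (lead-in frames must be person-free)."""
    bg, regions, plane = _setup_scene(frames, cfg)
    res = extract_states(frames, cfg, bg, regions, plane)
    if model is not None:
        res.rounds, res.labels = rounding_recognize(
            res.states, model, th_prob=cfg.th_prob, min_len=cfg.min_round,
            max_len=cfg.max_round, tau=cfg.tau, delta=cfg.delta,
            th_assist=cfg.th_assist, th_fall=cfg.th_fall)
    return res


def sequence_feature(states: Sequence[FrameState],
                     cfg: PipelineConfig) -> Optional[np.ndarray]:
    """Fused DMA/DMH HOG feature of one annotated short sequence."""
    maps = None
    prev = None
    for st in states:
        if st.patch is None:
            continue
        if maps is None:
            maps = ActionMaps(tau=cfg.tau, delta=cfg.delta,
                              shape=st.patch.shape)
        update_maps(maps, st.patch, prev)
        prev = st.patch
    if maps is None:
        return None
    return maps_to_feature(maps)


def build_training_set(cfg: PipelineConfig, seed: int,
                       per_label: int = 16, noise_sigma: float = 0.02,
                       hole_rate: float = 0.05, camera_tilt: float = 25.0):
    """Render labelled short sequences and extract their features.

    The empty reference room provides the background model; each script
    is rendered with the study noise levels and pushed through the same
    foreground-extraction path used at test time.
    """
    spec = synthetic.default_room(noise_sigma=noise_sigma,
                                  hole_rate=hole_rate,
                                  camera_tilt=camera_tilt,
                                  intrinsics=cfg.intrinsics)
    lead_script = synthetic.ActionScript(
        (synthetic.ScriptStep(0, cfg.background_frames),))
    lead_frames, _ = synthetic.render_sequence(spec, lead_script, seed)
    bg, regions, plane = _setup_scene(lead_frames, cfg)
    X, y = [], []
    for k, (label, script) in enumerate(
            synthetic.training_scripts(seed, per_label)):
        frames, _ = synthetic.render_sequence(spec, script,
                                              seed + 1000 + k)
        res = extract_states(frames, cfg, bg, regions, plane,
                             require_person=False)
        feat = sequence_feature(res.states, cfg)
        if feat is None:
            logger.warning("training script %d (label %d): no silhouette",
                           k, label)
            continue
        X.append(feat)
        y.append(label)
    return np.asarray(X), np.asarray(y)


def train_benchmark_model(cfg: PipelineConfig, seed: int,
                          per_label: int = 16) -> ActionClassifier:
    X, y = build_training_set(cfg, seed, per_label)
    return train_classifier(X, y, seed=seed % (2 ** 31))


def run_benchmark(cfg: PipelineConfig, model: ActionClassifier, seed: int,
                  noise_sigma: float = 0.02, hole_rate: float = 0.05):
    """Render and recognise the scripted 600-frame day sequence.

    Returns ``(result, ground_truth)``; ``result.labels`` holds the
    per-frame predictions.
    """
    spec = synthetic.default_room(noise_sigma=noise_sigma,
                                  hole_rate=hole_rate,
                                  intrinsics=cfg.intrinsics)
    frames, gt = synthetic.render_sequence(spec,
                                           synthetic.benchmark_script(),
                                           seed)
    res = process_sequence(frames, cfg, model)
    return res, gt
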