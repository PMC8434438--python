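"""Action classification and online segmentation of long sequences.

A multi-class linear SVM with Platt-calibrated probabilities is trained
on the 3168-dim fused DMA/DMH HOG features of short action sequences
(five trainable labels: Transition, Seated in wheelchair, Standing,
Sitting on the bed, Lying on the bed).  Long continuous sequences are
segmented online by the *automatic rounding* method: a recognition
window grows frame by frame (DMA/DMH accumulated incrementally, reset
at each round start) and closes as soon as the top class probability
reaches ``th_prob`` — or as "undetermined" when the window hits the
maximum duration of 30 frames.  Closed rounds are post-checked against
the person's height above the floor (Receiving assistance above 1.0 m,
Falling below 0.4 m on the floor) and the region the blob occupies.
Per-frame label streams are optionally condensed by a block median
filter (window 5) and scored frame-by-frame against ground truth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np
from sklearn.svm import SVC

from .features import ActionMaps, HOG_LEN, maps_to_feature, update_maps

logger = logging.getLogger(__name__)

FEATURE_LEN = 2 * HOG_LEN  # 3168


class ActionLabel(IntEnum):
    OUTSIDE = 0
    TRANSITION = 1
    SEATED_WHEELCHAIR = 2
    STANDING = 3
    SITTING_BED = 4
    LYING_BED = 5
    ASSISTANCE = 6
    FALLING = 7


UNDETERMINED = -1  # sentinel: round closed without a decision

TRAINABLE = (ActionLabel.TRANSITION, ActionLabel.SEATED_WHEELCHAIR,
             ActionLabel.STANDING, ActionLabel.SITTING_BED,
             ActionLabel.LYING_BED)


@dataclass
class ActionClassifier:
    """Linear max-margin classifier over fused features.

    Probabilities come from pairwise-coupled Platt scaling of the
    per-pair SVM margins.
    """
    svc: SVC
    classes: np.ndarray
    seed: int

    def predict_proba(self, feature: np.ndarray) -> dict[int, float]:
        feature = np.asarray(feature, dtype=float)
        if feature.shape != (FEATURE_LEN,):
            raise ValueError(f"feature must have length {FEATURE_LEN}")
        p = self.svc.predict_proba(feature[None])[0]
        return {int(c): float(pi) for c, pi in zip(self.classes, p)}


def train_classifier(features: Sequence[np.ndarray],
                     labels: Sequence[int], seed: int = 0,
                     C: float = 1.0) -> ActionClassifier:
    """Train the linear SVM on fused 3168-dim features.

    The height feature is deliberately not part of the SVM input; it
    drives the post-hoc assistance/fall rules instead.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[1] != FEATURE_LEN:
        raise ValueError(f"features must be (n, {FEATURE_LEN})")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to train")
    svc = SVC(kernel="linear", C=C, probability=True, random_state=seed)
    with warnings.catch_warnings():
        # scikit-learn flags SVC(probability=True) for future removal;
        # pairwise Platt scaling is exactly the calibration wanted here
        warnings.simplefilter("ignore", FutureWarning)
        svc.fit(X, y)
    return ActionClassifier(svc=svc, classes=svc.classes_, seed=seed)


# ---------------------------------------------------------------------------
# automatic rounding
# ---------------------------------------------------------------------------

@dataclass
class FrameState:
    """Per-frame pipeline output consumed by the recogniser."""
    patch: Optional[np.ndarray]       # normalised silhouette, None if absent
    location: str = "other"           # from blob/region overlap
    floor_distance: float = 0.0       # metres above the floor


@dataclass
class RecognitionRound:
    """One closed segment of the stream (half-open frame span)."""
    start_frame: int
    end_frame: int
    label: int                        # ActionLabel value or UNDETERMINED
    stop_probability: float

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def apply_context_rules(round_label: int, blob_location: str,
                        floor_distance: float, th_assist: float = 1.0,
                        th_fall: float = 0.4) -> int:
    """Height and region overrides on a closed round's SVM label.

    A blob taller than ``th_assist`` is a resident-plus-nurse silhouette
    (Receiving assistance); one lower than ``th_fall`` while on the
    floor has fallen.  Lying requires the bed region; a lying label off
    the bed is demoted to undetermined.
    """
    if floor_distance > th_assist:
        return int(ActionLabel.ASSISTANCE)
    if floor_distance < th_fall and blob_location == "floor":
        return int(ActionLabel.FALLING)
    if round_label == ActionLabel.LYING_BED and blob_location != "bed":
        logger.info("lying label off the bed demoted to undetermined")
        return UNDETERMINED
    return int(round_label)


def rounding_recognize(stream: Sequence[FrameState],
                       model: ActionClassifier, th_prob: float = 0.30,
                       min_len: int = 5, max_len: int = 30,
                       tau: int = 30, delta: float = 0.01,
                       th_assist: float = 1.0, th_fall: float = 0.4,
                       apply_rules: bool = True):
    """Segment a long stream into recognition rounds.

    Returns ``(rounds, per_frame_labels)``.  Frames with no person are
    labelled Outside the room and never belong to a round; rounds tile
    the person-present stretches without gaps or overlaps.  A round in
    progress when the person disappears (or the stream ends) closes as
    undetermined.
    """
    T = len(stream)
    labels = np.full(T, int(ActionLabel.OUTSIDE), dtype=int)
    rounds: list[RecognitionRound] = []
    maps: Optional[ActionMaps] = None
    start = 0
    locations: list[str] = []
    distances: list[float] = []
    prev_patch: Optional[np.ndarray] = None

    def close(end: int, label: int, prob: float) -> None:
        nonlocal maps, locations, distances
        lab = label
        if apply_rules and lab != UNDETERMINED:
            loc = max(set(locations), key=locations.count)
            dist = float(np.median(distances))
            lab = apply_context_rules(lab, loc, dist, th_assist, th_fall)
        rounds.append(RecognitionRound(start, end, lab, prob))
        labels[start:end] = lab
        maps = None
        locations, distances = [], []

    for t, st in enumerate(stream):
        if st.patch is None:
            if maps is not None:
                close(t, UNDETERMINED, 0.0)
            prev_patch = None
            continue
        if maps is None:
            maps = ActionMaps(tau=tau, delta=delta, shape=st.patch.shape)
            start = t
        update_maps(maps, st.patch, prev_patch)
        prev_patch = st.patch
        locations.append(st.location)
        distances.append(st.floor_distance)
        length = t - start + 1
        if length >= min_len:
            proba = model.predict_proba(maps_to_feature(maps))
            best = max(proba, key=proba.get)
            if proba[best] >= th_prob:
                close(t + 1, best, proba[best])
                continue
        if length >= max_len:
            close(t + 1, UNDETERMINED, 0.0)
    if maps is not None:
        close(T, UNDETERMINED, 0.0)
    return rounds, labels


# ---------------------------------------------------------------------------
# smoothing and evaluation
# ---------------------------------------------------------------------------

def median_filter_labels(labels: Sequence[int], window: int = 5) -> np.ndarray:
    """Block median: one output label per consecutive ``window`` frames.

    The lower median is used so outputs stay in the input label set; a
    trailing partial block still emits its median (logged).
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    labels = np.asarray(labels, dtype=int)
    if labels.size % window:
        logger.info("label count %d not a multiple of %d; trailing partial "
                    "block included", labels.size, window)
    out = []
    for i in range(0, labels.size, window):
        block = np.sort(labels[i:i + window])
        out.append(int(block[(block.size - 1) // 2]))
    return np.array(out, dtype=int)


def evaluate(predicted: Sequence[int], truth: Sequence[int],
             n_labels: int = 8):
    """Per-frame accuracy and an actual x predicted confusion matrix.

    Undetermined predictions are excluded from the denominator (the
    recogniser abstained on those frames).
    """
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    keep = predicted != UNDETERMINED
    confusion = np.zeros((n_labels, n_labels), dtype=int)
    np.add.at(confusion, (truth[keep], predicted[keep]), 1)
    n_eval = int(keep.sum())
    accuracy = float((predicted[keep] == truth[keep]).sum() / n_eval) \
        if n_eval else float("nan")
    return accuracy, confusion
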