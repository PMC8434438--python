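"""Camera model and pipeline configuration.

All tunable thresholds of the recognition pipeline live in
:class:`PipelineConfig` so that a whole run is reproducible from one YAML
file.  Defaults follow the published operating point of the monitoring
system this package implements (background-subtraction factor 0.2*sigma,
motion threshold 80, association gates 30 px / 5000 px / 0.5 m, DMH depth
step 0.01 m, height rules 1.0 m / 0.4 m, stop probability 0.30).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole model of the stereo depth camera.

    Parameters
    ----------
    focal_length : float
        Focal length in pixels (``f``).
    baseline : float
        Stereo baseline in metres; together with ``f`` it converts depth
        to disparity (disparity_px = f * baseline / depth).
    principal_point : tuple of float
        ``(c_x, c_y)`` in pixels, defaults to the centre of a 320x180 image.
    """

    focal_length: float = 160.0
    baseline: float = 0.05
    principal_point: tuple[float, float] = (160.0, 90.0)

    def __post_init__(self) -> None:
        if self.focal_length <= 0:
            raise ValueError("focal_length must be positive")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")

    @property
    def fb(self) -> float:
        """Focal length x baseline product (disparity numerator)."""
        return self.focal_length * self.baseline


@dataclass
class PipelineConfig:
    """Every threshold used across the pipeline, in one place.

    Attributes mirror the processing stages: background subtraction,
    object detection/tracking, feature extraction and action recognition.
    """

    # -- camera -----------------------------------------------------------
    intrinsics: CameraIntrinsics = field(default_factory=CameraIntrinsics)
    frame_rate: float = 1.0  # frames per second

    # -- preprocessing ----------------------------------------------------
    bilateral_diameter: int = 5        # px
    bilateral_sigma_value: float = 0.1  # metres
    bilateral_sigma_space: float = 3.0  # px
    background_frames: int = 30
    far_threshold: float = 6.0          # metres; more distant pixels removed

    # -- ROI extraction ---------------------------------------------------
    n_disparity_levels: int = 128
    min_depth: float = 1.0              # metres; sets disparity quantisation
    vmap_bin_threshold: int = 5         # votes to binarise V-disparity
    hough_angle_min: float = 20.0       # deg from horizontal, ground line
    hough_angle_max: float = 80.0
    hough_min_votes: int = 20
    line_tolerance: int = 1             # disparity bins
    bed_fraction: float = 0.70          # blob-on-bed rule
    floor_fraction: float = 0.30        # blob-on-floor rule
    curtain_min_cols: int = 120         # min column span of a curtain line

    # -- foreground / tracking -------------------------------------------
    bg_sub_factor: float = 0.2          # Th_bg_sub = 0.2 * sigma(frame)
    bg_sub_floor: float = 0.05          # metres, guard for sigma == 0
    min_blob_area: int = 100            # px after cleanup
    th_motion: float = 80.0             # sum |depth difference| in a bbox
    th_dist: float = 30.0               # px, centroid association gate
    th_area: float = 5000.0             # px, area association gate
    th_depth: float = 0.5               # metres, mean-depth association gate
    person_window: int = 10             # frames (10 s at 1 fps)
    person_min_true: int = 6            # strict: person iff count > 6
    track_grace: int = 5                # frames a lost track survives

    # -- features ---------------------------------------------------------
    canvas_height: int = 176            # 11 cells of 16 px
    canvas_width: int = 256             # 16 cells of 16 px
    hog_cell: int = 16
    hog_bins: int = 9
    tau: int = 30                       # DMH time window, frames
    delta: float = 0.01                 # metres, DMH motion step

    # -- recognition ------------------------------------------------------
    th_prob: float = 0.30
    min_round: int = 5                  # frames
    max_round: int = 30                 # frames
    th_assist: float = 1.0              # metres
    th_fall: float = 0.4                # metres
    median_window: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_round > self.max_round:
            raise ValueError("min_round must not exceed max_round")
        for name in ("th_motion", "th_dist", "th_area", "th_depth",
                     "th_prob", "th_assist", "th_fall", "delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.median_window % 2 == 0:
            raise ValueError("median_window must be odd")

    # -- YAML round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["intrinsics"] = {
            "focal_length": self.intrinsics.focal_length,
            "baseline": self.intrinsics.baseline,
            "principal_point": list(self.intrinsics.principal_point),
        }
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        intr = d.pop("intrinsics", None)
        cfg = cls(**d) if intr is None else cls(
            intrinsics=CameraIntrinsics(
                focal_length=intr["focal_length"],
                baseline=intr["baseline"],
                principal_point=tuple(intr["principal_point"]),
            ),
            **d,
        )
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
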