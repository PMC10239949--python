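"""Quantitative lung-ultrasound aeration from pixel-intensity statistics.

The estimated proportion of air (EPA) in the lung is obtained from the
coefficient of variation (CoV) of pixel intensity inside rectangular regions
of interest placed below the pleural line, between the acoustic shadows cast
by the ribs.  A liquid-filled lung images as homogeneous tissue-like speckle
(low CoV); an aerated lung produces a bright pleural line with reverberation
artifacts over a dark field (high CoV).  A linear calibration maps CoV onto
EPA in [0, 1], where 0 is a completely liquid-filled and 1 a completely
air-filled lung.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LUSClip",
    "ROI",
    "AerationEstimate",
    "Calibration",
    "pixel_cov",
    "detect_motion_frames",
    "fit_calibration",
    "cov_to_epa",
    "quantify_clip",
    "DEFAULT_MOTION_THRESHOLD",
]

#: Default normalised inter-frame difference above which a frame is treated
#: as motion-corrupted and excluded from the CoV average.
DEFAULT_MOTION_THRESHOLD = 0.15

_MIN_ROI_AREA = 64


@dataclass
class LUSClip:
    """A multi-frame lung-ultrasound clip (8-bit grayscale).

    ``frames`` has shape (n_frames, height, width).  ``acquisition_time_min``
    is minutes after the onset of air breathing (negative = before breathing).
    """

    frames: np.ndarray
    frame_rate: float = 15.0
    acquisition_time_min: float = 0.0
    lamb_id: str = ""
    side: str = "left"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim == 2:
            frames = frames[None, :, :]
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise ValueError("frames must be a (n_frames, H, W) stack with >= 1 frame")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest, 0-based, half-open pixel intervals.

    Covers rows ``y:y+height`` and columns ``x:x+width`` of a frame.
    """

    x: int
    y: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.x < 0 or self.y < 0:
            raise ValueError("ROI must have non-negative origin and positive size")
        if self.area < _MIN_ROI_AREA:
            raise ValueError(f"ROI area {self.area} px < minimum {_MIN_ROI_AREA} px")

    @property
    def area(self) -> int:
        return self.width * self.height

    def validate_within(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.y + self.height > h or self.x + self.width > w:
            raise ValueError(f"ROI {self} exceeds frame bounds {shape}")

    def extract(self, frame: np.ndarray) -> np.ndarray:
        return frame[self.y : self.y + self.height, self.x : self.x + self.width]

    def to_dict(self) -> dict:
        return {"x": self.x, "y": self.y, "width": self.width, "height": self.height}

    @classmethod
    def from_dict(cls, d: dict) -> "ROI":
        return cls(int(d["x"]), int(d["y"]), int(d["width"]), int(d["height"]))


@dataclass(frozen=True)
class Calibration:
    """Linear CoV -> EPA map: ``epa = intercept + slope * cov`` (then clamped)."""

    intercept: float
    slope: float
    r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")


@dataclass(frozen=True)
class AerationEstimate:
    """Per-clip aeration quantification result."""

    cov: float
    epa: float
    n_frames_used: int
    n_frames_excluded: int
    rois: tuple[ROI, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.epa <= 1.0:
            raise ValueError("epa must lie in [0, 1]")
        if self.n_frames_used < 1:
            raise ValueError("at least one frame must be used")


def _roi_cov(pixels: np.ndarray) -> float:
    """Population SD / mean of one ROI's pixels (float64)."""
    vals = pixels.astype(np.float64, copy=False)
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("degenerate ROI: mean pixel intensity is not positive")
    return float(vals.std(ddof=0) / mean)


def pixel_cov(
    clip: LUSClip,
    rois: Sequence[ROI],
    excluded_frames: Iterable[int] = (),
    pool_pixels: bool = False,
) -> float:
    """Mean pixel-intensity CoV of a clip over ROIs and non-excluded frames.

    The CoV of each (frame, ROI) pair is the population standard deviation of
    pixel intensity divided by the mean intensity; the clip value is the
    arithmetic mean over all non-excluded frames and all ROIs.  With
    ``pool_pixels=True`` the pixels of all ROIs and retained frames are pooled
    into a single population first (alternative aggregation).
    """
    if len(rois) == 0:
        raise ValueError("at least one ROI is required")
    for roi in rois:
        roi.validate_within(clip.shape)
    excluded = set(int(i) for i in excluded_frames)
    kept = [i for i in range(clip.n_frames) if i not in excluded]
    if not kept:
        raise ValueError("all frames excluded; cannot compute CoV")
    if pool_pixels:
        pooled = np.concatenate(
            [roi.extract(clip.frames[i]).ravel() for i in kept for roi in rois]
        )
        return _roi_cov(pooled)
    covs = [_roi_cov(roi.extract(clip.frames[i])) for i in kept for roi in rois]
    return float(np.mean(covs))


def detect_motion_frames(clip: LUSClip, threshold: float = DEFAULT_MOTION_THRESHOLD) -> set[int]:
    """Indices of frames corrupted by bulk movement.

    Frame i (i >= 1) is flagged when the mean absolute intensity difference
    from frame i-1, divided by the global mean intensity of the clip, exceeds
    ``threshold``.  Frame 0 is never flagged by this rule.  A single-frame
    clip returns the empty set.
    """
    frames = clip.frames.astype(np.float64, copy=False)
    if frames.shape[0] < 2:
        return set()
    global_mean = frames.mean()
    if global_mean <= 0:
        raise ValueError("clip has non-positive mean intensity")
    diffs = np.abs(np.diff(frames, axis=0)).mean(axis=(1, 2)) / global_mean
    return {int(i) + 1 for i in np.nonzero(diffs > threshold)[0]}


def fit_calibration(pairs: Sequence[tuple[float, float]]) -> Calibration:
    """Ordinary least-squares line mapping CoV to a reference EPA.

    ``pairs`` are (cov, reference_epa).  Requires >= 3 pairs, non-constant
    CoV, and non-constant reference (a constant reference has no slope and is
    rejected as degenerate).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] != 2:
        raise ValueError("need >= 3 (cov, reference_epa) pairs")
    cov, ref = arr[:, 0], arr[:, 1]
    if np.ptp(cov) == 0:
        raise ValueError("degenerate calibration input: all CoV values equal")
    if np.ptp(ref) == 0:
        raise ValueError("degenerate calibration input: constant reference EPA")
    slope, intercept = np.polyfit(cov, ref, 1)
    pred = intercept + slope * cov
    ss_res = float(np.sum((ref - pred) ** 2))
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return Calibration(intercept=float(intercept), slope=float(slope), r2=r2)


def cov_to_epa(cov: float, cal: Calibration) -> float:
    """EPA from CoV through a linear calibration, clamped to [0, 1]."""
    if not np.isfinite(cov):
        raise ValueError("cov must be finite")
    return float(np.clip(cal.intercept + cal.slope * cov, 0.0, 1.0))


def quantify_clip(
    clip: LUSClip,
    rois: Sequence[ROI],
    cal: Calibration,
    motion_threshold: float = DEFAULT_MOTION_THRESHOLD,
    pool_pixels: bool = False,
) -> AerationEstimate:
    """Full per-clip quantification: motion exclusion -> CoV -> EPA."""
    excluded = detect_motion_frames(clip, motion_threshold) if clip.n_frames > 1 else set()
    cov = pixel_cov(clip, rois, excluded_frames=excluded, pool_pixels=pool_pixels)
    epa = cov_to_epa(cov, cal)
    return AerationEstimate(
        cov=cov,
        epa=epa,
        n_frames_used=clip.n_frames - len(excluded),
        n_frames_excluded=len(excluded),
        rois=tuple(rois),
    )
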