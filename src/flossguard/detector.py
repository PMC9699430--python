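"""White-marker-rectangle detection on filter-windowed fluorescence frames.

The image pipeline mirrors the inspection camera's firmware: convert to
grayscale, linearly enhance intensities (x4 by default, clipping at full
scale), pick a global gray-level threshold by Otsu's between-class-variance
criterion, extract 8-connected bright regions, discard regions of 200 pixels
or fewer, and report a tight bounding rectangle per surviving region.  Any
marker present commands the vibration motor to STOP.

Otsu's criterion always proposes *some* split, even on a frame that contains
nothing but background texture, and on such a frame roughly half the pixels
land above the level and merge into one giant "region".  The detector
therefore checks the contrast of the proposed split — the gap between the
foreground and background class means as a fraction of full scale — and
treats frames below ``min_contrast`` as empty: weak, unimodal floss texture
(a few percent contrast) must not raise markers, while genuine bone, fillet,
nail, or glove signals sit far above the floor.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from skimage import measure

__all__ = [
    "DetectionResult",
    "DetectorConfig",
    "Frame",
    "MarkerRectangle",
    "MotorCommand",
    "ThresholdMethod",
    "ThresholdSelection",
    "annotate",
    "detect",
    "enhance_linear",
    "extract_regions",
    "select_threshold",
    "to_grayscale",
]

#: ITU-R BT.601 luminance weights for multichannel frames.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class Frame:
    """A camera frame: 2-D (or HxWx3) raster with a bit depth and a spatial
    scale in mm per pixel."""

    pixels: np.ndarray
    bit_depth: int = 16
    pixel_pitch_mm: float = 0.125

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        object.__setattr__(self, "pixels", px)
        if self.bit_depth not in (8, 16):
            raise ValueError("bit depth must be 8 or 16")
        if px.ndim not in (2, 3) or px.size == 0:
            raise ValueError("frame must be a nonempty 2-D or 3-channel raster")
        if px.ndim == 3 and px.shape[2] != 3:
            raise ValueError("multichannel frames must have exactly 3 channels")
        if not self.pixel_pitch_mm > 0:
            raise ValueError("pixel pitch must be positive")
        if px.min() < 0 or px.max() > self.max_value:
            raise ValueError(
                f"pixel values must lie in [0, {self.max_value}] for "
                f"{self.bit_depth}-bit frames"
            )

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape


class ThresholdMethod(str, enum.Enum):
    OTSU = "otsu"
    FIXED = "fixed"


class MotorCommand(str, enum.Enum):
    RUN = "RUN"
    STOP = "STOP"


@dataclass(frozen=True)
class DetectorConfig:
    """Tunables of the marker pipeline.

    ``gain`` is the linear enhancement factor; ``min_region_px`` is the
    strict area cut ("more than 200 pixels"); ``min_contrast`` is the
    class-contrast floor (fraction of full scale) below which a frame
    counts as foreground-free.
    """

    gain: float = 4.0
    min_region_px: int = 200
    threshold_method: ThresholdMethod = ThresholdMethod.OTSU
    fixed_level: int | None = None
    connectivity: int = 8
    min_contrast: float = 0.15

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError("gain must be positive")
        if self.min_region_px < 1:
            raise ValueError("min_region_px must be a positive integer")
        object.__setattr__(
            self, "threshold_method", ThresholdMethod(self.threshold_method)
        )
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if (self.threshold_method is ThresholdMethod.FIXED) != (
            self.fixed_level is not None
        ):
            raise ValueError(
                "fixed_level is required iff threshold_method is 'fixed'"
            )
        if not (0.0 <= self.min_contrast <= 1.0):
            raise ValueError("min_contrast must be in [0, 1]")


@dataclass(frozen=True)
class MarkerRectangle:
    """Tight bounding box of one bright region (0-based, half-open)."""

    bbox: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max)
    region_area_px: int
    mean_intensity: float

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.bbox
        if not (r0 < r1 and c0 < c1):
            raise ValueError("bounding box must be nonempty")
        if self.region_area_px < 1:
            raise ValueError("region area must be positive")
        if self.region_area_px > (r1 - r0) * (c1 - c0):
            raise ValueError("region area cannot exceed its bounding-box area")

    def intersects(self, other_bbox: tuple[int, int, int, int]) -> bool:
        r0, c0, r1, c1 = self.bbox
        s0, t0, s1, t1 = other_bbox
        return r0 < s1 and s0 < r1 and c0 < t1 and t0 < c1


@dataclass(frozen=True)
class DetectionResult:
    markers: tuple[MarkerRectangle, ...]
    threshold_used: int
    motor_command: MotorCommand
    separability: float = 1.0

    def __post_init__(self) -> None:
        expected = MotorCommand.STOP if self.markers else MotorCommand.RUN
        if self.motor_command is not expected:
            raise ValueError("motor command must be STOP iff markers are present")


class ThresholdSelection(NamedTuple):
    """Outcome of gray-level threshold selection.

    ``separability`` is Otsu's goodness measure (between-class over total
    variance); ``contrast`` is the gap between the class means as a fraction
    of full scale.
    """

    level: int
    separability: float
    degenerate: bool
    contrast: float = 0.0


# ---------------------------------------------------------------------------
# operations


def to_grayscale(frame: Frame) -> Frame:
    """Single-channel frames pass through; 3-channel frames collapse to the
    BT.601 luminance-weighted mean."""
    px = frame.pixels
    if px.ndim == 2:
        return frame
    gray = np.tensordot(px.astype(np.float64), _LUMA_WEIGHTS, axes=([2], [0]))
    gray = np.clip(np.rint(gray), 0, frame.max_value).astype(frame.dtype)
    return replace(frame, pixels=gray)


def enhance_linear(frame: Frame, gain: float) -> Frame:
    """Scale every pixel by ``gain``, rounding and clipping at full scale."""
    if not gain > 0:
        raise ValueError("gain must be positive")
    out = np.clip(np.rint(frame.pixels.astype(np.float64) * gain), 0, frame.max_value)
    return replace(frame, pixels=out.astype(frame.dtype))


def select_threshold(frame: Frame) -> ThresholdSelection:
    """Otsu's gray-level threshold for a single-channel frame.

    Returns the level t maximizing the between-class variance of the split
    {v <= t} / {v > t}, the separability measure (between-class variance over
    total variance, in [0, 1]), and a degeneracy flag.  A constant frame is
    degenerate: its own value is returned with separability 0.  Ties break
    toward the lowest level, so the result is deterministic.
    """
    px = frame.pixels
    if px.ndim != 2:
        raise ValueError("threshold selection expects a single-channel frame")
    levels = 1 << frame.bit_depth
    hist = np.bincount(px.ravel().astype(np.int64), minlength=levels).astype(
        np.float64
    )
    total = hist.sum()
    values = np.arange(levels, dtype=np.float64)
    mu_total = (hist * values).sum() / total
    var_total = (hist * (values - mu_total) ** 2).sum() / total
    if var_total == 0.0:
        return ThresholdSelection(int(px.flat[0]), 0.0, True, 0.0)
    w0 = np.cumsum(hist)
    s0 = np.cumsum(hist * values)
    w1 = total - w0
    # valid split points: both classes nonempty
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.divide(s0, w0, out=np.zeros_like(s0), where=w0 > 0)
    mu1 = np.divide(
        s0[-1] - s0, w1, out=np.zeros_like(s0), where=w1 > 0
    )
    sigma_b = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2 / total**2, -np.inf)
    level = int(np.argmax(sigma_b))
    separability = float(sigma_b[level] / var_total)
    contrast = float((mu1[level] - mu0[level]) / (levels - 1))
    return ThresholdSelection(level, separability, False, contrast)


def extract_regions(
    frame: Frame, level: int, config: DetectorConfig | None = None
) -> tuple[MarkerRectangle, ...]:
    """Connected components of pixels strictly above ``level`` whose area
    strictly exceeds ``min_region_px``, as marker rectangles ordered by
    (row_min, col_min)."""
    if config is None:
        config = DetectorConfig()
    px = frame.pixels
    if px.ndim != 2:
        raise ValueError("region extraction expects a single-channel frame")
    if not (0 <= level <= frame.max_value):
        raise ValueError("threshold level outside the frame's intensity range")
    mask = px > level
    labels = measure.label(mask, connectivity=1 if config.connectivity == 4 else 2)
    markers = []
    for region in measure.regionprops(labels, intensity_image=px):
        if region.area > config.min_region_px:
            r0, c0, r1, c1 = region.bbox
            markers.append(
                MarkerRectangle(
                    bbox=(int(r0), int(c0), int(r1), int(c1)),
                    region_area_px=int(region.area),
                    mean_intensity=float(region.intensity_mean),
                )
            )
    markers.sort(key=lambda m: (m.bbox[0], m.bbox[1]))
    return tuple(markers)


def detect(frame: Frame, config: DetectorConfig | None = None) -> DetectionResult:
    """Full marker pipeline: grayscale -> linear enhancement -> threshold ->
    bright-region extraction -> motor decision (STOP iff any marker)."""
    if config is None:
        config = DetectorConfig()
    gray = to_grayscale(frame)
    enhanced = enhance_linear(gray, config.gain)
    if config.threshold_method is ThresholdMethod.FIXED:
        level = int(config.fixed_level)  # type: ignore[arg-type]
        separability = 1.0
        empty = False
    else:
        selection = select_threshold(enhanced)
        level = selection.level
        separability = selection.separability
        empty = selection.degenerate or selection.contrast < config.min_contrast
    markers = () if empty else extract_regions(enhanced, level, config)
    command = MotorCommand.STOP if markers else MotorCommand.RUN
    return DetectionResult(
        markers=markers,
        threshold_used=level,
        motor_command=command,
        separability=separability,
    )


def annotate(frame: Frame, result: DetectionResult, thickness: int = 2) -> Frame:
    """Copy of the frame with full-scale marker outlines burned in."""
    gray = to_grayscale(frame)
    out = gray.pixels.copy()
    full = frame.max_value
    h, w = out.shape
    for marker in result.markers:
        r0, c0, r1, c1 = marker.bbox
        for t in range(thickness):
            rr0, cc0 = max(r0 - t, 0), max(c0 - t, 0)
            rr1, cc1 = min(r1 - 1 + t, h - 1), min(c1 - 1 + t, w - 1)
            out[rr0, cc0 : cc1 + 1] = full
            out[rr1, cc0 : cc1 + 1] = full
            out[rr0 : rr1 + 1, cc0] = full
            out[rr0 : rr1 + 1, cc1] = full
    return replace(gray, pixels=out)
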