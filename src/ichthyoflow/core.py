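"""Shared data model, units and coordinate conventions.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)``;
* bounding boxes are half-open ``(r0, c0, r1, c1)`` with ``r0 <= r < r1``;
* the pixel scale is a single isotropic scalar in mm/px (telecentric optics
  give an orthographic projection, so one scalar suffices);
* images are 8-bit grayscale; RGB input is collapsed to luminance on load.

All physical outputs are in mm (lengths), mm^2 (areas) and mm^3 (volumes).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class ConfigurationError(ValueError):
    """Raised for invalid configuration values (e.g. non-positive scale)."""


@dataclass(frozen=True)
class PixelScale:
    """Isotropic pixel scale in millimetres per pixel.

    Parameters
    ----------
    mm_per_px : float
        Physical size of one pixel side, mm. Must be positive.
    """

    mm_per_px: float

    def __post_init__(self) -> None:
        if not (self.mm_per_px > 0):
            raise ConfigurationError(
                f"mm_per_px must be positive, got {self.mm_per_px!r}"
            )

    @property
    def mm2_per_px2(self) -> float:
        return self.mm_per_px ** 2


def to_mm(value_px: float | np.ndarray, scale: PixelScale) -> float | np.ndarray:
    """Convert a length in pixels to millimetres."""
    return value_px * scale.mm_per_px


def area_to_mm2(area_px: float | np.ndarray, scale: PixelScale) -> float | np.ndarray:
    """Convert an area in square pixels to square millimetres."""
    return area_px * scale.mm2_per_px2


def as_gray(pixels: np.ndarray) -> np.ndarray:
    """Collapse an image to a 2-D uint8 luminance raster.

    RGB(A) input is averaged over the colour channels with equal weights;
    the alpha channel, if present, is ignored.
    """
    arr = np.asarray(pixels)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    elif arr.ndim != 2:
        raise ValueError(f"expected a 2-D or 3-D raster, got shape {arr.shape}")
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


@dataclass
class Frame:
    """One camera frame: an 8-bit grayscale raster with a stream index."""

    index: int
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("frame index must be non-negative")
        self.pixels = as_gray(self.pixels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


class FeatureClass(str, enum.Enum):
    """Segmentation feature classes.

    Larva mode uses {BODY, EYE, YOLK}; egg mode uses {EGG, BODY, YOLK} but
    only EGG regions are measured (embryo body and yolk segmentations inside
    eggs are unreliable and excluded from output).
    """

    BODY = "body"
    EYE = "eye"
    YOLK = "yolk"
    EGG = "egg"


LARVA_CLASSES = frozenset({FeatureClass.BODY, FeatureClass.EYE, FeatureClass.YOLK})
EGG_CLASSES = frozenset({FeatureClass.EGG, FeatureClass.BODY, FeatureClass.YOLK})


def tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Half-open tight bounding box ``(r0, c0, r1, c1)`` of a boolean mask."""
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    if not rows.any():
        raise ValueError("empty mask has no bounding box")
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    return int(r0), int(c0), int(r1) + 1, int(c1) + 1


@dataclass
class LabeledRegion:
    """One binary instance mask tagged with a feature class.

    The currency of the segmenter adapter: any external segmenter's output is
    converted to a list of these per frame.
    """

    feature_class: FeatureClass
    mask: np.ndarray
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        return tight_bbox(self.mask)

    @property
    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        return float(rr.mean()), float(cc.mean())


@dataclass
class LarvaRecord:
    """Per-larva morphometrics and volume estimates, physical units.

    Lengths in mm, areas in mm^2, volumes in mm^3. ``facing_direction`` is a
    unit ``(d_row, d_col)`` heading from tail to head in the image plane.
    A ``None`` field means the measurement was unavailable; the validity
    flags say which feature groups were measured at all.
    """

    standard_length_mm: Optional[float] = None
    body_area_mm2: Optional[float] = None
    total_volume_mm3: Optional[float] = None
    yolk_length_mm: Optional[float] = None
    yolk_width_mm: Optional[float] = None
    yolk_volume_mm3: Optional[float] = None
    structural_volume_mm3: Optional[float] = None
    eye_length_mm: Optional[float] = None
    eye_width_mm: Optional[float] = None  # reported as eye diameter
    eye_volume_mm3: Optional[float] = None
    eye_count: int = 0
    facing_direction: Optional[tuple[float, float]] = None
    body_valid: bool = False
    yolk_valid: bool = False
    eyes_valid: bool = False
    flags: list[str] = field(default_factory=list)


@dataclass
class EggRecord:
    """Per-egg morphometrics: only the egg shell is measured.

    Embryo body and internal yolk fields are deliberately absent — those
    segmentations are unreliable in egg images and are excluded by policy.
    """

    egg_major_mm: Optional[float] = None
    egg_minor_mm: Optional[float] = None
    egg_diameter_mm: Optional[float] = None
    egg_radius_mm: Optional[float] = None
    egg_volume_mm3: Optional[float] = None
    circularity: Optional[float] = None
    egg_valid: bool = False
    flags: list[str] = field(default_factory=list)
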