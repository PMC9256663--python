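"""Candidate-frame selection by moving-average background subtraction.

Most frames in a flow-through image stream are empty background. A per-pixel
mean over the surrounding frames estimates the background; pixels whose
absolute deviation from that mean exceeds a threshold are foreground.
Connected foreground blobs are filtered by area and bounding-box size, and
frames retaining at least one blob are selected as candidates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import measure

from .core import Frame, PixelScale


class StreamTooShortError(ValueError):
    """Stream has too few frames for the requested background window."""


@dataclass
class FrameStream:
    """An ordered sequence of same-shape frames."""

    frames: list[Frame]

    def __post_init__(self) -> None:
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"frames differ in shape: {sorted(shapes)}")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def as_array(self) -> np.ndarray:
        return np.stack([f.pixels for f in self.frames])

    @classmethod
    def from_array(cls, stack: np.ndarray) -> "FrameStream":
        return cls([Frame(i, img) for i, img in enumerate(stack)])


def read_stream(path: str | os.PathLike) -> FrameStream:
    """Read a stream from a directory of PNG/TIFF frames or a multi-page TIFF.

    Directory entries are ordered by filename (numeric-aware: zero-padded or
    plain integers both sort correctly via the natural key).
    """
    p = Path(path)
    if p.is_dir():
        files = sorted(
            [f for f in p.iterdir() if f.suffix.lower() in {".png", ".tif", ".tiff"}],
            key=_natural_key,
        )
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames in {p}")
        return FrameStream([Frame(i, iio.imread(f)) for i, f in enumerate(files)])
    imgs = iio.imread(p, index=None)
    imgs = np.asarray(imgs)
    if imgs.ndim == 2:
        imgs = imgs[None]
    return FrameStream([Frame(i, img) for i, img in enumerate(imgs)])


def _natural_key(path: Path) -> tuple:
    import re

    parts = re.split(r"(\d+)", path.stem)
    return tuple(int(s) if s.isdigit() else s for s in parts)


@dataclass
class BackgroundModel:
    """Per-pixel mean intensity over a window of surrounding frames."""

    mean_image: np.ndarray
    window_indices: tuple[int, ...]


def build_background(
    stream: FrameStream, index: int, window: int = 50
) -> BackgroundModel:
    """Mean image over the ``window`` frames nearest to ``index``.

    The target frame itself is excluded from its own window (a large object
    would otherwise suppress its own detection). At the ends of the stream the
    window is drawn from the nearest available frames, so it stays the same
    size but becomes asymmetric.
    """
    n = len(stream)
    if not 0 <= index < n:
        raise IndexError(f"frame index {index} out of range for {n} frames")
    if window < 1:
        raise ValueError("window must be >= 1")
    if n - 1 < window:
        raise StreamTooShortError(
            f"stream has {n} frames but the background window needs {window} "
            f"surrounding frames; use a smaller --window"
        )
    others = np.array([i for i in range(n) if i != index])
    # nearest `window` frames; ties broken toward earlier frames
    order = np.argsort(np.abs(others - index), kind="stable")
    chosen = np.sort(others[order[:window]])
    mean = np.mean([stream[i].pixels for i in chosen], axis=0)
    return BackgroundModel(mean_image=mean, window_indices=tuple(int(i) for i in chosen))


def foreground_mask(
    frame: Frame, bg: BackgroundModel, threshold: float = 25.0
) -> np.ndarray:
    """Binary foreground: pixels deviating from the background mean.

    A pixel is foreground iff ``|frame - mean| > threshold`` (strict). The
    comparison is in float, so a global additive intensity offset applied to
    every frame in the stream cancels exactly.
    """
    if frame.shape != bg.mean_image.shape:
        raise ValueError(
            f"frame shape {frame.shape} != background shape {bg.mean_image.shape}"
        )
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    return np.abs(frame.pixels.astype(np.float64) - bg.mean_image) > threshold


@dataclass
class Blob:
    """One connected component of the foreground mask."""

    label: int
    area_px: int
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]


def detect_blobs(mask: np.ndarray, connectivity: int = 8) -> list[Blob]:
    """Connected components of a binary mask as Blob records.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels = measure.label(mask.astype(bool), connectivity=1 if connectivity == 4 else 2)
    blobs = []
    for rp in measure.regionprops(labels):
        blobs.append(
            Blob(
                label=int(rp.label),
                area_px=int(rp.area),
                bbox=tuple(int(v) for v in rp.bbox),  # type: ignore[arg-type]
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            )
        )
    return blobs


def filter_blobs(
    blobs: Sequence[Blob], min_area_px: float = 0.0, min_bbox_side_px: float = 0.0
) -> list[Blob]:
    """Keep blobs that are large enough to be an egg or larva.

    A blob survives when its area is at least ``min_area_px`` AND both
    bounding-box sides are at least ``min_bbox_side_px``. Order is preserved.
    """
    if min_area_px < 0 or min_bbox_side_px < 0:
        raise ValueError("thresholds must be non-negative")
    out = []
    for b in blobs:
        r0, c0, r1, c1 = b.bbox
        if (
            b.area_px >= min_area_px
            and (r1 - r0) >= min_bbox_side_px
            and (c1 - c0) >= min_bbox_side_px
        ):
            out.append(b)
    return out


@dataclass
class SelectionConfig:
    """Parameters of candidate-frame selection.

    ``min_area_mm2`` and ``min_bbox_side_mm`` are physical so they survive
    resolution changes; they are converted through the pixel scale.
    """

    scale: PixelScale
    window: int = 50
    threshold: float = 25.0
    min_area_mm2: float = 0.2
    min_bbox_side_mm: float = 0.0
    connectivity: int = 8

    def min_area_px(self) -> float:
        return self.min_area_mm2 / self.scale.mm2_per_px2

    def min_bbox_side_px(self) -> float:
        return self.min_bbox_side_mm / self.scale.mm_per_px


@dataclass
class CandidateFrame:
    index: int
    blobs: list[Blob] = field(default_factory=list)

    @property
    def selected(self) -> bool:
        return len(self.blobs) > 0


def select_candidates(
    stream: FrameStream, config: SelectionConfig
) -> list[CandidateFrame]:
    """Run background subtraction + blob filtering over a whole stream.

    Returns one CandidateFrame per input frame; a frame is selected iff at
    least one blob survives the size filters. All frames passing the filters
    are selected (any manual sub-sampling for annotation is a downstream
    choice outside this function).
    """
    out = []
    for i in range(len(stream)):
        bg = build_background(stream, i, config.window)
        mask = foreground_mask(stream[i], bg, config.threshold)
        blobs = detect_blobs(mask, config.connectivity)
        kept = filter_blobs(blobs, config.min_area_px(), config.min_bbox_side_px())
        out.append(CandidateFrame(index=i, blobs=kept))
    return out


def selection_manifest(candidates: Iterable[CandidateFrame]) -> pd.DataFrame:
    """Tabular manifest of a selection run (one row per frame)."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "frame_index": c.index,
                "n_blobs": len(c.blobs),
                "max_blob_area_px": max((b.area_px for b in c.blobs), default=0),
                "selected": c.selected,
            }
        )
    return pd.DataFrame(rows, columns=["frame_index", "n_blobs", "max_blob_area_px", "selected"])
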