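"""Annotation data model: outline smoothing, even resampling, persistence.

Hand-drawn feature outlines are stored in two interchangeable forms:

* polygon CSVs — one row per vertex with columns
  ``image_id, feature_class, instance_index, point_index, row, col``;
* lossless 8-bit PNG label masks — one file per image per feature class,
  background 0, instances encoded as gray levels 1..n.

Outlines are smoothed with a circular moving average of the vertex
coordinates and re-parameterized as evenly spaced points along the closed
polyline. A seeded random 90/10 train/validation split is provided for
building segmenter training sets.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from skimage import measure
from skimage.draw import polygon2mask

from .core import FeatureClass


@dataclass
class Outline:
    """A closed polygon outline of one feature instance.

    ``points`` is an ``(n, 2)`` float array of ``(row, col)`` vertices; the
    polygon is implicitly closed (first vertex is not repeated at the end).
    """

    feature_class: FeatureClass
    points: np.ndarray
    source_image: Optional[str] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 3:
            raise ValueError("an outline needs >= 3 (row, col) vertices")


def smooth_outline(points: np.ndarray, smoothing_window: int = 5) -> np.ndarray:
    """Circular moving average of polygon vertex coordinates.

    Window 1 is the identity. The filter wraps around the closed polygon, so
    the vertex count and the centroid are preserved exactly.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("an outline needs >= 3 vertices")
    if smoothing_window < 1:
        raise ValueError("smoothing window must be >= 1")
    if smoothing_window == 1:
        return pts.copy()
    return uniform_filter1d(pts, size=smoothing_window, axis=0, mode="wrap")


def resample_evenly(points: np.ndarray, n_points: int = 100) -> np.ndarray:
    """Resample a closed polygon to ``n_points`` equally spaced vertices.

    Spacing is uniform in arc length (perimeter / n_points) along the closed
    polyline; the first output vertex is anchored at the first input vertex.
    """
    pts = np.asarray(points, dtype=float)
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = cum[-1]
    if perimeter <= 0:
        raise ValueError("zero-perimeter polygon cannot be resampled")
    targets = perimeter * np.arange(n_points) / n_points
    rows = np.interp(targets, cum, closed[:, 0])
    cols = np.interp(targets, cum, closed[:, 1])
    return np.column_stack([rows, cols])


def perimeter_of(points: np.ndarray) -> float:
    """Closed-polyline perimeter of a polygon."""
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


def outline_to_mask(outline: Outline, image_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize an outline to a boolean mask (interior filled).

    Vertices outside the image are clipped with a warning; an outline fully
    outside the image yields an empty mask.
    """
    pts = outline.points
    h, w = image_shape
    if (pts[:, 0].min() < -0.5 or pts[:, 1].min() < -0.5
            or pts[:, 0].max() > h - 0.5 or pts[:, 1].max() > w - 0.5):
        warnings.warn("outline extends outside the image; clipping", stacklevel=2)
    return polygon2mask(image_shape, pts)


def mask_to_outline(
    mask: np.ndarray, feature_class: FeatureClass = FeatureClass.BODY
) -> Outline:
    """Trace the boundary of a binary mask back to a polygon outline.

    The longest 0.5-level contour is used; round-tripping
    mask -> outline -> mask perturbs only boundary pixels.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("cannot trace an outline from an empty mask")
    padded = np.pad(m, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    longest = max(contours, key=len) - 1.0  # undo padding offset
    if len(longest) >= 2 and np.allclose(longest[0], longest[-1]):
        longest = longest[:-1]
    return Outline(feature_class=feature_class, points=longest)


def split_dataset(
    ids: Sequence[str], train_fraction: float = 0.9, seed: int = 0
) -> dict[str, str]:
    """Random train/validation assignment, deterministic for a given seed.

    The train count is ``round(train_fraction * n)``, so the realized split
    is within one item of the requested fraction.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    ids = list(ids)
    if not ids:
        return {}
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    assignment = {}
    for rank, idx in enumerate(order):
        assignment[ids[idx]] = "train" if rank < n_train else "validation"
    return assignment


def split_manifest(assignment: dict[str, str], seed: int) -> pd.DataFrame:
    return pd.DataFrame(
        [{"id": k, "split": v, "seed": seed} for k, v in sorted(assignment.items())]
    )


# ---------------------------------------------------------------------------
# persistence

CSV_COLUMNS = ["image_id", "feature_class", "instance_index", "point_index", "row", "col"]


def write_outlines_csv(outlines: Sequence[Outline], path: str | os.PathLike,
                       image_id: str = "") -> None:
    """Write outlines as a vertex-per-row polygon CSV (full float precision)."""
    rows = []
    by_class: dict[FeatureClass, int] = {}
    for o in outlines:
        inst = by_class.get(o.feature_class, 0)
        by_class[o.feature_class] = inst + 1
        img = o.source_image or image_id
        for j, (r, c) in enumerate(o.points):
            rows.append((img, o.feature_class.value, inst, j, r, c))
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def read_outlines_csv(path: str | os.PathLike) -> list[Outline]:
    """Read a polygon CSV back into outlines (coordinates round-trip exactly)."""
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for (img, cls, inst), grp in df.groupby(
        ["image_id", "feature_class", "instance_index"], sort=True
    ):
        grp = grp.sort_values("point_index")
        pts = grp[["row", "col"]].to_numpy(dtype=float)
        out.append(Outline(FeatureClass(cls), pts, source_image=str(img)))
    return out


def write_label_mask(masks: Sequence[np.ndarray], path: str | os.PathLike) -> None:
    """Write instance masks of one class as a single 8-bit PNG.

    Background is 0; instance ``i`` (0-based) is stored as gray level
    ``i + 1``. Later instances overwrite earlier ones where they overlap.
    """
    if len(masks) > 255:
        raise ValueError("at most 255 instances per label PNG")
    if not masks:
        raise ValueError("no masks to write")
    canvas = np.zeros(np.asarray(masks[0]).shape, dtype=np.uint8)
    for i, m in enumerate(masks):
        canvas[np.asarray(m, dtype=bool)] = i + 1
    iio.imwrite(Path(path), canvas)


def read_label_mask(path: str | os.PathLike) -> list[np.ndarray]:
    """Read an instance label PNG back to a list of boolean masks."""
    img = iio.imread(Path(path))
    if img.ndim == 3:
        img = img[..., 0]
    levels = np.unique(img)
    return [img == lv for lv in levels if lv != 0]


def derive_egg_yolk_mask(
    shell_mask: np.ndarray, non_yolk_mask: np.ndarray
) -> np.ndarray:
    """Yolk mask for egg annotations: egg interior minus the non-yolk area.

    Egg annotations outline the shell, the embryo and the *non-yolk* area;
    the yolk class consumed by a segmenter is derived as the filled shell
    interior with both the shell ring and the non-yolk area removed. This
    mapping is an interpretation of the annotation scheme, not a measurement.
    """
    from scipy.ndimage import binary_fill_holes

    interior = binary_fill_holes(np.asarray(shell_mask, dtype=bool))
    return interior & ~np.asarray(shell_mask, dtype=bool) & ~np.asarray(
        non_yolk_mask, dtype=bool
    )
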