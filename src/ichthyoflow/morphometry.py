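"""Per-individual measurements: centerline standard length, facing
direction, moment-ellipse axes, areas.

The standard length (SL) of a larva is measured along a centerline of the
body mask: the morphological skeleton is pruned of short side branches,
reduced to its longest end-to-end path, smoothed, and extended from both
endpoints to the mask boundary along the terminal tangent. The head end is
the one with the larger mean inscribed width over the terminal 20% of arc
length (heads are wider than tails).

Minor/major axes of eyes, yolk sacs and egg shells are the axes of the
ellipse with the same second central moments as the pixel set, with the
1/12 per-pixel (Sheppard) correction so a rasterized solid ellipse returns
its own axis lengths. Areas are pixel counts times the squared pixel scale,
with no smoothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from scipy.ndimage import uniform_filter1d
from skimage import measure, morphology

from . import volumetry
from .core import EggRecord, LarvaRecord, PixelScale, area_to_mm2, to_mm
from .postprocess import EggSegmentation, FishSegmentation


class MorphometryError(ValueError):
    """Raised for masks that cannot be measured (empty, disconnected)."""


@dataclass
class Centerline:
    """Head-to-tail body midline as an ordered (row, col) polyline."""

    points: np.ndarray
    arc_length_px: float
    flags: list[str] = field(default_factory=list)


@dataclass
class AxisMeasurement:
    major_px: float
    minor_px: float
    orientation: float  # radians, direction of the major axis in (row, col)
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# centerline


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    """8-connected pixel graph of a skeleton, diagonal edges weighted sqrt(2)."""
    g = nx.Graph()
    coords = np.argwhere(skel)
    pix = set(map(tuple, coords))
    for r, c in pix:
        g.add_node((r, c))
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
            nb = (r + dr, c + dc)
            if nb in pix:
                g.add_edge((r, c), nb, weight=math.hypot(dr, dc))
    return g


def _prune_spurs(g: nx.Graph, dt: np.ndarray, factor: float = 1.5) -> nx.Graph:
    """Iteratively remove terminal branches shorter than ``factor`` times the
    inscribed radius at their junction (corner artefacts of wide regions)."""
    g = g.copy()
    changed = True
    while changed and g.number_of_nodes() > 2:
        changed = False
        endpoints = [n for n in g.nodes if g.degree(n) == 1]
        for ep in endpoints:
            # walk from the endpoint to the nearest junction
            branch = [ep]
            prev, cur = None, ep
            length = 0.0
            while g.degree(cur) <= 2:
                nbrs = [n for n in g.neighbors(cur) if n != prev]
                if not nbrs:
                    break  # reached the other endpoint: whole path, keep
                nxt = nbrs[0]
                length += g.edges[cur, nxt]["weight"]
                prev, cur = cur, nxt
                branch.append(cur)
            else:
                # cur is a junction; branch[:-1] are removable
                if length < factor * dt[cur]:
                    g.remove_nodes_from(branch[:-1])
                    changed = True
    return g


def _longest_path(g: nx.Graph) -> list[tuple[int, int]]:
    endpoints = [n for n in g.nodes if g.degree(n) == 1]
    if len(endpoints) < 2:
        endpoints = list(g.nodes)[:8]  # cycles/degenerate: any pair
    best, best_len = None, -1.0
    for i, src in enumerate(endpoints):
        dist, paths = nx.single_source_dijkstra(g, src, weight="weight")
        for tgt in endpoints[i + 1:]:
            if tgt in dist and dist[tgt] > best_len:
                best_len = dist[tgt]
                best = paths[tgt]
    if best is None:
        best = list(g.nodes)[:1]
    return best


def _extend_to_boundary(
    mask: np.ndarray, point: np.ndarray, direction: np.ndarray
) -> np.ndarray:
    """March from ``point`` along ``direction`` until leaving the mask."""
    norm = np.linalg.norm(direction)
    if norm == 0:
        return point
    d = direction / norm
    p = point.astype(float)
    last_inside = p.copy()
    h, w = mask.shape
    for _ in range(2 * max(h, w)):
        p = p + 0.5 * d
        r, c = int(round(p[0])), int(round(p[1]))
        if not (0 <= r < h and 0 <= c < w) or not mask[r, c]:
            break
        last_inside = p.copy()
    return last_inside


def extract_centerline(
    body_mask: np.ndarray,
    prune_factor: float = 1.5,
    smooth_window: int = 9,
) -> Centerline:
    """Body centerline via pruned skeleton + tangent extension.

    Raises :class:`MorphometryError` for empty or disconnected masks. A mask
    with no meaningful elongation (e.g. a disc, whose skeleton collapses to
    a point) falls back to the moment-ellipse major axis through the
    centroid and is flagged ``low_elongation``.
    """
    mask = np.asarray(body_mask, dtype=bool)
    if not mask.any():
        raise MorphometryError("empty body mask")
    n_comp = measure.label(mask, connectivity=2).max()
    if n_comp != 1:
        raise MorphometryError(f"body mask has {n_comp} connected components")
    mask = ndi.binary_fill_holes(mask)
    dt = ndi.distance_transform_edt(mask)

    skel = morphology.skeletonize(mask)
    g = _skeleton_graph(skel)
    flags: list[str] = []
    path: list[tuple[int, int]] = []
    if g.number_of_nodes() >= 2:
        g = _prune_spurs(g, dt, prune_factor)
        path = _longest_path(g)

    if len(path) < max(5, int(1.0 * dt.max())):
        # Degenerate skeleton (disc-like region): use the moment major axis.
        flags.append("low_elongation")
        ax = measure_axes(mask)
        centroid = np.array(np.nonzero(mask)).mean(axis=1)
        d = np.array([math.sin(ax.orientation), math.cos(ax.orientation)])
        a = _extend_to_boundary(mask, centroid, d)
        b = _extend_to_boundary(mask, centroid, -d)
        pts = np.vstack([a, centroid, b])
        return Centerline(pts, float(np.linalg.norm(a - centroid) + np.linalg.norm(b - centroid)), flags)

    pts = np.asarray(path, dtype=float)
    win = min(smooth_window, len(pts))
    smoothed = uniform_filter1d(pts, size=win, axis=0, mode="nearest")
    k = max(3, min(len(smoothed) - 1, int(0.05 * len(smoothed))))
    head_dir = smoothed[0] - smoothed[k]
    tail_dir = smoothed[-1] - smoothed[-1 - k]
    ext0 = _extend_to_boundary(mask, smoothed[0], head_dir)
    ext1 = _extend_to_boundary(mask, smoothed[-1], tail_dir)
    full = np.vstack([ext0, smoothed, ext1])
    arc = float(np.linalg.norm(np.diff(full, axis=0), axis=1).sum())
    if arc < 3.0 * dt.max():
        flags.append("low_elongation")
    return Centerline(full, arc, flags)


def standard_length(centerline: Centerline, scale: PixelScale) -> float:
    """Standard length in mm: centerline arc length times the pixel scale."""
    return to_mm(centerline.arc_length_px, scale)


def facing_direction(
    body_mask: np.ndarray,
    centerline: Centerline,
    min_width_ratio: float = 1.1,
) -> tuple[tuple[float, float], np.ndarray, bool]:
    """Unit tail-to-head heading from the terminal-width asymmetry.

    Mean inscribed width (twice the distance transform) is compared over the
    terminal 20% of arc length at each end; the wider end is the head.
    Returns ``(heading, head_point, ambiguous)`` — ``ambiguous`` is set when
    the width ratio between ends is below ``min_width_ratio``.
    """
    mask = ndi.binary_fill_holes(np.asarray(body_mask, dtype=bool))
    dt = ndi.distance_transform_edt(mask)
    pts = centerline.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1] if cum[-1] > 0 else 1.0

    def mean_width(sel: np.ndarray) -> float:
        sub = pts[sel]
        rr = np.clip(np.round(sub[:, 0]).astype(int), 0, mask.shape[0] - 1)
        cc = np.clip(np.round(sub[:, 1]).astype(int), 0, mask.shape[1] - 1)
        return float(2.0 * dt[rr, cc].mean())

    w_start = mean_width(cum <= 0.2 * total)
    w_end = mean_width(cum >= 0.8 * total)
    if w_start >= w_end:
        head, tail = pts[0], pts[-1]
        ratio = w_start / max(w_end, 1e-9)
    else:
        head, tail = pts[-1], pts[0]
        ratio = w_end / max(w_start, 1e-9)
    v = head - tail
    v = v / max(np.linalg.norm(v), 1e-12)
    ambiguous = ratio < min_width_ratio
    return (float(v[0]), float(v[1])), head, ambiguous


# ---------------------------------------------------------------------------
# axes


def measure_axes(region_mask: np.ndarray) -> AxisMeasurement:
    """Axes of the equal-second-moment ellipse of a pixel set.

    The pixel-center covariance gets the +1/12 Sheppard correction (each
    pixel is a unit square, not a point), after which a rasterized solid
    ellipse with semi-axes (a, b) returns major ≈ 2a, minor ≈ 2b. The
    orientation is the angle of the major axis, ``atan2(d_row, d_col)``
    normalized to [0, pi).
    """
    mask = np.asarray(region_mask, dtype=bool)
    coords = np.argwhere(mask)
    if coords.size == 0:
        raise MorphometryError("empty region mask")
    flags = []
    if len(coords) == 1:
        flags.append("degenerate")
    cov = np.cov(coords.T, bias=True) if len(coords) > 1 else np.zeros((2, 2))
    cov = cov + np.eye(2) / 12.0
    evals, evecs = np.linalg.eigh(cov)
    minor = 4.0 * math.sqrt(max(evals[0], 0.0))
    major = 4.0 * math.sqrt(max(evals[1], 0.0))
    v = evecs[:, 1]  # (d_row, d_col) of major axis
    angle = math.atan2(v[0], v[1]) % math.pi
    return AxisMeasurement(major_px=major, minor_px=minor, orientation=angle, flags=flags)


# ---------------------------------------------------------------------------
# per-individual records


def measure_larva(
    seg: FishSegmentation, scale: PixelScale
) -> LarvaRecord:
    """Morphometrics + volumes for one validated larva segmentation.

    Missing body (edge-discarded, Fig-9C style) yields an organ-only record
    with ``body_valid=False``. A segmentation whose eye list had to be
    trimmed for cardinality (the merged/touching-fish failure mode) keeps
    its organ measurements but marks the body invalid.
    """
    rec = LarvaRecord(flags=list(seg.flags))
    body_suspect = "eye_cardinality_trimmed" in seg.flags

    if seg.body is not None:
        cl = extract_centerline(seg.body.mask)
        rec.flags += [f for f in cl.flags if f not in rec.flags]
        rec.standard_length_mm = standard_length(cl, scale)
        rec.body_area_mm2 = area_to_mm2(seg.body.area_px, scale)
        heading, _, ambiguous = facing_direction(seg.body.mask, cl)
        rec.facing_direction = heading
        if ambiguous:
            rec.flags.append("heading_ambiguous")
        rec.total_volume_mm3 = volumetry.larva_total_volume(
            rec.body_area_mm2, rec.standard_length_mm
        )
        rec.body_valid = not body_suspect and "low_elongation" not in rec.flags
        if body_suspect and "body_merge_suspect" not in rec.flags:
            rec.flags.append("body_merge_suspect")

    if seg.eyes:
        majors, minors = [], []
        for eye in seg.eyes:
            ax = measure_axes(eye.mask)
            majors.append(to_mm(ax.major_px, scale))
            minors.append(to_mm(ax.minor_px, scale))
        rec.eye_length_mm = float(np.mean(majors))
        rec.eye_width_mm = float(np.mean(minors))  # reported eye diameter
        rec.eye_volume_mm3 = volumetry.prolate_spheroid_volume(
            rec.eye_width_mm, rec.eye_length_mm
        )
        rec.eye_count = len(seg.eyes)
        rec.eyes_valid = True

    if seg.yolk is not None:
        ax = measure_axes(seg.yolk.mask)
        rec.yolk_length_mm = to_mm(ax.major_px, scale)
        rec.yolk_width_mm = to_mm(ax.minor_px, scale)
        rec.yolk_volume_mm3 = volumetry.prolate_spheroid_volume(
            rec.yolk_width_mm, rec.yolk_length_mm
        )
        rec.yolk_valid = True

    if rec.total_volume_mm3 is not None and rec.yolk_volume_mm3 is not None:
        v_s, suspect = volumetry.structural_volume(
            rec.total_volume_mm3, rec.yolk_volume_mm3
        )
        rec.structural_volume_mm3 = v_s
        if suspect:
            rec.flags.append("structural_volume_suspect")
    return rec


def measure_egg(seg: EggSegmentation, scale: PixelScale) -> EggRecord:
    """Shell-only egg morphometrics: axes, circularity, diameter, volume."""
    rec = EggRecord(flags=list(seg.flags))
    ax = measure_axes(seg.egg.mask)
    rec.egg_major_mm = to_mm(ax.major_px, scale)
    rec.egg_minor_mm = to_mm(ax.minor_px, scale)
    rec.circularity = rec.egg_minor_mm / rec.egg_major_mm
    d, r, eccentric = volumetry.egg_diameter(rec.egg_major_mm, rec.egg_minor_mm)
    rec.egg_diameter_mm = d
    rec.egg_radius_mm = r
    rec.egg_volume_mm3 = volumetry.egg_volume(d)
    if eccentric:
        rec.flags.append("eccentric_egg")
    rec.egg_valid = not eccentric
    return rec


def measure_individual(
    seg: FishSegmentation | EggSegmentation,
    scale: PixelScale,
    mode: str = "larva",
) -> LarvaRecord | EggRecord:
    """Dispatch to larva or egg measurement for one validated segmentation."""
    if mode == "larva":
        if not isinstance(seg, FishSegmentation):
            raise TypeError("larva mode expects a FishSegmentation")
        return measure_larva(seg, scale)
    if mode == "egg":
        if not isinstance(seg, EggSegmentation):
            raise TypeError("egg mode expects an EggSegmentation")
        return measure_egg(seg, scale)
    raise ValueError(f"mode must be 'larva' or 'egg', got {mode!r}")
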