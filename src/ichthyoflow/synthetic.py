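"""Synthetic flow-through imagery with exact ground truth.

Emulates the imaging geometry of a back-lit flow cell seen through a
telecentric lens: dark millimetre-scale larvae and eggs on a bright
(~220-count) background, rendered in orthographic 2-D projection. Every
rendered object carries analytic ground truth (spine arc length, axis
lengths, diameters) plus exact instance masks, so each pipeline stage can
be tested for parameter recovery without camera data or a trained
segmentation network.

A larva body is a tube of varying half-width swept along a parametric
spine (a circular arc, from straight up to a semicircle). The nose and
tail width profiles are capped at unit slope, which makes the swept
silhouette terminate exactly at the spine endpoints — the spine arc length
is therefore the exact ground-truth standard length. Eyes are a pair of
near-black ellipses in the head, the yolk sac a mid-contrast ellipse on
the belly; both lie inside the body envelope by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.draw import disk as draw_disk

from .core import FeatureClass, Frame, LabeledRegion, PixelScale
from .frames import FrameStream

DEFAULT_SCALE = PixelScale(0.0036)  # mm/px: 8.8 mm field of view over 2448 px
DEFAULT_BACKGROUND = 220.0


@dataclass
class LarvaSpec:
    """Generative parameters of one synthetic larva (mm units).

    Defaults mirror the magnitudes of early yolk-sac cod larvae: SL about
    4.5 mm, eye diameter about 0.28 mm, yolk sac about 0.6 x 0.28 mm.
    ``curvature_turn_rad`` is the total turning angle of the circular-arc
    spine (0 = straight, pi = semicircle). Intensity contrasts are counts
    below the background level.
    """

    standard_length_mm: float = 4.48
    curvature_turn_rad: float = 0.0
    head_halfwidth_mm: float = 0.21
    tail_halfwidth_frac: float = 0.15
    belly_bump_mm: float = 0.05
    yolk_length_mm: float = 0.60
    yolk_width_mm: float = 0.28
    yolk_center_t: float = 0.32
    eye_length_mm: float = 0.30
    eye_width_mm: float = 0.28
    eye_centers_t: tuple[float, float] = (0.10, 0.17)
    eye_offset_mm: float = 0.02
    body_contrast: float = 120.0
    yolk_contrast: float = 70.0
    eye_contrast: float = 195.0
    heading_rad: float = 0.0
    center_mm: Optional[tuple[float, float]] = None  # (row, col); None = frame centre
    with_yolk: bool = True
    with_eyes: bool = True

    def spine_mm(self, t: np.ndarray) -> np.ndarray:
        """Spine points (row, col) in mm at parameters ``t`` in [0, 1].

        The spine starts at the snout (t=0) and is arc-length parameterized,
        so the ground-truth standard length is exactly
        ``standard_length_mm``.
        """
        t = np.asarray(t, dtype=float)
        L, theta, phi0 = self.standard_length_mm, self.curvature_turn_rad, self.heading_rad
        if abs(theta) < 1e-9:
            dr, dc = math.sin(phi0), math.cos(phi0)
            return np.column_stack([t * L * dr, t * L * dc])
        R = L / theta
        phi = phi0 + theta * t
        rows = R * (np.cos(phi0) - np.cos(phi))
        cols = R * (np.sin(phi) - np.sin(phi0))
        return np.column_stack([rows, cols])

    def halfwidth_mm(self, t: np.ndarray) -> np.ndarray:
        """Body half-width profile along the spine, mm.

        Wide head tapering to a thin tail, with a belly bump under the yolk
        sac. Capped at unit slope from both ends (conical nose/tail caps) so
        the silhouette ends exactly at the spine tips.
        """
        t = np.asarray(t, dtype=float)
        L = self.standard_length_mm
        base = self.head_halfwidth_mm * (
            1.0 - (1.0 - self.tail_halfwidth_frac) * t ** 1.2
        )
        base = base + self.belly_bump_mm * np.exp(
            -(((t - self.yolk_center_t) / 0.12) ** 2)
        )
        s = t * L
        return np.minimum(base, np.minimum(s, L - s))


@dataclass
class EggSpec:
    """Generative parameters of one synthetic egg (mm units)."""

    diameter_mm: float = 1.36
    center_mm: Optional[tuple[float, float]] = None
    shell_thickness_mm: float = 0.04
    shell_contrast: float = 140.0
    interior_contrast: float = 50.0


@dataclass
class RenderedScene:
    """One rendered frame plus instance regions and per-object truth."""

    image: np.ndarray
    regions: list[LabeledRegion]
    truths: list[dict]
    scale: PixelScale


def _paint_ellipse(
    canvas: np.ndarray,
    center_px: tuple[float, float],
    semi_major_px: float,
    semi_minor_px: float,
    angle: float,
) -> None:
    """Set True inside an ellipse; angle = major-axis direction, (row, col)."""
    h, w = canvas.shape
    r0, c0 = center_px
    ext = semi_major_px + 2
    rr0, rr1 = max(0, int(r0 - ext)), min(h, int(r0 + ext) + 2)
    cc0, cc1 = max(0, int(c0 - ext)), min(w, int(c0 + ext) + 2)
    if rr1 <= rr0 or cc1 <= cc0:
        return
    rr, cc = np.mgrid[rr0:rr1, cc0:cc1]
    dr, dc = rr - r0, cc - c0
    u = dr * math.sin(angle) + dc * math.cos(angle)  # along major axis
    v = -dr * math.cos(angle) + dc * math.sin(angle)
    inside = (u / semi_major_px) ** 2 + (v / semi_minor_px) ** 2 <= 1.0
    canvas[rr0:rr1, cc0:cc1] |= inside


def _sample_spine(spec: LarvaSpec, scale: PixelScale) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive spine samples (t values and half-widths in px).

    Sample spacing follows sqrt(2.4 * r) so the sagitta of the union of
    discs stays below ~0.3 px everywhere.
    """
    L_px = spec.standard_length_mm / scale.mm_per_px
    ts = [0.0]
    s = 0.0
    while s < L_px:
        hw_px = spec.halfwidth_mm(np.array([s / L_px]))[0] / scale.mm_per_px
        step = float(np.clip(math.sqrt(max(2.4 * hw_px, 0.25)), 0.5, 8.0))
        s += step
        ts.append(min(s / L_px, 1.0))
    t = np.array(ts)
    return t, spec.halfwidth_mm(t) / scale.mm_per_px


def _larva_layout(
    spec: LarvaSpec, scale: PixelScale, image_shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spine sample positions in px after centering, with halfwidths (px)."""
    t, hw_px = _sample_spine(spec, scale)
    spine = spec.spine_mm(t) / scale.mm_per_px
    if spec.center_mm is None:
        lo = spine.min(axis=0) - hw_px.max()
        hi = spine.max(axis=0) + hw_px.max()
        mid = (lo + hi) / 2.0
        target = np.array([image_shape[0] / 2.0, image_shape[1] / 2.0])
        spine = spine - mid + target
    else:
        spine = spine + np.array(spec.center_mm) / scale.mm_per_px
    return t, spine, hw_px


def render_larva(
    spec: LarvaSpec,
    scale: PixelScale = DEFAULT_SCALE,
    image_shape: tuple[int, int] = (1536, 1536),
    seed: int = 0,
    background: float = DEFAULT_BACKGROUND,
    noise_sigma: float = 5.0,
) -> RenderedScene:
    """Render one larva: image + exact class masks + ground truth.

    Deterministic for a fixed seed. A spec extending outside the frame is
    rendered clipped and its truth flagged ``off_frame``.
    """
    canvas = np.full(image_shape, background, dtype=float)
    regions, truths = [], []
    _add_larva(canvas, regions, truths, spec, scale, image_shape)
    image = _finalize_image(canvas, noise_sigma, seed)
    return RenderedScene(image=image, regions=regions, truths=truths, scale=scale)


def _add_larva(
    canvas: np.ndarray,
    regions: list[LabeledRegion],
    truths: list[dict],
    spec: LarvaSpec,
    scale: PixelScale,
    image_shape: tuple[int, int],
    background: float = DEFAULT_BACKGROUND,
) -> None:
    t, spine, hw_px = _larva_layout(spec, scale, image_shape)
    body = np.zeros(image_shape, dtype=bool)
    clipped = False
    h, w = image_shape
    for (r, c), radius in zip(spine, hw_px):
        if radius < 0.5:
            continue
        if r - radius < 0 or c - radius < 0 or r + radius > h - 1 or c + radius > w - 1:
            clipped = True
        rr, cc = draw_disk((r, c), radius, shape=image_shape)
        body[rr, cc] = True

    # local tangent angles for organ placement
    def tangent_angle(tv: float) -> float:
        eps = 1e-4
        p0 = spec.spine_mm(np.array([max(tv - eps, 0.0)]))[0]
        p1 = spec.spine_mm(np.array([min(tv + eps, 1.0)]))[0]
        d = p1 - p0
        return math.atan2(d[0], d[1])

    def spine_at(tv: float) -> np.ndarray:
        return np.interp([tv], t, spine[:, 0])[0], np.interp([tv], t, spine[:, 1])[0]

    mm = scale.mm_per_px
    eye_masks = []
    if spec.with_eyes:
        for i, te in enumerate(spec.eye_centers_t):
            ang = tangent_angle(te)
            off = spec.eye_offset_mm / mm * (1 if i % 2 == 0 else -1)
            r0, c0 = spine_at(te)
            center = (r0 - off * math.cos(ang), c0 + off * math.sin(ang))
            m = np.zeros(image_shape, dtype=bool)
            _paint_ellipse(
                m, center, spec.eye_length_mm / 2 / mm, spec.eye_width_mm / 2 / mm, ang
            )
            eye_masks.append(m)

    yolk_mask = None
    if spec.with_yolk:
        ang = tangent_angle(spec.yolk_center_t)
        yolk_mask = np.zeros(image_shape, dtype=bool)
        _paint_ellipse(
            yolk_mask,
            spine_at(spec.yolk_center_t),
            spec.yolk_length_mm / 2 / mm,
            spec.yolk_width_mm / 2 / mm,
            ang,
        )

    for m in eye_masks:
        body |= m
    if yolk_mask is not None:
        body |= yolk_mask

    # within one larva the organ intensity overrides the body (the yolk is
    # brighter than the pigmented body); across objects the darker one wins
    local = np.full(canvas.shape, np.inf)
    local[body] = background - spec.body_contrast
    if yolk_mask is not None:
        local[yolk_mask] = background - spec.yolk_contrast
    for m in eye_masks:
        local[m] = background - spec.eye_contrast
    np.minimum(canvas, local, out=canvas)

    regions.append(LabeledRegion(FeatureClass.BODY, body, confidence=0.95))
    for m in eye_masks:
        regions.append(LabeledRegion(FeatureClass.EYE, m, confidence=0.9))
    if yolk_mask is not None:
        regions.append(LabeledRegion(FeatureClass.YOLK, yolk_mask, confidence=0.9))

    head = spine[0]
    tail = spine[-1]
    chord = head - tail
    chord = chord / max(np.linalg.norm(chord), 1e-12)
    truths.append(
        {
            "kind": "larva",
            "sl_mm": spec.standard_length_mm,
            "body_area_mm2": float(body.sum()) * scale.mm2_per_px2,
            "yolk_length_mm": spec.yolk_length_mm if spec.with_yolk else None,
            "yolk_width_mm": spec.yolk_width_mm if spec.with_yolk else None,
            "eye_length_mm": spec.eye_length_mm if spec.with_eyes else None,
            "eye_width_mm": spec.eye_width_mm if spec.with_eyes else None,
            "head_point_px": (float(head[0]), float(head[1])),
            "heading": (float(chord[0]), float(chord[1])),
            "off_frame": clipped,
            "spec": spec,
        }
    )


def render_egg(
    spec: EggSpec,
    scale: PixelScale = DEFAULT_SCALE,
    image_shape: tuple[int, int] = (600, 600),
    seed: int = 0,
    background: float = DEFAULT_BACKGROUND,
    noise_sigma: float = 5.0,
) -> RenderedScene:
    """Render one egg: bright field, dark shell ring, darker interior."""
    canvas = np.full(image_shape, background, dtype=float)
    regions, truths = [], []
    _add_egg(canvas, regions, truths, spec, scale, image_shape)
    image = _finalize_image(canvas, noise_sigma, seed)
    return RenderedScene(image=image, regions=regions, truths=truths, scale=scale)


def _add_egg(
    canvas: np.ndarray,
    regions: list[LabeledRegion],
    truths: list[dict],
    spec: EggSpec,
    scale: PixelScale,
    image_shape: tuple[int, int],
    background: float = DEFAULT_BACKGROUND,
) -> None:
    mm = scale.mm_per_px
    radius_px = spec.diameter_mm / 2.0 / mm
    if spec.diameter_mm / mm < 2.0:
        raise ValueError(
            f"egg diameter {spec.diameter_mm} mm is below 2 px at this scale"
        )
    if spec.center_mm is None:
        center = (image_shape[0] / 2.0, image_shape[1] / 2.0)
    else:
        center = (spec.center_mm[0] / mm, spec.center_mm[1] / mm)
    full = np.zeros(image_shape, dtype=bool)
    rr, cc = draw_disk(center, radius_px, shape=image_shape)
    full[rr, cc] = True
    inner = np.zeros(image_shape, dtype=bool)
    inner_r = max(radius_px - spec.shell_thickness_mm / mm, 1.0)
    rr, cc = draw_disk(center, inner_r, shape=image_shape)
    inner[rr, cc] = True
    shell = full & ~inner

    canvas[inner] = np.minimum(canvas[inner], background - spec.interior_contrast)
    canvas[shell] = np.minimum(canvas[shell], background - spec.shell_contrast)

    overlaps = any((r.mask & full).any() for r in regions)
    regions.append(LabeledRegion(FeatureClass.EGG, full, confidence=0.95))
    truths.append(
        {
            "kind": "egg",
            "diameter_mm": spec.diameter_mm,
            "center_px": center,
            "overlaps": overlaps,
            "spec": spec,
        }
    )


def _finalize_image(canvas: np.ndarray, noise_sigma: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, noise_sigma, canvas.shape)
    return np.clip(np.round(canvas), 0, 255).astype(np.uint8)


def render_multi(
    larvae: Sequence[LarvaSpec] = (),
    eggs: Sequence[EggSpec] = (),
    scale: PixelScale = DEFAULT_SCALE,
    image_shape: tuple[int, int] = (1536, 1536),
    seed: int = 0,
    noise_sigma: float = 5.0,
) -> RenderedScene:
    """Render several objects into one frame (shared background + noise)."""
    canvas = np.full(image_shape, DEFAULT_BACKGROUND, dtype=float)
    regions: list[LabeledRegion] = []
    truths: list[dict] = []
    for sp in larvae:
        _add_larva(canvas, regions, truths, sp, scale, image_shape)
    for sp in eggs:
        _add_egg(canvas, regions, truths, sp, scale, image_shape)
    image = _finalize_image(canvas, noise_sigma, seed)
    return RenderedScene(image=image, regions=regions, truths=truths, scale=scale)


# ---------------------------------------------------------------------------
# frame streams


@dataclass
class StreamTruth:
    """Which frames of a synthetic stream truly contain a large object."""

    object_frames: tuple[int, ...]
    distractor_frames: tuple[int, ...]


def render_stream(
    n_frames: int = 200,
    n_objects: int = 12,
    n_distractors: int = 20,
    image_shape: tuple[int, int] = (256, 320),
    scale: PixelScale = PixelScale(0.012),
    background: float = DEFAULT_BACKGROUND,
    drift_amplitude: float = 3.0,
    drift_period: float = 97.0,
    noise_sigma: float = 2.0,
    object_contrast: float = 80.0,
    object_diameter_mm: float = 1.3,
    distractor_radius_px: tuple[int, int] = (4, 12),
    seed: int = 0,
    object_frames: Optional[Sequence[int]] = None,
) -> tuple[FrameStream, StreamTruth]:
    """A frame stream with scheduled transient objects and small distractors.

    The background drifts slowly (sinusoidal, a few counts) and carries
    Gaussian pixel noise. Each scheduled object (a dark egg-sized disc,
    super-threshold in both contrast and area) appears in exactly one
    frame, emulating a particle carried through the flow cell. Distractors
    (bubbles, fibres) are dark discs with area below any sensible minimum
    blob area. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    if object_frames is None:
        object_frames = sorted(
            rng.choice(n_frames, size=n_objects, replace=False).tolist()
        )
    else:
        object_frames = sorted(int(i) for i in object_frames)
        if object_frames and object_frames[-1] >= n_frames:
            raise ValueError("scheduled frame beyond the stream length")
    obj_set = set(object_frames)
    distractor_frames = sorted(
        rng.choice(n_frames, size=n_distractors, replace=False).tolist()
    )

    radius_px = object_diameter_mm / 2.0 / scale.mm_per_px
    frames = []
    for i in range(n_frames):
        img = np.full(image_shape, background, dtype=float)
        img += drift_amplitude * math.sin(2 * math.pi * i / drift_period)
        if i in obj_set:
            margin = radius_px + 4
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            rr, cc = draw_disk((r, c), radius_px, shape=image_shape)
            img[rr, cc] -= object_contrast
        if i in distractor_frames:
            rad = rng.integers(distractor_radius_px[0], distractor_radius_px[1] + 1)
            r = rng.uniform(rad + 2, h - rad - 2)
            c = rng.uniform(rad + 2, w - rad - 2)
            rr, cc = draw_disk((r, c), float(rad), shape=image_shape)
            img[rr, cc] -= object_contrast
        img += rng.normal(0.0, noise_sigma, image_shape)
        frames.append(Frame(i, np.clip(np.round(img), 0, 255)))
    return FrameStream(frames), StreamTruth(
        object_frames=tuple(object_frames),
        distractor_frames=tuple(distractor_frames),
    )


# ---------------------------------------------------------------------------
# random populations and curated failure scenarios


def random_larva_spec(
    rng: np.random.Generator,
    sl_mean_mm: float = 4.48,
    sl_sd_mm: float = 0.36,
    max_turn_rad: float = math.pi / 3,
) -> LarvaSpec:
    """A larva drawn from the study-like population: SL ~ N(4.48, 0.36) mm
    (truncated at ±2 sd), mild random curvature and pose."""
    sl = float(np.clip(rng.normal(sl_mean_mm, sl_sd_mm),
                       sl_mean_mm - 2 * sl_sd_mm, sl_mean_mm + 2 * sl_sd_mm))
    return LarvaSpec(
        standard_length_mm=sl,
        curvature_turn_rad=float(rng.uniform(0.0, max_turn_rad)),
        heading_rad=float(rng.uniform(0.0, 2 * math.pi)),
        yolk_length_mm=float(rng.uniform(0.5, 0.7)),
        yolk_width_mm=float(rng.uniform(0.24, 0.3)),
        eye_width_mm=float(rng.uniform(0.27, 0.29)),
        eye_length_mm=float(rng.uniform(0.29, 0.32)),
    )


def random_egg_spec(
    rng: np.random.Generator,
    diameter_mean_mm: float = 1.36,
    diameter_sd_mm: float = 0.02,
) -> EggSpec:
    return EggSpec(diameter_mm=float(rng.normal(diameter_mean_mm, diameter_sd_mm)))


@dataclass
class Scenario:
    """A curated scene with its expected pipeline behaviour."""

    name: str
    scene: RenderedScene
    expected_tags: frozenset[str] = field(default_factory=frozenset)
    mode: str = "larva"


def scenario_suite(
    seed: int = 0,
    scale: PixelScale = DEFAULT_SCALE,
    image_shape: tuple[int, int] = (1536, 1536),
) -> list[Scenario]:
    """Clean scenes plus the documented segmentation failure modes.

    * ``clean`` — one well-posed larva; everything valid.
    * ``edge_clipped_body`` — body crosses the frame edge: the body must be
      discarded while interior eye and yolk measurements are retained.
    * ``excessive_curvature`` — semicircular pose; SL still recoverable.
    * ``overlapping_larvae`` / ``touching_larvae`` — the segmenter emits one
      merged body with four eye candidates: body measurement is invalid.
    * ``top_view`` — eyes merge into a single figure-8 region with a
      waist: flagged ``eye_shape_suspect``; no visible yolk.
    """
    scenarios: list[Scenario] = []

    scenarios.append(
        Scenario("clean", render_larva(LarvaSpec(), scale, image_shape, seed=seed))
    )

    # Tail crosses the right frame edge; organs stay interior.
    clipped = LarvaSpec(
        heading_rad=math.pi / 2,  # along columns
        center_mm=(
            image_shape[0] / 2 * scale.mm_per_px,
            image_shape[1] * scale.mm_per_px - 3.0,
        ),
    )
    scenarios.append(
        Scenario(
            "edge_clipped_body",
            render_larva(clipped, scale, image_shape, seed=seed + 1),
            frozenset({"body_discarded", "organs_retained"}),
        )
    )

    scenarios.append(
        Scenario(
            "excessive_curvature",
            render_larva(
                LarvaSpec(curvature_turn_rad=math.pi), scale, image_shape, seed=seed + 2
            ),
            frozenset({"high_curvature"}),
        )
    )

    # Two larvae crossing: one merged body region + 4 eyes + 2 yolks.
    h_mm = image_shape[0] * scale.mm_per_px
    w_mm = image_shape[1] * scale.mm_per_px
    for name, (h2, b_start) in {
        # heading 0 runs along columns; the second fish either crosses at an
        # angle or swims parallel close enough to touch flanks
        "overlapping_larvae": (math.pi / 5, (h_mm / 2 - 1.5, 0.5)),
        "touching_larvae": (0.0, (h_mm / 2 + 0.33, 0.48)),
    }.items():
        a = LarvaSpec(heading_rad=0.0, center_mm=(h_mm / 2, (w_mm - 4.48) / 2))
        b = LarvaSpec(heading_rad=h2, center_mm=b_start)
        scene = render_multi([a, b], scale=scale, image_shape=image_shape,
                             seed=seed + 3)
        bodies = [r for r in scene.regions if r.feature_class is FeatureClass.BODY]
        others = [r for r in scene.regions if r.feature_class is not FeatureClass.BODY]
        merged = LabeledRegion(
            FeatureClass.BODY, bodies[0].mask | bodies[1].mask, confidence=0.9
        )
        scene.regions = [merged] + others
        scenarios.append(Scenario(name, scene, frozenset({"body_invalid"})))

    # Top view: narrow silhouette, no visible yolk, eyes merged figure-8.
    top = LarvaSpec(with_yolk=False, with_eyes=False, belly_bump_mm=0.0)
    scene = render_multi([top], scale=scale, image_shape=image_shape, seed=seed + 4)
    body = next(r for r in scene.regions if r.feature_class is FeatureClass.BODY)
    t, spine, hw_px = _larva_layout(top, scale, image_shape)
    mm = scale.mm_per_px
    head_r, head_c = np.interp(0.13, t, spine[:, 0]), np.interp(0.13, t, spine[:, 1])
    eye_r = 0.12 / mm
    eye_gap = 0.30 / mm  # centre separation > 2r: joined by a thin waist
    ang = math.atan2(spine[-1][0] - spine[0][0], spine[-1][1] - spine[0][1])
    fig8 = np.zeros(image_shape, dtype=bool)
    for sgn in (-0.5, 0.5):
        c = (head_r + sgn * eye_gap * math.sin(ang),
             head_c + sgn * eye_gap * math.cos(ang))
        rr, cc = draw_disk(c, eye_r, shape=image_shape)
        fig8[rr, cc] = True
    _paint_ellipse(fig8, (head_r, head_c), eye_gap / 2, 0.02 / mm, ang)  # waist bridge
    body = LabeledRegion(FeatureClass.BODY, body.mask | fig8, confidence=0.9)
    scene.regions = [body, LabeledRegion(FeatureClass.EYE, fig8, confidence=0.8)]
    scenarios.append(
        Scenario("top_view", scene, frozenset({"eye_shape_suspect"}))
    )

    return scenarios
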