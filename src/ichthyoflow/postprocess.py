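"""Rule-based validation of raw segmentation masks.

Raw instance masks from any segmenter are cleaned with a fixed set of
conditions before measurement:

1. regions have no internal holes (holes are filled);
2. a fish has at most one body region;
3. a fish has no more than two eyes;
4. a fish has at most one yolk sac;
5. eye and yolk masks lie inside the body mask;
6. body regions (and any body part) touching the image edge are discarded —
   but interior eyes/yolks survive the loss of their edge-clipped body;
7. eyes and yolk sacs are associated with a corresponding body.

The order is: fill holes -> discard edge regions -> associate parts to
bodies (containment + per-body cardinality). Hole-filling first makes the
containment test meaningful; edge-discard before association lets organs
survive the loss of their body. In egg mode only egg-shell regions are
validated (embryo body/yolk measurements inside eggs are excluded by
policy): shells are hole-filled and edge-touching shells discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .core import FeatureClass, LabeledRegion

CARDINALITY_LIMITS = {FeatureClass.BODY: 1, FeatureClass.EYE: 2, FeatureClass.YOLK: 1}


@dataclass
class PostprocessConfig:
    containment_slack_px: float = 0.0
    eye_solidity_threshold: float = 0.85
    association_min_fraction: float = 0.5


@dataclass
class FishSegmentation:
    """A validated grouping of one body with its associated organs."""

    body: Optional[LabeledRegion] = None
    eyes: list[LabeledRegion] = field(default_factory=list)
    yolk: Optional[LabeledRegion] = None
    body_discarded_reason: str = "none"  # none | edge_contact | cardinality
    flags: list[str] = field(default_factory=list)

    def regions(self) -> list[LabeledRegion]:
        out = list(self.eyes)
        if self.body is not None:
            out.append(self.body)
        if self.yolk is not None:
            out.append(self.yolk)
        return out


@dataclass
class EggSegmentation:
    """A validated egg-shell region (internal features excluded by policy)."""

    egg: LabeledRegion
    flags: list[str] = field(default_factory=list)

    def regions(self) -> list[LabeledRegion]:
        return [self.egg]


@dataclass
class AuditEntry:
    feature_class: str
    reason: str
    area_px: int


def fill_holes(region: LabeledRegion) -> LabeledRegion:
    """Fill enclosed background holes in a region's mask.

    Idempotent; never decreases area. Concavities open to the image border
    are not enclosed and are left alone.
    """
    if not region.mask.any():
        raise ValueError("cannot fill holes of an empty region")
    filled = ndi.binary_fill_holes(region.mask)
    return LabeledRegion(region.feature_class, filled, region.confidence)


def touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())


def discard_edge_regions(
    regions: Sequence[LabeledRegion],
) -> tuple[list[LabeledRegion], list[AuditEntry], bool]:
    """Drop regions with any pixel on the image border.

    Returns (kept, audit, body_was_discarded). Interior organs are kept even
    when their body is discarded; the caller groups them bodiless.
    """
    kept, audit = [], []
    body_discarded = False
    for r in regions:
        if touches_border(r.mask):
            audit.append(AuditEntry(r.feature_class.value, "edge_contact", r.area_px))
            if r.feature_class is FeatureClass.BODY:
                body_discarded = True
        else:
            kept.append(r)
    return kept, audit, body_discarded


def containment_excess_px(part: LabeledRegion, filled_body_mask: np.ndarray) -> float:
    """Greatest distance (px) any part pixel lies outside the filled body."""
    outside = part.mask & ~filled_body_mask
    if not outside.any():
        return 0.0
    # Euclidean distance from each outside pixel to the body
    dist = ndi.distance_transform_edt(~filled_body_mask)
    return float(dist[outside].max())


def enforce_containment(
    body: LabeledRegion,
    parts: Sequence[LabeledRegion],
    slack_px: float = 0.0,
) -> tuple[list[LabeledRegion], list[AuditEntry]]:
    """Keep parts lying within ``slack_px`` of the body's filled mask."""
    filled = ndi.binary_fill_holes(body.mask)
    kept, audit = [], []
    for p in parts:
        if containment_excess_px(p, filled) <= slack_px:
            kept.append(p)
        else:
            audit.append(AuditEntry(p.feature_class.value, "outside_body", p.area_px))
    return kept, audit


def _rank_key(r: LabeledRegion):
    conf = r.confidence if r.confidence is not None else -1.0
    return (-conf, -r.area_px, r.centroid)


def enforce_cardinality(
    candidates: Sequence[LabeledRegion], feature_class: FeatureClass
) -> tuple[list[LabeledRegion], list[AuditEntry]]:
    """Keep the top-k candidates of a class (k = 1 body / 2 eyes / 1 yolk).

    Ranked by confidence, ties broken by larger area, then by lower (row,
    col) centroid; deterministic. Segmenters emitting no confidence fall
    back to the area/centroid ranking.
    """
    limit = CARDINALITY_LIMITS[feature_class]
    ranked = sorted(candidates, key=_rank_key)
    kept = ranked[:limit]
    audit = [
        AuditEntry(r.feature_class.value, "cardinality", r.area_px)
        for r in ranked[limit:]
    ]
    return kept, audit


def region_solidity(region: LabeledRegion) -> float:
    """Area / convex-hull area; low values flag two-lobed (figure-8) shapes."""
    r0, c0, r1, c1 = region.bbox
    sub = region.mask[r0:r1, c0:c1]
    props = measure.regionprops(sub.astype(np.uint8))
    return float(props[0].solidity)


def associate_parts(
    bodies: Sequence[LabeledRegion],
    parts: Sequence[LabeledRegion],
    config: PostprocessConfig = PostprocessConfig(),
    any_body_edge_discarded: bool = False,
) -> tuple[list[FishSegmentation], list[AuditEntry]]:
    """Assign eyes and yolks to bodies and build per-fish segmentations.

    Each part goes to the body whose filled mask contains the largest
    fraction of its pixels, provided that fraction exceeds 50%. Unassigned
    parts are dropped — unless no body survived and at least one body was
    discarded for edge contact, in which case the orphan organs are grouped
    into a single bodiless segmentation (their measurements are retained).
    """
    audit: list[AuditEntry] = []
    filled = [ndi.binary_fill_holes(b.mask) for b in bodies]
    assigned: dict[int, list[LabeledRegion]] = {i: [] for i in range(len(bodies))}
    orphans: list[LabeledRegion] = []

    for p in parts:
        if bodies:
            fracs = [
                (p.mask & fb).sum() / max(p.area_px, 1) for fb in filled
            ]
            best = int(np.argmax(fracs))
            if fracs[best] > config.association_min_fraction:
                assigned[best].append(p)
                continue
        orphans.append(p)

    segmentations: list[FishSegmentation] = []
    for i, body in enumerate(bodies):
        seg = FishSegmentation(body=body)
        contained, aud = enforce_containment(
            body, assigned[i], config.containment_slack_px
        )
        audit += aud
        eyes = [p for p in contained if p.feature_class is FeatureClass.EYE]
        yolks = [p for p in contained if p.feature_class is FeatureClass.YOLK]
        seg.eyes, aud = enforce_cardinality(eyes, FeatureClass.EYE)
        audit += aud
        if aud:
            seg.flags.append("eye_cardinality_trimmed")
        kept_yolks, aud = enforce_cardinality(yolks, FeatureClass.YOLK)
        audit += aud
        if aud:
            seg.flags.append("yolk_cardinality_trimmed")
        seg.yolk = kept_yolks[0] if kept_yolks else None
        for eye in seg.eyes:
            if region_solidity(eye) < config.eye_solidity_threshold:
                if "eye_shape_suspect" not in seg.flags:
                    seg.flags.append("eye_shape_suspect")
        segmentations.append(seg)

    if not bodies and any_body_edge_discarded and orphans:
        seg = FishSegmentation(body=None, body_discarded_reason="edge_contact")
        eyes = [p for p in orphans if p.feature_class is FeatureClass.EYE]
        yolks = [p for p in orphans if p.feature_class is FeatureClass.YOLK]
        seg.eyes, aud = enforce_cardinality(eyes, FeatureClass.EYE)
        audit += aud
        kept_yolks, aud = enforce_cardinality(yolks, FeatureClass.YOLK)
        audit += aud
        seg.yolk = kept_yolks[0] if kept_yolks else None
        for eye in seg.eyes:
            if region_solidity(eye) < config.eye_solidity_threshold:
                if "eye_shape_suspect" not in seg.flags:
                    seg.flags.append("eye_shape_suspect")
        segmentations.append(seg)
    else:
        for p in orphans:
            audit.append(AuditEntry(p.feature_class.value, "no_body", p.area_px))

    return segmentations, audit


def postprocess(
    regions: Sequence[LabeledRegion | FishSegmentation | EggSegmentation],
    image_shape: tuple[int, int],
    mode: str = "larva",
    config: PostprocessConfig = PostprocessConfig(),
) -> tuple[list[FishSegmentation] | list[EggSegmentation], list[AuditEntry]]:
    """Apply the full validation rule set to one frame's raw regions.

    Idempotent: re-running on the output segmentations reproduces them. The
    input may mix raw regions with previously validated segmentations; a
    bodiless segmentation whose body was edge-discarded keeps that context,
    so its retained organs survive revalidation.
    """
    prior_edge_discard = False
    flat: list[LabeledRegion] = []
    for item in regions:
        if isinstance(item, (FishSegmentation, EggSegmentation)):
            flat.extend(item.regions())
            if getattr(item, "body_discarded_reason", "none") == "edge_contact":
                prior_edge_discard = True
        else:
            flat.append(item)
    regions = flat
    for r in regions:
        if r.mask.shape != tuple(image_shape):
            raise ValueError("all regions must share the frame shape")
    if mode not in ("larva", "egg"):
        raise ValueError(f"mode must be 'larva' or 'egg', got {mode!r}")

    audit: list[AuditEntry] = []
    nonempty = []
    for r in regions:
        if r.mask.any():
            nonempty.append(fill_holes(r))
        else:
            audit.append(AuditEntry(r.feature_class.value, "empty", 0))

    if mode == "egg":
        eggs: list[EggSegmentation] = []
        for r in nonempty:
            if r.feature_class is not FeatureClass.EGG:
                audit.append(AuditEntry(r.feature_class.value, "egg_mode_excluded", r.area_px))
                continue
            if touches_border(r.mask):
                audit.append(AuditEntry(r.feature_class.value, "edge_contact", r.area_px))
                continue
            eggs.append(EggSegmentation(egg=r))
        return eggs, audit

    kept, aud, body_discarded = discard_edge_regions(nonempty)
    audit += aud
    bodies = [r for r in kept if r.feature_class is FeatureClass.BODY]
    parts = [r for r in kept if r.feature_class is not FeatureClass.BODY]
    segs, aud = associate_parts(
        bodies, parts, config,
        any_body_edge_discarded=body_discarded or prior_edge_discard,
    )
    audit += aud
    return segs, audit
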