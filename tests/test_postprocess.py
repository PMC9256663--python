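import numpy as np
import pytest

from ichthyoflow.core import FeatureClass, LabeledRegion
from ichthyoflow.postprocess import (
    EggSegmentation,
    FishSegmentation,
    PostprocessConfig,
    associate_parts,
    discard_edge_regions,
    enforce_cardinality,
    enforce_containment,
    fill_holes,
    postprocess,
    region_solidity,
    touches_border,
)

from conftest import make_disc, region


class TestFillHoles:
    def test_annulus_filled_to_disc(self):
        shape = (100, 100)
        annulus = make_disc(shape, (50, 50), 30) & ~make_disc(shape, (50, 50), 10)
        inner = make_disc(shape, (50, 50), 10)
        filled = fill_holes(region(annulus, FeatureClass.YOLK))
        assert filled.area_px == annulus.sum() + inner.sum()

    def test_idempotent_on_solid_disc(self):
        disc = region(make_disc((80, 80), (40, 40), 25))
        once = fill_holes(disc)
        twice = fill_holes(once)
        assert np.array_equal(once.mask, disc.mask)
        assert np.array_equal(twice.mask, once.mask)

    def test_border_open_concavity_not_filled(self):
        mask = np.zeros((30, 30), bool)
        mask[0:20, 5:25] = True
        mask[0:10, 12:18] = False  # notch open to the top border
        filled = fill_holes(region(mask))
        assert np.array_equal(filled.mask, mask)


class TestEdgeDiscard:
    def _scene(self, body_at_edge):
        shape = (120, 120)
        body = np.zeros(shape, bool)
        if body_at_edge:
            body[40:80, 0:90] = True  # touches left border
        else:
            body[40:80, 10:90] = True
        eye = make_disc(shape, (60, 30), 6)
        yolk = make_disc(shape, (60, 60), 10)
        return (
            region(body, FeatureClass.BODY),
            region(eye, FeatureClass.EYE),
            region(yolk, FeatureClass.YOLK),
        )

    def test_edge_body_removed_organs_kept(self):
        regs = self._scene(body_at_edge=True)
        kept, audit, body_discarded = discard_edge_regions(regs)
        assert body_discarded
        assert {r.feature_class for r in kept} == {FeatureClass.EYE, FeatureClass.YOLK}
        assert audit[0].reason == "edge_contact"

    def test_interior_regions_identity(self):
        regs = self._scene(body_at_edge=False)
        kept, audit, body_discarded = discard_edge_regions(regs)
        assert len(kept) == 3 and not audit and not body_discarded

    def test_edge_eye_removed_individually(self):
        shape = (50, 50)
        eye = np.zeros(shape, bool)
        eye[0:5, 10:15] = True
        kept, audit, _ = discard_edge_regions([region(eye, FeatureClass.EYE)])
        assert not kept and audit[0].feature_class == "eye"


class TestContainment:
    def _body(self):
        body = np.zeros((100, 100), bool)
        body[20:80, 20:60] = True
        return region(body, FeatureClass.BODY)

    def test_inside_kept_disjoint_removed(self):
        inside = np.zeros((100, 100), bool)
        inside[40:50, 30:40] = True
        outside = np.zeros((100, 100), bool)
        outside[40:50, 80:90] = True
        kept, audit = enforce_containment(
            self._body(),
            [region(inside, FeatureClass.EYE), region(outside, FeatureClass.YOLK)],
        )
        assert len(kept) == 1 and kept[0].feature_class is FeatureClass.EYE
        assert audit[0].reason == "outside_body"

    def test_slack_semantics(self):
        # eye spills 3 px past the body boundary (cols 60..62)
        eye = np.zeros((100, 100), bool)
        eye[40:50, 53:63] = True
        e = region(eye, FeatureClass.EYE)
        assert len(enforce_containment(self._body(), [e], slack_px=0)[0]) == 0
        assert len(enforce_containment(self._body(), [e], slack_px=5)[0]) == 1


class TestCardinality:
    def test_top_two_eyes_by_confidence(self):
        eyes = [
            region(make_disc((60, 60), (20, 20), 5), FeatureClass.EYE, 0.9),
            region(make_disc((60, 60), (20, 40), 5), FeatureClass.EYE, 0.8),
            region(make_disc((60, 60), (40, 30), 5), FeatureClass.EYE, 0.4),
        ]
        kept, audit = enforce_cardinality(eyes, FeatureClass.EYE)
        assert [k.confidence for k in kept] == [0.9, 0.8]
        assert audit[0].reason == "cardinality"

    def test_single_body_retained(self):
        body = [region(make_disc((60, 60), (30, 30), 10), FeatureClass.BODY, 0.7)]
        kept, audit = enforce_cardinality(body, FeatureClass.BODY)
        assert len(kept) == 1 and not audit

    def test_tie_broken_by_area(self):
        big = region(make_disc((80, 80), (30, 30), 13), FeatureClass.YOLK, 0.5)
        small = region(make_disc((80, 80), (60, 60), 10), FeatureClass.YOLK, 0.5)
        kept, _ = enforce_cardinality([small, big], FeatureClass.YOLK)
        assert kept[0] is big


class TestAssociation:
    def _fish(self, row_offset):
        shape = (300, 160)
        body = np.zeros(shape, bool)
        body[row_offset : row_offset + 60, 20:140] = True
        eyes = [
            make_disc(shape, (row_offset + 30, 40), 8),
            make_disc(shape, (row_offset + 30, 60), 8),
        ]
        yolk = make_disc(shape, (row_offset + 30, 100), 12)
        return body, eyes, yolk

    def test_two_fish_grouped_completely(self):
        b1, e1, y1 = self._fish(20)
        b2, e2, y2 = self._fish(180)
        bodies = [region(b1, FeatureClass.BODY), region(b2, FeatureClass.BODY)]
        parts = [region(m, FeatureClass.EYE) for m in e1 + e2] + [
            region(y1, FeatureClass.YOLK),
            region(y2, FeatureClass.YOLK),
        ]
        segs, audit = associate_parts(bodies, parts)
        assert len(segs) == 2
        for seg in segs:
            assert len(seg.eyes) == 2 and seg.yolk is not None
        assert not audit

    def test_orphan_part_dropped_when_body_exists(self):
        b1, e1, y1 = self._fish(20)
        stray = make_disc((300, 160), (250, 80), 8)
        segs, audit = associate_parts(
            [region(b1, FeatureClass.BODY)],
            [region(stray, FeatureClass.EYE)],
        )
        assert segs[0].eyes == []
        assert audit[0].reason == "no_body"

    def test_bodiless_group_only_after_edge_discard(self):
        _, e1, y1 = self._fish(20)
        parts = [region(m, FeatureClass.EYE) for m in e1] + [
            region(y1, FeatureClass.YOLK)
        ]
        segs, _ = associate_parts([], parts, any_body_edge_discarded=True)
        assert len(segs) == 1 and segs[0].body is None
        assert segs[0].body_discarded_reason == "edge_contact"
        assert len(segs[0].eyes) == 2 and segs[0].yolk is not None
        # without edge discard, orphans are dropped
        segs, audit = associate_parts([], parts, any_body_edge_discarded=False)
        assert not segs and all(a.reason == "no_body" for a in audit)


def _fixture_scene():
    """One fish with a holed yolk + assorted spurious regions."""
    shape = (300, 400)
    body = np.zeros(shape, bool)
    body[100:200, 50:350] = True
    eyes = [make_disc(shape, (150, 80), 12), make_disc(shape, (150, 115), 12)]
    extra_eye = make_disc(shape, (150, 320), 9)
    yolk = make_disc(shape, (150, 200), 30) & ~make_disc(shape, (150, 200), 10)
    # mostly inside the body but spilling past its boundary -> containment
    stray_yolk = make_disc(shape, (150, 345), 15)
    regs = (
        [region(body, FeatureClass.BODY, 0.95)]
        + [region(m, FeatureClass.EYE, 0.9) for m in eyes]
        + [region(extra_eye, FeatureClass.EYE, 0.3)]
        + [region(yolk, FeatureClass.YOLK, 0.9), region(stray_yolk, FeatureClass.YOLK, 0.8)]
    )
    return regs, shape


class TestPostprocess:
    def test_rules_applied_in_concert(self):
        regs, shape = _fixture_scene()
        segs, audit = postprocess(regs, shape)
        assert len(segs) == 1
        seg = segs[0]
        assert len(seg.eyes) == 2 and seg.yolk is not None
        # the holed yolk was filled
        assert seg.yolk.area_px == make_disc(shape, (150, 200), 30).sum()
        reasons = {a.reason for a in audit}
        assert "cardinality" in reasons and "outside_body" in reasons

    def test_idempotence(self):
        regs, shape = _fixture_scene()
        segs, _ = postprocess(regs, shape)
        flat = [r for s in segs for r in s.regions()]
        segs2, audit2 = postprocess(flat, shape)
        assert len(segs2) == len(segs)
        for a, b in zip(segs, segs2):
            assert np.array_equal(a.body.mask, b.body.mask)
            assert np.array_equal(a.yolk.mask, b.yolk.mask)
            for ea, eb in zip(
                sorted(a.eyes, key=lambda r: r.centroid),
                sorted(b.eyes, key=lambda r: r.centroid),
            ):
                assert np.array_equal(ea.mask, eb.mask)

    def test_cardinality_caps_never_exceeded(self, rng):
        shape = (120, 120)
        classes = [FeatureClass.BODY, FeatureClass.EYE, FeatureClass.YOLK]
        regs = []
        for _ in range(12):
            cls = classes[int(rng.integers(0, 3))]
            c = rng.integers(20, 100, 2)
            regs.append(
                region(make_disc(shape, tuple(c), int(rng.integers(4, 15))),
                       cls, float(rng.random()))
            )
        segs, _ = postprocess(regs, shape)
        for seg in segs:
            assert seg.body is not None
            assert len(seg.eyes) <= 2
            assert seg.yolk is None or isinstance(seg.yolk.mask, np.ndarray)

    def test_egg_mode_validates_shells_only(self):
        shape = (200, 200)
        shell = make_disc(shape, (100, 100), 40) & ~make_disc(shape, (100, 100), 36)
        edge_egg = make_disc(shape, (0, 100), 30)
        embryo = make_disc(shape, (100, 100), 15)
        regs = [
            region(shell, FeatureClass.EGG, 0.9),
            region(edge_egg, FeatureClass.EGG, 0.9),
            region(embryo, FeatureClass.BODY, 0.9),
        ]
        eggs, audit = postprocess(regs, shape, mode="egg")
        assert len(eggs) == 1 and isinstance(eggs[0], EggSegmentation)
        # the ring was filled to a solid disc
        assert eggs[0].egg.area_px == make_disc(shape, (100, 100), 40).sum()
        reasons = {a.reason for a in audit}
        assert {"edge_contact", "egg_mode_excluded"} <= reasons

    def test_empty_input(self):
        segs, audit = postprocess([], (50, 50))
        assert segs == [] and audit == []

    def test_figure_eight_eye_flagged_by_solidity(self):
        shape = (200, 200)
        body = np.zeros(shape, bool)
        body[40:160, 20:180] = True
        fig8 = make_disc(shape, (100, 80), 15) | make_disc(shape, (100, 120), 15)
        fig8[98:103, 80:120] = True  # narrow waist joining the lobes
        regs = [region(body, FeatureClass.BODY, 0.9),
                region(fig8, FeatureClass.EYE, 0.9)]
        segs, _ = postprocess(regs, shape)
        assert region_solidity(segs[0].eyes[0]) < 0.85
        assert "eye_shape_suspect" in segs[0].flags
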