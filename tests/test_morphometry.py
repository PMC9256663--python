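import math

import numpy as np
import pytest
from skimage import measure as skmeasure

from ichthyoflow.core import FeatureClass, PixelScale
from ichthyoflow.morphometry import (
    Centerline,
    MorphometryError,
    extract_centerline,
    facing_direction,
    measure_axes,
    measure_individual,
    standard_length,
)
from ichthyoflow.postprocess import EggSegmentation, FishSegmentation, postprocess
from ichthyoflow.synthetic import (
    DEFAULT_SCALE,
    EggSpec,
    LarvaSpec,
    render_egg,
    render_larva,
)

from conftest import make_disc, make_ellipse, region


class TestCenterline:
    def test_rectangle_midline_length(self):
        mask = np.zeros((120, 480), bool)
        mask[40:80, 40:440] = True  # 400 x 40
        cl = extract_centerline(mask)
        assert cl.arc_length_px == pytest.approx(400, abs=8)

    def test_semicircular_tube_arc_length(self):
        rr, cc = np.mgrid[0:260, 0:460]
        rho = np.hypot(rr - 250.0, cc - 230.0)
        tube = (rho >= 185) & (rho <= 215) & (rr <= 250)
        cl = extract_centerline(tube)
        assert cl.arc_length_px == pytest.approx(math.pi * 200, rel=0.03)

    def test_disc_degenerates_to_diameter(self):
        disc = make_disc((140, 140), (70, 70), 55)
        cl = extract_centerline(disc)
        assert "low_elongation" in cl.flags
        assert cl.arc_length_px == pytest.approx(110, abs=6)

    def test_all_points_inside_mask(self):
        mask = np.zeros((120, 480), bool)
        mask[40:80, 40:440] = True
        cl = extract_centerline(mask)
        rr = np.round(cl.points[:, 0]).astype(int)
        cc = np.round(cl.points[:, 1]).astype(int)
        assert mask[rr, cc].all()

    def test_disconnected_mask_rejected(self):
        mask = np.zeros((60, 60), bool)
        mask[5:15, 5:15] = True
        mask[40:50, 40:50] = True
        with pytest.raises(MorphometryError, match="components"):
            extract_centerline(mask)

    def test_empty_mask_rejected(self):
        with pytest.raises(MorphometryError):
            extract_centerline(np.zeros((10, 10), bool))


class TestStandardLength:
    def test_pixel_to_mm_conversion(self):
        cl = Centerline(np.zeros((2, 2)), arc_length_px=1244.0)
        assert standard_length(cl, PixelScale(0.0036)) == pytest.approx(4.4784)

    def test_straight_synthetic_larva_recovered(self):
        spec = LarvaSpec(standard_length_mm=4.20)
        scene = render_larva(spec, seed=3)
        body = next(r for r in scene.regions if r.feature_class is FeatureClass.BODY)
        sl = standard_length(extract_centerline(body.mask), DEFAULT_SCALE)
        assert sl == pytest.approx(4.20, abs=0.08)


class TestFacingDirection:
    def test_synthetic_head_identified(self):
        scene = render_larva(LarvaSpec(heading_rad=1.1), seed=5)
        body = next(r for r in scene.regions if r.feature_class is FeatureClass.BODY)
        cl = extract_centerline(body.mask)
        heading, head_pt, ambiguous = facing_direction(body.mask, cl)
        truth = scene.truths[0]["heading"]
        assert not ambiguous
        assert heading[0] * truth[0] + heading[1] * truth[1] > 0.95

    def test_symmetric_capsule_is_ambiguous(self):
        cap = np.zeros((80, 400), bool)
        cap[25:55, 40:360] = True
        cap |= make_disc((80, 400), (40, 40), 15)
        cap |= make_disc((80, 400), (40, 360), 15)
        cl = extract_centerline(cap)
        _, _, ambiguous = facing_direction(cap, cl)
        assert ambiguous

    def test_mirror_equivariance(self):
        scene = render_larva(LarvaSpec(curvature_turn_rad=0.8), seed=9)
        body = next(r for r in scene.regions if r.feature_class is FeatureClass.BODY)
        h1, _, _ = facing_direction(body.mask, extract_centerline(body.mask))
        flipped = body.mask[:, ::-1]
        h2, _, _ = facing_direction(flipped, extract_centerline(flipped))
        assert h2[0] == pytest.approx(h1[0], abs=0.02)
        assert h2[1] == pytest.approx(-h1[1], abs=0.02)


class TestAxes:
    def test_solid_ellipse_axes(self):
        mask = make_ellipse((200, 200), (100, 100), 60, 30)
        ax = measure_axes(mask)
        assert ax.major_px == pytest.approx(120, abs=1)
        assert ax.minor_px == pytest.approx(60, abs=1)

    def test_disc_isotropy(self):
        ax = measure_axes(make_disc((160, 160), (80, 80), 50))
        assert ax.major_px == pytest.approx(100, abs=1)
        assert ax.minor_px == pytest.approx(100, abs=1)

    def test_rotation_invariance_of_axes(self):
        th = math.radians(37)
        mask = make_ellipse((260, 260), (130, 130), 60, 30, th)
        ax = measure_axes(mask)
        assert ax.major_px == pytest.approx(120, abs=1)
        assert ax.minor_px == pytest.approx(60, abs=1)
        assert ax.orientation == pytest.approx(th, abs=math.radians(1))

    def test_against_regionprops_reference(self):
        # independent route: skimage's moment-ellipse axes (no 1/12 term)
        mask = make_ellipse((300, 300), (150, 150), 90, 45, 0.6)
        ax = measure_axes(mask)
        rp = skmeasure.regionprops(mask.astype(np.uint8))[0]
        assert ax.major_px == pytest.approx(rp.axis_major_length, rel=0.01)
        assert ax.minor_px == pytest.approx(rp.axis_minor_length, rel=0.01)

    def test_single_pixel_flagged_degenerate(self):
        mask = np.zeros((10, 10), bool)
        mask[4, 4] = True
        assert "degenerate" in measure_axes(mask).flags

    def test_translation_and_flip_equivariance(self):
        m = make_ellipse((200, 260), (90, 120), 50, 20, 0.4)
        a = measure_axes(m)
        b = measure_axes(np.roll(m, (12, -17), axis=(0, 1)))
        c = measure_axes(m[::-1])
        assert b.major_px == pytest.approx(a.major_px, abs=1e-9)
        assert c.major_px == pytest.approx(a.major_px, abs=1e-6)
        assert c.minor_px == pytest.approx(a.minor_px, abs=1e-6)


class TestMeasureIndividual:
    def test_synthetic_larva_recovery(self):
        spec = LarvaSpec()
        scene = render_larva(spec, seed=21)
        segs, _ = postprocess(scene.regions, scene.image.shape, mode="larva")
        rec = measure_individual(segs[0], DEFAULT_SCALE, mode="larva")
        truth = scene.truths[0]
        assert rec.body_valid and rec.eyes_valid and rec.yolk_valid
        assert rec.standard_length_mm == pytest.approx(truth["sl_mm"], rel=0.03)
        assert rec.body_area_mm2 == pytest.approx(truth["body_area_mm2"], rel=0.03)
        assert rec.yolk_length_mm == pytest.approx(truth["yolk_length_mm"], rel=0.03)
        assert rec.yolk_width_mm == pytest.approx(truth["yolk_width_mm"], rel=0.03)
        assert rec.eye_width_mm == pytest.approx(truth["eye_width_mm"], rel=0.03)
        assert rec.yolk_width_mm <= rec.yolk_length_mm
        assert rec.eye_width_mm <= rec.eye_length_mm
        # structural volume consistency
        assert rec.structural_volume_mm3 == pytest.approx(
            rec.total_volume_mm3 - rec.yolk_volume_mm3
        )

    def test_synthetic_egg_recovery(self):
        scene = render_egg(EggSpec(diameter_mm=1.36), seed=4)
        eggs, _ = postprocess(scene.regions, scene.image.shape, mode="egg")
        rec = measure_individual(eggs[0], DEFAULT_SCALE, mode="egg")
        px_mm = DEFAULT_SCALE.mm_per_px
        assert rec.egg_major_mm == pytest.approx(1.36, abs=2 * px_mm)
        assert rec.egg_minor_mm == pytest.approx(1.36, abs=2 * px_mm)
        assert rec.egg_diameter_mm == pytest.approx(1.36, abs=2 * px_mm)
        assert rec.circularity == pytest.approx(1.0, abs=0.02)
        assert rec.egg_valid

    def test_bodiless_segmentation_keeps_organ_fields(self):
        scene = render_larva(LarvaSpec(), seed=2)
        eyes = [r for r in scene.regions if r.feature_class is FeatureClass.EYE]
        yolk = next(r for r in scene.regions if r.feature_class is FeatureClass.YOLK)
        seg = FishSegmentation(
            body=None, eyes=eyes, yolk=yolk, body_discarded_reason="edge_contact"
        )
        rec = measure_individual(seg, DEFAULT_SCALE, mode="larva")
        assert not rec.body_valid
        assert rec.standard_length_mm is None
        assert rec.eyes_valid and rec.yolk_valid
        assert rec.eye_width_mm is not None and rec.yolk_volume_mm3 is not None

    def test_mode_type_mismatch_rejected(self):
        with pytest.raises(TypeError):
            measure_individual(FishSegmentation(), DEFAULT_SCALE, mode="egg")
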