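"""Cord skeleton/boundary geometry, crevice filtering, and coil counting."""

import numpy as np
import pytest

from conftest import coil_config
from plax.coiling import (CoilResult, CreviceSegment, analyze_cord,
                          classify_hypercoiled, coilness, cord_geometry,
                          count_coils, detect_crevices)
from plax.scene import CORD, generate_scene


def make_segment(position, span, e1=(0.0, 0.0)):
    return CreviceSegment(pixels=np.zeros((2, 2)), e1=e1, e2=e1, e3=e1, e4=e1,
                          boundary_side=0, boundary_pos=position,
                          boundary_span=span, position=position,
                          angle_to_skeleton=np.pi / 2, length_px=5.0)


class TestCordGeometry:
    def test_straight_bar_skeleton_length(self):
        bar = np.zeros((60, 260), bool)
        bar[20:40, 30:230] = True
        g = cord_geometry(bar)
        assert 195 <= g.length_px <= 205

    def test_semicircular_cord_arc_length(self):
        H = W = 320
        y, x = np.mgrid[0:H, 0:W]
        r = np.hypot(x - 160, y - 280)
        mask = (np.abs(r - 120) <= 12) & (y <= 280)
        g = cord_geometry(mask)
        assert g.length_px == pytest.approx(np.pi * 120, rel=0.03)

    def test_boundaries_partition_the_contour(self):
        bar = np.zeros((40, 200), bool)
        bar[15:28, 20:180] = True
        g = cord_geometry(bar)
        from skimage.measure import find_contours
        contour = max(find_contours(bar.astype(float), 0.5), key=len)
        total = len(g.boundary_a) + len(g.boundary_b)
        assert abs(total - len(contour)) <= 4   # endpoints shared

    def test_skeleton_inside_mask(self, coil_scene):
        mask = coil_scene.label_map == CORD
        g = cord_geometry(mask)
        rr = np.clip(np.round(g.skeleton[:, 0]).astype(int), 0, mask.shape[0] - 1)
        cc = np.clip(np.round(g.skeleton[:, 1]).astype(int), 0, mask.shape[1] - 1)
        assert mask[rr, cc].mean() > 0.99

    def test_multiple_components_warns_and_uses_largest(self):
        m = np.zeros((60, 120), bool)
        m[10:20, 10:110] = True
        m[40:46, 10:20] = True
        with pytest.warns(UserWarning, match="largest"):
            g = cord_geometry(m)
        assert g.length_px > 80

    def test_too_narrow_rejected(self):
        m = np.zeros((20, 80), bool)
        m[10, 5:75] = True
        with pytest.raises(ValueError, match="narrow"):
            cord_geometry(m)


class TestDetectCrevices:
    def test_planted_crevices_found(self, coil_scene):
        mask = coil_scene.label_map == CORD
        g = cord_geometry(mask)
        segs = detect_crevices(coil_scene.image, mask, g)
        assert len(segs) == coil_scene.truth.coil_count

    def test_smooth_cord_yields_nothing(self):
        sc = generate_scene(coil_config(0), seed=3)
        mask = sc.label_map == CORD
        segs = detect_crevices(sc.image, mask, cord_geometry(mask))
        assert segs == []

    def test_axial_streak_rejected_by_angle_filter(self):
        # straight bar cord with a dark line along its axis: parallel edge
        mask = np.zeros((60, 260), bool)
        mask[20:40, 30:230] = True
        img = np.full((60, 260, 3), 220, np.uint8)
        img[~mask] = 60
        img[29:31, 80:160] = 30          # axial streak, angle ~0
        g = cord_geometry(mask)
        segs = detect_crevices(img, mask, g)
        assert len(segs) == 0
        # the same streak drawn across the cord is kept
        img2 = np.full((60, 260, 3), 220, np.uint8)
        img2[~mask] = 60
        img2[24:37, 120:122] = 30        # perpendicular mark
        segs2 = detect_crevices(img2, mask, g)
        assert len(segs2) == 1
        assert np.degrees(segs2[0].angle_to_skeleton) > 60

    def test_segments_ordered_along_cord(self, coil_scene):
        mask = coil_scene.label_map == CORD
        g = cord_geometry(mask)
        segs = detect_crevices(coil_scene.image, mask, g)
        pos = [s.position for s in segs]
        assert pos == sorted(pos)


class TestCountCoils:
    def test_close_pair_from_one_crevice_counted_once(self):
        segs = [make_segment(100.0, span=10.0), make_segment(112.0, span=10.0)]
        # d = 12 = 1.2 * T < 2T: the second segment is absorbed
        assert count_coils(segs).n == 1

    def test_well_separated_all_counted(self):
        segs = [make_segment(50.0 * i, span=5.0) for i in range(6)]
        assert count_coils(segs).n == 6

    def test_zero_segments(self):
        res = count_coils([])
        assert res.n == 0 and res.segments == []

    def test_duplicate_at_zero_distance_never_increments(self):
        base = make_segment(80.0, span=4.0)
        res = count_coils([base, make_segment(80.0, span=4.0)])
        assert res.n == 1

    def test_spacing_measured_from_last_counted(self):
        # 3 segments: s2 absorbed by s1, s3 spacing measured from s1 (not s2)
        segs = [make_segment(0.0, span=10.0), make_segment(15.0, span=10.0),
                make_segment(22.0, span=10.0)]
        assert count_coils(segs).n == 2     # 22 > 2*10 from the first


class TestCoilness:
    def test_arithmetic(self):
        assert coilness(8, 20.0) == pytest.approx(4.0)
        assert coilness(0, 10.0) == 0.0

    def test_homogeneity(self):
        assert coilness(6, 15.0) == pytest.approx(coilness(12, 30.0))

    def test_exact_rational_identity(self, rng):
        for _ in range(20):
            n = int(rng.integers(0, 30))
            l = float(rng.uniform(5, 60))
            assert abs(coilness(n, l) * l - 10.0 * n) < 1e-12

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            coilness(3, 0.0)


class TestHypercoiled:
    def test_inclusive_boundary(self):
        assert classify_hypercoiled(4.0) is True
        assert classify_hypercoiled(3.99) is False
        assert classify_hypercoiled(0.0) is False

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_hypercoiled(-1.0)


def test_analyze_cord_end_to_end(coil_scene):
    mask = coil_scene.label_map == CORD
    res = analyze_cord(coil_scene.image, mask,
                       coil_scene.truth.pixels_per_cm_true)
    assert abs(res.n - coil_scene.truth.coil_count) <= 1
    assert res.coilness == pytest.approx(10.0 * res.n / res.length_cm)
    assert res.hypercoiled == (res.coilness >= 4.0)
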