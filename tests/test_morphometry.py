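"""Disc recovery, ruler calibration, caliper axes and insertion category."""

import numpy as np
import pytest

from plax.morphometry import (CategoryThresholds, RulerUnreadableError,
                              categorize_insertion, disc_axes, fit_thresholds,
                              margin_distance, measure_insertion, px_to_cm,
                              recover_disc, ruler_scale, RulerScale)
from plax.scene import (CORD, DISC, SceneConfig, _disc_mask, generate_scene)


def make_scene(seed=0, **kw):
    return generate_scene(SceneConfig.for_size(384, 512, **kw), seed=seed)


class TestRecoverDisc:
    def test_recovers_occluded_ellipse(self):
        for seed in range(4):
            sc = make_scene(seed)
            rec = recover_disc(sc.label_map)
            truth = _disc_mask(sc.truth, sc.label_map.shape)
            iou = (rec & truth).sum() / (rec | truth).sum()
            assert iou >= 0.98

    def test_superset_of_raw_disc(self):
        sc = make_scene(3)
        rec = recover_disc(sc.label_map)
        assert np.all(rec[sc.label_map == DISC])

    def test_idempotent(self):
        sc = make_scene(4)
        rec = recover_disc(sc.label_map)
        relabeled = np.where(rec, DISC, np.where(sc.label_map == CORD, 0, 0)
                             ).astype(np.uint8)
        assert np.array_equal(recover_disc(relabeled), rec)

    def test_maternal_without_junction_unchanged_up_to_closing(self):
        sc = make_scene(5, side="maternal")
        rec = recover_disc(sc.label_map)
        disc = sc.label_map == DISC
        # no cord junction: recovery is just the morphological closing
        assert np.all(rec[disc])
        assert (rec & ~disc).sum() <= 0.01 * disc.sum()

    def test_no_disc_rejected(self):
        with pytest.raises(ValueError, match="disc"):
            recover_disc(np.zeros((32, 32), np.uint8))


class TestRulerScale:
    def test_reads_pitch_at_zero_and_oblique_orientation(self):
        for angle, seed in [(0.0, 31), (np.deg2rad(33), 32)]:
            cfg = SceneConfig.for_size(576, 768, tick_pitch=(25.0, 25.0),
                                       ruler_angle=angle)
            sc = generate_scene(cfg, seed=seed)
            rs = ruler_scale(sc.image, sc.label_map)
            assert 24.0 <= rs.pixels_per_cm <= 26.0

    def test_blank_ruler_unreadable(self):
        sc = make_scene(6)
        image = sc.image.copy()
        from plax.scene import RULER
        image[sc.label_map == RULER] = (240, 240, 240)   # erase the ticks
        with pytest.raises(RulerUnreadableError):
            ruler_scale(image, sc.label_map)

    def test_empty_ruler_class_rejected(self):
        sc = make_scene(7)
        labels = np.where(sc.label_map == 3, 0, sc.label_map).astype(np.uint8)
        with pytest.raises(RulerUnreadableError):
            ruler_scale(sc.image, labels)

    def test_mm_tick_unit_scales_by_ten(self):
        cfg = SceneConfig.for_size(576, 768, tick_pitch=(20.0, 20.0))
        sc = generate_scene(cfg, seed=33)
        cm = ruler_scale(sc.image, sc.label_map, tick_unit="cm").pixels_per_cm
        mm = ruler_scale(sc.image, sc.label_map, tick_unit="mm").pixels_per_cm
        assert mm == pytest.approx(10 * cm)


def raster_ellipse_mask(A, B, shape=(400, 400), angle=0.0):
    H, W = shape
    y, x = np.mgrid[0:H, 0:W]
    xc, yc = W / 2, H / 2
    xp = (x - xc) * np.cos(angle) + (y - yc) * np.sin(angle)
    yp = -(x - xc) * np.sin(angle) + (y - yc) * np.cos(angle)
    return (xp / A) ** 2 + (yp / B) ** 2 <= 1.0


class TestDiscAxes:
    def test_ellipse_diameters(self):
        lo, sh, ang = disc_axes(raster_ellipse_mask(120, 60))
        assert lo == pytest.approx(240, abs=2)
        assert sh == pytest.approx(120, abs=2)

    def test_circle(self):
        lo, sh, _ = disc_axes(raster_ellipse_mask(90, 90))
        assert lo == pytest.approx(180, abs=2)
        assert sh == pytest.approx(180, abs=2)

    def test_rotation_equivariance(self):
        lo0, sh0, a0 = disc_axes(raster_ellipse_mask(120, 60, angle=0.0))
        th = np.deg2rad(25)
        lo1, sh1, a1 = disc_axes(raster_ellipse_mask(120, 60, angle=th))
        assert lo1 == pytest.approx(lo0, abs=2)
        assert sh1 == pytest.approx(sh0, abs=2)
        diff = abs(np.degrees(a1 - a0)) % 180
        assert min(diff, 180 - diff) == pytest.approx(25, abs=1)

    def test_single_pixel(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        lo, sh, _ = disc_axes(mask)
        assert lo == 1.0 and sh == 1.0


class TestMarginDistance:
    def test_circle_center(self):
        mask = raster_ellipse_mask(100, 100, shape=(260, 260))
        d, _ = margin_distance((130, 130), mask)
        assert 99 <= d <= 100

    def test_boundary_point_is_zero(self):
        mask = raster_ellipse_mask(50, 50, shape=(140, 140))
        from scipy import ndimage
        boundary = mask & ~ndimage.binary_erosion(mask, np.ones((3, 3)))
        p = tuple(np.argwhere(boundary)[0])
        d, mp = margin_distance(p, mask)
        assert d == 0.0 and mp == p

    def test_one_lipschitz(self, rng):
        mask = raster_ellipse_mask(80, 50, shape=(220, 220))
        p = (110.0, 100.0)
        d0, _ = margin_distance(p, mask)
        for dp in [(1, 0), (0, 1), (-1, 0), (0, -1)]:
            d1, _ = margin_distance((p[0] + dp[0], p[1] + dp[1]), mask)
            assert abs(d1 - d0) <= 1.0 + 1e-9


class TestCategorize:
    def test_spec_boundaries(self):
        thr = CategoryThresholds(0.1, 1 / 3)
        assert categorize_insertion(0.0, thr) == "marginal"
        assert categorize_insertion(0.5, thr) == "central"
        assert categorize_insertion(1 / 3, thr) == "central"   # tie goes up
        assert categorize_insertion(0.2, thr) == "eccentric"

    def test_monotone_in_ratio(self):
        thr = CategoryThresholds(0.1, 0.3)
        order = {"marginal": 0, "eccentric": 1, "central": 2}
        cats = [order[categorize_insertion(r, thr)]
                for r in np.linspace(0, 0.5, 26)]
        assert all(b >= a for a, b in zip(cats, cats[1:]))

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            CategoryThresholds(0.4, 0.3)


class TestFitThresholds:
    def test_planted_boundaries_recovered(self, rng):
        ratios = ([(r, "marginal") for r in rng.uniform(0.02, 0.05, 8)]
                  + [(r, "eccentric") for r in rng.uniform(0.15, 0.25, 8)]
                  + [(r, "central") for r in rng.uniform(0.35, 0.45, 8)])
        thr = fit_thresholds(ratios)
        assert 0.05 < thr.t_marginal < 0.15
        assert 0.25 < thr.t_central < 0.35
        pred = [categorize_insertion(r, thr) for r, _ in ratios]
        assert pred == [c for _, c in ratios]

    def test_single_example_per_class(self):
        thr = fit_thresholds([(0.02, "marginal"), (0.2, "eccentric"),
                              (0.4, "central")])
        assert categorize_insertion(0.02, thr) == "marginal"
        assert categorize_insertion(0.2, thr) == "eccentric"
        assert categorize_insertion(0.4, thr) == "central"

    def test_one_class_only_warns(self):
        with pytest.warns(UserWarning):
            fit_thresholds([(0.1, "eccentric"), (0.2, "eccentric")])

    def test_disordered_categories_warn_but_fit(self):
        with pytest.warns(UserWarning, match="ordering"):
            fit_thresholds([(0.4, "marginal"), (0.02, "central"),
                            (0.2, "eccentric")])


class TestPxToCm:
    def test_arithmetic_and_round_trip(self):
        scale = RulerScale(pixels_per_cm=25.0, crest_positions=[0.0, 25.0],
                           rect_angle=0.0)
        assert px_to_cm(50, scale) == pytest.approx(2.0)
        assert px_to_cm(0, scale) == 0.0
        assert px_to_cm(3.7 * 25.0, scale) == pytest.approx(3.7, abs=1e-9)


def test_measure_insertion_end_to_end():
    sc = make_scene(8)
    meas = measure_insertion(sc.label_map, sc.truth.insertion_point)
    A, B = sc.truth.disc_semi_axes
    assert meas.long_axis_px == pytest.approx(2 * A, rel=0.03)
    assert meas.short_axis_px == pytest.approx(2 * B, rel=0.03)
    analytic = sc.truth.margin_distance_px()
    assert meas.margin_distance_px == pytest.approx(
        analytic, abs=0.05 * analytic + 0.1 * sc.truth.pixels_per_cm_true)
    assert meas.category in ("marginal", "eccentric", "central")
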