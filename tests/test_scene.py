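"""Synthetic scene generator: contracts and geometric ground truth."""

import dataclasses

import numpy as np
import pytest

from conftest import coil_config
from plax.scene import (BACKGROUND, CORD, DISC, RULER, SceneConfig,
                        SceneGenerationError, _disc_mask, degrade_scene,
                        generate_scene, read_scene, render_label_map,
                        write_scene)


@pytest.fixture(scope="module")
def scene():
    return generate_scene(SceneConfig.for_size(384, 512, coil_count=4,
                                               cord_length=(380.0, 440.0),
                                               cord_halfwidth=(8.0, 9.5)), seed=1)


class TestGenerate:
    def test_all_four_classes_present(self, scene):
        assert set(np.unique(scene.label_map)) == {BACKGROUND, DISC, CORD, RULER}

    def test_deterministic_for_fixed_seed(self, scene):
        cfg = SceneConfig.for_size(384, 512, coil_count=4,
                                   cord_length=(380.0, 440.0),
                                   cord_halfwidth=(8.0, 9.5))
        again = generate_scene(cfg, seed=1)
        assert np.array_equal(scene.image, again.image)
        assert np.array_equal(scene.label_map, again.label_map)
        assert scene.truth == again.truth

    def test_truth_is_sufficient_for_label_map(self, scene):
        rendered = render_label_map(scene.truth, scene.label_map.shape)
        assert np.array_equal(rendered, scene.label_map)

    def test_cord_overpaints_disc(self, scene):
        """Disc pixels plus the cord-covered part restore the full ellipse."""
        ellipse = _disc_mask(scene.truth, scene.label_map.shape)
        disc = scene.label_map == DISC
        cord = scene.label_map == CORD
        assert np.array_equal(disc | (cord & ellipse), ellipse)
        assert not (disc & cord).any()

    def test_insertion_point_inside_disc(self, scene):
        r, c = scene.truth.insertion_point
        ellipse = _disc_mask(scene.truth, scene.label_map.shape)
        assert ellipse[int(round(r)), int(round(c))]

    def test_ruler_disjoint_from_disc_and_cord(self, scene):
        ruler = scene.label_map == RULER
        ellipse = _disc_mask(scene.truth, scene.label_map.shape)
        assert not (ruler & ellipse).any()

    def test_maternal_scene_has_no_insertion_and_clear_disc(self):
        sc = generate_scene(SceneConfig.for_size(384, 512, side="maternal"), seed=2)
        assert sc.truth.insertion_point is None
        ellipse = _disc_mask(sc.truth, sc.label_map.shape)
        assert not ((sc.label_map == CORD) & ellipse).any()

    def test_star_amplitude_zero_gives_exact_ellipse(self, scene):
        assert scene.truth.star_amplitude == 0.0
        tr = dataclasses.replace(scene.truth, star_amplitude=0.0, star_points=0)
        assert np.array_equal(_disc_mask(tr, scene.label_map.shape),
                              _disc_mask(scene.truth, scene.label_map.shape))

    def test_star_disc_more_irregular_than_ellipse(self):
        from plax.shape import fit_ellipse, irregularity
        flat = generate_scene(SceneConfig.for_size(384, 512), seed=7)
        star = generate_scene(SceneConfig.for_size(384, 512, star_amplitude=0.3,
                                                   star_points=4), seed=7)
        def index(sc):
            mask = _disc_mask(sc.truth, sc.label_map.shape)
            return irregularity(mask, fit_ellipse(mask)).index
        assert index(star) > index(flat)

    def test_impossible_layout_raises_naming_object(self):
        cfg = SceneConfig.for_size(384, 512)
        cfg.semi_axis_a = (180.0, 185.0)     # disc leaves no room
        cfg.semi_axis_b = (150.0, 160.0)
        with pytest.raises(SceneGenerationError):
            generate_scene(cfg, seed=0)


def test_tick_spacing_matches_pitch_at_any_orientation():
    """Rendered dark tick marks are tick_pitch apart within +-1 px."""
    for angle in (0.0, 0.6, 1.1):
        cfg = SceneConfig.for_size(576, 768, tick_pitch=(24.0, 24.0),
                                   ruler_angle=angle)
        sc = generate_scene(cfg, seed=3)
        corners = np.asarray(sc.truth.ruler_rect)
        gray = sc.image.mean(axis=2)
        dark = (gray < 100) & (sc.label_map == RULER)
        pts = np.argwhere(dark).astype(float)
        # project on the long edge and cluster into ticks
        e = corners[0] - corners[3]
        u = e / np.linalg.norm(e)
        proj = np.sort(pts @ u)
        gaps = np.diff(proj)
        centers = []
        start = 0
        for i, g in enumerate(gaps):
            if g > 5:
                centers.append(proj[start:i + 1].mean())
                start = i + 1
        centers.append(proj[start:].mean())
        spacing = np.diff(centers)
        assert np.all(np.abs(spacing - 24.0) <= 1.0)


class TestDegrade:
    def test_identity_when_no_noise(self, scene):
        out = degrade_scene(scene, noise_sd=0.0, blur_sigma=0.0)
        assert np.array_equal(out.image, scene.image)

    def test_deterministic_noise(self, scene):
        a = degrade_scene(scene, noise_sd=5.0, seed=9)
        b = degrade_scene(scene, noise_sd=5.0, seed=9)
        assert np.array_equal(a.image, b.image)
        assert not np.array_equal(a.image, scene.image)

    def test_labels_and_truth_untouched(self, scene):
        out = degrade_scene(scene, noise_sd=10.0, blur_sigma=1.5, seed=4)
        assert np.array_equal(out.label_map, scene.label_map)
        assert out.truth == scene.truth

    def test_negative_parameters_rejected(self, scene):
        with pytest.raises(ValueError):
            degrade_scene(scene, noise_sd=-1.0)


def test_scene_io_round_trip(tmp_path, scene):
    write_scene(scene, tmp_path, "s1")
    back = read_scene(tmp_path, "s1")
    assert np.array_equal(back.image, scene.image)
    assert np.array_equal(back.label_map, scene.label_map)
    assert back.truth.disc_center == scene.truth.disc_center
    assert back.truth.insertion_point == scene.truth.insertion_point
    assert back.truth.ruler_rect == scene.truth.ruler_rect


def test_margin_distance_oracle_matches_dense_rasterization():
    """The analytic point-to-boundary distance agrees with a pixel search."""
    sc = generate_scene(SceneConfig.for_size(384, 512), seed=21)
    analytic = sc.truth.margin_distance_px()
    ellipse = _disc_mask(sc.truth, sc.label_map.shape)
    from scipy import ndimage
    boundary = ellipse & ~ndimage.binary_erosion(ellipse)
    pts = np.argwhere(boundary)
    brute = np.linalg.norm(pts - np.asarray(sc.truth.insertion_point),
                           axis=1).min()
    assert analytic == pytest.approx(brute, abs=1.0)
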