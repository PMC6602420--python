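"""Phantom synthesis: geometry ground truth, determinism, render physics."""

import numpy as np
import pytest

from fluoroguide import (
    CArmPose,
    PhantomNoiseSpec,
    make_catheter_curve,
    make_spine_phantom,
    render_fluoroscopy,
)
from fluoroguide.phantom import FieldOfViewWarning, RoundedBox
from fluoroguide.projection import project_point

from conftest import FRAME_SIZE, POSES, SPACING


class TestMakeSpinePhantom:
    def test_single_symmetric_solid_centroid_is_box_center(self):
        m = make_spine_phantom(n_vertebrae=1, jitter_mm=0.0, size_taper=0.0)
        assert len(m.vertebrae) == 1
        np.testing.assert_allclose(m.vertebrae[0].center, [0.0, 0.0, 0.0])

    def test_centroid_spacing_is_height_plus_gap(self):
        m = make_spine_phantom(
            n_vertebrae=5, vertebra_size=(24, 20, 20), gap=4.0, jitter_mm=0.0
        )
        ys = m.vertebra_centroids[:, 1]
        np.testing.assert_allclose(np.diff(ys), 24.0)

    def test_same_seed_is_bit_identical(self):
        a = make_spine_phantom(jitter_mm=0.8, seed=42)
        b = make_spine_phantom(jitter_mm=0.8, seed=42)
        np.testing.assert_array_equal(a.vertebra_centroids, b.vertebra_centroids)
        for va, vb in zip(a.vertebrae, b.vertebrae):
            np.testing.assert_array_equal(va.size, vb.size)

    def test_taper_makes_inferior_bodies_wider(self):
        m = make_spine_phantom(jitter_mm=0.0, size_taper=0.05)
        widths = [v.size[0] for v in m.vertebrae]
        assert widths == sorted(widths, reverse=True)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_vertebrae=0), dict(gap=-1.0), dict(vertebra_size=(0, 10, 10))],
    )
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            make_spine_phantom(**kwargs)


class TestMakeCatheterCurve:
    def test_two_waypoints_linear_midpoint(self):
        c = make_catheter_curve([(0, 0, 0), (2, 4, 6)], samples_per_segment=1)
        assert len(c) == 2
        c2 = make_catheter_curve([(0, 0, 0), (2, 4, 6)], samples_per_segment=2)
        np.testing.assert_allclose(c2.points[1], [1, 2, 3])

    def test_tip_equals_last_waypoint_exactly(self):
        wps = [(0, -10, 0), (3, 0, 2), (1, 12, 5)]
        c = make_catheter_curve(wps, samples_per_segment=8)
        np.testing.assert_array_equal(c.tip, np.asarray(wps[-1], float))

    def test_resampling_density_invariance(self):
        wps = [(0, -40, 0), (4, -10, 2), (-2, 20, 6), (1, 45, 9)]
        coarse = make_catheter_curve(wps, samples_per_segment=25)
        fine = make_catheter_curve(wps, samples_per_segment=50)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(fine.points).query(coarse.points)
        assert d.max() < 0.1  # mm

    def test_duplicate_waypoints_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_catheter_curve([(0, 0, 0), (0, 0, 0), (1, 1, 1)])

    def test_ordered_insertion_to_tip(self):
        c = make_catheter_curve([(0, -50, 0), (0, 0, 0), (0, 30, 0)])
        assert c.points[0, 1] < c.points[-1, 1]
        assert np.all(np.diff(c.arc_length) >= 0)


class TestRenderFluoroscopy:
    def test_empty_scene_is_constant_background(self):
        img = render_fluoroscopy(
            make_spine_phantom(with_heart=False, with_connector=False),
            None,
            POSES["AP"],
            SPACING,
            (64, 64),
        )
        # only the vertebra column is present; crop a corner far from it
        corner = img.pixels[:10, :10]
        assert np.ptp(corner) == 0

    def test_single_voxel_solid_darkest_at_projected_location(self):
        from fluoroguide.phantom import AnatomyModel

        p = np.array([7.0, -3.0, 5.0])
        solid = RoundedBox("dot", p, np.array([0.5, 0.5, 0.5]), corner_frac=None)
        model = AnatomyModel(vertebrae=[solid])
        for pose in POSES.values():
            img = render_fluoroscopy(model, None, pose, SPACING, (256, 256))
            r, c = np.unravel_index(np.argmin(img.pixels), img.pixels.shape)
            expected = project_point(p, pose, SPACING, (256, 256))
            assert abs(c - expected[0]) < 1.5
            assert abs(r - expected[1]) < 1.5

    @pytest.mark.filterwarnings("ignore::fluoroguide.phantom.FieldOfViewWarning")
    def test_determinism_bit_identical(self, model, catheter):
        spec = PhantomNoiseSpec(gaussian_sigma=3.0, photon_noise_scale=0.5, seed=11)
        a = render_fluoroscopy(model, catheter, POSES["LAO30"], SPACING, (256, 256), spec)
        b = render_fluoroscopy(model, catheter, POSES["LAO30"], SPACING, (256, 256), spec)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_polarity_objects_darker_than_background(self, model, catheter):
        img = render_fluoroscopy(model, catheter, POSES["AP"], SPACING, FRAME_SIZE)
        bg = np.median(img.pixels)
        # spine centroid pixels and catheter pixels strictly darker
        for p in model.vertebra_centroids:
            x, y = project_point(p, POSES["AP"], SPACING, FRAME_SIZE)
            assert img.pixels[int(round(y)), int(round(x))] < bg
        x, y = project_point(catheter.points[len(catheter) // 2], POSES["AP"], SPACING, FRAME_SIZE)
        assert img.pixels[int(round(y)), int(round(x))] < bg

    def test_out_of_view_catheter_warns(self, model):
        c = make_catheter_curve([(-34, -200, 0), (-30, 0, 4)], samples_per_segment=10)
        with pytest.warns(FieldOfViewWarning):
            render_fluoroscopy(model, c, POSES["AP"], SPACING, (128, 128))

    def test_projection_consistency_with_project_point(self, model):
        """Rendered location of a marked world point matches project_point."""
        v = model.vertebrae[2]
        for pose in POSES.values():
            img = render_fluoroscopy(
                type(model)(vertebrae=[v]), None, pose, SPACING, (512, 512)
            )
            dark = img.pixels < np.median(img.pixels) - 20
            ys, xs = np.nonzero(dark)
            centroid = np.array([xs.mean(), ys.mean()])
            expected = project_point(v.center, pose, SPACING, (512, 512))
            assert np.linalg.norm(centroid - expected) < 0.5
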