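"""Biplane triangulation: exactness, correspondence, and noise propagation."""

import numpy as np
import pytest

from fluoroguide import (
    CArmPose,
    Curve3D,
    ReconstructionError,
    correspond_centerlines,
    make_catheter_curve,
    reconstruct,
    triangulate_point,
)
from fluoroguide.projection import project_points, rotation_about_y, view_transform
from fluoroguide.tracking import Centerline2D

SPACING = 0.25
SIZE = (640, 640)


def pose_for(theta: float) -> CArmPose:
    if theta > 0:
        return CArmPose("LAO", theta)
    if theta < 0:
        return CArmPose("RAO", -theta)
    return CArmPose("AP")


def synthetic_centerline(curve: Curve3D, pose: CArmPose, sigma_px=0.0, rng=None):
    """Exact projected centerline of a 3-D curve, optional detector-x noise."""
    pts = project_points(curve.points, pose, SPACING, SIZE)
    if sigma_px > 0:
        pts = pts.copy()
        pts[:, 0] += rng.normal(0.0, sigma_px, len(pts))
    n = len(pts)
    return Centerline2D(
        points=pts,
        directions=np.tile([0.0, -1.0], (n, 1)),
        widths=np.full(n, 16.0),
        spacing=SPACING,
        image_shape=SIZE,
    )


def propagated_pair_rms(thetas_deg, sigma_mm):
    """Closed-form linear propagation of detector noise into the per-point
    deviation-from-mean statistic (RMS form).

    Independent of the reconstruction code: builds the exact Jacobian of
    each pair's triangulated point with respect to the per-view detector
    noise (x and y of each view), subtracts the pair mean, and returns the
    average RMS deviation over pairs.
    """
    n_views = len(thetas_deg)
    pairs = [
        (i, j)
        for i in range(n_views)
        for j in range(i + 1, n_views)
        if abs(thetas_deg[i] - thetas_deg[j]) >= 5.0
    ]
    jacobians = []
    for i, j in pairs:
        th = np.deg2rad(thetas_deg[i] - thetas_deg[j])
        a = np.zeros((3, 2 * n_views))  # view-j frame; columns: x_0..x_n, y_0..y_n
        a[0, j] = 1.0  # x = x_j
        a[1, n_views + i] = 0.5  # y = (y_i + y_j)/2
        a[1, n_views + j] = 0.5
        a[2, i] = 1.0 / np.sin(th)  # z = (x_i - x_j cos)/sin
        a[2, j] = -np.cos(th) / np.sin(th)
        r_inv = rotation_about_y(-thetas_deg[j])
        jacobians.append(r_inv @ a)
    mean_jac = np.mean(jacobians, axis=0)
    rms = []
    for jac in jacobians:
        d = jac - mean_jac
        cov = sigma_mm**2 * d @ d.T
        rms.append(np.sqrt(np.trace(cov)))
    return float(np.mean(rms))


class TestTriangulatePoint:
    def test_axis_point_has_zero_depth(self):
        p = triangulate_point((0.0, 5.0), (0.0, 5.0), 30.0)
        np.testing.assert_allclose(p, [0.0, 5.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("theta", [10.0, 30.0, 60.0, 90.0])
    def test_exact_inverse_of_projection(self, theta):
        p = np.array([10.0, 5.0, 20.0])
        v1 = view_transform(pose_for(theta)) @ p
        v2 = view_transform(pose_for(0.0)) @ p
        rec = triangulate_point(v1[:2], v2[:2], theta)
        np.testing.assert_allclose(rec, p, atol=1e-9)

    def test_degenerate_angle_rejected(self):
        with pytest.raises(ReconstructionError, match="separation"):
            triangulate_point((1.0, 0.0), (1.0, 0.0), 2.0)

    def test_row_mismatch_rejected(self):
        with pytest.raises(ReconstructionError, match="mismatch"):
            triangulate_point((1.0, 0.0), (1.0, 3.0), 30.0)

    def test_depth_noise_grows_as_inverse_sine(self):
        """Monte-Carlo z-error ratio between 30 and 60 degree separations
        matches the closed form sqrt(1 + cos^2) / sin within 15%."""
        rng = np.random.default_rng(0)
        p = np.array([10.0, 5.0, 20.0])
        sigma = 0.25
        stds = {}
        for theta in (30.0, 60.0):
            v1 = view_transform(pose_for(theta)) @ p
            v2 = view_transform(pose_for(0.0)) @ p
            zs = []
            for _ in range(4000):
                n1 = v1[:2] + [rng.normal(0, sigma), 0]
                n2 = v2[:2] + [rng.normal(0, sigma), 0]
                zs.append(triangulate_point(n1, n2, theta)[2])
            stds[theta] = np.std(zs)
            expected = sigma * np.sqrt(1 + np.cos(np.deg2rad(theta)) ** 2) / np.sin(
                np.deg2rad(theta)
            )
            assert stds[theta] == pytest.approx(expected, rel=0.15)
        assert stds[30.0] / stds[60.0] == pytest.approx(2.05, rel=0.15)


class TestCorrespondCenterlines:
    @pytest.fixture()
    def curve(self):
        return make_catheter_curve(
            [(-34, -70, 0), (-31, -30, 2), (-32, 0, 4), (-28, 25, 6)],
            samples_per_segment=30,
        )

    def test_identical_traces_match_themselves(self, curve):
        cl = synthetic_centerline(curve, CArmPose("AP"))
        y, x1, x2 = correspond_centerlines(cl, cl)
        np.testing.assert_allclose(x1, x2, atol=1e-12)

    def test_round_trip_through_two_views(self, curve):
        c1 = synthetic_centerline(curve, pose_for(30.0))
        c2 = synthetic_centerline(curve, pose_for(0.0))
        y, x1, x2 = correspond_centerlines(c1, c2)
        pts = np.array(
            [triangulate_point((a, yy), (b, yy), 30.0) for a, b, yy in zip(x1, x2, y)]
        )
        from scipy.spatial import cKDTree

        d, _ = cKDTree(curve.resample(4000).points).query(pts)
        assert d.max() < 0.1  # mm, noiseless

    def test_truncated_trace_restricts_to_overlap(self, curve):
        c1 = synthetic_centerline(curve, CArmPose("AP"))
        half = Centerline2D(
            points=c1.points[: len(c1) // 2],
            directions=c1.directions[: len(c1) // 2],
            widths=c1.widths[: len(c1) // 2],
            spacing=SPACING,
            image_shape=SIZE,
        )
        y, _, _ = correspond_centerlines(c1, half)
        mm_half = half.points[:, 1]
        cy = (SIZE[0] - 1) / 2
        y_range_half = ((cy - mm_half) * SPACING).min(), ((cy - mm_half) * SPACING).max()
        assert y.min() >= y_range_half[0] - 1e-9
        assert y.max() <= y_range_half[1] + 1e-9

    def test_disjoint_rows_rejected(self, curve):
        c1 = synthetic_centerline(curve, CArmPose("AP"))
        shifted = Centerline2D(
            points=c1.points + [0.0, 5000.0],
            directions=c1.directions,
            widths=c1.widths,
            spacing=SPACING,
            image_shape=SIZE,
        )
        with pytest.raises(ReconstructionError):
            correspond_centerlines(c1, shifted)


class TestReconstruct:
    @pytest.fixture()
    def curve(self):
        return make_catheter_curve(
            [(-34, -70, 0), (-31, -30, 2), (-32, 0, 4), (-28, 25, 6)],
            samples_per_segment=30,
        )

    def three_views(self, curve, sigma_px=0.0, seed=0):
        rng = np.random.default_rng(seed)
        return [
            (synthetic_centerline(curve, pose_for(t), sigma_px, rng), pose_for(t))
            for t in (-30.0, 0.0, 30.0)
        ]

    def test_noiseless_three_views_agree_exactly(self, curve):
        _, report = reconstruct(self.three_views(curve))
        assert report.n_pairs == 3
        assert report.mean_mse < 1e-6

    def test_two_views_single_pair_caveat(self, curve):
        views = self.three_views(curve)[1:]
        _, report = reconstruct(views)
        assert report.n_pairs == 1
        assert report.single_pair
        assert report.mean_mse == 0.0

    def test_mse_matches_propagation_within_factor_two(self, curve):
        sigma_mm = 0.25
        _, report = reconstruct(self.three_views(curve, sigma_px=sigma_mm / SPACING))
        oracle = propagated_pair_rms([-30.0, 0.0, 30.0], sigma_mm)
        assert oracle / 2 < report.mean_mse < oracle * 2

    def test_mse_scales_linearly_in_sigma(self, curve):
        mses = []
        for sigma_mm in (0.1, 0.25, 0.5):
            _, rep = reconstruct(
                self.three_views(curve, sigma_px=sigma_mm / SPACING, seed=3)
            )
            mses.append(rep.mean_mse)
        assert mses[1] / mses[0] == pytest.approx(2.5, rel=0.25)
        assert mses[2] / mses[1] == pytest.approx(2.0, rel=0.25)

    def test_fewer_than_two_views_rejected(self, curve):
        with pytest.raises(ReconstructionError):
            reconstruct(self.three_views(curve)[:1])

    def test_consensus_ordered_insertion_to_tip(self, curve):
        out, _ = reconstruct(self.three_views(curve))
        assert out.points[0, 1] < out.points[-1, 1]
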