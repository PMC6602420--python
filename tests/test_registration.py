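"""Fourier-Mellin registration: spectral properties, phase correlation
oracle, and similarity recovery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import ndimage

from fluoroguide import (
    RigidTransform2D,
    apply_transform,
    phase_correlation,
    register,
    spectral_magnitude,
    to_log_polar,
)
from fluoroguide.registration import _center_similarity_matrix, _warp_by


def smooth_random_image(seed, shape=(128, 128), sigma=4.0):
    rng = np.random.default_rng(seed)
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma)


def center_params(t: RigidTransform2D, center):
    """Decompose into (k, alpha, translation-at-center) for comparisons."""
    c = np.array([*center, 1.0])
    sr = _center_similarity_matrix(t.k, t.alpha_deg, center)
    tc = (t.matrix @ c)[:2] - (sr @ c)[:2]
    return t.k, t.alpha_deg, tc


class TestRigidTransform2D:
    def test_identity_leaves_points(self):
        t = RigidTransform2D()
        pts = np.array([[3.0, 4.0], [-1.0, 7.5]])
        np.testing.assert_allclose(apply_transform(t, pts), pts)

    def test_pure_scale(self):
        t = RigidTransform2D(k=2.0)
        np.testing.assert_allclose(apply_transform(t, [[1.0, 1.0]]), [[2.0, 2.0]])

    @given(
        st.floats(0.5, 2.0),
        st.floats(-179.0, 179.0),
        st.floats(-50, 50),
        st.floats(-50, 50),
    )
    def test_inverse_round_trip(self, k, a, tx, ty):
        t = RigidTransform2D(k, a, tx, ty)
        pts = np.array([[10.0, -3.0], [0.0, 0.0], [99.0, 42.0]])
        back = apply_transform(t.inverse(), apply_transform(t, pts))
        np.testing.assert_allclose(back, pts, atol=1e-9)

    @given(st.floats(0.5, 2.0), st.floats(-179.0, 179.0))
    def test_matrix_determinant_is_k_squared(self, k, a):
        t = RigidTransform2D(k, a, 5.0, -2.0)
        det = np.linalg.det(t.matrix[:2, :2])
        assert det == pytest.approx(k**2, rel=1e-12)

    def test_from_matrix_round_trip(self):
        t = RigidTransform2D(1.3, 27.0, 12.0, -8.0)
        t2 = RigidTransform2D.from_matrix(t.matrix)
        assert (t2.k, t2.alpha_deg, t2.tx, t2.ty) == pytest.approx(
            (t.k, t.alpha_deg, t.tx, t.ty)
        )


class TestSpectralMagnitude:
    def test_translation_invariance(self):
        img = smooth_random_image(0)
        a = spectral_magnitude(img, window=False, highpass=False)
        b = spectral_magnitude(np.roll(img, (17, -9), axis=(0, 1)), window=False, highpass=False)
        np.testing.assert_allclose(a, b, rtol=1e-6, atol=1e-9)

    def test_constant_image_energy_at_dc_only(self):
        mag = spectral_magnitude(
            np.full((32, 32), 5.0), window=False, highpass=False
        )
        # mean is subtracted, so even the DC bin is zero for a constant image
        assert mag.max() < 1e-9

    def test_rotation_rotates_magnitude(self):
        """A 37-degree image rotation rotates the spectral magnitude by the
        same angle.  The band-limited input is a sum of sinusoids under a
        Gaussian envelope, so the rotated image can be evaluated analytically
        (no image-domain interpolation error)."""
        n = 256
        yy, xx = np.mgrid[:n, :n]
        x = xx - (n - 1) / 2
        y = yy - (n - 1) / 2
        rng = np.random.default_rng(5)
        freqs = rng.uniform(0.05, 0.25, (12, 2)) * rng.choice([-1, 1], (12, 2))
        phases = rng.uniform(0, 2 * np.pi, 12)
        env = np.exp(-(x**2 + y**2) / (2 * (n / 10) ** 2))

        def field(xa, ya):
            s = np.zeros_like(xa, dtype=float)
            for (fx, fy), p in zip(freqs, phases):
                s += np.cos(2 * np.pi * (fx * xa + fy * ya) + p)
            return s

        img = env * field(x, y)
        t = np.deg2rad(37.0)
        rot = env * field(
            np.cos(t) * x + np.sin(t) * y, -np.sin(t) * x + np.cos(t) * y
        )
        mag_a = spectral_magnitude(img, window=True, highpass=False)
        mag_b = spectral_magnitude(rot, window=True, highpass=False)
        mag_a_rot = ndimage.rotate(mag_a, -37.0, reshape=False, order=3)
        disc = x**2 + y**2 < (n / 3) ** 2
        corr = np.corrcoef(np.log1p(mag_a_rot[disc]), np.log1p(mag_b[disc]))[0, 1]
        assert corr > 0.99


class TestLogPolar:
    def test_identity_scale_gives_zero_gamma_shift(self):
        img = smooth_random_image(2)
        lp1 = to_log_polar(spectral_magnitude(img))
        lp2 = to_log_polar(spectral_magnitude(img.copy()))
        peak = phase_correlation(lp1.values, lp2.values)
        assert abs(peak.shift[0]) < 1e-6 and abs(peak.shift[1]) < 1e-6

    def test_scaling_shifts_gamma_axis_by_log_k(self):
        """Radially rescaling a magnitude grid by 1/k (the spectral effect of
        magnifying the image by k) shifts the log-polar map by log(k)/dgamma
        bins along gamma."""
        mag = spectral_magnitude(smooth_random_image(3, shape=(256, 256), sigma=3.0))
        k = 1.25
        # resample the magnitude itself: rho -> rho*k about the center
        scaled_mag = _warp_by(
            mag, np.linalg.inv(_center_similarity_matrix(1 / k, 0.0, (127.5, 127.5)))
        )
        lp_a = to_log_polar(mag)
        lp_b = to_log_polar(scaled_mag)
        peak = phase_correlation(lp_a.values, lp_b.values)
        measured_bins = abs(peak.shift[1])
        expected_bins = np.log(k) / lp_a.dgamma
        assert abs(measured_bins - expected_bins) < 0.5

    def test_180_degree_rotation_gives_identical_map(self):
        img = smooth_random_image(4)
        rot = ndimage.rotate(img, 180.0, reshape=False, order=1)
        lp_a = to_log_polar(spectral_magnitude(img, window=False))
        lp_b = to_log_polar(spectral_magnitude(rot, window=False))
        corr = np.corrcoef(lp_a.values.ravel(), lp_b.values.ravel())[0, 1]
        assert corr > 0.999

    def test_degenerate_bounds_rejected(self):
        mag = spectral_magnitude(smooth_random_image(5))
        with pytest.raises(ValueError):
            to_log_polar(mag, rho_bounds=(10.0, 5.0))


class TestPhaseCorrelation:
    def test_identity_peak_at_origin(self):
        img = smooth_random_image(6, shape=(64, 64), sigma=2.0)
        peak = phase_correlation(img, img)
        assert peak.shift[0] == pytest.approx(0.0, abs=1e-9)
        assert peak.shift[1] == pytest.approx(0.0, abs=1e-9)
        assert peak.height > 0.95

    def test_circular_shift_recovered(self):
        img = smooth_random_image(7, shape=(64, 64), sigma=2.0)
        shifted = np.roll(img, (7, -3), axis=(0, 1))
        peak = phase_correlation(img, shifted)
        assert peak.shift[0] == pytest.approx(7, abs=0.1)
        assert peak.shift[1] == pytest.approx(-3, abs=0.1)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_ncc(self, seed):
        """Oracle: exhaustive circular-shift normalized cross-correlation."""
        rng = np.random.default_rng(seed)
        img = ndimage.gaussian_filter(rng.standard_normal((64, 64)), 1.5)
        shift = tuple(rng.integers(-20, 20, 2))
        moved = np.roll(img, shift, axis=(0, 1))

        best, best_s = -np.inf, None
        a = img - img.mean()
        na = np.linalg.norm(a)
        for dr in range(64):
            rolled_r = np.roll(a, dr, axis=0)
            for dc in range(64):
                b = np.roll(rolled_r, dc, axis=1)
                score = (b * (moved - moved.mean())).sum() / na
                if score > best:
                    best, best_s = score, (dr, dc)
        brute = tuple((s + 32) % 64 - 32 for s in best_s)
        peak = phase_correlation(img, moved)
        assert abs(peak.shift[0] - brute[0]) < 0.5
        assert abs(peak.shift[1] - brute[1]) < 0.5

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError):
            phase_correlation(np.zeros((16, 16)), np.ones((16, 16)))


class TestRegister:
    def test_self_registration_is_identity(self, spine_silhouette):
        res = register(spine_silhouette, spine_silhouette)
        k, a, tc = center_params(res.transform, (255.5, 255.5))
        assert k == pytest.approx(1.0, abs=0.01)
        assert a == pytest.approx(0.0, abs=0.2)
        assert np.abs(tc).max() < 0.2

    def test_known_warp_recovered(self, spine_silhouette):
        sil = np.asarray(spine_silhouette.pixels, float)
        center = (255.5, 255.5)
        gt = np.array([[1, 0, 15.0], [0, 1, -8.0], [0, 0, 1]]) @ _center_similarity_matrix(
            1.1, 12.0, center
        )
        moving = _warp_by(sil, np.linalg.inv(gt))
        res = register(sil, moving)
        k, a, tc = center_params(res.transform, center)
        assert k == pytest.approx(1.1, rel=0.01)
        assert a == pytest.approx(12.0, abs=0.5)
        np.testing.assert_allclose(tc, [15.0, -8.0], atol=0.5)

    def test_175_degree_ambiguity_resolved(self, spine_silhouette):
        sil = np.asarray(spine_silhouette.pixels, float)
        center = (255.5, 255.5)
        gt = _center_similarity_matrix(1.0, 175.0, center)
        moving = _warp_by(sil, np.linalg.inv(gt))
        res = register(sil, moving)
        a = res.transform.alpha_deg % 360.0
        assert a == pytest.approx(175.0, abs=1.0)  # not wrapped to -5

    def test_rotation_scale_invariant_to_translation(self, spine_silhouette):
        sil = np.asarray(spine_silhouette.pixels, float)
        center = (255.5, 255.5)
        sr = _center_similarity_matrix(1.05, 8.0, center)
        res_a = register(sil, _warp_by(sil, np.linalg.inv(sr)))
        shift = np.array([[1, 0, 40.0], [0, 1, -25.0], [0, 0, 1]])
        res_b = register(sil, _warp_by(sil, np.linalg.inv(shift @ sr)))
        assert res_a.transform.k == pytest.approx(res_b.transform.k, rel=0.01)
        assert res_a.transform.alpha_deg == pytest.approx(
            res_b.transform.alpha_deg, abs=0.5
        )

    def test_mismatched_spacing_rejected(self, spine_silhouette):
        from fluoroguide import Image2D

        other = Image2D(np.asarray(spine_silhouette.pixels), spacing=0.5)
        with pytest.raises(ValueError, match="spacing"):
            register(spine_silhouette, other)
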