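"""Fourier-Mellin similarity registration by phase correlation.

The method aligns a fluoroscopic spine image (moving) to a CT-derived
reference projection (fixed) by a similarity transform — scale ``k``,
rotation ``alpha`` and translation ``(tx, ty)``:

* The Fourier spectral magnitude is translation-invariant; image rotation
  rotates it and scaling by ``k`` scales it by ``1/k``.
* Resampled on (angle, log-radius) axes, rotation and scale both become
  translations of the log-polar magnitude map.
* A phase correlation (inverse transform of the normalized cross-power
  spectrum) therefore shows a delta-like peak at the (rotation, log-scale)
  shift; a second phase correlation, after warping the moving image by the
  recovered rotation/scale, yields the translation.

Because real images have centrally symmetric spectral magnitudes, the
angular axis only spans 180 degrees and every solution carries an
``alpha`` / ``alpha + 180`` ambiguity; both candidates are tried and the one
with the stronger translation peak wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

from .core import Image2D

__all__ = [
    "RigidTransform2D",
    "LogPolarSpectrum",
    "CorrelationPeak",
    "RegistrationParams",
    "RegistrationResult",
    "spectral_magnitude",
    "to_log_polar",
    "phase_correlation",
    "register",
    "apply_transform",
]


@dataclass
class RigidTransform2D:
    """Similarity transform mapping moving (x, y) px to fixed (x, y) px.

    The homogeneous matrix is
    ``[[k cos a, k sin a, tx], [-k sin a, k cos a, ty], [0, 0, 1]]``
    with ``a = alpha_deg`` and ``k > 0``.
    """

    k: float = 1.0
    alpha_deg: float = 0.0
    tx: float = 0.0
    ty: float = 0.0

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("scale k must be positive")

    @property
    def matrix(self) -> np.ndarray:
        a = np.deg2rad(self.alpha_deg)
        c, s = np.cos(a), np.sin(a)
        return np.array(
            [
                [self.k * c, self.k * s, self.tx],
                [-self.k * s, self.k * c, self.ty],
                [0.0, 0.0, 1.0],
            ]
        )

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform2D":
        m = np.asarray(m, dtype=float)
        det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
        if det <= 0:
            raise ValueError("matrix is not an orientation-preserving similarity")
        k = float(np.sqrt(det))
        alpha = float(np.degrees(np.arctan2(m[0, 1], m[0, 0])))
        return cls(k=k, alpha_deg=alpha, tx=float(m[0, 2]), ty=float(m[1, 2]))

    def inverse(self) -> "RigidTransform2D":
        return RigidTransform2D.from_matrix(np.linalg.inv(self.matrix))

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Transform applying ``other`` first, then ``self``."""
        return RigidTransform2D.from_matrix(self.matrix @ other.matrix)


def apply_transform(t: RigidTransform2D, points: np.ndarray) -> np.ndarray:
    """Apply the homogeneous similarity to (N, 2) pixel points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    homo = np.column_stack([pts, np.ones(len(pts))])
    out = homo @ t.matrix.T
    return out[:, :2]


@dataclass
class LogPolarSpectrum:
    """Spectral magnitude resampled on (theta, gamma=log rho) axes."""

    values: np.ndarray  # (n_theta, n_gamma)
    theta_range: float  # degrees covered by the theta axis (usually 180)
    rho_min: float  # px radius in the centred magnitude grid
    rho_max: float

    def __post_init__(self) -> None:
        if self.values.size == 0:
            raise ValueError("empty log-polar grid")
        if not 0 < self.rho_min < self.rho_max:
            raise ValueError("need 0 < rho_min < rho_max")

    @property
    def n_theta(self) -> int:
        return self.values.shape[0]

    @property
    def n_gamma(self) -> int:
        return self.values.shape[1]

    @property
    def dtheta(self) -> float:
        return self.theta_range / self.n_theta

    @property
    def dgamma(self) -> float:
        return (np.log(self.rho_max) - np.log(self.rho_min)) / (self.n_gamma - 1)


@dataclass
class CorrelationPeak:
    """Subpixel phase-correlation peak: ``shift`` is (row, col) displacement
    such that the second input equals the first shifted by ``shift``."""

    shift: tuple[float, float]
    height: float
    secondary_ratio: float


@dataclass(frozen=True)
class RegistrationParams:
    n_theta: int = 360
    n_gamma: int = 256
    rho_min_px: float = 4.0
    rho_max_frac: float = 0.9  # fraction of Nyquist radius
    window: bool = True
    highpass: bool = True
    smooth_sigma: float = 1.0  # light blur of binary inputs before the FFT
    min_peak_height: float = 0.03
    refine: bool = True


@dataclass
class RegistrationResult:
    transform: RigidTransform2D
    rotation_peak: CorrelationPeak
    translation_peak: CorrelationPeak
    low_confidence: bool = False
    notes: list = field(default_factory=list)


def _as_array(image) -> np.ndarray:
    if isinstance(image, Image2D):
        return np.asarray(image.pixels, dtype=float)
    return np.asarray(image, dtype=float)


def _raised_cosine(shape: tuple[int, int]) -> np.ndarray:
    wy = np.hanning(shape[0])
    wx = np.hanning(shape[1])
    return np.outer(wy, wx)


def spectral_magnitude(image, window: bool = True, highpass: bool = True) -> np.ndarray:
    """Zero-frequency-centred |FFT| of the (mean-subtracted) image.

    ``window`` applies a raised-cosine taper to suppress edge leakage;
    ``highpass`` applies the standard radial emphasis filter
    ``(1 - X)(2 - X)`` with ``X = cos(pi fx) cos(pi fy)`` to the magnitude,
    damping the low frequencies that would otherwise dominate the log-polar
    correlation.
    """
    img = _as_array(image)
    if img.size == 0:
        raise ValueError("empty image")
    img = img - img.mean()
    if window:
        img = img * _raised_cosine(img.shape)
    mag = np.abs(np.fft.fftshift(np.fft.fft2(img)))
    if highpass:
        fy = np.fft.fftshift(np.fft.fftfreq(img.shape[0]))
        fx = np.fft.fftshift(np.fft.fftfreq(img.shape[1]))
        x = np.cos(np.pi * fx)[None, :] * np.cos(np.pi * fy)[:, None]
        mag = mag * (1.0 - x) * (2.0 - x)
    return mag


def to_log_polar(
    mag: np.ndarray,
    n_theta: int = 360,
    n_gamma: int = 256,
    rho_bounds: tuple[float, float] | None = None,
) -> LogPolarSpectrum:
    """Bilinear resampling of a centred magnitude grid onto (theta, gamma).

    A rotation of the source image by ``a`` degrees shifts the map by
    ``a / dtheta`` bins along theta (circularly, 180-degree period), and a
    scaling by ``k`` shifts it by ``-log(k) / dgamma`` bins along gamma.
    """
    mag = np.asarray(mag, dtype=float)
    nyquist = min(mag.shape) / 2.0
    if rho_bounds is None:
        rho_bounds = (4.0, 0.9 * nyquist)
    rho_min, rho_max = float(rho_bounds[0]), float(rho_bounds[1])
    if not 0 < rho_min < rho_max or rho_max > nyquist:
        raise ValueError("degenerate rho bounds (need 0 < rho_min < rho_max <= Nyquist)")

    thetas = np.deg2rad(np.linspace(0.0, 180.0, n_theta, endpoint=False))
    gammas = np.linspace(np.log(rho_min), np.log(rho_max), n_gamma)
    rhos = np.exp(gammas)
    cy = (mag.shape[0] - 1) / 2.0
    cx = (mag.shape[1] - 1) / 2.0
    rows = cy + rhos[None, :] * np.sin(thetas)[:, None]
    cols = cx + rhos[None, :] * np.cos(thetas)[:, None]
    values = ndimage.map_coordinates(
        mag, np.stack([rows, cols]), order=1, mode="constant", cval=0.0
    )
    return LogPolarSpectrum(values, theta_range=180.0, rho_min=rho_min, rho_max=rho_max)


def _parabolic_offset(m1: float, c: float, p1: float) -> float:
    denom = m1 - 2.0 * c + p1
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (m1 - p1) / denom, -0.5, 0.5))


def _correlation_surface(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("inputs must have equal shapes")
    if not a.any() or not b.any():
        raise ValueError("phase correlation of an all-zero input")
    cross = np.fft.fft2(b) * np.conj(np.fft.fft2(a))
    denom = np.abs(cross)
    denom[denom == 0] = 1.0
    return np.real(np.fft.ifft2(cross / denom))


def _peak_at(surface: np.ndarray, r: int, c: int) -> CorrelationPeak:
    """Subpixel peak description at integer location (r, c)."""
    nr, nc = surface.shape
    height = float(surface[r, c])
    dr = _parabolic_offset(
        surface[(r - 1) % nr, c], surface[r, c], surface[(r + 1) % nr, c]
    )
    dc = _parabolic_offset(
        surface[r, (c - 1) % nc], surface[r, c], surface[r, (c + 1) % nc]
    )
    shift_r = r + dr
    shift_c = c + dc
    if shift_r > nr / 2:
        shift_r -= nr
    if shift_c > nc / 2:
        shift_c -= nc
    # secondary peak outside a 3x3 exclusion zone around the main peak
    masked = surface.copy()
    rr = (np.arange(nr)[:, None] - r + nr // 2) % nr - nr // 2
    cc = (np.arange(nc)[None, :] - c + nc // 2) % nc - nc // 2
    masked[(np.abs(rr) <= 1) & (np.abs(cc) <= 1)] = -np.inf
    second = float(masked.max())
    ratio = height / second if second > 0 else np.inf
    return CorrelationPeak(
        shift=(float(shift_r), float(shift_c)),
        height=float(np.clip(height, 0.0, 1.0)),
        secondary_ratio=ratio,
    )


def _top_peaks(surface: np.ndarray, n: int = 3, exclusion: int = 5):
    """The ``n`` highest locally separated maxima of a correlation surface."""
    nr, nc = surface.shape
    work = surface.copy()
    peaks = []
    for _ in range(n):
        r, c = np.unravel_index(np.argmax(work), work.shape)
        if not np.isfinite(work[r, c]):
            break
        peaks.append((int(r), int(c)))
        rr = (np.arange(nr)[:, None] - r + nr // 2) % nr - nr // 2
        cc = (np.arange(nc)[None, :] - c + nc // 2) % nc - nc // 2
        work[(np.abs(rr) <= exclusion) & (np.abs(cc) <= exclusion)] = -np.inf
    return peaks


def phase_correlation(a: np.ndarray, b: np.ndarray) -> CorrelationPeak:
    """Phase-correlation displacement of ``b`` relative to ``a``.

    Returns the subpixel (row, col) shift ``d`` maximizing the correlation
    surface, with ``b(x) ~= a(x - d)`` under circular boundary conditions.
    Wrapped shifts are unwrapped to the signed interval (-n/2, n/2]; the
    peak is refined by a parabolic fit over its 3x3 neighbourhood.
    """
    surface = _correlation_surface(a, b)
    r, c = np.unravel_index(np.argmax(surface), surface.shape)
    return _peak_at(surface, int(r), int(c))


def _pad_to_square_pow2(img: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, n), dtype=float)
    r0 = (n - img.shape[0]) // 2
    c0 = (n - img.shape[1]) // 2
    out[r0 : r0 + img.shape[0], c0 : c0 + img.shape[1]] = img
    return out


def _center_similarity_matrix(k: float, alpha_deg: float, center: tuple[float, float]) -> np.ndarray:
    """Similarity about an image centre, in (x, y) pixel convention."""
    a = np.deg2rad(alpha_deg)
    c, s = np.cos(a), np.sin(a)
    cx, cy = center
    sr = np.array([[k * c, k * s, 0.0], [-k * s, k * c, 0.0], [0.0, 0.0, 1.0]])
    t_to = np.array([[1.0, 0.0, cx], [0.0, 1.0, cy], [0.0, 0.0, 1.0]])
    t_from = np.array([[1.0, 0.0, -cx], [0.0, 1.0, -cy], [0.0, 0.0, 1.0]])
    return t_to @ sr @ t_from


def _warp_by(img: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Forward-warp ``img`` by a (x, y)-convention homogeneous matrix."""
    return sktransform.warp(
        img, inverse_map=np.linalg.inv(matrix), order=1, mode="constant", cval=0.0
    )


def _rotation_scale_estimate(lp_fixed, lp_moving, params):
    peak = phase_correlation(lp_fixed.values, lp_moving.values)
    dtheta_bins, dgamma_bins = peak.shift
    alpha = dtheta_bins * lp_fixed.dtheta
    kappa = dgamma_bins * lp_fixed.dgamma
    return alpha, float(np.exp(kappa)), peak


def register(
    fixed: Image2D | np.ndarray,
    moving: Image2D | np.ndarray,
    params: RegistrationParams = RegistrationParams(),
) -> RegistrationResult:
    """Recover the similarity transform aligning ``moving`` onto ``fixed``.

    Both inputs must share a pixel spacing (resample beforehand otherwise);
    binary masks are accepted and lightly smoothed before the transforms.
    Returns a :class:`RegistrationResult` whose transform maps moving pixel
    coordinates into fixed pixel coordinates; a weak correlation peak sets
    ``low_confidence`` rather than raising.
    """
    fixed_arr = _as_array(fixed)
    moving_arr = _as_array(moving)
    if isinstance(fixed, Image2D) and isinstance(moving, Image2D):
        if not np.isclose(fixed.spacing, moving.spacing):
            raise ValueError("images must share pixel spacing; resample first")

    n = 1 << int(np.ceil(np.log2(max(*fixed_arr.shape, *moving_arr.shape))))
    fixed_p = _pad_to_square_pow2(fixed_arr, n)
    moving_p = _pad_to_square_pow2(moving_arr, n)
    if params.smooth_sigma > 0:
        fixed_p = ndimage.gaussian_filter(fixed_p, params.smooth_sigma)
        moving_p = ndimage.gaussian_filter(moving_p, params.smooth_sigma)

    rho_bounds = (params.rho_min_px, params.rho_max_frac * n / 2.0)

    def logpolar(img):
        mag = spectral_magnitude(img, window=params.window, highpass=params.highpass)
        return to_log_polar(mag, params.n_theta, params.n_gamma, rho_bounds)

    center = ((n - 1) / 2.0, (n - 1) / 2.0)
    lp_fixed = logpolar(fixed_p)
    alpha, k, rot_peak = _rotation_scale_estimate(lp_fixed, logpolar(moving_p), params)

    w = _raised_cosine(fixed_p.shape) if params.window else 1.0

    def _ncc(a, b):
        a = a - a.mean()
        b = b - b.mean()
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        return float((a * b).sum() / denom) if denom > 0 else -1.0

    # resolve the 180-degree ambiguity and guard against translation aliases
    # (a quasi-periodic spine column yields strong correlation peaks one
    # vertebral level apart): try both candidate rotations and the top few
    # translation peaks of each, and keep whichever actually overlays best
    best = None
    for cand in (alpha, alpha + 180.0):
        cand = (cand + 180.0) % 360.0 - 180.0
        sr = _center_similarity_matrix(k, cand, center)
        warped = _warp_by(moving_p, sr)
        if not warped.any():
            continue
        surface = _correlation_surface(warped * w, fixed_p * w)
        for r, c in _top_peaks(surface, n=3):
            peak = _peak_at(surface, r, c)
            dy, dx = peak.shift
            t_try = np.array([[1.0, 0.0, dx], [0.0, 1.0, dy], [0.0, 0.0, 1.0]]) @ sr
            aligned = _warp_by(moving_p, t_try)
            score = _ncc(aligned, fixed_p)
            if best is None or score > best[3]:
                best = (cand, t_try, peak, score)
    if best is None:
        raise ValueError("moving image left the frame under all candidate warps")

    alpha, full_pad, trans_peak, _ = best

    if params.refine:
        # joint refinement: with the bulk motion removed, the window weighs
        # both images symmetrically, so both the log-polar rotation/scale
        # residual and the translation peak become unbiased and subpixel.
        # Each update must improve the actual overlay (NCC); a worsening
        # update is rejected and refinement stops, which keeps the loop from
        # drifting onto a periodicity alias of the vertebral column.
        best_score = _ncc(_warp_by(moving_p, full_pad), fixed_p)
        for _ in range(4):
            warped = _warp_by(moving_p, full_pad)
            if not warped.any():
                break
            d_alpha, d_k, _ = _rotation_scale_estimate(
                lp_fixed, logpolar(warped), params
            )
            if abs(d_alpha) > 15.0 or not 0.7 < d_k < 1.4:
                d_alpha, d_k = 0.0, 1.0
            corr = _center_similarity_matrix(d_k, d_alpha, center)
            warped2 = _warp_by(moving_p, corr @ full_pad)
            if not warped2.any():
                break
            peak = phase_correlation(warped2 * w, fixed_p * w)
            ddy, ddx = peak.shift
            candidate = (
                np.array([[1.0, 0.0, ddx], [0.0, 1.0, ddy], [0.0, 0.0, 1.0]])
                @ corr
                @ full_pad
            )
            score = _ncc(_warp_by(moving_p, candidate), fixed_p)
            if score < best_score:
                break
            best_score = score
            full_pad = candidate
            trans_peak = peak
            if (
                abs(d_alpha) < 0.02
                and abs(d_k - 1.0) < 2e-4
                and abs(ddx) < 0.05
                and abs(ddy) < 0.05
            ):
                break

    # composed matrix maps padded coords; remove the padding offsets so the
    # transform acts on original image pixel coordinates
    r0f = (n - fixed_arr.shape[0]) // 2
    c0f = (n - fixed_arr.shape[1]) // 2
    r0m = (n - moving_arr.shape[0]) // 2
    c0m = (n - moving_arr.shape[1]) // 2
    pad_m = np.array([[1.0, 0.0, c0m], [0.0, 1.0, r0m], [0.0, 0.0, 1.0]])
    unpad_f = np.array([[1.0, 0.0, -c0f], [0.0, 1.0, -r0f], [0.0, 0.0, 1.0]])
    full = unpad_f @ full_pad @ pad_m

    transform = RigidTransform2D.from_matrix(full)
    low = trans_peak.height < params.min_peak_height
    notes = ["translation peak below confidence floor"] if low else []
    return RegistrationResult(
        transform=transform,
        rotation_peak=rot_peak,
        translation_peak=trans_peak,
        low_confidence=low,
        notes=notes,
    )
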