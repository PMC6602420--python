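"""Synthetic labeled anatomy, catheter curves, and fluoroscopy-like renders.

This module stands in for a 3D-printed heart/spine phantom imaged under an
interventional X-ray system.  It provides:

* a stack of rounded-box vertebral bodies along the patient Y axis (five by
  default, named T4-T8, the fiducial levels adjacent to the atria) with
  exact centroids stored as ground truth, connected by a narrower posterior
  column so the projected spine binarizes as one connected object, plus a
  faint ellipsoidal heart shell;
* smooth spline catheter curves through user waypoints (default diameter
  4 mm, the size of a 12-Fr catheter);
* orthographic attenuation renders ``I = I0 * exp(-sum(mu_i * L_i))`` with
  bright background / dark bone-and-catheter polarity, an optional intensity
  gradient, additive Gaussian noise and an optional signal-dependent
  (Poisson-like) term.  All randomness is seeded: equal inputs give
  bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .core import CArmPose, Curve3D, Image2D
from .projection import project_points

__all__ = [
    "RoundedBox",
    "Ellipsoid",
    "TargetRing",
    "AnatomyModel",
    "PhantomNoiseSpec",
    "RenderParams",
    "FieldOfViewWarning",
    "make_spine_phantom",
    "make_catheter_curve",
    "default_catheter_curve",
    "render_fluoroscopy",
]


class FieldOfViewWarning(UserWarning):
    """Geometry extends beyond the detector; the render is partial."""


@dataclass
class RoundedBox:
    """Axis-aligned box intersected with an elliptic cylinder along Y.

    ``corner_frac`` scales the cylinder semi-axes relative to the box half
    extents; values slightly above 1 round the axial corners while keeping
    the flat superior/inferior endplates.
    """

    name: str
    center: np.ndarray
    size: np.ndarray
    corner_frac: float = 1.2

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.size = np.asarray(self.size, dtype=float)
        if np.any(self.size <= 0):
            raise ValueError("solid dimensions must be positive")


@dataclass
class Ellipsoid:
    name: str
    center: np.ndarray
    semiaxes: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.semiaxes = np.asarray(self.semiaxes, dtype=float)
        if np.any(self.semiaxes <= 0):
            raise ValueError("semiaxes must be positive")


@dataclass
class TargetRing:
    center: np.ndarray
    normal: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0 or self.radius <= 0:
            raise ValueError("ring needs a nonzero normal and positive radius")
        self.normal = n / norm


@dataclass
class AnatomyModel:
    """Labeled 3-D geometry in one shared world frame (mm, Y superior)."""

    vertebrae: list
    heart: Ellipsoid | None = None
    connector: RoundedBox | None = None
    planned_path: np.ndarray | None = None
    target_rings: list = field(default_factory=list)
    frame: str = "world"

    def __post_init__(self) -> None:
        if len(self.vertebrae) < 1:
            raise ValueError("model needs at least one vertebra")

    @property
    def spine_labels(self) -> dict:
        """Named spine solids (vertebral bodies plus the posterior column)."""
        labels = {v.name: v for v in self.vertebrae}
        if self.connector is not None:
            labels[self.connector.name] = self.connector
        return labels

    @property
    def vertebra_centroids(self) -> np.ndarray:
        """Exact (n, 3) ground-truth centroids, inferior to superior."""
        return np.array([v.center for v in self.vertebrae])

    @property
    def spine_centroid(self) -> np.ndarray:
        return self.vertebra_centroids.mean(axis=0)


@dataclass(frozen=True)
class PhantomNoiseSpec:
    """Detector noise model: none of it is physical dose simulation, just the
    graininess and shading visible in clinical frames."""

    gaussian_sigma: float = 0.0  # additive, 8-bit intensity units
    background_gradient: tuple[float, float] = (0.0, 0.0)  # intensity/px (gx, gy)
    photon_noise_scale: float = 0.0  # scales sqrt(I)-proportional noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0 or self.photon_noise_scale < 0:
            raise ValueError("noise magnitudes must be >= 0")


@dataclass(frozen=True)
class RenderParams:
    """Attenuation coefficients (1/mm) and background level (8-bit units).

    Coefficients are free parameters: they set the contrast of the metal
    coated spine, the faint heart shell and the catheter and were chosen so
    a vertebral body reads ~0.2x background and the heart ~0.85x.
    """

    mu_bone: float = 0.08
    mu_connector: float = 0.085
    mu_heart: float = 0.0008
    mu_catheter: float = 0.45
    catheter_diameter_mm: float = 4.0
    background: float = 230.0


_THORACIC_NAMES = ["T4", "T5", "T6", "T7", "T8"]


def make_spine_phantom(
    n_vertebrae: int = 5,
    vertebra_size: tuple[float, float, float] = (24.0, 18.0, 20.0),
    gap: float = 4.0,
    seed: int = 0,
    jitter_mm: float = 0.0,
    size_taper: float = 0.05,
    with_heart: bool = True,
    with_connector: bool = True,
) -> AnatomyModel:
    """Build a vertebral stack along +Y with known centroids.

    Parameters
    ----------
    n_vertebrae:
        Number of vertebral bodies (>= 1); with 5 they are named T4..T8.
    vertebra_size:
        Full extents (x, y, z) of each body in mm.
    gap:
        Intervertebral spacing in mm, so consecutive centroids are
        ``height + gap`` apart along Y when ``jitter_mm == 0``.
    jitter_mm:
        Standard deviation of per-vertebra lateral (x, z) offsets and size
        perturbations, drawn deterministically from ``seed``.
    size_taper:
        Fractional increase in transverse (x, z) vertebra dimensions per
        level moving inferiorly, mimicking the craniocaudal growth of
        vertebral bodies.  Heights are untouched so centroid spacing stays
        ``height + gap`` exactly.
    """
    if n_vertebrae < 1:
        raise ValueError("n_vertebrae must be >= 1")
    size = np.asarray(vertebra_size, dtype=float)
    if np.any(size <= 0) or gap <= 0:
        raise ValueError("vertebra_size and gap must be positive")

    rng = np.random.default_rng(seed)
    height = size[1]
    span = n_vertebrae * height + (n_vertebrae - 1) * gap
    y0 = -span / 2.0 + height / 2.0

    vertebrae = []
    for i in range(n_vertebrae):
        if n_vertebrae == 5:
            # clinical naming runs superior->inferior; index 0 is most inferior
            name = _THORACIC_NAMES[n_vertebrae - 1 - i]
        else:
            name = f"V{i + 1}"
        offset = rng.normal(0.0, jitter_mm, size=2) if jitter_mm > 0 else np.zeros(2)
        dsize = (
            size * (1.0 + rng.normal(0.0, jitter_mm / 50.0, size=3))
            if jitter_mm > 0
            else size.copy()
        )
        # index 0 is the most inferior (largest) body
        taper = 1.0 + size_taper * (n_vertebrae - 1 - i)
        dsize = dsize * np.array([taper, 1.0, taper])
        center = np.array([offset[0], y0 + i * (height + gap), offset[1]])
        vertebrae.append(RoundedBox(name, center, dsize))

    connector = None
    if with_connector and n_vertebrae > 1:
        connector = RoundedBox(
            "posterior_column",
            np.array([0.0, 0.0, -(size[2] / 2.0 + 3.0)]),
            np.array([size[0] * 0.45, span, 9.0]),
            corner_frac=1.1,
        )

    heart = None
    if with_heart:
        heart = Ellipsoid("heart", np.array([0.0, -5.0, 40.0]), np.array([48.0, 52.0, 40.0]))

    return AnatomyModel(vertebrae=vertebrae, heart=heart, connector=connector)


def make_catheter_curve(waypoints, samples_per_segment: int = 20) -> Curve3D:
    """Interpolating cubic spline through 3-D waypoints, arc-length stored.

    The curve is ordered from the insertion end (first waypoint, lowest Y for
    an inferior-vena-cava entry) to the tip (last waypoint, hit exactly).
    """
    wps = np.atleast_2d(np.asarray(waypoints, dtype=float))
    if len(wps) < 2:
        raise ValueError("need at least two waypoints")
    if samples_per_segment < 1:
        raise ValueError("samples_per_segment must be >= 1")
    seg = np.linalg.norm(np.diff(wps, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValueError("duplicate consecutive waypoints")
    t = np.concatenate([[0.0], np.cumsum(seg)])
    if len(wps) == 2:
        u = np.linspace(0.0, t[-1], samples_per_segment + 1)
        pts = wps[0] + (u / t[-1])[:, None] * (wps[1] - wps[0])
    else:
        spline = CubicSpline(t, wps, axis=0, bc_type="natural")
        u = np.concatenate(
            [
                np.linspace(t[i], t[i + 1], samples_per_segment, endpoint=False)
                for i in range(len(t) - 1)
            ]
            + [t[-1:]]
        )
        pts = spline(u)
    pts[-1] = wps[-1]  # tip is exact by construction; guard against fp drift
    return Curve3D(pts)


def default_catheter_curve(samples_per_segment: int = 40) -> Curve3D:
    """The study-condition catheter: enters below the field of view to the
    patient's right of the spine column and curves gently anteriorly toward
    a tip beside the mid-thoracic vertebrae."""
    waypoints = [
        (-34.0, -79.9, 0.0),
        (-31.0, -40.0, 2.0),
        (-32.0, -5.0, 4.0),
        (-28.0, 25.0, 6.0),
    ]
    return make_catheter_curve(waypoints, samples_per_segment=samples_per_segment)


def render_fluoroscopy(
    model: AnatomyModel,
    catheter: Curve3D | None,
    pose: CArmPose,
    spacing: float = 0.25,
    size: tuple[int, int] = (640, 640),
    noise: PhantomNoiseSpec = PhantomNoiseSpec(),
    params: RenderParams = RenderParams(),
) -> Image2D:
    """Orthographic attenuation render of the phantom at a C-arm pose.

    Spine solids and catheter are dark on a bright background; the heart
    shell is nearly transparent.  Deterministic for fixed inputs and seed.
    """
    from . import _raycast

    if spacing <= 0 or min(size) <= 0:
        raise ValueError("spacing and size must be positive")

    nrows, ncols = int(size[0]), int(size[1])
    origins, direction = _raycast.pixel_rays(pose, spacing, (nrows, ncols))
    optical = np.zeros(origins.shape[0])

    if model is not None:
        for v in model.vertebrae:
            optical += params.mu_bone * _raycast.solid_path_length(v, origins, direction)
        if model.connector is not None:
            optical += params.mu_connector * _raycast.solid_path_length(
                model.connector, origins, direction
            )
        if model.heart is not None:
            optical += params.mu_heart * _raycast.solid_path_length(
                model.heart, origins, direction
            )

    if catheter is not None and len(catheter) >= 2:
        proj = project_points(catheter.points, pose, spacing, (nrows, ncols))
        inside_x = (proj[:, 0] >= -0.5) & (proj[:, 0] <= ncols - 0.5)
        inside_y = (proj[:, 1] >= -0.5) & (proj[:, 1] <= nrows - 0.5)
        if not np.all(inside_x & inside_y):
            warnings.warn(
                "catheter extends outside the field of view; rendering the "
                "visible portion",
                FieldOfViewWarning,
                stacklevel=2,
            )
        optical += params.mu_catheter * _raycast.tube_path_length(
            proj, spacing, (nrows, ncols), params.catheter_diameter_mm / 2.0
        ).ravel()

    img = params.background * np.exp(-optical)
    img = img.reshape(nrows, ncols)

    gx, gy = noise.background_gradient
    if gx != 0.0 or gy != 0.0:
        cols, rows = np.meshgrid(np.arange(ncols), np.arange(nrows))
        img = img + gx * (cols - (ncols - 1) / 2.0) + gy * (rows - (nrows - 1) / 2.0)

    if noise.gaussian_sigma > 0 or noise.photon_noise_scale > 0:
        rng = np.random.default_rng(noise.seed)
        if noise.gaussian_sigma > 0:
            img = img + rng.normal(0.0, noise.gaussian_sigma, size=img.shape)
        if noise.photon_noise_scale > 0:
            img = img + noise.photon_noise_scale * np.sqrt(
                np.clip(img, 0.0, None)
            ) * rng.standard_normal(img.shape)

    return Image2D(np.clip(img, 0.0, 255.0), spacing=spacing)
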