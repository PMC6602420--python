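"""Parallel-beam ray casting against analytic convex solids.

Every detector pixel carries one ray: origin at the pixel's detector-plane
position, direction along the view depth axis.  Solids are convex, so a ray
intersects each in a single parameter interval; the X-ray path length is the
interval length.  Intervals are computed over the full line (t in R), which
is exact for orthographic geometry and keeps everything vectorised.

Solid objects are duck-typed:

* rounded box: attributes ``center`` (3,), ``size`` (3, full extents) and
  ``corner_frac`` — an axis-aligned box intersected with an elliptic cylinder
  along Y whose semi-axes are ``corner_frac * size/2`` in x/z, which rounds
  the axial cross-section corners;
* ellipsoid: attributes ``center`` (3,) and ``semiaxes`` (3,).
"""

from __future__ import annotations

import numpy as np

from .core import CArmPose
from .projection import rotation_about_y  # noqa: F401  (re-export convenience)

_EPS = 1e-12


def pixel_rays(pose: CArmPose, spacing: float, size: tuple[int, int]):
    """World-frame ray origins (H*W, 3) and shared unit direction (3,)."""
    nrows, ncols = int(size[0]), int(size[1])
    cx, cy = (ncols - 1) / 2.0, (nrows - 1) / 2.0
    cols, rows = np.meshgrid(np.arange(ncols), np.arange(nrows))
    x_mm = (cols.ravel() - cx) * spacing
    y_mm = (cy - rows.ravel()) * spacing
    view_pts = np.column_stack([x_mm, y_mm, np.zeros_like(x_mm)])
    r_inv = rotation_about_y(-pose.signed_angle_deg)
    origins = view_pts @ r_inv.T
    direction = r_inv @ np.array([0.0, 0.0, 1.0])
    return origins, direction


def _intersect(lo1, hi1, lo2, hi2):
    return np.maximum(lo1, lo2), np.minimum(hi1, hi2)


def _slab_interval(o, d, lo, hi):
    """Interval of t with lo <= o + t*d <= hi for one coordinate."""
    n = o.shape[0]
    tmin = np.full(n, -np.inf)
    tmax = np.full(n, np.inf)
    if abs(d) < _EPS:
        outside = (o < lo) | (o > hi)
        tmin[outside] = np.inf
        tmax[outside] = -np.inf
    else:
        t1 = (lo - o) / d
        t2 = (hi - o) / d
        tmin = np.minimum(t1, t2)
        tmax = np.maximum(t1, t2)
    return tmin, tmax


def _box_interval(origins, d, center, size):
    half = np.asarray(size, dtype=float) / 2.0
    c = np.asarray(center, dtype=float)
    tmin = np.full(origins.shape[0], -np.inf)
    tmax = np.full(origins.shape[0], np.inf)
    for axis in range(3):
        lo, hi = _slab_interval(
            origins[:, axis], d[axis], c[axis] - half[axis], c[axis] + half[axis]
        )
        tmin, tmax = _intersect(tmin, tmax, lo, hi)
    return tmin, tmax


def _quadratic_interval(a_coef, b_coef, c_coef):
    """Solve a t^2 + b t + c <= 0 for the inside interval (vectorised)."""
    n = b_coef.shape[0]
    tmin = np.full(n, np.inf)
    tmax = np.full(n, -np.inf)
    if a_coef < _EPS:
        inside = c_coef <= 0
        tmin[inside] = -np.inf
        tmax[inside] = np.inf
        return tmin, tmax
    disc = b_coef**2 - 4.0 * a_coef * c_coef
    hit = disc > 0
    sq = np.sqrt(np.maximum(disc, 0.0))
    tmin[hit] = (-b_coef[hit] - sq[hit]) / (2.0 * a_coef)
    tmax[hit] = (-b_coef[hit] + sq[hit]) / (2.0 * a_coef)
    return tmin, tmax


def _elliptic_cylinder_interval(origins, d, center, semi_x, semi_z):
    """Elliptic cylinder with axis parallel to world Y."""
    ux = (origins[:, 0] - center[0]) / semi_x
    uz = (origins[:, 2] - center[2]) / semi_z
    dx = d[0] / semi_x
    dz = d[2] / semi_z
    a = dx * dx + dz * dz
    b = 2.0 * (ux * dx + uz * dz)
    c = ux * ux + uz * uz - 1.0
    return _quadratic_interval(a, b, c)


def _ellipsoid_interval(origins, d, center, semiaxes):
    u = (origins - np.asarray(center, dtype=float)) / np.asarray(semiaxes, dtype=float)
    dv = np.asarray(d, dtype=float) / np.asarray(semiaxes, dtype=float)
    a = float(dv @ dv)
    b = 2.0 * (u @ dv)
    c = np.einsum("ij,ij->i", u, u) - 1.0
    return _quadratic_interval(a, b, c)


def solid_interval(solid, origins, d):
    if hasattr(solid, "semiaxes"):
        return _ellipsoid_interval(origins, d, solid.center, solid.semiaxes)
    if hasattr(solid, "size"):
        tmin, tmax = _box_interval(origins, d, solid.center, solid.size)
        frac = getattr(solid, "corner_frac", None)
        if frac is not None and np.isfinite(frac):
            half = np.asarray(solid.size, dtype=float) / 2.0
            clo, chi = _elliptic_cylinder_interval(
                origins, d, np.asarray(solid.center, dtype=float),
                half[0] * frac, half[2] * frac,
            )
            tmin, tmax = np.maximum(tmin, clo), np.minimum(tmax, chi)
        return tmin, tmax
    raise TypeError(f"unsupported solid type {type(solid)!r}")


def solid_path_length(solid, origins, d):
    """Chord length (mm) of each ray through the solid, as an (H, W)-able array."""
    tmin, tmax = solid_interval(solid, origins, d)
    length = np.clip(tmax - tmin, 0.0, None)
    length[~np.isfinite(length)] = 0.0
    return length


def tube_path_length(curve_points_px, spacing, size, radius_mm, step_px=0.2):
    """Path length through a tube around a 3-D curve, per detector pixel.

    For parallel rays the 3-D distance from a ray to the curve equals the
    2-D distance between the projected curve and the pixel in the detector
    plane, so the chord through a locally straight tube of radius r is
    ``2*sqrt(r^2 - d^2)``.  The projected centerline is densely resampled and
    queried with a KD-tree.
    """
    from scipy.spatial import cKDTree

    pts = np.atleast_2d(np.asarray(curve_points_px, dtype=float))
    if len(pts) < 2:
        raise ValueError("need at least two projected curve points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n_dense = max(int(s[-1] / step_px), 2)
    sd = np.linspace(0.0, s[-1], n_dense)
    dense = np.column_stack([np.interp(sd, s, pts[:, i]) for i in range(2)])
    tree = cKDTree(dense)

    nrows, ncols = int(size[0]), int(size[1])
    cols, rows = np.meshgrid(np.arange(ncols), np.arange(nrows))
    grid = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
    r_px = radius_mm / spacing
    d_px, idx = tree.query(grid, distance_upper_bound=r_px + 1.0)
    d_mm = d_px * spacing
    inside = d_mm < radius_mm

    # blunt (flat-cut) ends: drop shadow beyond the tip / before the entry so
    # the dark band terminates exactly at the curve endpoints
    for end, sign in ((0, -1.0), (n_dense - 1, 1.0)):
        at_end = inside & (idx == end)
        if not at_end.any():
            continue
        tangent = dense[min(end + 1, n_dense - 1)] - dense[max(end - 1, 0)]
        tangent = tangent / np.linalg.norm(tangent)
        axial = (grid[at_end] - dense[end]) @ (sign * tangent)
        cut = np.flatnonzero(at_end)[axial > 0]
        inside[cut] = False

    length = np.zeros(grid.shape[0])
    length[inside] = 2.0 * np.sqrt(radius_mm**2 - d_mm[inside] ** 2)
    return length.reshape(nrows, ncols)
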