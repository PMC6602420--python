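"""Biplane 3-D reconstruction of the catheter from Y-axis-rotated views.

Two views whose frames are related by a rotation ``theta`` about the patient
Y axis share the detector row coordinate of every point, so depth follows in
closed form from the two detector x positions:

    z2 = (x1 - x2 cos(theta)) / sin(theta)
    z1 = -x2 sin(theta) + z2 cos(theta)

(all in detector-plane mm, ``theta`` the signed angle from view 2 to
view 1).  With three views, every admissible pair (AP+LAO, AP+RAO, LAO+RAO)
produces an independent estimate; precision is summarized by the mean
absolute deviation of the per-pair positions from their mean,

    MSE = (1/n) * sum_i |P_i - Pbar|,

a precision (not accuracy) measure, reported per sampled point in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CArmPose, Curve3D, ReconstructionError
from .projection import rotation_about_y
from .tracking import Centerline2D

__all__ = [
    "PrecisionReport",
    "triangulate_point",
    "correspond_centerlines",
    "reconstruct",
]

_DEFAULT_MIN_ANGLE_DEG = 5.0
_DEFAULT_ROW_TOL_MM = 0.5  # 2 px at 0.25 mm/px


@dataclass
class PrecisionReport:
    """Per-point and aggregate precision of a multi-view reconstruction."""

    per_point_mse: np.ndarray  # mm, one entry per consensus point
    mean_mse: float
    std_mse: float
    n_points: int
    n_pairs: int
    pairs: list
    single_pair: bool = False  # MSE is identically 0 when only one pair exists

    def __post_init__(self) -> None:
        self.per_point_mse = np.asarray(self.per_point_mse, dtype=float)
        if np.any(self.per_point_mse < -1e-12):
            raise ValueError("MSE must be non-negative")


def triangulate_point(
    p1_mm,
    p2_mm,
    theta_deg: float,
    min_angle_deg: float = _DEFAULT_MIN_ANGLE_DEG,
    row_tol_mm: float = _DEFAULT_ROW_TOL_MM,
) -> np.ndarray:
    """Recover a 3-D point (view-2 frame, mm) from two detector positions.

    ``p1_mm``/``p2_mm`` are (x, y) detector-plane mm positions of the same
    physical point in views related by ``rotation_about_y(theta_deg)``
    (view-1 coordinates = rotation @ view-2 coordinates).  The y coordinate
    is shared between views up to ``row_tol_mm``; the returned y is their
    mean.
    """
    x1, y1 = float(p1_mm[0]), float(p1_mm[1])
    x2, y2 = float(p2_mm[0]), float(p2_mm[1])
    if abs(theta_deg) < min_angle_deg:
        raise ReconstructionError(
            f"view separation {theta_deg:g} deg below minimum {min_angle_deg:g} deg"
        )
    if abs(y1 - y2) > row_tol_mm:
        raise ReconstructionError(
            f"row mismatch {abs(y1 - y2):.3f} mm exceeds tolerance {row_tol_mm:g} mm"
        )
    t = np.deg2rad(theta_deg)
    z2 = (x1 - x2 * np.cos(t)) / np.sin(t)
    return np.array([x2, (y1 + y2) / 2.0, z2])


def _centerline_mm(cl: Centerline2D) -> np.ndarray:
    if cl.image_shape is None:
        raise ReconstructionError("centerline lacks image_shape; cannot convert to mm")
    nrows, ncols = cl.image_shape
    cx, cy = (ncols - 1) / 2.0, (nrows - 1) / 2.0
    out = np.empty_like(cl.points)
    out[:, 0] = (cl.points[:, 0] - cx) * cl.spacing
    out[:, 1] = (cy - cl.points[:, 1]) * cl.spacing
    return out


def correspond_centerlines(
    c1: Centerline2D | np.ndarray,
    c2: Centerline2D | np.ndarray,
    row_step_mm: float = 0.25,
):
    """Match centerline points across two Y-rotated views by detector row.

    Returns ``(y_grid, x1, x2)``: a common, ascending grid of detector-plane
    y (mm) over the overlapping row range, and each centerline's x (mm)
    interpolated on it.  Raises on non-overlapping row ranges.
    """
    a = _centerline_mm(c1) if isinstance(c1, Centerline2D) else np.asarray(c1, float)
    b = _centerline_mm(c2) if isinstance(c2, Centerline2D) else np.asarray(c2, float)
    if len(a) == 0 or len(b) == 0:
        raise ReconstructionError("empty centerline")
    lo = max(a[:, 1].min(), b[:, 1].min())
    hi = min(a[:, 1].max(), b[:, 1].max())
    if hi <= lo:
        raise ReconstructionError("centerline row ranges do not overlap")
    n = max(int(np.floor((hi - lo) / row_step_mm)) + 1, 2)
    y = np.linspace(lo, hi, n)

    def interp(pts):
        order = np.argsort(pts[:, 1])
        return np.interp(y, pts[order, 1], pts[order, 0])

    return y, interp(a), interp(b)


def reconstruct(
    view_data: list[tuple[Centerline2D, CArmPose]],
    spacing: float | None = None,
    transforms: list | None = None,
    min_angle_deg: float = _DEFAULT_MIN_ANGLE_DEG,
    row_step_mm: float = 0.25,
) -> tuple[Curve3D, PrecisionReport]:
    """Triangulate a catheter curve from >= 2 views and report precision.

    Parameters
    ----------
    view_data:
        ``(centerline, pose)`` tuples; poses must differ pairwise by at
        least ``min_angle_deg`` about Y for a pair to be used.
    transforms:
        Optional per-view :class:`~fluoroguide.registration.RigidTransform2D`
        objects mapping each view's fluoroscopic pixels into its CT reference
        projection; applied to the centerline pixels before triangulation so
        the output lives in the CT model's world frame.
    spacing:
        Override mm/px; defaults to each centerline's own spacing.

    Returns
    -------
    The consensus world-frame curve (mean over view pairs, ordered insertion
    to tip) and the :class:`PrecisionReport` with the per-point mean absolute
    deviation of pair estimates.
    """
    if len(view_data) < 2:
        raise ReconstructionError("need at least two views")
    from .registration import apply_transform  # local import avoids a cycle

    prepared = []
    for i, (cl, pose) in enumerate(view_data):
        if not isinstance(cl, Centerline2D):
            raise TypeError("view_data entries must be (Centerline2D, CArmPose)")
        if transforms is not None and transforms[i] is not None:
            pts = apply_transform(transforms[i], cl.points)
            cl = Centerline2D(
                points=pts,
                directions=cl.directions,
                widths=cl.widths,
                stop_reason=cl.stop_reason,
                spacing=spacing or cl.spacing,
                image_shape=cl.image_shape,
            )
        elif spacing is not None and spacing != cl.spacing:
            cl = Centerline2D(
                points=cl.points,
                directions=cl.directions,
                widths=cl.widths,
                stop_reason=cl.stop_reason,
                spacing=spacing,
                image_shape=cl.image_shape,
            )
        prepared.append((cl, pose))

    pairs = []
    for i in range(len(prepared)):
        for j in range(i + 1, len(prepared)):
            dtheta = (
                prepared[i][1].signed_angle_deg - prepared[j][1].signed_angle_deg
            )
            if abs(dtheta) >= min_angle_deg:
                pairs.append((i, j))
    if not pairs:
        raise ReconstructionError("no view pair exceeds the minimum separation angle")

    # common row grid across *all* views so every pair estimates the same
    # physical samples (required for the deviation-from-mean precision)
    mms = [_centerline_mm(cl) for cl, _ in prepared]
    lo = max(mm[:, 1].min() for mm in mms)
    hi = min(mm[:, 1].max() for mm in mms)
    if hi <= lo:
        raise ReconstructionError("view row ranges do not overlap")
    n = max(int(np.floor((hi - lo) / row_step_mm)) + 1, 2)
    y_grid = np.linspace(lo, hi, n)

    xs = []
    for mm in mms:
        order = np.argsort(mm[:, 1])
        xs.append(np.interp(y_grid, mm[order, 1], mm[order, 0]))

    estimates = np.empty((len(pairs), n, 3))
    for p_idx, (i, j) in enumerate(pairs):
        theta = prepared[i][1].signed_angle_deg - prepared[j][1].signed_angle_deg
        t = np.deg2rad(theta)
        z2 = (xs[i] - xs[j] * np.cos(t)) / np.sin(t)
        pts_view2 = np.column_stack([xs[j], y_grid, z2])
        # back to the world frame: p_world = R(-s_j) @ p_view2
        r_inv = rotation_about_y(-prepared[j][1].signed_angle_deg)
        estimates[p_idx] = pts_view2 @ r_inv.T

    consensus = estimates.mean(axis=0)
    if len(pairs) == 1:
        per_point = np.zeros(n)
        single = True
    else:
        per_point = np.linalg.norm(estimates - consensus[None], axis=2).mean(axis=0)
        single = False

    report = PrecisionReport(
        per_point_mse=per_point,
        mean_mse=float(per_point.mean()),
        std_mse=float(per_point.std()),
        n_points=n,
        n_pairs=len(pairs),
        pairs=[(str(prepared[i][1]), str(prepared[j][1])) for i, j in pairs],
        single_pair=single,
    )
    curve = Curve3D(consensus, provenance=report.pairs)
    return curve, report
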