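"""Orthographic C-arm projection geometry and CT-side reference projections.

The two fluoroscopic views used for depth recovery are related by a pure
rotation about the patient's long axis (Y).  With the parallel-beam model
used here, a world point ``p`` seen at pose ``theta`` projects exactly like
the rotated point ``R_y(theta) @ p`` seen in the AP view, which is what makes
the two-view depth equations linear and row-preserving: the detector row of a
point is the same in every view.

The CT-side reference image (the fixed image of the registration step) is a
binary silhouette of the selected spine labels rendered at the requested pose
and pixel spacing.
"""

from __future__ import annotations

import numpy as np

from .core import CArmPose, Image2D

__all__ = [
    "rotation_about_y",
    "view_transform",
    "project_point",
    "project_points",
    "render_reference_projection",
]


def rotation_about_y(theta_deg: float) -> np.ndarray:
    """3x3 rotation about the world Y axis.

    Uses the convention ``[[cos, 0, sin], [0, 1, 0], [-sin, 0, cos]]`` so that
    ``rotation_about_y(a) @ rotation_about_y(b) == rotation_about_y(a + b)``.
    """
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def view_transform(pose: CArmPose) -> np.ndarray:
    """World -> view-frame rotation for a pose.

    ``p_view = view_transform(pose) @ p_world``; the view x/y are the
    detector-plane mm axes and view z is the (dropped) depth.
    """
    return rotation_about_y(pose.signed_angle_deg)


def project_points(
    points: np.ndarray,
    pose: CArmPose,
    spacing: float,
    size: tuple[int, int],
) -> np.ndarray:
    """Project world mm points to detector pixel (x=col, y=row) coordinates.

    Points outside the image bounds are returned as-is (no clipping): the
    caller decides what off-detector geometry means.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    view = pts @ view_transform(pose).T
    nrows, ncols = int(size[0]), int(size[1])
    cx, cy = (ncols - 1) / 2.0, (nrows - 1) / 2.0
    out = np.empty((len(pts), 2))
    out[:, 0] = cx + view[:, 0] / spacing
    out[:, 1] = cy - view[:, 1] / spacing
    return out


def project_point(
    p: np.ndarray,
    pose: CArmPose,
    spacing: float,
    size: tuple[int, int],
) -> np.ndarray:
    """Single-point convenience wrapper around :func:`project_points`."""
    return project_points(np.asarray(p, dtype=float)[None, :], pose, spacing, size)[0]


def render_reference_projection(
    model,
    pose: CArmPose,
    spacing: float = 0.25,
    size: tuple[int, int] = (512, 512),
    spine_only: bool = True,
    labels: list[str] | None = None,
    binarize: bool = True,
) -> Image2D:
    """Render the spine projection of the model at a pose (the fixed image).

    The selected solids are projected as an attenuation image (a simple DRR)
    and, by default, binarized with the same smoothing-and-Otsu pipeline the
    fluoroscopic segmentation uses, so that the reference silhouette and a
    segmented fluoroscopic mask cut the projected bone edges at commensurate
    positions.  (A purely geometric any-path silhouette is systematically
    wider than an intensity-thresholded mask at oblique poses, where rays
    graze the rotated vertebral bodies; likewise an unsmoothed threshold
    cuts ramped edges a few pixels outside a smoothed one.)

    Parameters
    ----------
    model:
        An :class:`~fluoroguide.phantom.AnatomyModel`.
    spine_only:
        If True (default) only the spine labels are rendered; otherwise the
        heart silhouette contributes as well.
    labels:
        Optional subset of ``model.spine_labels`` names to render.
    binarize:
        If True return pixels in {0.0, 1.0} (1 = spine); otherwise return
        the grayscale attenuation projection (bright background, dark bone).

    No anti-aliasing or noise is applied, so renders are bit-reproducible.
    """
    from . import _raycast  # deferred: _raycast depends on this module
    from .phantom import RenderParams

    solids = model.spine_labels
    if labels is not None:
        missing = [name for name in labels if name not in solids]
        if missing:
            raise ValueError(f"unknown labels: {missing}")
        solids = {name: solids[name] for name in labels}
    if not solids and spine_only:
        raise ValueError("no spine labels selected")

    params = RenderParams()
    origins, direction = _raycast.pixel_rays(pose, spacing, size)
    depth = np.zeros(origins.shape[0], dtype=float)
    for name, solid in solids.items():
        mu = params.mu_bone
        if model.connector is not None and name == model.connector.name:
            mu = params.mu_connector
        depth += mu * _raycast.solid_path_length(solid, origins, direction)
    if not spine_only and model.heart is not None:
        depth += params.mu_heart * _raycast.solid_path_length(
            model.heart, origins, direction
        )
    img = (params.background * np.exp(-depth)).reshape(int(size[0]), int(size[1]))
    if not binarize:
        return Image2D(img, spacing=spacing)
    from .core import SegmentationError
    from .segmentation import otsu_threshold, segment_spine

    gray = Image2D(img, spacing=spacing)
    try:
        mask = segment_spine(gray).pixels
    except SegmentationError:
        # tiny/degenerate renders: fall back to a plain Otsu cut
        mask = img < otsu_threshold(img)
    return Image2D(mask.astype(float), spacing=spacing)
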