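"""End-to-end guidance chain on synthetic or provided data.

``run_guidance`` wires the full sequence for a set of C-arm views:

    render (or accept) fluoroscopy  ->  segment the spine  ->
    register each view to its CT reference projection  ->
    trace the catheter centerline  ->  triangulate view pairs  ->
    assemble the registered 3-D scene

Each view is registered independently (the patient may not lie identically
for CT and fluoroscopy); the per-view transform is applied to that view's
centerline before triangulation, so the reconstructed curve lives in the CT
model's world frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CArmPose, Curve3D, Image2D
from .evaluation import registration_error, vertebra_centroids
from .phantom import AnatomyModel, PhantomNoiseSpec, render_fluoroscopy
from .projection import project_points, render_reference_projection
from .reconstruct import PrecisionReport, reconstruct
from .registration import RegistrationResult, register
from .scene import Scene, build_scene
from .segmentation import segment_spine
from .tracking import Centerline2D, trace_centerline

__all__ = ["ViewResult", "GuidanceResult", "run_guidance"]


@dataclass
class ViewResult:
    pose: CArmPose
    fluoro: Image2D
    reference: Image2D
    mask: np.ndarray
    registration: RegistrationResult
    centerline: Centerline2D
    vertebra_error_mm: np.ndarray | None = None


@dataclass
class GuidanceResult:
    views: list[ViewResult]
    curve: Curve3D
    report: PrecisionReport
    scene: Scene
    mean_vertebra_error_mm: float = float("nan")

    @property
    def tip_mm(self) -> np.ndarray:
        return self.curve.tip


def run_guidance(
    model: AnatomyModel,
    catheter: Curve3D,
    poses: list[CArmPose],
    spacing: float = 0.25,
    size: tuple[int, int] = (640, 640),
    noise: PhantomNoiseSpec = PhantomNoiseSpec(),
    misalignment_mm: np.ndarray | None = None,
    fluoro_frames: list[Image2D] | None = None,
    expected_n: int | None = None,
) -> GuidanceResult:
    """Run the full chain and return every intermediate product.

    Parameters
    ----------
    model, catheter:
        Ground-truth anatomy and catheter curve (the phantom).
    poses:
        C-arm poses; at least two, e.g. AP + LAO30 + RAO30.
    misalignment_mm:
        Optional world translation applied to the whole phantom when
        rendering fluoroscopy, emulating a patient shift between the CT and
        the procedure; per-view registration corrects it.
    fluoro_frames:
        Pre-rendered (or externally acquired) frames, one per pose; when
        given, ``noise``/``misalignment_mm`` are ignored for rendering.
    expected_n:
        Vertebra count for centroid-based error reporting (defaults to the
        model's count).
    """
    if len(poses) < 2:
        raise ValueError("need at least two C-arm poses")
    expected_n = expected_n or len(model.vertebrae)

    shifted_model = model
    shifted_catheter = catheter
    if misalignment_mm is not None and fluoro_frames is None:
        offset = np.asarray(misalignment_mm, dtype=float)
        from copy import deepcopy

        shifted_model = deepcopy(model)
        for solid in shifted_model.vertebrae:
            solid.center = solid.center + offset
        if shifted_model.connector is not None:
            shifted_model.connector.center = shifted_model.connector.center + offset
        if shifted_model.heart is not None:
            shifted_model.heart.center = shifted_model.heart.center + offset
        shifted_catheter = Curve3D(catheter.points + offset)

    views: list[ViewResult] = []
    for i, pose in enumerate(poses):
        if fluoro_frames is not None:
            fluoro = fluoro_frames[i]
        else:
            fluoro = render_fluoroscopy(
                shifted_model, shifted_catheter, pose, spacing, size, noise
            )
        reference = render_reference_projection(model, pose, spacing, size)
        mask = segment_spine(fluoro)
        reg = register(reference, Image2D(mask.pixels.astype(float), spacing=spacing))
        centerline = trace_centerline(fluoro)

        vert_err = None
        try:
            fixed_set = vertebra_centroids(reference.pixels > 0.5, expected_n)
            moving_set = vertebra_centroids(mask.pixels, expected_n)
            vert_err = registration_error(
                fixed_set, moving_set, reg.transform, spacing
            )
        except Exception:
            pass
        views.append(
            ViewResult(pose, fluoro, reference, mask.pixels, reg, centerline, vert_err)
        )

    curve, report = reconstruct(
        [(v.centerline, v.pose) for v in views],
        spacing=spacing,
        transforms=[v.registration.transform for v in views],
    )

    meta = [
        {
            "pose": str(v.pose),
            "k": v.registration.transform.k,
            "alpha_deg": v.registration.transform.alpha_deg,
            "tx_px": v.registration.transform.tx,
            "ty_px": v.registration.transform.ty,
            "translation_peak": v.registration.translation_peak.height,
            "low_confidence": v.registration.low_confidence,
        }
        for v in views
    ]
    scene = build_scene(model=model, catheter=curve, registration_meta=meta)

    errs = [v.vertebra_error_mm.mean() for v in views if v.vertebra_error_mm is not None]
    mean_err = float(np.mean(errs)) if errs else float("nan")
    return GuidanceResult(
        views=views, curve=curve, report=report, scene=scene,
        mean_vertebra_error_mm=mean_err,
    )
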