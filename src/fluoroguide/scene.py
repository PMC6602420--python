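"""Registered 3-D scene assembly and viewer-agnostic export.

The end product of the guidance chain is a single world frame containing the
CT-derived anatomy (heart and spine meshes), the reconstructed catheter with
ten key points (rendered downstream as 4 mm spheres), the planned path and
target rings when present, and a virtual camera at the catheter tip looking
along the tip direction.  Everything is written as STL meshes plus a
versioned JSON manifest that any 3-D/AR viewer can consume; the
head-mounted-display presentation layer itself is out of scope.

A 2-D per-view registration cannot correct depth; the manifest records each
view's transform and correlation diagnostics so downstream consumers can see
exactly what was (and was not) corrected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import CArmPose, Curve3D
from .projection import rotation_about_y
from .registration import RigidTransform2D

__all__ = [
    "TipCamera",
    "Scene",
    "SCENE_SCHEMA",
    "catheter_key_points",
    "tip_camera_pose",
    "lift_transform_to_world",
    "apply_placement",
    "build_scene",
    "write_scene",
    "read_scene",
]

SCENE_SCHEMA = "fluoroguide.scene/1"
KEY_POINT_DIAMETER_MM = 4.0
N_KEY_POINTS = 10


@dataclass
class TipCamera:
    """First-person camera at the catheter tip, looking along the tip."""

    position: np.ndarray
    forward: np.ndarray
    up: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.forward = np.asarray(self.forward, dtype=float)
        self.up = np.asarray(self.up, dtype=float)
        if not np.isclose(np.linalg.norm(self.forward), 1.0, atol=1e-9):
            raise ValueError("forward must be a unit vector")


@dataclass
class Scene:
    """All registered geometry in one shared world frame (mm)."""

    meshes: dict = field(default_factory=dict)  # name -> trimesh.Trimesh
    catheter: Curve3D | None = None
    key_points: np.ndarray | None = None  # (<=10, 3) mm
    planned_path: np.ndarray | None = None
    target_rings: list = field(default_factory=list)  # phantom.TargetRing
    tip_camera: TipCamera | None = None
    frame: str = "world"
    registration_meta: list = field(default_factory=list)


def catheter_key_points(curve: Curve3D, n: int = N_KEY_POINTS) -> np.ndarray:
    """``n`` points sampled uniformly in arc length along the curve."""
    if len(curve) >= n:
        return curve.resample(n).points
    return curve.points.copy()


def tip_camera_pose(curve: Curve3D) -> TipCamera:
    """Camera at the distal tip, forward along the last segment.

    ``up`` is the world Y axis projected orthogonal to forward (falling back
    to world Z when the tip points along Y itself).
    """
    if len(curve) < 2:
        raise ValueError("curve must have at least 2 points")
    position = curve.points[-1]
    seg = curve.points[-1] - curve.points[-2]
    norm = np.linalg.norm(seg)
    if norm == 0:
        raise ValueError("degenerate tip segment")
    forward = seg / norm
    up = np.array([0.0, 1.0, 0.0])
    up = up - (up @ forward) * forward
    if np.linalg.norm(up) < 1e-8:
        up = np.array([0.0, 0.0, 1.0])
        up = up - (up @ forward) * forward
    up = up / np.linalg.norm(up)
    return TipCamera(position=position, forward=forward, up=up)


def lift_transform_to_world(
    t: RigidTransform2D,
    pose: CArmPose,
    spacing: float,
    size: tuple[int, int],
) -> np.ndarray:
    """4x4 world-frame placement induced by a per-view 2-D registration.

    The 2-D similarity acts in the view's detector plane (pixel coords);
    this composes pixel->mm conversion, the in-plane similarity, and the
    view rotation into one affine map of world points.  Depth along the view
    axis is untouched — a 2-D registration cannot correct it.
    ``size`` is the (rows, cols) shape of the registered images, needed
    because the transform's translation is expressed about the pixel origin.
    """
    nrows, ncols = int(size[0]), int(size[1])
    cx, cy = (ncols - 1) / 2.0, (nrows - 1) / 2.0
    m = t.matrix

    # view-frame (mm) affine: x' row of the similarity conjugated with the
    # px<->mm maps (mm y is antiparallel to pixel rows)
    a00, a01 = m[0, 0], -m[0, 1]
    a10, a11 = -m[1, 0], m[1, 1]
    ox = spacing * (m[0, 0] * cx + m[0, 1] * cy + m[0, 2] - cx)
    oy = -spacing * (m[1, 0] * cx + m[1, 1] * cy + m[1, 2] - cy)

    a_view = np.eye(4)
    a_view[0, :2] = [a00, a01]
    a_view[1, :2] = [a10, a11]
    a_view[0, 3] = ox
    a_view[1, 3] = oy

    r = np.eye(4)
    r[:3, :3] = rotation_about_y(pose.signed_angle_deg)
    r_inv = np.eye(4)
    r_inv[:3, :3] = rotation_about_y(-pose.signed_angle_deg)
    return r_inv @ a_view @ r


def apply_placement(matrix: np.ndarray, points: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    homo = np.column_stack([pts, np.ones(len(pts))])
    return (homo @ np.asarray(matrix, float).T)[:, :3]


def _model_meshes(model) -> dict:
    """Build trimesh meshes for the anatomy solids (for viewing/export).

    Vertebral bodies are exported as their bounding boxes and the heart as a
    scaled icosphere; the analytic manifest carries the exact solid
    parameters.
    """
    import trimesh

    meshes = {}
    for name, solid in model.spine_labels.items():
        box = trimesh.creation.box(extents=np.asarray(solid.size, float))
        box.apply_translation(np.asarray(solid.center, float))
        meshes[f"spine_{name}"] = box
    if model.heart is not None:
        sphere = trimesh.creation.icosphere(subdivisions=2)
        sphere.apply_scale(np.asarray(model.heart.semiaxes, float))
        sphere.apply_translation(np.asarray(model.heart.center, float))
        meshes["heart"] = sphere
    return meshes


def build_scene(
    model=None,
    catheter: Curve3D | None = None,
    planned_path=None,
    target_rings=None,
    registration_meta: list | None = None,
    frame: str = "world",
) -> Scene:
    """Assemble a Scene from anatomy and a reconstructed catheter curve."""
    meshes = _model_meshes(model) if model is not None else {}
    key_points = None
    tip_cam = None
    if catheter is not None and len(catheter) >= 2:
        key_points = catheter_key_points(catheter)
        tip_cam = tip_camera_pose(catheter)
    rings = list(target_rings) if target_rings else (
        list(model.target_rings) if model is not None else []
    )
    path = planned_path if planned_path is not None else (
        model.planned_path if model is not None else None
    )
    return Scene(
        meshes=meshes,
        catheter=catheter,
        key_points=key_points,
        planned_path=None if path is None else np.asarray(path, float),
        target_rings=rings,
        tip_camera=tip_cam,
        frame=frame,
        registration_meta=registration_meta or [],
    )


def write_scene(scene: Scene, out_dir) -> Path:
    """Write STL meshes + JSON manifest; returns the manifest path.

    The manifest is versioned (``fluoroguide.scene/1``); optional entries
    (planned path, rings, camera) are simply omitted when absent.  Every
    coordinate in the manifest is tagged with the single scene frame.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    mesh_entries = {}
    for name, mesh in scene.meshes.items():
        fname = f"{name}.stl"
        mesh.export(out / fname)
        mesh_entries[name] = fname

    manifest = {
        "schema": SCENE_SCHEMA,
        "frame": scene.frame,
        "units": "mm",
        "meshes": mesh_entries,
        "registration": scene.registration_meta,
        "notes": [
            "per-view 2-D registration corrects in-plane pose only; "
            "depth along each view axis is uncorrected"
        ],
    }
    if scene.catheter is not None:
        manifest["catheter"] = {
            "points_mm": scene.catheter.points.tolist(),
            "frame": scene.frame,
        }
    if scene.key_points is not None:
        manifest["key_points"] = {
            "points_mm": np.asarray(scene.key_points, float).tolist(),
            "diameter_mm": KEY_POINT_DIAMETER_MM,
            "frame": scene.frame,
        }
    if scene.planned_path is not None:
        manifest["planned_path"] = {
            "points_mm": np.asarray(scene.planned_path, float).tolist(),
            "frame": scene.frame,
        }
    if scene.target_rings:
        manifest["target_rings"] = [
            {
                "center_mm": np.asarray(r.center, float).tolist(),
                "normal": np.asarray(r.normal, float).tolist(),
                "radius_mm": float(r.radius),
                "frame": scene.frame,
            }
            for r in scene.target_rings
        ]
    if scene.tip_camera is not None:
        manifest["tip_camera"] = {
            "position_mm": scene.tip_camera.position.tolist(),
            "forward": scene.tip_camera.forward.tolist(),
            "up": scene.tip_camera.up.tolist(),
            "frame": scene.frame,
        }

    path = out / "scene.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_scene(manifest_path) -> Scene:
    """Read a scene written by :func:`write_scene` (lossless round trip)."""
    import trimesh

    path = Path(manifest_path)
    manifest = json.loads(path.read_text())
    if manifest.get("schema") != SCENE_SCHEMA:
        raise ValueError(f"unsupported scene schema {manifest.get('schema')!r}")
    frame = manifest["frame"]

    meshes = {}
    for name, fname in manifest.get("meshes", {}).items():
        meshes[name] = trimesh.load(path.parent / fname)

    catheter = None
    if "catheter" in manifest:
        catheter = Curve3D(np.asarray(manifest["catheter"]["points_mm"], float))
    key_points = None
    if "key_points" in manifest:
        key_points = np.asarray(manifest["key_points"]["points_mm"], float)
    planned = None
    if "planned_path" in manifest:
        planned = np.asarray(manifest["planned_path"]["points_mm"], float)
    rings = []
    if "target_rings" in manifest:
        from .phantom import TargetRing

        rings = [
            TargetRing(
                center=np.asarray(r["center_mm"], float),
                normal=np.asarray(r["normal"], float),
                radius=float(r["radius_mm"]),
            )
            for r in manifest["target_rings"]
        ]
    tip_cam = None
    if "tip_camera" in manifest:
        c = manifest["tip_camera"]
        tip_cam = TipCamera(
            position=np.asarray(c["position_mm"], float),
            forward=np.asarray(c["forward"], float),
            up=np.asarray(c["up"], float),
        )
    return Scene(
        meshes=meshes,
        catheter=catheter,
        key_points=key_points,
        planned_path=planned,
        target_rings=rings,
        tip_camera=tip_cam,
        frame=frame,
        registration_meta=manifest.get("registration", []),
    )
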