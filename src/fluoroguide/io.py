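"""File I/O: images (PNG/TIFF/DICOM), transform/centerline/curve JSON,
and the phantom model manifest.

All JSON payloads carry a ``schema`` tag so files remain self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import CArmPose, Curve3D, Image2D
from .registration import RegistrationResult, RigidTransform2D
from .tracking import Centerline2D

TRANSFORM_SCHEMA = "fluoroguide.transform/1"
CENTERLINE_SCHEMA = "fluoroguide.centerline/1"
CURVE_SCHEMA = "fluoroguide.curve3d/1"
MODEL_SCHEMA = "fluoroguide.model/1"


def read_image(path, spacing: float = 0.25) -> Image2D:
    """Read a grayscale image; DICOM via pydicom, raster formats via imageio.

    DICOM pixel spacing (and MONOCHROME1 polarity) is honoured when present;
    multi-channel rasters are averaged to grayscale.
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom", ".ima"):
        import pydicom

        ds = pydicom.dcmread(str(path))
        pixels = ds.pixel_array.astype(float)
        if getattr(ds, "PhotometricInterpretation", "") == "MONOCHROME1":
            pixels = pixels.max() - pixels  # invert so dense objects are dark
        if getattr(ds, "PixelSpacing", None):
            spacing = float(ds.PixelSpacing[0])
        return Image2D(pixels, spacing=spacing)
    import imageio.v3 as iio

    pixels = np.asarray(iio.imread(path), dtype=float)
    if pixels.ndim == 3:
        pixels = pixels[..., :3].mean(axis=2)
    return Image2D(pixels, spacing=spacing)


def write_image(image: Image2D, path) -> None:
    import imageio.v3 as iio

    pixels = np.asarray(image.pixels, dtype=float)
    if pixels.dtype != np.uint16:
        lo, hi = pixels.min(), pixels.max()
        if hi > 255 or lo < 0:
            pixels = (pixels - lo) / max(hi - lo, 1e-12) * 255.0
        elif hi <= 1.0 and pixels.dtype != np.uint8:
            pixels = pixels * 255.0
        pixels = np.clip(np.round(pixels), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), pixels)


def save_transform(result: RegistrationResult | RigidTransform2D, path, spacing=0.25):
    if isinstance(result, RegistrationResult):
        t = result.transform
        peaks = {
            "rotation_peak": result.rotation_peak.height,
            "translation_peak": result.translation_peak.height,
        }
        low = result.low_confidence
    else:
        t, peaks, low = result, {}, False
    payload = {
        "schema": TRANSFORM_SCHEMA,
        "k": t.k,
        "alpha_deg": t.alpha_deg,
        "tx_px": t.tx,
        "ty_px": t.ty,
        "peak_heights": peaks,
        "low_confidence": low,
        "spacing_mm_per_px": spacing,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_transform(path) -> tuple[RigidTransform2D, dict]:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != TRANSFORM_SCHEMA:
        raise ValueError(f"unsupported transform schema {payload.get('schema')!r}")
    t = RigidTransform2D(
        k=payload["k"], alpha_deg=payload["alpha_deg"],
        tx=payload["tx_px"], ty=payload["ty_px"],
    )
    return t, payload


def save_centerline(cl: Centerline2D, path) -> None:
    payload = {
        "schema": CENTERLINE_SCHEMA,
        "points_px": cl.points.tolist(),
        "widths_px": cl.widths.tolist(),
        "stop_reason": cl.stop_reason,
        "spacing_mm_per_px": cl.spacing,
        "image_shape": list(cl.image_shape) if cl.image_shape else None,
        "params": None if cl.params is None else vars(cl.params).copy(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_centerline(path) -> Centerline2D:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != CENTERLINE_SCHEMA:
        raise ValueError(f"unsupported centerline schema {payload.get('schema')!r}")
    pts = np.asarray(payload["points_px"], float)
    n = len(pts)
    return Centerline2D(
        points=pts,
        directions=np.tile([0.0, -1.0], (n, 1)),
        widths=np.asarray(payload["widths_px"], float),
        stop_reason=payload.get("stop_reason", ""),
        spacing=payload["spacing_mm_per_px"],
        image_shape=tuple(payload["image_shape"]) if payload.get("image_shape") else None,
    )


def save_curve(curve: Curve3D, report, path, frame: str = "world") -> None:
    payload = {
        "schema": CURVE_SCHEMA,
        "frame": frame,
        "points_mm": curve.points.tolist(),
        "per_point_mse_mm": None if report is None else report.per_point_mse.tolist(),
        "mean_mse_mm": None if report is None else report.mean_mse,
        "n_pairs": None if report is None else report.n_pairs,
        "pairs": None if report is None else report.pairs,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_curve(path) -> tuple[Curve3D, dict]:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != CURVE_SCHEMA:
        raise ValueError(f"unsupported curve schema {payload.get('schema')!r}")
    return Curve3D(np.asarray(payload["points_mm"], float)), payload


def save_model(model, out_dir) -> Path:
    """Write the phantom as STL meshes plus an analytic JSON manifest.

    The manifest stores the exact solid parameters (and ground-truth
    centroids), so :func:`load_model` reconstructs the model losslessly; the
    STL meshes are a convenience for external viewers.
    """
    from .scene import _model_meshes

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meshes = _model_meshes(model)
    files = {}
    for name, mesh in meshes.items():
        fname = f"{name}.stl"
        mesh.export(out / fname)
        files[name] = fname

    def solid_entry(s):
        entry = {"center_mm": s.center.tolist()}
        if hasattr(s, "semiaxes"):
            entry["semiaxes_mm"] = s.semiaxes.tolist()
        else:
            entry["size_mm"] = s.size.tolist()
            entry["corner_frac"] = s.corner_frac
        return entry

    manifest = {
        "schema": MODEL_SCHEMA,
        "frame": model.frame,
        "units": "mm",
        "files": files,
        "vertebrae": {v.name: solid_entry(v) for v in model.vertebrae},
        "connector": None if model.connector is None
        else {model.connector.name: solid_entry(model.connector)},
        "heart": None if model.heart is None else solid_entry(model.heart),
        "centroids_mm": {v.name: v.center.tolist() for v in model.vertebrae},
        "planned_path_mm": None if model.planned_path is None
        else np.asarray(model.planned_path, float).tolist(),
    }
    path = out / "model.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_model(manifest_path):
    from .phantom import AnatomyModel, Ellipsoid, RoundedBox

    payload = json.loads(Path(manifest_path).read_text())
    if payload.get("schema") != MODEL_SCHEMA:
        raise ValueError(f"unsupported model schema {payload.get('schema')!r}")
    vertebrae = [
        RoundedBox(name, np.asarray(e["center_mm"]), np.asarray(e["size_mm"]),
                   corner_frac=e.get("corner_frac", 1.2))
        for name, e in payload["vertebrae"].items()
    ]
    connector = None
    if payload.get("connector"):
        name, e = next(iter(payload["connector"].items()))
        connector = RoundedBox(
            name, np.asarray(e["center_mm"]), np.asarray(e["size_mm"]),
            corner_frac=e.get("corner_frac", 1.1),
        )
    heart = None
    if payload.get("heart"):
        heart = Ellipsoid(
            "heart",
            np.asarray(payload["heart"]["center_mm"]),
            np.asarray(payload["heart"]["semiaxes_mm"]),
        )
    planned = payload.get("planned_path_mm")
    return AnatomyModel(
        vertebrae=vertebrae,
        heart=heart,
        connector=connector,
        planned_path=None if planned is None else np.asarray(planned, float),
        frame=payload.get("frame", "world"),
    )
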