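"""Shared domain types for the guidance chain.

Coordinate conventions used throughout the package:

* World frame: right-handed, millimetres.  ``Y`` is the patient's long axis
  (positive = superior), ``X`` is patient left-right, ``Z`` is the
  anterior-posterior depth axis.  The C-arm rotates about ``Y`` only.
* Detector/image frame: pixels, origin at the top-left.  ``x`` indexes
  columns, ``y`` indexes rows and increases downward, so patient-superior is
  toward row 0.  The detector centre maps to the world origin.
* C-arm angles: LAO is a positive rotation about ``+Y``, RAO negative,
  AP is zero.  (The sign convention is a package choice; the CLI accepts
  either spelling, e.g. ``LAO30`` or ``RAO30``.)
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Image2D",
    "CArmPose",
    "Curve3D",
    "FluoroGuideError",
    "SegmentationError",
    "TrackingError",
    "ReconstructionError",
    "EvaluationError",
]


class FluoroGuideError(RuntimeError):
    """Base class for pipeline failures."""


class SegmentationError(FluoroGuideError):
    """Spine segmentation could not produce a usable mask."""


class TrackingError(FluoroGuideError):
    """Catheter tracing failed (seed not found or trace too short)."""


class ReconstructionError(FluoroGuideError):
    """Triangulation/correspondence failure (degenerate geometry etc.)."""


class EvaluationError(FluoroGuideError):
    """Evaluation bookkeeping failure (e.g. vertebra splitting)."""


@dataclass
class Image2D:
    """A grayscale raster with physical pixel spacing.

    Parameters
    ----------
    pixels:
        2-D array of intensities (any numeric dtype; kept as given).
    spacing:
        Pixel size in mm/px.  The default 0.25 mm/px reproduces the detector
        scale at which 2 px correspond to 0.5 mm.
    """

    pixels: np.ndarray
    spacing: float = 0.25

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("Image2D requires a non-empty 2-D pixel array")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive (mm/px)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def center(self) -> tuple[float, float]:
        """Detector centre as (cx, cy) in pixel (col, row) coordinates."""
        nrows, ncols = self.pixels.shape
        return ((ncols - 1) / 2.0, (nrows - 1) / 2.0)

    def px_to_mm(self, points_px: np.ndarray) -> np.ndarray:
        """Map (x=col, y=row) pixel points to detector-plane mm coordinates.

        The detector centre is mm origin; mm-y points patient-superior
        (i.e. opposite the row direction).
        """
        pts = np.atleast_2d(np.asarray(points_px, dtype=float))
        cx, cy = self.center
        out = np.empty_like(pts)
        out[:, 0] = (pts[:, 0] - cx) * self.spacing
        out[:, 1] = (cy - pts[:, 1]) * self.spacing
        return out

    def mm_to_px(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        cx, cy = self.center
        out = np.empty_like(pts)
        out[:, 0] = cx + pts[:, 0] / self.spacing
        out[:, 1] = cy - pts[:, 1] / self.spacing
        return out


_POSE_RE = re.compile(r"^(AP|LAO|RAO)\s*([0-9]+(?:\.[0-9]+)?)?$", re.IGNORECASE)


@dataclass(frozen=True)
class CArmPose:
    """C-arm orientation: a view side plus an angle about the patient Y axis.

    ``AP`` has angle 0; ``LAO``/``RAO`` angles are in (0, 90] degrees.
    ``signed_angle_deg`` applies the package sign convention
    (LAO positive, RAO negative).
    """

    side: str
    angle_deg: float = 0.0

    def __post_init__(self) -> None:
        side = self.side.upper()
        object.__setattr__(self, "side", side)
        if side not in ("AP", "LAO", "RAO"):
            raise ValueError(f"unknown view side {self.side!r}")
        if side == "AP":
            if self.angle_deg != 0:
                raise ValueError("AP pose must have angle 0")
        else:
            if not (0 < self.angle_deg <= 90):
                raise ValueError("LAO/RAO angle must be in (0, 90] degrees")

    @property
    def signed_angle_deg(self) -> float:
        if self.side == "LAO":
            return float(self.angle_deg)
        if self.side == "RAO":
            return -float(self.angle_deg)
        return 0.0

    @classmethod
    def from_string(cls, text: str) -> "CArmPose":
        """Parse 'AP', 'LAO30', 'RAO 60', ... into a pose."""
        m = _POSE_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse C-arm pose {text!r}")
        side = m.group(1).upper()
        angle = float(m.group(2)) if m.group(2) else 0.0
        return cls(side, angle)

    def __str__(self) -> str:
        return "AP" if self.side == "AP" else f"{self.side}{self.angle_deg:g}"


@dataclass
class Curve3D:
    """An ordered 3-D polyline in world mm, insertion end first, tip last."""

    points: np.ndarray
    arc_length: np.ndarray = field(default=None)  # cumulative, mm
    provenance: list | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3:
            raise ValueError("Curve3D points must be (N, 3)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("Curve3D points must be finite")
        if self.arc_length is None:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            self.arc_length = np.concatenate([[0.0], np.cumsum(seg)])
        else:
            self.arc_length = np.asarray(self.arc_length, dtype=float)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def tip(self) -> np.ndarray:
        return self.points[-1]

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    def resample(self, n: int) -> "Curve3D":
        """Resample to ``n`` points uniformly in arc length."""
        if n < 2:
            raise ValueError("need at least 2 samples")
        s = np.linspace(0.0, self.arc_length[-1], n)
        pts = np.column_stack(
            [np.interp(s, self.arc_length, self.points[:, i]) for i in range(3)]
        )
        return Curve3D(pts, arc_length=s)
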