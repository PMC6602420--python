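"""Catheter centerline tracing by iterative ROI walking.

A 12-Fr catheter (4 mm, ~16 px at 0.25 mm/px) appears as a dark band.  The
trace starts at the bottom edge of the frame (the inferior-vena-cava entry
direction), where the bottom rows are binarized adaptively and the widest
dark object seeds the first region of interest.  At each step the intensity
profile perpendicular to the current direction is averaged over a short
stretch of the band and differentiated; the two global derivative extrema
are the catheter edges, their midpoint the centerline sample.  The ROI then
advances along the (turn-clamped, smoothed) direction and the process
repeats until the frame edge, a contrast loss, or the step limit.

After a contrast loss the tracer backtracks and advances in single-pixel
steps so the reported tip sits at the end of the visible band rather than
one full ROI step short.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import Image2D, TrackingError
from .segmentation import otsu_threshold

__all__ = ["TrackingParams", "Centerline2D", "seed_roi", "edge_pair", "trace_centerline"]


@dataclass(frozen=True)
class TrackingParams:
    seed_rows: int = 10
    roi_length: int = 50  # profile extent across the catheter axis, px
    roi_width: int = 10  # averaging / advance extent along the axis, px
    min_edge_contrast: float = 8.0  # intensity/px floor on derivative extrema
    max_turn_deg: float = 30.0  # per step
    max_steps: int = 500
    direction_smoothing: float = 0.4  # weight on the previous direction
    nominal_width_mm: float = 4.0

    def __post_init__(self) -> None:
        if min(self.seed_rows, self.roi_length, self.roi_width, self.max_steps) <= 0:
            raise ValueError("ROI dimensions and step limits must be positive")
        if self.min_edge_contrast <= 0 or self.max_turn_deg <= 0:
            raise ValueError("contrast floor and turn clamp must be positive")


@dataclass
class Centerline2D:
    """Ordered subpixel centerline from the image bottom toward the tip."""

    points: np.ndarray  # (N, 2) as (x=col, y=row)
    directions: np.ndarray  # (N, 2) unit vectors
    widths: np.ndarray  # (N,) px
    stop_reason: str = ""
    spacing: float = 0.25
    image_shape: tuple[int, int] | None = None
    params: TrackingParams | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        self.widths = np.asarray(self.widths, dtype=float)
        if len(self.points) < 2:
            raise TrackingError("a valid trace needs at least 2 points")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def tip(self) -> np.ndarray:
        return self.points[-1]

    @property
    def arc_length_px(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


class _LostTrack(Exception):
    """Internal signal: derivative extrema below the contrast floor."""


def seed_roi(
    image: Image2D, params: TrackingParams = TrackingParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Locate the catheter in the bottom rows; return (center, up-direction).

    The bottom ``seed_rows`` are binarized with an adaptive (Otsu) threshold;
    among the dark objects the widest one wins (the catheter is the widest
    dark structure entering from below).  Raises :class:`TrackingError` when
    no dark object is present.
    """
    pixels = np.asarray(image.pixels, dtype=float)
    strip = pixels[-params.seed_rows :, :]
    if np.ptp(strip) == 0:
        raise TrackingError("blank seed rows: no catheter at the bottom edge")
    dark = strip < otsu_threshold(strip)
    labels, n = ndimage.label(dark)
    if n == 0:
        raise TrackingError("no dark object in the bottom seed rows")
    widths = []
    for i in range(1, n + 1):
        cols = np.nonzero(labels == i)[1]
        widths.append(cols.max() - cols.min() + 1)
    chosen = int(np.argmax(widths)) + 1
    rows, cols = np.nonzero(labels == chosen)
    center = np.array(
        [cols.mean(), pixels.shape[0] - 1 - (params.seed_rows - 1) / 2.0]
    )
    direction = np.array([0.0, -1.0])  # image-up along Y
    return center, direction


def _profile(image_px: np.ndarray, center, direction, params):
    """Averaged perpendicular intensity profile and its sample positions."""
    direction = np.asarray(direction, dtype=float)
    perp = np.array([-direction[1], direction[0]])
    half = params.roi_length / 2.0
    s = np.arange(-np.floor(half), np.floor(half) + 1.0)  # 1 px sampling
    along = np.linspace(-params.roi_width / 2.0, params.roi_width / 2.0, params.roi_width)
    # sample grid: rows = along-axis offsets, cols = across-axis positions
    xs = center[0] + along[:, None] * direction[0] + s[None, :] * perp[0]
    ys = center[1] + along[:, None] * direction[1] + s[None, :] * perp[1]
    vals = ndimage.map_coordinates(
        image_px, np.stack([ys, xs]), order=1, mode="nearest"
    )
    return s, vals.mean(axis=0), perp


def edge_pair(
    image: Image2D,
    center: np.ndarray,
    direction: np.ndarray,
    params: TrackingParams = TrackingParams(),
):
    """Detect the two catheter edges around ``center``.

    Returns ``(edge1, edge2, new_center, width_px)`` where edges and centre
    are (x, y) pixel points; raises :class:`TrackingError` when the profile
    has no usable contrast (the lost-track signal).
    """
    pixels = np.asarray(image.pixels, dtype=float)
    s, prof, perp = _profile(pixels, np.asarray(center, float), direction, params)
    if np.ptp(prof) == 0:
        raise TrackingError("uniform profile: lost track")
    deriv = np.gradient(prof, s)
    i_min = int(np.argmin(deriv))
    i_max = int(np.argmax(deriv))
    if -deriv[i_min] < params.min_edge_contrast or deriv[i_max] < params.min_edge_contrast:
        raise TrackingError("edge contrast below floor: lost track")
    if s[i_max] <= s[i_min]:
        # dark band must be entered (negative slope) before it is exited
        raise TrackingError("edge order inconsistent with a dark band: lost track")

    def refine(i):
        if 0 < i < len(s) - 1:
            d = deriv[i - 1] - 2 * deriv[i] + deriv[i + 1]
            if d != 0:
                return s[i] + float(np.clip(0.5 * (deriv[i - 1] - deriv[i + 1]) / d, -0.5, 0.5))
        return s[i]

    s1, s2 = refine(i_min), refine(i_max)
    mid = (s1 + s2) / 2.0
    e1 = np.asarray(center) + s1 * perp
    e2 = np.asarray(center) + s2 * perp
    new_center = np.asarray(center) + mid * perp
    return e1, e2, new_center, float(s2 - s1)


def _clamp_turn(prev: np.ndarray, new: np.ndarray, max_turn_deg: float) -> np.ndarray:
    cosang = float(np.clip(prev @ new, -1.0, 1.0))
    ang = np.degrees(np.arccos(cosang))
    if ang <= max_turn_deg:
        return new
    # rotate prev toward new by the clamp angle
    sign = np.sign(prev[0] * new[1] - prev[1] * new[0]) or 1.0
    t = np.deg2rad(max_turn_deg) * sign
    c, sn = np.cos(t), np.sin(t)
    return np.array([c * prev[0] - sn * prev[1], sn * prev[0] + c * prev[1]])


def trace_centerline(
    image: Image2D, params: TrackingParams = TrackingParams()
) -> Centerline2D:
    """Walk the catheter from the bottom seed to its visible end."""
    pixels = np.asarray(image.pixels, dtype=float)
    nrows, ncols = pixels.shape
    center, direction = seed_roi(image, params)

    points, dirs, widths = [], [], []
    stop_reason = "max_steps"
    margin = params.roi_width / 2.0 + 1.0

    def in_bounds(p):
        return margin <= p[0] <= ncols - 1 - margin and margin <= p[1] <= nrows - 1 - margin

    step = float(params.roi_width)
    for _ in range(params.max_steps):
        try:
            _, _, new_center, width = edge_pair(image, center, direction, params)
        except TrackingError:
            stop_reason = "lost_track"
            break
        points.append(new_center)
        widths.append(width)
        if len(points) >= 2:
            d_new = points[-1] - points[-2]
            norm = np.linalg.norm(d_new)
            if norm > 0:
                d_new = _clamp_turn(direction, d_new / norm, params.max_turn_deg)
                lam = params.direction_smoothing
                direction = lam * direction + (1 - lam) * d_new
                direction = direction / np.linalg.norm(direction)
        dirs.append(direction.copy())
        center = new_center + step * direction
        if not in_bounds(center):
            stop_reason = "out_of_bounds"
            break

    # tip refinement: creep forward in 1 px steps from the last good sample,
    # with a narrow along-axis window so the profile stops seeing the band
    # as soon as the tip is passed
    if stop_reason == "lost_track" and points:
        tip_params = replace(params, roi_width=2)

        def visible(p):
            try:
                edge_pair(image, p, direction, tip_params)
                return True
            except TrackingError:
                return False

        # trim samples the wide window placed beyond the visible band
        trimmed = 0
        while len(points) > 2 and trimmed < 3 and not visible(points[-1]):
            points.pop(), widths.pop(), dirs.pop()
            trimmed += 1
        center = points[-1] + direction
        w_med = float(np.median(widths))
        for _ in range(2 * int(step) + 2):
            try:
                _, _, c_ref, w_ref = edge_pair(image, center, direction, tip_params)
            except TrackingError:
                break
            if not 0.6 * w_med <= w_ref <= 1.5 * w_med:
                break  # implausible band width: past the tip
            points.append(c_ref)
            widths.append(w_ref)
            dirs.append(direction.copy())
            center = c_ref + direction

    if len(points) < 2:
        raise TrackingError(f"trace too short ({len(points)} points): {stop_reason}")
    return Centerline2D(
        points=np.array(points),
        directions=np.array(dirs),
        widths=np.array(widths),
        stop_reason=stop_reason,
        spacing=image.spacing,
        image_shape=(nrows, ncols),
        params=params,
    )
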