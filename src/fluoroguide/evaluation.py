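"""Registration evaluation: vertebra-centroid errors and benchmark runs.

The registration error for one image pair is the distance (mm) between
corresponding vertebral-body centroids in the two registered modalities:
centroids are extracted from the fluoroscopic spine mask and from the CT
reference projection, paired by row order (robust for a vertically stacked
spine), and compared after mapping the moving centroids through the
recovered transform.

The benchmark runner registers a dataset of image pairs with one or more
registrar callables and tabulates success rate and error statistics — the
machine-readable analog of an operator-judged success table.  Success is
classified by an error threshold (default 5 mm, the radius of the clinically
quoted safe region around a transseptal puncture target).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .core import EvaluationError, Image2D
from .registration import RigidTransform2D, apply_transform
from .segmentation import BinaryMask

__all__ = [
    "VertebraSet",
    "BenchmarkRecord",
    "vertebra_centroids",
    "registration_error",
    "run_benchmark",
    "make_benchmark_suite",
]


@dataclass
class VertebraSet:
    """Ordered (label, centroid) pairs from a mask, superior row first."""

    labels: list
    centroids: np.ndarray  # (n, 2) px as (x=col, y=row)

    def __post_init__(self) -> None:
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        if len(self.labels) != len(self.centroids):
            raise ValueError("labels and centroids must align")

    def __len__(self) -> int:
        return len(self.centroids)


@dataclass
class BenchmarkRecord:
    method: str
    pair_id: str
    success: bool
    error_mm: float  # nan on failure
    runtime_s: float  # informational only; never part of acceptance
    detail: str = ""


def _component_centroids(mask: np.ndarray):
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.empty((0, 2)), np.empty(0)
    idx = np.arange(1, n + 1)
    centroids_rc = np.array(ndimage.center_of_mass(mask, labels, idx))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=idx)
    return centroids_rc, sizes


def _split_merged(mask: np.ndarray, expected_n: int) -> np.ndarray:
    """Cut a merged spine mask at local minima of the row-width profile."""
    widths = mask.sum(axis=1).astype(float)
    rows = np.flatnonzero(widths > 0)
    if len(rows) == 0:
        return mask
    smoothed = ndimage.uniform_filter1d(widths, size=5)
    # local minima of the width profile = intervertebral waists; find_peaks
    # on the negated profile handles the flat-bottomed gaps
    minima, _ = find_peaks(-smoothed, prominence=0.1 * np.ptp(smoothed))
    minima = [r for r in minima if widths[r] > 0]
    if not minima:
        return mask
    out = mask.copy()
    out[minima, :] = False
    return out


def vertebra_centroids(mask: BinaryMask | np.ndarray, expected_n: int) -> VertebraSet:
    """Extract ``expected_n`` vertebra centroids from a spine mask.

    Connected components are used directly when enough exist; a merged mask
    (e.g. vertebrae bridged by the morphological closing or by the posterior
    column) is split at local minima of its row-wise width profile first.
    Raises :class:`EvaluationError` when the expected count cannot be
    produced — an evaluation failure, not a registration-method failure.
    """
    pixels = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    if expected_n < 1:
        raise ValueError("expected_n must be >= 1")

    centroids_rc, sizes = _component_centroids(pixels)
    if len(centroids_rc) < expected_n:
        split = _split_merged(pixels, expected_n)
        centroids_rc, sizes = _component_centroids(split)
    if len(centroids_rc) < expected_n:
        raise EvaluationError(
            f"found {len(centroids_rc)} separable components, expected {expected_n}"
        )
    keep = np.argsort(sizes)[::-1][:expected_n]
    centroids_rc = centroids_rc[keep]
    order = np.argsort(centroids_rc[:, 0])  # by row: superior first
    centroids_xy = centroids_rc[order][:, ::-1]
    labels = [f"vertebra_{i + 1}" for i in range(expected_n)]
    return VertebraSet(labels=labels, centroids=centroids_xy)


def registration_error(
    fixed_set: VertebraSet,
    moving_set: VertebraSet,
    t: RigidTransform2D,
    spacing: float,
) -> np.ndarray:
    """Per-vertebra centroid distances (mm) after applying ``t`` to moving."""
    if len(fixed_set) != len(moving_set):
        raise EvaluationError(
            f"vertebra count mismatch: {len(fixed_set)} vs {len(moving_set)}"
        )
    mapped = apply_transform(t, moving_set.centroids)
    return np.linalg.norm(mapped - fixed_set.centroids, axis=1) * spacing


def run_benchmark(
    dataset: list[dict],
    methods: dict,
    success_threshold_mm: float = 5.0,
    expected_n: int = 5,
    segment=None,
) -> tuple[list[BenchmarkRecord], dict]:
    """Register every dataset pair with every method and tabulate results.

    Parameters
    ----------
    dataset:
        List of dicts with keys ``fixed`` (reference-projection
        :class:`Image2D`), ``moving`` (fluoroscopic :class:`Image2D`), and
        optionally ``id``.
    methods:
        Mapping of method name to a callable
        ``(fixed: Image2D, moving_mask: Image2D) -> RigidTransform2D``.
    segment:
        Optional override for the spine-mask extraction applied to the
        moving image (defaults to :func:`fluoroguide.segmentation.segment_spine`).

    Returns
    -------
    (records, summary): per-pair records plus, per method, the success rate
    in percent and the mean/std of per-image mean errors over successes.
    Method exceptions are recorded as failures; the run continues.
    """
    from .segmentation import segment_spine

    if not methods:
        raise ValueError("need at least one method")
    if not dataset:
        raise ValueError("dataset is empty")
    seg = segment or segment_spine

    records: list[BenchmarkRecord] = []
    for entry_idx, entry in enumerate(dataset):
        fixed = entry["fixed"]
        moving = entry["moving"]
        pair_id = str(entry.get("id", entry_idx))
        try:
            moving_mask = seg(moving)
            fixed_set = vertebra_centroids(fixed.pixels > 0.5, expected_n)
            moving_set = vertebra_centroids(moving_mask.pixels, expected_n)
        except Exception as exc:  # evaluation failure hits every method
            for name in methods:
                records.append(
                    BenchmarkRecord(name, pair_id, False, np.nan, 0.0, f"eval: {exc}")
                )
            continue
        moving_mask_img = Image2D(
            moving_mask.pixels.astype(float), spacing=moving.spacing
        )
        for name, method in methods.items():
            t0 = time.perf_counter()
            try:
                t = method(fixed, moving_mask_img)
                err = float(
                    registration_error(fixed_set, moving_set, t, fixed.spacing).mean()
                )
                ok = err <= success_threshold_mm
                detail = ""
            except Exception as exc:
                err, ok, detail = np.nan, False, str(exc)
            records.append(
                BenchmarkRecord(name, pair_id, ok, err, time.perf_counter() - t0, detail)
            )

    summary = {}
    for name in methods:
        rows = [r for r in records if r.method == name]
        errs = np.array([r.error_mm for r in rows if r.success])
        summary[name] = {
            "n_pairs": len(rows),
            "success_rate_pct": 100.0 * sum(r.success for r in rows) / len(rows),
            "mean_error_mm": float(errs.mean()) if len(errs) else np.nan,
            "std_error_mm": float(errs.std()) if len(errs) else np.nan,
        }
    return records, summary


def make_benchmark_suite(
    seed: int = 0,
    poses: tuple[str, ...] = ("AP", "LAO30", "LAO60", "RAO30", "RAO60"),
    n_conditions: int = 7,
    size: tuple[int, int] = (512, 512),
    spacing: float = 0.25,
) -> list[dict]:
    """Build the packaged synthetic benchmark: len(poses) x n_conditions pairs.

    Each pair is the CT-side spine silhouette at one pose (fixed) and a
    warped, noisy fluoroscopic render at the same pose (moving); the warp
    parameters (scale 0.9-1.1, rotation +-10 deg, translation +-30 px) and
    the noise level cycle deterministically from ``seed``.  With the default
    five poses and seven conditions the suite has 35 pairs.
    """
    from skimage import transform as sktransform

    from .core import CArmPose
    from .phantom import PhantomNoiseSpec, make_spine_phantom, render_fluoroscopy
    from .projection import render_reference_projection
    from .registration import _center_similarity_matrix

    rng = np.random.default_rng(seed)
    model = make_spine_phantom(jitter_mm=0.8, seed=seed)
    dataset = []
    for pose_txt in poses:
        pose = CArmPose.from_string(pose_txt)
        fixed = render_reference_projection(model, pose, spacing, size)
        base = render_fluoroscopy(model, None, pose, spacing, size)
        for c in range(n_conditions):
            k = rng.uniform(0.9, 1.1)
            alpha = rng.uniform(-10.0, 10.0)
            tx, ty = rng.uniform(-30.0, 30.0, 2)
            sigma = [0.0, 1.0, 2.0, 3.0, 4.0, 2.0, 3.0][c % 7]
            center = ((size[1] - 1) / 2.0, (size[0] - 1) / 2.0)
            m_mf = np.array(
                [[1.0, 0.0, tx], [0.0, 1.0, ty], [0.0, 0.0, 1.0]]
            ) @ _center_similarity_matrix(k, alpha, center)
            # moving(x) = base(M x): the warp whose inverse is the gt transform
            warped = sktransform.warp(
                np.asarray(base.pixels, float),
                inverse_map=m_mf,
                order=1,
                mode="constant",
                cval=float(np.median(base.pixels)),
            )
            if sigma > 0:
                warped = np.clip(
                    warped + rng.normal(0.0, sigma, warped.shape), 0.0, 255.0
                )
            dataset.append(
                {
                    "id": f"{pose_txt}-c{c}",
                    "fixed": fixed,
                    "moving": Image2D(warped, spacing=spacing),
                    "true_transform": RigidTransform2D.from_matrix(m_mf),
                    "pose": pose,
                }
            )
    return dataset


def fourier_method(fixed: Image2D, moving_mask: Image2D) -> RigidTransform2D:
    """Default registrar adapter: the package's Fourier-Mellin register()."""
    from .registration import register

    return register(fixed, moving_mask).transform
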