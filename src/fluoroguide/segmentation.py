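"""Spine extraction from fluoroscopic frames (the moving image of the
registration step).

Pipeline: Gaussian smoothing -> Otsu threshold keeping the dark side ->
largest connected component -> refined Otsu restricted to that component's
bounding box -> morphological closing -> small-object removal.  The spine is
assumed darker than the background (standard fluoroscopic polarity); callers
with inverted frames must invert first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

from .core import Image2D, SegmentationError

__all__ = ["BinaryMask", "SegmentationParams", "otsu_threshold", "segment_spine"]


@dataclass
class BinaryMask:
    """Boolean mask aligned with its source image (same shape and spacing)."""

    pixels: np.ndarray
    spacing: float = 0.25

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("mask must be non-empty 2-D")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def as_image(self, background: float = 255.0) -> Image2D:
        """Render the mask back into fluoroscopic polarity (dark object)."""
        return Image2D(
            np.where(self.pixels, 0.0, background).astype(float), spacing=self.spacing
        )


@dataclass(frozen=True)
class SegmentationParams:
    gaussian_sigma: float = 2.0  # px
    close_radius: int = 3  # px
    min_component_px: int = 100

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0 or self.close_radius < 0 or self.min_component_px < 0:
            raise ValueError("segmentation parameters must be >= 0")


def otsu_threshold(image: Image2D | np.ndarray) -> float:
    """Threshold maximizing between-class variance of the intensity histogram."""
    pixels = image.pixels if isinstance(image, Image2D) else np.asarray(image)
    if np.ptp(pixels) == 0:
        raise SegmentationError("constant image has no Otsu threshold")
    return float(filters.threshold_otsu(pixels))


def segment_spine(
    image: Image2D, params: SegmentationParams = SegmentationParams()
) -> BinaryMask:
    """Extract the binary spine mask from a grayscale fluoroscopic frame.

    Raises
    ------
    SegmentationError
        For blank/constant input or when no dark component reaches
        ``params.min_component_px``.
    """
    pixels = np.asarray(image.pixels, dtype=float)
    if np.ptp(pixels) == 0:
        raise SegmentationError("blank or constant image: empty mask")

    smoothed = (
        ndimage.gaussian_filter(pixels, params.gaussian_sigma)
        if params.gaussian_sigma > 0
        else pixels
    )

    # global pass: dark side of Otsu, keep the largest object
    dark = smoothed < otsu_threshold(smoothed)
    labels, n = ndimage.label(dark)
    if n == 0:
        raise SegmentationError("no dark object found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    if sizes[largest - 1] < params.min_component_px:
        raise SegmentationError(
            f"largest component {int(sizes[largest - 1])} px < "
            f"min_component_px={params.min_component_px}"
        )

    # refined pass: re-threshold restricted to the largest object's bbox
    obj = ndimage.find_objects((labels == largest).astype(np.int32))[0]
    sub = smoothed[obj]
    if np.ptp(sub) == 0:
        refined_sub = np.ones_like(sub, dtype=bool)
    else:
        refined_sub = sub < otsu_threshold(sub)
    mask = np.zeros_like(dark)
    mask[obj] = refined_sub

    if params.close_radius > 0:
        mask = morphology.closing(mask, morphology.disk(params.close_radius))
    if params.min_component_px > 0:
        lab2, n2 = ndimage.label(mask)
        if n2 > 0:
            sizes2 = ndimage.sum_labels(
                np.ones_like(lab2), lab2, index=np.arange(1, n2 + 1)
            )
            keep = np.flatnonzero(sizes2 >= params.min_component_px) + 1
            mask = np.isin(lab2, keep)
    if not mask.any():
        raise SegmentationError("segmentation produced an empty mask")
    return BinaryMask(mask, spacing=image.spacing)
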