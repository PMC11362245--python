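"""Hypoechoic-lesion detection in 2-D B-mode frames.

A classical intensity/blob detector that returns the lesion mask, its
sub-pixel area centroid and its circle-equivalent diameter.  It is interface
parity with a segmentation network (mask + centre pixel), so a trained
backend can replace it without touching the navigation pipeline; externally
produced masks are accepted via :func:`load_mask_as_result`.

Pipeline: Gaussian smoothing -> dark-region threshold at a fraction of the
background median -> connected components -> area and circularity filters ->
highest-contrast component -> area centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import filters, measure

from .transforms import PixelPoint

__all__ = [
    "DetectionParams",
    "SegmentationResult",
    "NoLesionFoundError",
    "detect_lesion",
    "load_mask_as_result",
]


class NoLesionFoundError(RuntimeError):
    """No connected component passed the lesion filters."""


@dataclass(frozen=True)
class DetectionParams:
    """Tunable detector settings.

    Attributes
    ----------
    smoothing_sigma
        Gaussian pre-smoothing, px.
    threshold_fraction
        A pixel is lesion-candidate when its smoothed intensity is below
        ``threshold_fraction * median(image)`` (the median is the background
        estimate; the lesion occupies a small image fraction).
    min_area, max_area
        Component area bounds, px^2.
    min_circularity
        ``4 pi A / P^2`` lower bound; 1.0 is a perfect disc.
    """

    smoothing_sigma: float = 2.0
    threshold_fraction: float = 0.5
    min_area: float = 50.0
    max_area: float = 5000.0
    min_circularity: float = 0.6


@dataclass(frozen=True)
class SegmentationResult:
    mask: np.ndarray = field(repr=False)
    centroid: PixelPoint
    equivalent_diameter_px: float

    def to_json_dict(self) -> dict:
        return {
            "centroid_col_row": [self.centroid.col, self.centroid.row],
            "equivalent_diameter_px": self.equivalent_diameter_px,
        }


def _validate_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("intensities must lie in [0, 1]")
    return np.clip(img, 0.0, 1.0)


def _result_from_mask(mask: np.ndarray, reference: np.ndarray | None = None):
    props = measure.regionprops(mask.astype(np.uint8))[0]
    row, col = props.centroid
    return SegmentationResult(
        mask=mask,
        centroid=PixelPoint(col=float(col), row=float(row)),
        equivalent_diameter_px=float(props.equivalent_diameter_area),
    )


def detect_lesion(
    image: np.ndarray, params: DetectionParams = DetectionParams()
) -> SegmentationResult:
    """Locate the hypoechoic target and return mask, centroid and diameter.

    The centroid is the area centroid of the selected component, reported as a
    sub-pixel :class:`~usnav.transforms.PixelPoint` (col, row).  When several
    components survive the area/circularity filters, the one with the highest
    contrast against the background median wins.

    Raises
    ------
    NoLesionFoundError
        When no component passes the filters (e.g. a blank frame).
    """
    img = _validate_image(image)
    smoothed = filters.gaussian(img, sigma=params.smoothing_sigma)
    background = np.median(smoothed)
    candidates = smoothed < params.threshold_fraction * background
    labels = measure.label(candidates)
    best = None
    best_contrast = -np.inf
    for props in measure.regionprops(labels, intensity_image=smoothed):
        if not (params.min_area <= props.area <= params.max_area):
            continue
        if props.perimeter == 0:
            continue
        circularity = 4.0 * np.pi * props.area / props.perimeter**2
        if circularity < params.min_circularity:
            continue
        contrast = background - props.intensity_mean
        if contrast > best_contrast:
            best_contrast = contrast
            best = props
    if best is None:
        raise NoLesionFoundError("no component passed area/circularity filters")
    # Refine to the half-amplitude contour: the detection threshold (a fraction
    # of the background) sits inside the blurred lesion edge and shrinks the
    # mask; for a smoothed step the true boundary is where the intensity
    # crosses midway between lesion and background level.
    lesion_level = float(np.median(smoothed[labels == best.label]))
    half = 0.5 * (lesion_level + background)
    refined = measure.label(smoothed < half)
    seed_row, seed_col = np.round(best.centroid).astype(int)
    label_at_seed = refined[seed_row, seed_col]
    mask = refined == label_at_seed if label_at_seed else labels == best.label
    return _result_from_mask(mask)


def load_mask_as_result(mask: np.ndarray) -> SegmentationResult:
    """Wrap an externally produced binary mask (e.g. a network output).

    Accepts boolean or 0/255-style arrays; all foreground pixels are treated
    as one lesion.
    """
    m = np.asarray(mask)
    if m.ndim != 2 or m.size == 0:
        raise ValueError("mask must be a non-empty 2-D array")
    binary = m > (m.max() / 2 if m.dtype != bool and m.max() > 1 else 0)
    if not binary.any():
        raise ValueError("mask has no foreground pixels")
    return _result_from_mask(binary)
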