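"""Per-ROI morphological and intensity features.

Features are measured on the darkfield crop, where particles are
bright on a dark background and foreground masks are easiest to
obtain.  Lengths are reported sample-side in micrometres (pixel
measurements scaled by pixel_pitch / magnification), areas in um^2,
intensities in normalized [0, 1] units.

The focus-sensitive *edge noise gradient* is the mean gradient
magnitude over the one-pixel boundary band of the object mask,
normalized by the mean object intensity: sharp in-focus edges score
high, defocused edges low.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.filters import sobel, threshold_otsu

from .detect import ROI
from .optics import OpticalConfig

FEATURE_NAMES = (
    "area",
    "minor_axis_length",
    "major_axis_length",
    "eccentricity",
    "circularity",
    "perimeter",
    "equivalent_diameter",
    "object_intensity_sum",
    "mean_intensity",
    "intensity_std",
    "edge_noise_gradient",
    "solidity",
    "extent",
)

# Crops with less contrast than this are treated as background-only.
_MIN_CONTRAST = 0.05


class EmptyObjectError(ValueError):
    """Raised when a feature is requested for an empty mask."""


def segment_roi(roi: ROI) -> np.ndarray:
    """Foreground mask of an ROI: largest Otsu-thresholded component.

    Returns an all-False mask for background-only crops.
    """
    crop = roi.crop
    empty = np.zeros(crop.shape, dtype=bool)
    if crop.max() - crop.min() < _MIN_CONTRAST:
        return empty
    thr = threshold_otsu(crop)
    mask = crop > thr
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return empty
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def edge_noise_gradient(roi: ROI, mask: np.ndarray) -> float:
    """Mean boundary-band gradient magnitude over mean object intensity."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyObjectError("empty mask")
    band = mask & ~ndimage.binary_erosion(mask)
    if not band.any():
        raise EmptyObjectError("mask has no boundary band")
    grad = sobel(roi.crop)
    mean_int = float(roi.crop[mask].mean())
    if mean_int <= 0:
        return 0.0
    return float(grad[band].mean() / mean_int)


def extract_features(
    roi: ROI, mask: Optional[np.ndarray] = None, cfg: Optional[OpticalConfig] = None
) -> dict:
    """Compute the named feature registry for one ROI.

    Parameters
    ----------
    mask : optional
        Foreground mask; computed with :func:`segment_roi` when omitted.
    cfg : optional
        Optics used for the micron conversion; defaults to the config
        attached to the ROI's frame, falling back to package defaults.
    """
    if mask is None:
        mask = segment_roi(roi)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyObjectError("cannot extract features from an empty object")
    cfg = cfg or OpticalConfig()
    s = cfg.sample_pixel_size  # um per pixel, sample side

    props = measure.regionprops(mask.astype(np.uint8), intensity_image=roi.crop)[0]
    perimeter_px = props.perimeter
    area_px = props.area
    circularity = (
        4.0 * math.pi * area_px / (perimeter_px**2) if perimeter_px > 0 else 0.0
    )
    inside = roi.crop[mask]
    return {
        "area": float(area_px * s * s),
        "minor_axis_length": float(props.axis_minor_length * s),
        "major_axis_length": float(props.axis_major_length * s),
        "eccentricity": float(props.eccentricity),
        "circularity": float(circularity),
        "perimeter": float(perimeter_px * s),
        "equivalent_diameter": float(props.equivalent_diameter_area * s),
        "object_intensity_sum": float(inside.sum()),
        "mean_intensity": float(inside.mean()),
        "intensity_std": float(inside.std()),
        "edge_noise_gradient": edge_noise_gradient(roi, mask),
        "solidity": float(props.solidity),
        "extent": float(props.extent),
    }


def features_table(rois: list[ROI], cfg: Optional[OpticalConfig] = None) -> pd.DataFrame:
    """Feature table for a list of ROIs (rows indexed by position).

    ROIs whose crop segments to an empty mask are dropped; the index
    keeps the original ROI positions.
    """
    rows, idx = [], []
    for i, roi in enumerate(rois):
        mask = segment_roi(roi)
        if not mask.any():
            continue
        rows.append(extract_features(roi, mask, cfg))
        idx.append(i)
    return pd.DataFrame(rows, index=idx, columns=list(FEATURE_NAMES))
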