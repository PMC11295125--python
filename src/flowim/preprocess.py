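"""Frame containers, flat-field normalization, and denoising.

Frames are held as floating-point arrays in [0, 1] regardless of the
bit depth on disk.  Luminance is normalized against a pair of blank
calibration frames: a *positive blank* (unobstructed view of the light
path) and a *negative blank* (fully obstructed view).  Blanks are
lightly Gaussian-smoothed before use so that their own shot noise is
not amplified by the per-pixel division.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .optics import OpticalConfig

BRIGHTFIELD = "brightfield"
DARKFIELD = "darkfield"

# Rec.601 luma weights for RGB -> grayscale conversion at the I/O boundary.
_REC601 = np.array([0.299, 0.587, 0.114])


@dataclass
class Frame:
    """One illumination-normalized image.

    Attributes
    ----------
    pixels : ndarray
        2-D float array; values in [0, 1] once normalized.
    modality : str
        ``"brightfield"`` or ``"darkfield"``.
    optical_config : OpticalConfig
    source : str
        Identifier of the imaged field of view (used to pair modalities).
    """

    pixels: np.ndarray
    modality: str
    optical_config: OpticalConfig
    source: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("Frame pixels must be 2-D")
        if self.modality not in (BRIGHTFIELD, DARKFIELD):
            raise ValueError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Frame pixels must be finite")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class BlankPair:
    """Positive (open path) and negative (obstructed) calibration blanks."""

    positive_blank: Frame
    negative_blank: Frame

    def __post_init__(self) -> None:
        if self.positive_blank.shape != self.negative_blank.shape:
            raise ValueError("blank frames must share a shape")
        if self.positive_blank.pixels.mean() <= self.negative_blank.pixels.mean():
            raise ValueError("positive blank must be brighter than negative blank")


@dataclass
class MultimodalView:
    """Paired brightfield/darkfield frames of the same field of view."""

    bright: Frame
    dark: Frame

    def __post_init__(self) -> None:
        if self.bright.shape != self.dark.shape:
            raise ValueError("paired frames must share a shape")
        if self.bright.source != self.dark.source:
            raise ValueError(
                f"field identifiers differ: {self.bright.source!r} vs {self.dark.source!r}"
            )
        if self.bright.modality != BRIGHTFIELD or self.dark.modality != DARKFIELD:
            raise ValueError("pair must be (brightfield, darkfield)")

    @property
    def shape(self) -> tuple:
        return self.dark.shape


def to_float01(pixels: np.ndarray) -> np.ndarray:
    """Convert an 8/16-bit or float image (grayscale or RGB) to float [0,1]."""
    a = np.asarray(pixels)
    if a.ndim == 3:
        if a.shape[2] == 4:  # drop alpha
            a = a[..., :3]
        a = a.astype(np.float64) @ _REC601
    if np.issubdtype(np.asarray(pixels).dtype, np.integer):
        scale = float(np.iinfo(np.asarray(pixels).dtype).max)
        a = a.astype(np.float64) / scale
    else:
        a = a.astype(np.float64)
    return np.clip(a, 0.0, 1.0)


def read_frame(
    path: str | Path,
    modality: str,
    cfg: Optional[OpticalConfig] = None,
    source: str = "",
) -> Frame:
    """Read a TIFF or PNG image into a normalized-range Frame."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        raw = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        raw = iio.imread(path)
    return Frame(
        pixels=to_float01(raw),
        modality=modality,
        optical_config=cfg or OpticalConfig(),
        source=source or path.stem,
    )


def write_frame(path: str | Path, frame: Frame) -> None:
    """Write a frame as 16-bit grayscale TIFF or PNG."""
    path = Path(path)
    data = np.clip(frame.pixels, 0.0, 1.0)
    data16 = np.round(data * 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, data16)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, data16)


def flat_field_normalize(
    raw: Frame, blanks: BlankPair, blank_smoothing_sigma: float = 5.0
) -> Frame:
    """Normalize a frame between its negative and positive blanks.

    ``out = clip((raw - negative) / (positive - negative), 0, 1)`` with
    blanks Gaussian-smoothed (default sigma 5 px).  Pixels where the
    smoothed blanks still coincide are repaired with the median
    blank separation so that the division stays finite.
    """
    if raw.shape != blanks.positive_blank.shape:
        raise ValueError("frame and blanks must share a shape")
    pos = blanks.positive_blank.pixels
    neg = blanks.negative_blank.pixels
    if blank_smoothing_sigma > 0:
        pos = ndimage.gaussian_filter(pos, blank_smoothing_sigma)
        neg = ndimage.gaussian_filter(neg, blank_smoothing_sigma)
    denom = pos - neg
    typical = np.median(np.abs(denom))
    if typical <= 0:
        raise ValueError("blanks are indistinguishable after smoothing")
    denom = np.where(np.abs(denom) < 1e-6, typical, denom)
    out = np.clip((raw.pixels - neg) / denom, 0.0, 1.0)
    return replace(raw, pixels=out)


def denoise(f: Frame, kernel_radius: int = 1) -> Frame:
    """Median-filter a frame; radius 0 is the identity."""
    if kernel_radius < 0:
        raise ValueError("kernel radius must be >= 0")
    if kernel_radius == 0:
        return replace(f, pixels=f.pixels.copy())
    size = 2 * kernel_radius + 1
    return replace(f, pixels=ndimage.median_filter(f.pixels, size=size))


def pair_modalities(bright: Frame, dark: Frame) -> MultimodalView:
    """Pair brightfield and darkfield frames of the same field of view."""
    return MultimodalView(bright=bright, dark=dark)
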