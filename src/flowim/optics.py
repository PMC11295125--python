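"""Closed-form optical calibration math.

Resolution is assessed against a USAF-1951 bar target, whose element
spatial frequency is ``2**(group + (element - 1) / 6)`` line pairs per
millimetre.  The system resolution implied by the smallest resolvable
element is taken as the line-pair period divided by sqrt(2), following
the convention used for reverse-lens flow microscopes.  Numerical
aperture is derived from the objective f-number via the exact marginal
ray angle, ``NA = sin(arctan(1 / (2 N)))``, rather than the paraxial
``1 / (2 N)`` approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

__all__ = [
    "OpticalConfig",
    "USAFElement",
    "usaf_frequency",
    "resolution_from_element",
    "theoretical_na",
    "object_pixel_span",
    "empirical_magnification",
    "imaged_volume",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry of the imaging train and flow channel.

    Parameters
    ----------
    pixel_pitch : float
        Sensor pixel pitch in micrometres per sensor-side pixel.
    magnification : float
        Empirical lateral magnification of the objective train.
    objective_f_number : float
        Working f-number of the objective lens.
    channel_depth, channel_width : float
        Flow-channel cross-section in micrometres.
    frame_volume : float
        Sample volume imaged per frame, in microlitres.  This is a
        calibrated instrument constant used by quantitation; see
        :func:`imaged_volume` for the purely geometric estimate.
    frame_width_px, frame_height_px : int
        Sensor frame dimensions in pixels.
    """

    pixel_pitch: float = 1.12
    magnification: float = 5.0
    objective_f_number: float = 2.0
    channel_depth: float = 200.0
    channel_width: float = 1000.0
    frame_volume: float = 0.062
    frame_width_px: int = 3280
    frame_height_px: int = 2464

    def __post_init__(self) -> None:
        for name in (
            "pixel_pitch",
            "magnification",
            "objective_f_number",
            "channel_depth",
            "channel_width",
            "frame_volume",
            "frame_width_px",
            "frame_height_px",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"OpticalConfig.{name} must be positive")

    @property
    def sample_pixel_size(self) -> float:
        """Sample-side size of one pixel in micrometres."""
        return self.pixel_pitch / self.magnification

    @property
    def fov_width_um(self) -> float:
        return self.frame_width_px * self.sample_pixel_size

    @property
    def fov_height_um(self) -> float:
        return self.frame_height_px * self.sample_pixel_size

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        return cls(**d)


@dataclass(frozen=True)
class USAFElement:
    """One group/element position on a USAF-1951 resolution target."""

    group: int
    element: int

    def __post_init__(self) -> None:
        if not (-2 <= self.group <= 9):
            raise ValueError(f"USAF group {self.group} outside -2..9")
        if not (1 <= self.element <= 6):
            raise ValueError(f"USAF element {self.element} outside 1..6")


def usaf_frequency(el: USAFElement) -> float:
    """Spatial frequency of a USAF-1951 element in line pairs / mm."""
    return 2.0 ** (el.group + (el.element - 1) / 6.0)


def resolution_from_element(el: USAFElement) -> float:
    """Optical resolution (um) implied by the smallest resolved element.

    The line-pair period (1000 um/mm divided by the element frequency)
    is divided by sqrt(2).
    """
    period_um = 1000.0 / usaf_frequency(el)
    return period_um / math.sqrt(2.0)


def theoretical_na(f_number: float) -> float:
    """Numerical aperture of an objective from its f-number (in air)."""
    if f_number <= 0:
        raise ValueError("f-number must be positive")
    return math.sin(math.atan(1.0 / (2.0 * f_number)))


def object_pixel_span(object_size_um: float, cfg: OpticalConfig) -> float:
    """Number of sensor pixels spanned by an object of given size (um)."""
    if object_size_um <= 0:
        raise ValueError("object size must be positive")
    return object_size_um * cfg.magnification / cfg.pixel_pitch


def empirical_magnification(
    known_feature_width_um: float, measured_span_px: float, pixel_pitch_um: float
) -> float:
    """Magnification from a calibration feature of known physical width."""
    if known_feature_width_um <= 0 or measured_span_px <= 0 or pixel_pitch_um <= 0:
        raise ValueError("all calibration quantities must be positive")
    return measured_span_px * pixel_pitch_um / known_feature_width_um


def imaged_volume(cfg: OpticalConfig) -> dict:
    """Geometric imaged volume vs the configured per-frame volume.

    The geometric estimate is the field of view clipped to the channel
    width, times the channel depth, converted to microlitres
    (1 uL = 1e9 um^3).  The configured ``frame_volume`` is the value
    quantitation uses; the two are reported together with a flag when
    they disagree by more than 10%.
    """
    w = min(cfg.fov_width_um, cfg.channel_width)
    h = min(cfg.fov_height_um, cfg.channel_width)
    geometric_ul = w * h * cfg.channel_depth / 1e9
    configured_ul = cfg.frame_volume
    agree = (
        configured_ul > 0
        and abs(geometric_ul - configured_ul) <= 0.10 * configured_ul
    )
    return {
        "geometric_ul": geometric_ul,
        "configured_ul": configured_ul,
        "consistent": bool(agree),
    }
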