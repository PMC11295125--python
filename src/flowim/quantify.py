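"""Cell-density quantitation with merge correction and detection limits.

Counts of classified ROIs are converted to cells/mL with volume and
dilution accounting:

    density = (in_focus + merges * occupancy) / (frames * V_frame[uL])
              * 1000 * dilution

where multi-object (merge) ROIs contribute their estimated occupancy
(mean cells per merge crop) and debris / out-of-focus ROIs are
excluded.  Detection limits follow the standard blank-based scheme:
LoB = mean + z*sd of blank false-positive densities, LoD = LoB + z*sd
of low-concentration replicates (z = 1.645, the one-sided 95th normal
quantile), and LoQ is the lowest dilution level whose replicate CV
stays within 20% with a mean at or above the LoD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .optics import OpticalConfig

Z_DEFAULT = 1.645
LOQ_CV_DEFAULT = 0.20
MERGE_OCCUPANCY_FLOOR = 2


@dataclass
class RoiClassCounts:
    """Classified ROI tallies for one sample."""

    in_focus_cells: int = 0
    out_of_focus_cells: int = 0
    debris: int = 0
    multi_object_rois: int = 0

    def __post_init__(self) -> None:
        for name in ("in_focus_cells", "out_of_focus_cells", "debris",
                     "multi_object_rois"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return (self.in_focus_cells + self.out_of_focus_cells + self.debris
                + self.multi_object_rois)


@dataclass
class ConcentrationEstimate:
    """Cells/mL decomposed into single-object and merge contributions."""

    cells_per_ml: float
    single_object_component: float
    merge_component: float
    frames_analyzed: int
    volume_per_frame: float  # uL
    dilution_factor: float = 1.0
    replicate_cv: Optional[float] = None


@dataclass
class DetectionLimits:
    lob: float
    lod: float
    loq: Optional[float]
    z: float = Z_DEFAULT
    loq_cv_criterion: float = LOQ_CV_DEFAULT

    def __post_init__(self) -> None:
        if self.lod < self.lob - 1e-9:
            raise ValueError("LoD cannot be below LoB")
        if self.loq is not None and self.loq < self.lod - 1e-9:
            raise ValueError("LoQ cannot be below LoD")


@dataclass
class DilutionSeries:
    step_factors: list

    def __post_init__(self) -> None:
        for f in self.step_factors:
            if f <= 1:
                raise ValueError("every dilution step factor must exceed 1")

    @property
    def cumulative_factors(self) -> list:
        out, acc = [], 1.0
        for f in self.step_factors:
            acc *= f
            out.append(acc)
        return out


def dilution_series(steps: Sequence[float] = (12, 10, 8, 6, 4, 2)) -> DilutionSeries:
    """A serial dilution design; default is the parabolic 12x..2x series
    whose cumulative levels are 12, 120, 960, 5760, 23040, 46080."""
    return DilutionSeries(step_factors=list(steps))


def estimate_concentration(
    counts: RoiClassCounts,
    merge_occupancy: float = float(MERGE_OCCUPANCY_FLOOR),
    frames: int = 1,
    cfg: Optional[OpticalConfig] = None,
    dilution: float = 1.0,
    volume_per_frame_ul: Optional[float] = None,
    replicate_densities: Optional[Sequence[float]] = None,
) -> ConcentrationEstimate:
    """Convert classified ROI counts to a cell density.

    Debris and out-of-focus ROIs are excluded; each multi-object ROI
    contributes ``merge_occupancy`` cells.
    """
    if frames < 1:
        raise ValueError("need at least one analyzed frame")
    if counts.multi_object_rois > 0 and merge_occupancy < MERGE_OCCUPANCY_FLOOR:
        raise ValueError(
            f"merge occupancy must be >= {MERGE_OCCUPANCY_FLOOR} when merges exist"
        )
    volume = (
        volume_per_frame_ul
        if volume_per_frame_ul is not None
        else (cfg or OpticalConfig()).frame_volume
    )
    scale = 1000.0 * dilution / (frames * volume)  # uL -> mL, dilution back-out
    single = counts.in_focus_cells * scale
    merged = counts.multi_object_rois * merge_occupancy * scale
    cv = None
    if replicate_densities is not None and len(replicate_densities) >= 2:
        arr = np.asarray(replicate_densities, dtype=float)
        cv = float(arr.std(ddof=1) / arr.mean()) if arr.mean() > 0 else float("nan")
    return ConcentrationEstimate(
        cells_per_ml=single + merged,
        single_object_component=single,
        merge_component=merged,
        frames_analyzed=frames,
        volume_per_frame=volume,
        dilution_factor=dilution,
        replicate_cv=cv,
    )


def merge_occupancy_estimate(
    merge_areas_um2: Sequence[float], median_single_area_um2: float
) -> float:
    """Mean cells per multi-object ROI from foreground-area ratios.

    Each merge ROI is assigned ``max(2, round(area / median single-cell
    area))`` occupants; the floor of 2 encodes that a merge contains at
    least two objects by definition.
    """
    if len(merge_areas_um2) == 0:
        raise ValueError("no merge ROIs to estimate occupancy from")
    if median_single_area_um2 <= 0:
        raise ValueError("median single-object area must be positive")
    occ = [
        max(MERGE_OCCUPANCY_FLOOR, int(round(a / median_single_area_um2)))
        for a in merge_areas_um2
    ]
    return float(np.mean(occ))


def limit_of_blank(
    blank_densities: Sequence[float], z: float = Z_DEFAULT
) -> float:
    """LoB = mean + z * sd of blank false-positive densities."""
    if len(blank_densities) < 2:
        raise ValueError("need at least two blank measurements")
    arr = np.asarray(blank_densities, dtype=float)
    return float(arr.mean() + z * arr.std(ddof=1))


def limit_of_detection(
    lob: float, low_sample_densities: Sequence[float], z: float = Z_DEFAULT
) -> float:
    """LoD = LoB + z * sd of low-concentration replicate densities."""
    if len(low_sample_densities) < 2:
        raise ValueError("need at least two low-sample measurements")
    arr = np.asarray(low_sample_densities, dtype=float)
    return float(lob + z * arr.std(ddof=1))


def limit_of_quantitation(
    series_estimates: Sequence[Sequence[float]],
    cv_criterion: float = LOQ_CV_DEFAULT,
    lod: float = 0.0,
) -> Optional[float]:
    """Lowest-concentration level quantifiable with acceptable precision.

    ``series_estimates`` holds replicate density estimates per dilution
    level, in any order; levels are ranked by mean density.  The LoQ is
    the mean of the lowest level whose replicate CV is within
    ``cv_criterion`` and whose mean is at or above the LoD.  Returns
    None when no level qualifies.
    """
    qualifying = []
    for reps in series_estimates:
        if len(reps) < 2:
            raise ValueError("each level needs at least two replicates")
        arr = np.asarray(reps, dtype=float)
        mean = arr.mean()
        if mean <= 0:
            continue
        cv = arr.std(ddof=1) / mean
        if cv <= cv_criterion and mean >= lod:
            qualifying.append(float(mean))
    return min(qualifying) if qualifying else None


def detection_limits(
    blank_densities: Sequence[float],
    low_sample_densities: Sequence[float],
    series_estimates: Sequence[Sequence[float]],
    z: float = Z_DEFAULT,
    cv_criterion: float = LOQ_CV_DEFAULT,
) -> DetectionLimits:
    """Compute the LoB <= LoD <= LoQ chain from calibration measurements."""
    lob = limit_of_blank(blank_densities, z=z)
    lod = limit_of_detection(lob, low_sample_densities, z=z)
    loq = limit_of_quantitation(series_estimates, cv_criterion=cv_criterion, lod=lod)
    return DetectionLimits(lob=lob, lod=lod, loq=loq, z=z,
                           loq_cv_criterion=cv_criterion)
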