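"""End-to-end sample processing: detect -> classify -> quantify.

The pipeline consumes paired bright/dark frames (real or simulated),
detects ROIs with the configured detector, extracts features, sorts
ROIs into the four quantitation classes (in-focus single cells,
out-of-focus cells, debris, multi-object crops), and converts counts
to a cell density.  Without a trained classifier the class assignment
uses transparent feature rules: debris by small foreground area,
out-of-focus by low edge sharpness, merges by foreground area well
above the single-cell median.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .config import RunConfig
from .detect import fast_detect, segment_detect
from .features import features_table
from .preprocess import MultimodalView
from .quantify import (
    RoiClassCounts,
    estimate_concentration,
    merge_occupancy_estimate,
)

# Feature-rule thresholds for the model-free classifier.
DEBRIS_MAX_AREA_UM2 = 3.0
MERGE_AREA_RATIO = 1.8  # x median single-object area: merge regardless of shape
MERGE_AREA_RATIO_BILOBED = 1.25  # x median, when the component is multi-peaked
OUT_OF_FOCUS_ENG = 0.05  # edge-noise-gradient floor for "in focus"


def _primary_peak_count(roi, min_distance: int = 6) -> int:
    """Intensity peaks inside the ROI's primary foreground component.

    Touching/overlapping cells segment to one connected component but
    keep one intensity maximum per cell; a count >= 2 marks a doublet
    that area alone cannot separate from a large single cell.
    """
    from scipy import ndimage as ndi
    from skimage.feature import peak_local_max

    from .features import segment_roi

    mask = segment_roi(roi)
    if not mask.any():
        return 0
    smoothed = ndi.gaussian_filter(roi.crop, 2.0)
    peaks = peak_local_max(
        smoothed,
        min_distance=min_distance,
        threshold_abs=0.3 * float(smoothed.max()),
        labels=mask.astype(int),
    )
    return len(peaks)


def classify_rois_by_rules(feats, rois=None) -> list[str]:
    """Rule-based four-way ROI classification.

    Debris by small foreground area; out-of-focus by low edge
    sharpness; multi-object crops by foreground area well above the
    single-cell median, or moderately above it when the component
    carries two or more intensity peaks (an overlapping doublet).
    """
    areas = feats["area"].to_numpy()
    keep = areas > DEBRIS_MAX_AREA_UM2
    median_area = float(np.median(areas[keep])) if keep.any() else float("inf")
    out = []
    for pos, (_, row) in enumerate(feats.iterrows()):
        if row["area"] <= DEBRIS_MAX_AREA_UM2:
            out.append("debris")
        elif row["area"] >= MERGE_AREA_RATIO * median_area:
            out.append("multi_object")
        elif (
            rois is not None
            and row["area"] >= MERGE_AREA_RATIO_BILOBED * median_area
            and _primary_peak_count(rois[pos]) >= 2
        ):
            out.append("multi_object")
        elif row["edge_noise_gradient"] < OUT_OF_FOCUS_ENG:
            out.append("out_of_focus")
        else:
            out.append("in_focus")
    return out


def run_pipeline(
    views: Sequence[MultimodalView],
    cfg: RunConfig,
    classifier: Optional[Callable] = None,
) -> dict:
    """Process a set of fields of view into a per-sample report.

    Parameters
    ----------
    views : paired frames, one per field of view
    cfg : run configuration (detector choice, optics, quantitation)
    classifier : optional callable mapping a feature table to a list of
        labels in {"in_focus", "out_of_focus", "debris", "multi_object"};
        defaults to :func:`classify_rois_by_rules`.

    Returns a JSON-serializable report with ROI counts by class, the
    density estimate, and stage timings.
    """
    detect_fn = fast_detect if cfg.detector == "fast" else segment_detect
    timings = {}

    t0 = time.perf_counter()
    all_rois = []
    for view in views:
        all_rois.extend(detect_fn(view, **cfg.detector_params))
    timings["detect_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    feats = features_table(all_rois, cfg.optical)
    timings["features_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if len(feats) == 0:
        labels = []
    elif classifier is not None:
        labels = list(classifier(feats))
    else:
        labels = classify_rois_by_rules(feats, [all_rois[i] for i in feats.index])
    timings["classify_s"] = time.perf_counter() - t0

    counts = RoiClassCounts(
        in_focus_cells=labels.count("in_focus"),
        out_of_focus_cells=labels.count("out_of_focus"),
        debris=labels.count("debris"),
        multi_object_rois=labels.count("multi_object"),
    )

    merge_areas = [
        feats.iloc[i]["area"] for i, lab in enumerate(labels) if lab == "multi_object"
    ]
    single_areas = [
        feats.iloc[i]["area"] for i, lab in enumerate(labels) if lab == "in_focus"
    ]
    occupancy = float(cfg.merge_occupancy_floor)
    if merge_areas and single_areas:
        occupancy = merge_occupancy_estimate(
            merge_areas, float(np.median(single_areas))
        )

    est = estimate_concentration(
        counts,
        merge_occupancy=occupancy,
        frames=max(1, len(views)),
        cfg=cfg.optical,
        dilution=cfg.dilution_factor,
    )

    return {
        "frames_analyzed": len(views),
        "rois_detected": len(all_rois),
        "roi_counts": {
            "in_focus_cells": counts.in_focus_cells,
            "out_of_focus_cells": counts.out_of_focus_cells,
            "debris": counts.debris,
            "multi_object_rois": counts.multi_object_rois,
        },
        "merge_occupancy": occupancy,
        "cells_per_ml": est.cells_per_ml,
        "single_object_component": est.single_object_component,
        "merge_component": est.merge_component,
        "volume_per_frame_ul": est.volume_per_frame,
        "dilution_factor": est.dilution_factor,
        "detector": cfg.detector,
        "timings": timings,
    }


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
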