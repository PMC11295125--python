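"""Detection-error scoring against annotated ground truth.

Mimics hemocytometer-style manual scoring: the frame is tiled into
counting squares, and every detector ROI is assigned to one of five
classes by how much of each annotated object's mask it encapsulates:

* **correct** — the primary object is >= 90% inside the box and no
  second object is >= 50% inside;
* **split** — the primary object is < 90% inside (the object was cut);
* **merge** — primary >= 90% plus at least one additional object
  >= 50% inside (a multi-object crop);
* **false positive** — the box contains no object pixels at all;
* **false negative** — an object intersected by no ROI.

An ROI that is split-like and merge-like at once counts as a split
(the costlier error takes precedence).  All counts are normalized by
the number of valid annotated objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .detect import BBox, ROI

ENCAPSULATION_CORRECT = 0.9  # primary object fraction needed for a clean crop
ENCAPSULATION_MERGE = 0.5    # secondary object fraction that makes a merge


@dataclass
class AnnotatedObject:
    """Ground-truth object: a binary mask placed at ``origin`` (row, col)."""

    id: int
    center: tuple  # (row, col) in frame coordinates
    mask: np.ndarray  # local boolean mask
    origin: tuple = (0, 0)  # (row0, col0) of the mask in the frame
    valid: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("annotated object mask must be non-empty")

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def intersection_area(self, box: BBox) -> int:
        """Pixels of this object's mask inside a rectangle."""
        r0, c0 = self.origin
        y0 = max(box.y0, r0) - r0
        y1 = min(box.y1, r0 + self.mask.shape[0]) - r0
        x0 = max(box.x0, c0) - c0
        x1 = min(box.x1, c0 + self.mask.shape[1]) - c0
        if y1 <= y0 or x1 <= x0:
            return 0
        return int(self.mask[y0:y1, x0:x1].sum())


@dataclass
class DetectionScore:
    """Five-way detection error tally, normalized by valid object count."""

    total_objects: int
    correct: int = 0
    false_positives: int = 0
    false_negatives: int = 0
    merges: int = 0
    splits: int = 0

    @property
    def normalized(self) -> dict:
        if self.total_objects == 0:
            return {k: float("nan") for k in
                    ("correct", "false_positives", "false_negatives", "merges", "splits")}
        t = self.total_objects
        return {
            "correct": self.correct / t,
            "false_positives": self.false_positives / t,
            "false_negatives": self.false_negatives / t,
            "merges": self.merges / t,
            "splits": self.splits / t,
        }

    @property
    def undefined(self) -> bool:
        return self.total_objects == 0

    def to_dict(self) -> dict:
        d = {
            "total_objects": self.total_objects,
            "correct": self.correct,
            "false_positives": self.false_positives,
            "false_negatives": self.false_negatives,
            "merges": self.merges,
            "splits": self.splits,
        }
        d["normalized"] = self.normalized
        return d


def mask_to_rle(mask: np.ndarray) -> dict:
    """Row-major run-length encoding of a boolean mask (starts with the
    count of leading zeros, alternating zero/one runs)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    changes = np.flatnonzero(np.diff(flat))
    bounds = np.concatenate(([0], changes + 1, [flat.size]))
    counts = np.diff(bounds).tolist()
    if flat.size and flat[0]:
        counts = [0] + counts
    return {"shape": list(mask.shape), "counts": counts}


def rle_to_mask(rle: dict) -> np.ndarray:
    shape = tuple(rle["shape"])
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, val = 0, False
    for run in rle["counts"]:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    return flat.reshape(shape)


def make_grid(frame_shape: tuple, tile: int) -> list[BBox]:
    """Tile a frame into non-overlapping ``tile x tile`` counting squares.

    Tiles are emitted row-major; partial remainders at the right/bottom
    edges are excluded (a frame smaller than one tile yields none).
    """
    if tile <= 0:
        raise ValueError("tile size must be positive")
    h, w = frame_shape
    tiles = []
    for r in range(h // tile):
        for c in range(w // tile):
            tiles.append(BBox(c * tile, r * tile, (c + 1) * tile, (r + 1) * tile))
    return tiles


def score_detections(
    truth: list[AnnotatedObject], rois: list[ROI] | list[BBox]
) -> DetectionScore:
    """Score detector ROIs against annotated objects.

    Encapsulation of object *o* by ROI *r* is
    ``|mask(o) inside bbox(r)| / |mask(o)|``.  The primary object of an
    ROI is the one with the highest encapsulation (ties broken toward
    the lower object id).  Invalid objects are ignored entirely.
    """
    objects = [o for o in truth if o.valid]
    boxes = [r.bbox if isinstance(r, ROI) else r for r in rois]
    score = DetectionScore(total_objects=len(objects))

    touched = np.zeros(len(objects), dtype=bool)
    areas = np.array([o.area for o in objects], dtype=float)

    for box in boxes:
        if not objects:
            score.false_positives += 1
            continue
        inter = np.array([o.intersection_area(box) for o in objects], dtype=float)
        frac = inter / areas
        touched |= inter > 0
        if not np.any(frac > 0):
            score.false_positives += 1
            continue
        primary = int(np.argmax(frac))  # argmax is first-max: lower id wins ties
        if frac[primary] < ENCAPSULATION_CORRECT:
            score.splits += 1
        else:
            others = np.delete(frac, primary)
            if np.any(others >= ENCAPSULATION_MERGE):
                score.merges += 1
            else:
                score.correct += 1

    score.false_negatives = int(np.count_nonzero(~touched))
    return score


def score_by_tile(
    truth: list[AnnotatedObject],
    rois: list[ROI],
    frame_shape: tuple,
    tile: int = 800,
) -> list[dict]:
    """Per-counting-square scores: objects/ROIs are assigned to the tile
    containing their center."""
    tiles = make_grid(frame_shape, tile)
    out = []
    for t in tiles:
        objs = [
            o for o in truth
            if t.y0 <= o.center[0] < t.y1 and t.x0 <= o.center[1] < t.x1
        ]
        in_tile = []
        for r in rois:
            cy = (r.bbox.y0 + r.bbox.y1) / 2
            cx = (r.bbox.x0 + r.bbox.x1) / 2
            if t.y0 <= cy < t.y1 and t.x0 <= cx < t.x1:
                in_tile.append(r)
        s = score_detections(objs, in_tile)
        out.append({"tile": (t.x0, t.y0, t.x1, t.y1), "score": s.to_dict()})
    return out
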