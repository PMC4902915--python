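"""Majority-vote fusion of the eight method masks into one plant detection.

A pixel belongs to the composite mask when at least ``min_votes`` (default 4)
of the eight method masks contain it; of the resulting foreground only the
largest connected object is kept.  Counting votes in integers is exactly
equivalent to accumulating each mask at 256/8 = 32 of a 255-maximum
intensity image and thresholding at 128 (4 x 32 = 128), without 8-bit
rounding ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging import RasterImage, largest_component
from .segmentation import METHOD_NAMES, MaskSet

__all__ = ["PlantDetection", "composite_vote", "overlay_outline", "validate_detection"]

STATUS_OK = "ok"
STATUS_EMPTY = "empty"
STATUS_IMPLAUSIBLE = "implausible"


@dataclass
class PlantDetection:
    """Composite mask, per-pixel vote image and summary for one image."""

    vote_image: np.ndarray            # uint8 counts 0-8
    composite: np.ndarray             # bool mask, largest >= min_votes object
    area_px: int
    outline: np.ndarray               # (n, 2) boundary pixel coordinates (row, col)
    status: str
    image_id: str = ""

    def vote_histogram(self) -> np.ndarray:
        """Pixel counts for each vote level 0..8."""
        return np.bincount(self.vote_image.ravel(), minlength=9)


def composite_vote(masks: MaskSet, min_votes: int = 4) -> PlantDetection:
    """Fuse a complete MaskSet by per-pixel majority vote."""
    if not 1 <= min_votes <= 8:
        raise ValueError("min_votes must be in 1..8")
    votes = np.zeros(masks.shape, dtype=np.uint8)
    for name in METHOD_NAMES:
        votes += masks[name].astype(np.uint8)
    composite = largest_component(votes >= min_votes)
    area = int(composite.sum())
    outline = _boundary(composite)
    status = STATUS_OK if area > 0 else STATUS_EMPTY
    return PlantDetection(
        vote_image=votes,
        composite=composite,
        area_px=area,
        outline=outline,
        status=status,
        image_id=masks.image_id,
    )


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with a 4-neighbour outside the mask (outer edge ring)."""
    if not mask.any():
        return np.empty((0, 2), dtype=np.int64)
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return np.argwhere(mask & ~interior)


def overlay_outline(
    rgb: RasterImage, det: PlantDetection, colour: tuple[int, int, int] = (255, 0, 0)
) -> RasterImage:
    """Recolour the detection boundary on a copy of the input image."""
    rgb.require("RGB8")
    if rgb.shape != det.composite.shape:
        raise ValueError("image and detection shapes differ")
    out = rgb.pixels.copy()
    if det.outline.size:
        out[det.outline[:, 0], det.outline[:, 1]] = colour
    return RasterImage(out, "RGB8")


def validate_detection(
    det: PlantDetection,
    truth: np.ndarray | None = None,
    iou_min: float = 0.8,
    border_frac_max: float = 0.25,
    frame_frac_max: float = 0.60,
) -> str:
    """Automatic plausibility check, standing in for visual inspection.

    With a ground-truth mask the detection is ``ok`` iff its
    intersection-over-union with the truth reaches ``iou_min``.  Without
    truth, a heuristic flags detections that are empty, hug more than
    ``border_frac_max`` of the frame border, or cover more than
    ``frame_frac_max`` of the frame.  The resulting status is also stored
    on the detection.
    """
    comp = det.composite
    if not comp.any():
        det.status = STATUS_EMPTY
        return det.status
    if truth is not None:
        truth = np.asarray(truth, dtype=bool)
        inter = np.logical_and(comp, truth).sum()
        union = np.logical_or(comp, truth).sum()
        iou = inter / union if union else 0.0
        det.status = STATUS_OK if iou >= iou_min else STATUS_IMPLAUSIBLE
        return det.status
    rows, cols = comp.shape
    border = np.concatenate([comp[0], comp[-1], comp[:, 0], comp[:, -1]])
    border_frac = border.mean()
    frame_frac = comp.mean()
    if border_frac > border_frac_max or frame_frac > frame_frac_max:
        det.status = STATUS_IMPLAUSIBLE
    else:
        det.status = STATUS_OK
    return det.status


def intersection_over_union(a: np.ndarray, b: np.ndarray) -> float:
    """IoU of two binary masks (0 when both are empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)
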