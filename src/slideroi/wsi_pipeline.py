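"""End-to-end ROI detection on a slide and evaluation against annotators.

Stages run in fixed order: tiling -> screening -> classification of the
surviving candidate blocks. Screened-out blocks (empty, artifact, poor
quality) are never passed to the classifier.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation_consensus import annotator_covers
from .pyramid import (
    BlockState,
    ROIMap,
    SlidePyramid,
    TileBlock,
    read_block_image,
    round_half_up,
    tile_grid,
)
from .synthetic_slide import AnnotationSet
from .tile_screen import ScreenConfig, screen_block

__all__ = [
    "AffineTransform",
    "DetectionEvaluation",
    "SingularTransformError",
    "detect_rois",
    "evaluate_detection",
    "transfer_coordinates",
]

logger = logging.getLogger(__name__)


class SingularTransformError(ValueError):
    pass


def detect_rois(
    slide: SlidePyramid,
    classifier,
    magnification: float = 10.0,
    config: ScreenConfig | None = None,
    threshold: float = 0.5,
) -> ROIMap:
    """Screen and classify every block of a slide at one magnification.

    ``classifier`` must expose ``predict_proba(images) -> p(positive)`` and
    may carry a ``magnification`` attribute; a mismatch with the requested
    magnification is an error.
    """
    clf_mag = getattr(classifier, "magnification", None)
    if clf_mag is not None and clf_mag != magnification:
        raise ValueError(
            f"classifier trained at {clf_mag}x but detection requested at "
            f"{magnification}x"
        )
    config = config or ScreenConfig()
    blocks = tile_grid(slide, magnification)
    candidates: list[TileBlock] = []
    for block in blocks:
        block.state = screen_block(slide, block, config)
        if block.state == BlockState.CANDIDATE:
            candidates.append(block)
    if candidates:
        images = np.stack(
            [read_block_image(slide, b, at_mag=magnification) for b in candidates]
        )
        probs = np.asarray(classifier.predict_proba(images))
        for block, p in zip(candidates, probs):
            block.state = (
                BlockState.REPRESENTATIVE
                if p >= threshold
                else BlockState.NON_REPRESENTATIVE
            )
    roi_map = ROIMap(slide.slide_id, magnification, blocks)
    logger.info("detect_rois %s: %s", slide.slide_id, roi_map.counts())
    return roi_map


@dataclass
class DetectionEvaluation:
    """Block-level comparison of detections with three annotators.

    False-positive subtypes: type1 = method + 2 annotators, type2 = method +
    1 annotator, type3 = method only.
    """

    true_positives: int = 0
    false_negatives: int = 0
    false_positives_by_type: dict[str, int] = field(
        default_factory=lambda: {"type1": 0, "type2": 0, "type3": 0}
    )

    @property
    def false_positives(self) -> int:
        return sum(self.false_positives_by_type.values())


def evaluate_detection(
    roi_map: ROIMap,
    annotations: Sequence[AnnotationSet],
    min_overlap: float = 0.5,
) -> DetectionEvaluation:
    """Fig-4-style taxonomy; defined for exactly three annotators."""
    if len(annotations) != 3:
        raise ValueError(f"taxonomy requires 3 annotation sets, got {len(annotations)}")
    ev = DetectionEvaluation()
    for block in roi_map.blocks:
        n_marked = sum(annotator_covers(block, a, min_overlap) for a in annotations)
        detected = block.state == BlockState.REPRESENTATIVE
        if detected and n_marked == 3:
            ev.true_positives += 1
        elif detected:
            ev.false_positives_by_type[f"type{3 - n_marked}"] += 1
        elif n_marked == 3:
            ev.false_negatives += 1
    return ev


@dataclass(frozen=True)
class AffineTransform:
    """2x3 affine map (x', y') = (a x + b y + tx, c x + d y + ty)."""

    a: float = 1.0
    b: float = 0.0
    c: float = 0.0
    d: float = 1.0
    tx: float = 0.0
    ty: float = 0.0

    @property
    def determinant(self) -> float:
        return self.a * self.d - self.b * self.c

    def apply(self, x: float, y: float) -> tuple[int, int]:
        return (
            round_half_up(self.a * x + self.b * y + self.tx),
            round_half_up(self.c * x + self.d * y + self.ty),
        )

    def inverse(self) -> "AffineTransform":
        det = self.determinant
        if abs(det) < 1e-12:
            raise SingularTransformError("affine transform is singular")
        ia, ib, ic, id_ = self.d / det, -self.b / det, -self.c / det, self.a / det
        return AffineTransform(
            ia, ib, ic, id_, -(ia * self.tx + ib * self.ty), -(ic * self.tx + id_ * self.ty)
        )

    @classmethod
    def from_json(cls, path) -> "AffineTransform":
        with open(path) as fh:
            return cls(**json.load(fh))


def transfer_coordinates(roi_map: ROIMap, transform: AffineTransform) -> ROIMap:
    """Copy block states into a registered serial-slide frame."""
    if abs(transform.determinant) < 1e-12:
        raise SingularTransformError("affine transform is singular")
    blocks = []
    for b in roi_map.blocks:
        x, y = transform.apply(b.origin_x, b.origin_y)
        blocks.append(
            TileBlock(
                slide_id=b.slide_id,
                grid_row=b.grid_row,
                grid_col=b.grid_col,
                magnification=b.magnification,
                origin_x=x,
                origin_y=y,
                size=b.size,
                state=b.state,
            )
        )
    return ROIMap(roi_map.slide_id, roi_map.magnification, blocks)
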